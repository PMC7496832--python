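"""Habitat-suitability thresholding and multi-species climate-refugia stacking.

Suitability probability rasters (from upstream ensemble niche models) are
binarised at the threshold maximising sensitivity + specificity (MSS) on
presence/absence calibration points. A cell is a climate refugium for a
species when it is suitable under both present-day and future conditions;
stacking the per-species refugium maps gives the per-cell count of species
retaining suitable habitat — assemblage-level climate refugia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, ValidationError


@dataclass
class SuitabilityMap:
    """Per-cell suitability probabilities for one species and period."""

    species: str
    period: str                      # "present" or "future"
    probability: np.ndarray
    grid: Grid | None = None
    scenario: str = ""

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float)
        finite = np.isfinite(self.probability)
        if np.any((self.probability[finite] < 0) | (self.probability[finite] > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.period not in ("present", "future"):
            raise ValidationError("period must be 'present' or 'future'")


@dataclass
class RefugiaStack:
    """Per-cell count of species whose refugium map is true."""

    species: list[str]
    counts: np.ndarray

    def __post_init__(self):
        n = len(self.species)
        if self.counts.min() < 0 or self.counts.max() > n:
            raise ValidationError("counts must lie in [0, n_species]")


def mss_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity (MSS).

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores, plus 0 and 1; classification is ``score >= threshold`` =>
    suitable. On a tied plateau of consecutive optimal candidates the
    plateau midpoint is returned, which is deterministic and centres the
    threshold in the optimal score gap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be matching 1-D arrays")
    if np.any((scores < 0) | (scores > 1)):
        raise ValidationError("scores must lie in [0, 1]")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both presence and absence labels are required")

    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    objective = np.array([_sens_spec_sum(scores, labels, t) for t in candidates])
    best = objective.max()
    optimal = np.flatnonzero(np.isclose(objective, best, rtol=0, atol=1e-12))
    # plateau midpoint: centre of the first contiguous optimal run
    run_end = optimal[0]
    for idx in optimal[1:]:
        if idx == run_end + 1:
            run_end = idx
        else:
            break
    return float(0.5 * (candidates[optimal[0]] + candidates[run_end]))


def _sens_spec_sum(scores, labels, threshold) -> float:
    pred = scores >= threshold
    pos = labels == 1
    sens = (pred & pos).sum() / pos.sum()
    spec = (~pred & ~pos).sum() / (~pos).sum()
    return float(sens + spec)


def binarize(suitability: SuitabilityMap | np.ndarray, threshold: float) -> np.ndarray:
    """Binary suitability: cell true iff probability >= threshold.

    The comparison is non-strict at the threshold (>=), which matters for
    boundary cells and is therefore stated explicitly.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    prob = (suitability.probability if isinstance(suitability, SuitabilityMap)
            else np.asarray(suitability, dtype=float))
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(prob), prob >= threshold, False)


def refugium_map(present_binary: np.ndarray,
                 future_binary: np.ndarray) -> np.ndarray:
    """Cells suitable under both present and future conditions (logical AND)."""
    present_binary = np.asarray(present_binary, dtype=bool)
    future_binary = np.asarray(future_binary, dtype=bool)
    if present_binary.shape != future_binary.shape:
        raise ValidationError("present/future maps on different grids")
    return present_binary & future_binary


def stack_refugia(refugium_maps: dict[str, np.ndarray] | list[np.ndarray],
                  species: list[str] | None = None) -> RefugiaStack:
    """Per-cell count of species with refugium = true.

    Order-independent and additive: stacking the union of two disjoint
    species sets equals the sum of their stacks.
    """
    if isinstance(refugium_maps, dict):
        species = list(refugium_maps.keys())
        maps = [np.asarray(refugium_maps[s], dtype=bool) for s in species]
    else:
        maps = [np.asarray(m, dtype=bool) for m in refugium_maps]
        species = species or [f"species_{i:02d}" for i in range(len(maps))]
    if len(maps) < 1:
        raise ValidationError("need at least one species")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValidationError("refugium maps on different grids")
    counts = np.sum(maps, axis=0).astype(int)
    return RefugiaStack(species=species, counts=counts)
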