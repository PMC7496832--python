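"""Vent-to-vent larval transport frequencies under a circulation change.

Passive particles are released monthly from synthetic vent sites into a
time-varying double-gyre flow and tracked for 180 days at a fixed dispersal
depth. Transport frequencies (fraction of release events connecting a source
to a destination within a 50-km capture radius) are computed for a control
and a strengthened-circulation scenario, and every vent pair is classified:
enhanced (>100% increase), reduced (<50% reduction), lost, or novel.
"""

import numpy as np

import deepsea_exposure as dse
from deepsea_exposure.synthetic import FlowSpec

grid = dse.regular_grid(21, 21, lat_range=(-10, 10), lon_range=(-10, 10))
sites = dse.gen_vent_sites(grid, n_sites=5, seed=0)
release_times = tuple(30.0 * i for i in range(6))
times = np.arange(0.0, release_times[-1] + 211.0, 15.0)
spec = dse.ReleaseSpec(particles_per_release=5,
                       release_times_days=release_times,
                       duration_days=180.0, dt_hours=6.0,
                       diffusivity_m2s=100.0, capture_radius_km=50.0, seed=0)

matrices = {}
for label, amplitude in (("control", 0.10), ("future", 0.18)):
    flow = FlowSpec(kind="double_gyre", amplitude=amplitude, period_days=30.0)
    field = dse.gen_velocity_field(flow, grid, times)
    traj = dse.advect_particles(field, sites, spec)
    matrices[label] = dse.transport_frequency(traj, sites, spec)
    print(f"{label:8s} mean transport frequency: "
          f"{matrices[label].P.mean():.3f} over {len(sites)}x{len(sites)} "
          f"vent pairs, {len(release_times)} release events")

delta = dse.compare_scenarios(matrices["future"], matrices["control"])
for cls in ("enhanced", "reduced", "lost", "novel"):
    print(f"{cls:9s} connections: {delta.count(cls)}")
# 'lost' pairs were connected in the control run but never in the future
# run; 'enhanced' pairs more than doubled their transport frequency.
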