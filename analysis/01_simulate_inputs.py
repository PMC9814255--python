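#!/usr/bin/env python
"""Generate example synthetic inputs for every pipeline stage.

Writes a small set of breathing+event bond-series files, an opening-angle
ensemble, a stepwise double-proton-transfer reaction path, and an
energy-level table under results/synthetic/.  Later analysis steps generate
their own (larger) ensembles in memory with fixed seeds; these files exist
so every on-disk format the pipeline reads has a concrete example.
"""

from pathlib import Path

import numpy as np

from bpopen.energetics import write_energy_levels
from bpopen.io import write_bond_series
from bpopen.synthetic import (
    BreathingConfig,
    EventConfig,
    MixtureConfig,
    gen_angle_mixture,
    gen_energy_levels,
    gen_event_ensemble,
    gen_reaction_path,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2024

series = gen_event_ensemble(
    3, BreathingConfig(), EventConfig(speed=1.2), seed=SEED
)
for s in series:
    write_bond_series(s, OUT / f"bonds_{s.replica_id}.csv")

mixture = gen_angle_mixture(MixtureConfig(n=2000, seed=SEED))
np.savetxt(OUT / "opening_angles_deg.txt", mixture.thetas, fmt="%.10g",
           header="signed opening angle (degrees), one event per line")

path = gen_reaction_path(n_images=29, transfer_q_b1=0.8, transfer_q_b2=0.2)
path.to_xyz(OUT / "dpt_path.xyz")

levels = gen_energy_levels(separations=[0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
                           slope1=1.41)
write_energy_levels(levels, OUT / "energy_levels.csv")

print(f"wrote {len(series)} bond series, 1 angle ensemble (n={mixture.n}), "
      f"1 reaction path (29 images), 1 level table -> {OUT}")
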