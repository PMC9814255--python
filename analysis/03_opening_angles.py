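#!/usr/bin/env python
"""Bimodal opening-angle statistics of separation events.

Draws 2000 event angles from the calibrated two-mode mixture (modes +18.9
and -17.4 degrees, component sd 5 degrees, negative-mode weight 0.39) and
recovers the mode locations, the asymmetric-event fraction (|theta| > 3
degrees) and the fraction opening in the negative (electronic-structure
favoured) direction.
"""

import json
from pathlib import Path

from bpopen.angles import asymmetric_fraction, directional_fraction, estimate_modes
from bpopen.synthetic import MixtureConfig, gen_angle_mixture

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 7

ens = gen_angle_mixture(MixtureConfig(n=2000, seed=SEED))
pos, neg = estimate_modes(ens, seed=SEED)
asym, asym_ci = asymmetric_fraction(ens, threshold=3.0, seed=SEED)
direc, direc_ci = directional_fraction(ens, threshold=3.0, seed=SEED)

summary = {
    "n_events": ens.n,
    "mode_positive_deg": pos.location,
    "mode_positive_stderr_deg": pos.location_stderr,
    "mode_negative_deg": neg.location,
    "mode_negative_stderr_deg": neg.location_stderr,
    "asymmetric_fraction": asym,
    "asymmetric_fraction_ci95": list(asym_ci),
    "directional_fraction": direc,
    "directional_fraction_ci95": list(direc_ci),
}
(OUT / "angle_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

print(f"positive mode : {pos.location:+.2f} +/- {pos.location_stderr:.2f} deg "
      "(generator +18.90)")
print(f"negative mode : {neg.location:+.2f} +/- {neg.location_stderr:.2f} deg "
      "(generator -17.40)")
print(f"|theta| > 3 deg : {100*asym:.1f}% of events")
print(f"negative-mode share : {100*direc:.1f}% (generator 39.0%)")
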