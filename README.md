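# bpopen — base-pair opening analysis for G–C strand separation

When the DNA double helix is pulled apart — by a helicase, or by a steering
force in simulation — individual G–C base pairs open on picosecond
timescales.  If a double proton transfer (DPT) along the B1 and B2 hydrogen
bonds happens first, the pair separates as the rare tautomer G\*–C\*, which
mispairs at replication.  Whether that matters hinges on desk-scale
quantities extracted from expensive simulations: how fast a pair separates,
how asymmetrically it opens, and how the DPT barriers and step ordering
change with separation.

`bpopen` implements those extractions as a tested, reusable library for
people analysing steered-MD hydrogen-bond time series and
electronic-structure reaction paths:

* **Separation kinetics** — from the three bond-length series
  (B1 = DG:O6–DC:N4, B2 = DG:N1–DC:N1, B3 = DG:N2–DC:O2) build the
  separation metric s(t) = mean bond extension, detect above-noise
  excursions, fit the first 2 Å of each with OLS, discard fits with
  negative slope or relative slope error > 5%, and pool speeds per force
  and base pair.
* **Opening angles** — the signed angle θ between G = DG:N2→DG:O6 and
  C = DC:O2→DC:N4 (sign from the cross product against the helix axis);
  KDE mode locations of the bimodal θ distribution, the asymmetric-event
  fraction (|θ| > 3°) and the fraction opening in the negative,
  quantum-chemistry-favoured direction.
* **DPT bookkeeping** — the asynchronicity
  α = |α_B1 − α_B2| / ‖q_IRC‖ of the two proton hops along a reaction
  path, forward/reverse barriers and reaction asymmetry from
  stationary-state energy levels, the barrier-vs-separation trend, and the
  tautomer survival threshold d/v.
* **Synthetic data** — Ornstein–Uhlenbeck breathing, ramp events with a
  prescribed implied θ, calibrated bimodal angle mixtures, stepwise
  reaction paths and linear-trend level tables, all bit-reproducible by
  seed, so every stage is testable without MD or DFT.

## Worked example

```python
from bpopen import (BreathingConfig, EventConfig, MixtureConfig,
                    gen_event_ensemble, gen_angle_mixture, run_pipeline,
                    estimate_modes, directional_fraction,
                    published_levels_eq, barrier_summary, survival_threshold)

# 200 synthetic steered-MD replicas, one 1.2 A/ps event each
series = gen_event_ensemble(200, BreathingConfig(), EventConfig(speed=1.2),
                            seed=2024)
res = run_pipeline(series)
print(f"pooled speed {res.pooled.mean_speed:.3f} +/- {res.pooled.stderr_speed:.3f} A/ps")
print(f"survival bound {survival_threshold(2.0, res.pooled.mean_speed):.2f} ps")

# bimodal opening-angle statistics
ens = gen_angle_mixture(MixtureConfig(n=2000, seed=7))
pos, neg = estimate_modes(ens, seed=7)
frac, _ = directional_fraction(ens, seed=7)
print(f"modes {pos.location:+.2f} / {neg.location:+.2f} deg, "
      f"negative share {100*frac:.1f}%")

# stepwise-DPT barriers at zero separation
s = barrier_summary(published_levels_eq())
print(f"forward barrier {s.forward_1:.3f} eV, asymmetry {s.asymmetry:.3f} eV")
```

prints

```
pooled speed 1.203 +/- 0.004 A/ps
survival bound 1.66 ps
modes +19.16 / -17.66 deg, negative share 39.6%
forward barrier 0.574 eV, asymmetry 0.507 eV
```

i.e. the pipeline recovers the generator's 1.2 Å ps⁻¹ separation speed
within one standard error — implying a tautomer must live ~1.7 ps to
outlast a 2 Å opening — locates both angle modes within ~0.3° of the
generating mixture (+18.9°/−17.4°, negative weight 39%), and the
zero-separation level table yields a 0.574 eV first barrier with a
0.507 eV reaction asymmetry.

The numbered drivers under `analysis/` run the same stages as a narrative
sequence (`01_simulate_inputs.py` … `05_energetics.py`) and write their
tables under `results/`.  A thin CLI wraps the library for shell use:

```bash
bpopen simulate --n-series 10 --seed 3 --out-dir synth/
bpopen run synth/ --report report.json
bpopen async --path dpt_path.xyz --b1-atom H41 --b2-atom H1
bpopen barriers --levels levels.csv
```

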