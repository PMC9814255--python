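# Methods

`bpopen` packages the desk-scale computations around G–C base-pair strand
separation and tautomerisation: separation-event kinetics from hydrogen-bond
time series, opening-angle statistics, and the energetics/asynchronicity
bookkeeping of the double proton transfer (DPT).  The expensive producers of
the raw data — steered molecular dynamics and electronic-structure reaction
paths — are out of scope; a synthetic generator emulates their outputs with
known ground truth so every stage is testable end to end.

## Separation metric and event kinetics

A run supplies the lengths of the three G–C hydrogen bonds
(B1 = DG:O6–DC:N4, B2 = DG:N1–DC:N1, B3 = DG:N2–DC:O2) at a constant time
step.  The scalar separation metric is the mean bond extension

    s(t) = (1/3) Σ_b [ r_b(t) − r_b^eq ].

Equilibrium lengths default to the per-bond median over the leading 10% of
frames (the pre-steering baseline); fixed values, e.g. the
electronic-structure equilibria 2.89/2.96/2.89 Å, can be configured instead.
The two conventions differ because force-field and quantum equilibria
differ; the baseline median is the default because it matches the
trajectory actually being analysed.

**Noise floor.**  No closed-form floor accompanies the procedure the
analysis follows, so a robust estimate is used:
`floor = median(s) + 3 × 1.4826 × MAD(s | s < Q90)`.  The 90th-percentile
clip keeps genuine separation ramps from inflating the floor (verified by
simulation: one large ramp shifts the floor by < 25%); the scaled MAD is
the robust sigma of the breathing noise.  The floor is overridable.

**Event windows.**  An event is one contiguous excursion of s(t) above its
baseline (series median) whose peak clears the noise floor.  The fit window
runs from the first frame at or above the noise floor to the first frame at
or above the 2.0 Å fit limit (beyond which the bonds are considered
broken); events that never reach the limit are fitted to their peak and
flagged `partial`.  The excursion's last baseline up-crossing is kept as
`onset_index` metadata but deliberately does **not** open the fit window:
with correlated breathing noise (OU, τ = 1 ps) the last baseline crossing
precedes lift-off by O(τ) of flat baseline, and including those frames
biases fitted speeds low by about 1% — several pooled standard errors at
ensemble size 200.  Opening at the floor crossing removes the bias (any
sub-window of a linear ramp estimates the same slope) and was validated by
window-decomposition simulations against oracle windows.

**Speed fits and filters.**  The speed is the OLS slope of s(t) over the
window, with the usual residual-variance standard error.  Fits with
non-positive slope are discarded (`negative_slope`), as are fits whose
relative standard error exceeds 5% (`high_uncertainty`).  Filtering is per
event, before pooling.  Group statistics (per force and base pair) and the
pooled statistic are arithmetic means with standard errors s/√n; a
single-event group reports SE 0 with a warning.

**Smoothing.**  A Savitzky–Golay filter (window 63 frames, polynomial
order 2) is available and is exact on polynomials of degree ≤ 2 at interior
points.  The pipeline *detects and fits on the raw metric by default*
(`fit_on="raw"`).  Reason: at the synthetic sampling interval of 0.1 ps the
63-frame window spans 6.3 ps, several times the ~1.7 ps a 1.2 Å ps⁻¹ event
needs to cross 2 Å.  Smoothing a ramp foot with a window longer than the
event rounds the onset upward by up to ~0.35 Å, the fit window then starts
inside the distorted foot, and recovered speeds drop by tens of percent.
`fit_on="smoothed"` restores the literal smooth-first procedure and is
appropriate when frames are saved densely enough that the window is short
relative to events.

## Opening angle

The signed opening angle θ measures how asymmetrically the pair opens:
its magnitude is the angle between G = DG:N2→DG:O6 and C = DC:O2→DC:N4,
and the sign is negative when (G × C) is anti-aligned with the
caller-supplied helix axis (no axis-inference procedure is attempted).
θ < 0 corresponds to B1 staying closed while B3 opens.  A vanishing cross
product (parallel vectors) is the symmetric limit and takes sign +.
Angles are reported in degrees.  Each event contributes one θ, by default
at its onset frame (first frame at or above the noise floor); `peak` and
`mean-over-event` are configurable alternatives.

**Mode estimation.**  The event-angle distribution is bimodal.  The
ensemble is partitioned at θ = 0 (exact zeros excluded) and each side's
mode is the argmax of a Gaussian-kernel KDE evaluated on a fine grid with
parabolic refinement.  The bandwidth is h = 2 σ̂ n^(−1/7), not a
density-oriented rule: Silverman's h ∝ n^(−1/5) minimises density L2 error
but undersmooths for locating the argmax — at the study conditions
(n = 2000, component sd 5°) it leaves the mode estimate with a sampling sd
of ~0.7°, larger than the ~0.5° precision the recovery analysis needs.
For a symmetric peak a wider Gaussian kernel does not move the mode, so
variance can be bought at essentially no bias; n^(−1/7) is the
AMSE-optimal rate for mode estimation, and the constant 2 was calibrated
on synthetic mixtures with component sd 3–8° (recovery RMSE ≈ 0.1–0.3°,
bias < 0.03°).  Wider-still kernels would start to couple the estimate to
side-shape asymmetry in real data, so the constant is kept moderate.
Uncertainty is a seeded 200-resample bootstrap (resampled modes are
searched on a local grid around the full-sample mode for speed).

The asymmetric fraction (|θ| > 3°) and directional fraction (θ < −3°, the
electronic-structure-consistent direction) are sample proportions with
percentile bootstrap 95% intervals (200 seeded resamples).  The
directional fraction is computed per event; per-trajectory and per-event
counts coincide in the synthetic model (one event per replica).

## Double-proton-transfer bookkeeping

**Asynchronicity.**  Along a reaction path with cumulative coordinate
q_IRC, each transferring proton i has a transfer position
α_i = the q_IRC midpoint of the path segment where ‖Δx_i/Δq‖² is maximal
(finite differences per segment; zero-advance segments skipped; ties take
the earliest midpoint with a warning).  The asynchronicity is

    α = |α_B1 − α_B2| / ‖q_IRC‖  ∈ [0, 1].

Only the named proton's Cartesian triple enters the derivative; the
normalisation "relative to the collective rearrangement of all atoms" is
carried entirely by ‖q_IRC‖, the total all-atom arc length — the only
reading consistent with the defining ratio.  If q_IRC is not supplied it
is computed as cumulative all-atom Cartesian displacement between images
(plain, not mass-weighted; no mass-weighting is specified anywhere).
α is invariant under rigid translation and under uniform rescaling of
q_IRC, and equals a brute-force finite-difference enumeration on random
paths to machine precision (property-tested).

**Energy levels and barriers.**  A level set holds the five
stationary-state energies at one separation (canonical ≡ 0 after
re-referencing on load): TS1, single-proton-transfer intermediate, TS2,
tautomer.  Derived exactly by subtraction:
forward₁ = E(TS1), reverse₁ = E(TS1) − E(int), forward₂ = E(TS2) − E(int),
reverse₂ = E(TS2) − E(taut), asymmetry = E(taut).

The packaged zero-separation table (`data/gc_dpt_levels_eq.csv`) stores the
published B3LYP+XDM values: E(TS1) = 0.574 eV, E(int) = 0.399 eV,
E(taut) = 0.507 eV.  The published numbers are not mutually consistent:
a "second barrier" of 0.516 eV fits no referencing of these levels
(TS2 − int = 0.516 would put TS2 at 0.915 eV, implying a reverse barrier
of 0.408 eV, not the quoted 0.058 eV).  The table therefore places
E(TS2) = E(taut) + 0.058 = 0.565 eV, which reproduces the quoted first
barrier, asymmetry and reverse barrier exactly; the 0.516 eV figure is
documented here rather than resolved.

`barrier_trend` fits forward₁ against separation by OLS (duplicate
separations averaged first; ≥ 2 distinct separations required — the
two-point endpoint fit 0.57 → 4.80 eV is a legitimate use) and flags
monotonicity.  `survival_threshold(d, v) = d / v` is the minimum tautomer
lifetime to outlive separation past the no-return distance d; at the
characteristic speed 1.2 Å ps⁻¹ and d = 2.0 Å it is 1.67 ≈ 1.7 ps.

## Synthetic data: what it emulates and what it does not

* **Breathing**: three independent Ornstein–Uhlenbeck series around the
  bond equilibria, exact discretisation (x_{k+1} = ρx_k + σ√(1−ρ²)ε,
  ρ = e^(−dt/τ)), started from stationarity.  Defaults: dt 0.1 ps,
  duration 20 ps, σ 0.1 Å, τ 1 ps — fluctuations small against the 2 Å
  break threshold, as thermal breathing is against real separation.
* **Events**: linear metric ramps at a set speed (default 1.2 Å ps⁻¹,
  starting at 14 ps, capped at 3 Å, after which the pair stays open).  The
  extension is shared across bonds by a linear shear in θ: at θ = −17.4°
  B1 carries nothing and B3 twice the mean (mirrored for +θ, saturating
  beyond); the weights always average to one so the metric slope is exact.
  The geometric relation "B3 stretched ~1.4 Å at the negative mode" serves
  only as qualitative calibration of that map, not as an enforced
  constraint.
* **Angle ensembles**: two-component Gaussian mixture, modes +18.9°/−17.4°,
  negative weight 0.39, component sd 5° (the underlying widths are not
  published; 5° is a free generator parameter chosen to keep the modes
  well separated yet overlapping near zero).
* **Reaction paths**: each proton hops 1 Å across its hydrogen bond over a
  single inter-image step centred at a tunable fraction of a uniform
  q_IRC; heavy atoms fixed.  This reproduces the stepwise mechanism
  (B2 proton first, then B1) in idealised form.
* **Level tables**: forward₁ grows linearly with separation at a set slope
  (default 1.41 eV Å⁻¹, the slope implied by 0.57 eV at contact and
  4.80 eV at 3 Å); the other levels follow fixed sub-unit multiples of the
  same trend.

All generators are bit-reproducible given their config and seed; ensemble
replicas draw per-replica seeds from a spawned `SeedSequence`.

Passing recovery tests on these inputs shows the *analysis* is unbiased
and correctly calibrated under its own model assumptions.  It does not
show the model matches real MD: real breathing is neither Gaussian nor
bond-independent, real events are not perfectly linear ramps, per-force
speed structure is not emulated (force is metadata only), and solvent,
backbone and force-field effects are absent entirely.

## Problem sizes and numerical choices

Recovery analyses use 200 replicas × 200 frames for speeds and n = 2000
for angle ensembles — large enough that pooled standard errors resolve
~1% biases, small enough that the full suite runs in seconds.  Uniform
time steps are required; irregular series are rejected, not resampled.
Arccos arguments are clipped to [−1, 1]; a degenerate (zero-length)
angle vector raises rather than returning NaN.  Bootstrap resample counts
are fixed at 200 with seeded generators.  Reports serialise as
sorted-key JSON and CSV floats as `%.17g`, so identical configs and seeds
give byte-identical outputs.

## Known limitations

* The opening-angle helix axis must be supplied; none is inferred.
* No kinetic/tunnelling model is attempted: the survival threshold is a
  kinematic bound, not a rate.
* Partial events (never reaching 2 Å) are fitted to their peak for
  diagnostics but flagged, and excluded from nothing by default other
  than by the standard filters.
* The packaged level table inherits the published TS2 inconsistency
  described above.
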