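#!/usr/bin/env python
"""Estimate the characteristic strand-separation speed from synthetic MD.

Runs the detection -> fit -> filter -> pool pipeline on 200 synthetic
steered-MD replicas (OU breathing noise sd 0.1 A, tau 1 ps; one 1.2 A/ps
separation event each) and reports the pooled mean speed, its standard
error, and the implied tautomer survival-time threshold at 2.0 A.
"""

from pathlib import Path

from bpopen.energetics import survival_threshold
from bpopen.io import write_events, write_report, write_speed_stats
from bpopen.pipeline import PipelineConfig, run_pipeline
from bpopen.synthetic import BreathingConfig, EventConfig, gen_event_ensemble

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2024

series = gen_event_ensemble(
    200, BreathingConfig(ou_sigma=0.1, ou_tau=1.0, dt=0.1),
    EventConfig(speed=1.2), seed=SEED,
)
result = run_pipeline(series, PipelineConfig(seed=SEED))
write_events(result.events, OUT / "separation_events.csv")
write_speed_stats(result.stats, result.pooled, OUT / "speed_stats.csv")
write_report(result.report, OUT / "speed_report.json")

v, se = result.pooled.mean_speed, result.pooled.stderr_speed
tau = survival_threshold(2.0, v)
print(f"accepted events : {result.pooled.n_events} / {result.report['n_events']}")
print(f"pooled speed    : {v:.3f} +/- {se:.3f} A/ps (generator truth 1.200)")
print(f"survival bound  : {tau:.2f} ps for 2.0 A of separation "
      f"(~{round(tau, 1)} ps)")
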