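#!/usr/bin/env python
"""An enforced crossfeeding interaction appears as a transfer-entropy peak.

Runs the short crossfeeding scenario with and without injecting the
metabolite hyper-producing strain at step 28 and compares the
producer-to-target apparent TE.  The target's abundance responds at step
30 (the two-step metabolite lag) and only the manipulated run shows a TE
peak there.  Outputs under results/crossfeeding/.
"""

from pathlib import Path

from infodyn.community import crossfeeding_config
from infodyn.pipeline import report, run_crossfeeding_experiment
from infodyn.tables import AnalysisConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "crossfeeding"


def main():
    run = run_crossfeeding_experiment(
        crossfeeding_config(rng_seed=0),
        AnalysisConfig(n_estimation_runs=25, rng_seed=0),
        significance=True,
    )
    s = run.summary
    print(f"{s['producer']} -> {s['target']}, injection at step {s['injection_step']}")
    for k, c in s["te"].items():
        print(f"k={k}: peak TE plain {c['peak_te_plain']:.3f} vs manipulated "
              f"{c['peak_te_manipulated']:.3f} nats (peak at step "
              f"{c['peak_step_manipulated']}; p plain={c['p_plain']}, "
              f"manipulated={c['p_manipulated']})")
    report(run, OUT)
    print(f"wrote outputs to {OUT}")


if __name__ == "__main__":
    main()
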