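#!/usr/bin/env python
"""Stopped-flow analysis: observed CO-binding rates and phase amplitudes.

Runs the rapid-mixing pipeline on the wild-type-like (monoexponential)
and CDless-like (biexponential, two heme-insertion populations) trace
series, prints the recovered observed rates at 500 uM CO and the
fast/slow amplitude split, and writes the full reports to results/.

Findings on the packaged fixtures: the wild-type-like series is
monoexponential at every concentration with k_obs(500 uM) ~ 0.13 s^-1;
the CDless-like series needs two exponentials (~0.62 and ~1.2 s^-1 at
500 uM) with ~73% of the amplitude in the fast phase, the signature of
the reversed-heme majority population.
"""

import json
from pathlib import Path

from ngbkin.pipelines import run_rapid_mixing
from ngbkin.synthetic_data import get_fixture, make_stopped_flow_set

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {}
    for name in ("wt_like", "cdless_like"):
        fx = get_fixture(name)
        report = run_rapid_mixing(make_stopped_flow_set(fx))
        out[name] = report.to_dict()
        print(f"--- {name} ---")
        print(report.human_summary())
    (RESULTS / "rapid_mixing.json").write_text(json.dumps(out, indent=2) + "\n")
    print("reports written to results/rapid_mixing.json")


if __name__ == "__main__":
    main()
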