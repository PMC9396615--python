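#!/usr/bin/env python
"""Flash-photolysis analysis: geminate partition and His64 displacement.

Runs the LFP pipeline on wild-type-like and CDless-like progress curves
(1 ns - 10 s, 0.2 mM CO), reports the geminate amplitude phi and
apparent rate k_gem, their partition into the pocket rebinding rate
k_-1 = phi*k_gem and the escape rate k_out = (1-phi)*k_gem, and the
seconds-scale His64 displacement rate.  Also demonstrates the
docking-site trap contrast at low CO, where the ~7 us phase is
kinetically isolated from bimolecular rebinding.

Findings on the packaged fixtures: phi ~ 12% / k_gem ~ 2.9e7 s^-1
(wild-type-like) against ~16% / ~5.4e7 s^-1 (CDless-like), so both the
pocket rebinding and the escape rates are higher for the mutant.
"""

import json
from pathlib import Path

from ngbkin.pipelines import run_lfp
from ngbkin.synthetic_data import get_fixture, make_lfp_curve

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {}
    for name in ("wt_like", "cdless_like"):
        fx = get_fixture(name)
        report = run_lfp(make_lfp_curve(fx), fx.lfp_co_conc)
        out[name] = report.to_dict()
        print(f"--- {name} (0.2 mM CO) ---")
        print(report.human_summary())

    cdless = get_fixture("cdless_like")
    trap_on = run_lfp(make_lfp_curve(cdless, co_conc=2e-6, trap=True), 2e-6)
    trap_off = run_lfp(make_lfp_curve(cdless, co_conc=2e-6, trap=False), 2e-6)
    out["trap_contrast_2uM"] = {
        "with_trap": None if trap_on.trap is None else trap_on.trap.__dict__,
        "without_trap": None if trap_off.trap is None else trap_off.trap.__dict__,
    }
    print("--- docking-site contrast at 2 uM CO ---")
    print(f"trap enabled : {'detected, lifetime %.2g s' % trap_on.trap.lifetime if trap_on.trap else 'not detected'}")
    print(f"trap disabled: {'detected' if trap_off.trap else 'not detected'}")
    (RESULTS / "flash_photolysis.json").write_text(json.dumps(out, indent=2) + "\n")
    print("reports written to results/flash_photolysis.json")


if __name__ == "__main__":
    main()
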