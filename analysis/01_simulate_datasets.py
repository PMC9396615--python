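#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes stopped-flow trace series, flash-photolysis progress curves,
equilibrium titrations and nu3-region spectra for the wild-type-like
and CDless-like fixtures to scratch/data/ (large, regenerable) and a
small manifest of what was generated to results/.
"""

import json
from pathlib import Path

from ngbkin.io_cli import write_trace, write_xy, write_spectrum
from ngbkin.synthetic_data import (
    FIXTURE_NAMES,
    get_fixture,
    make_lfp_curve,
    make_nu3_spectrum,
    make_stopped_flow_set,
    make_titration,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    manifest = {}
    for name in FIXTURE_NAMES:
        fx = get_fixture(name)
        files = []
        meta = f"fixture: {name}\nseed: {fx.seed}"
        if fx.mixture is not None:
            for conc, curve in make_stopped_flow_set(fx):
                path = DATA / f"{name}_sf_{conc * 1e6:.0f}uM.csv"
                write_trace(curve, path, metadata=meta + f"\nco_conc_M: {conc:g}")
                files.append(path.name)
            lfp_path = DATA / f"{name}_lfp.csv"
            write_trace(make_lfp_curve(fx), lfp_path, metadata=meta)
            files.append(lfp_path.name)
            tit = make_titration(fx)
            tit_path = DATA / f"{name}_titration.csv"
            write_xy(
                [p.co_conc for p in tit], [p.bound_fraction for p in tit], tit_path,
                header=meta + "\ncolumns: co_conc_M, bound_fraction",
            )
            files.append(tit_path.name)
        if fx.bands:
            sp_path = DATA / f"{name}_nu3.csv"
            write_spectrum(make_nu3_spectrum(fx), sp_path, metadata=meta)
            files.append(sp_path.name)
        manifest[name] = {"seed": fx.seed, "noise_sd": fx.noise_sd, "files": files}
        print(f"{name}: wrote {len(files)} file(s)")
    (RESULTS / "dataset_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"datasets under {DATA}; manifest in results/dataset_manifest.json")


if __name__ == "__main__":
    main()
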