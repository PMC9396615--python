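# ngbkin

Kinetic and spectral analysis of CO binding to hexacoordinate globins
— a His64-gated reaction-network simulator with the estimators used to
characterise neuroglobin ligand binding: multiexponential trace
decomposition, geminate-partition analysis of flash-photolysis data,
stopped-flow k_obs([CO]) fitting, Hill-plot affinities, and ν3-region
resonance-Raman band decomposition. Every input can be generated
synthetically from seeded fixtures, so the full analysis chain runs
without instrument data.

## The science

In neuroglobin the heme iron is hexacoordinate: the distal His64
occupies the sixth coordination site, and CO can bind only after the
His64–Fe bond breaks. The package models the species
{deoxy (5c), bis-His hexa (6c), CO-bound, pocket CO pair, docking-site
trap} as a linear network and reports the unliganded fraction
N(t) = 1 − [CO-bound].

Key relations (field notation):

* gated binding: k_obs = k_−H·k′[CO] / (k_H + k′[CO]), saturating at
  the His64 dissociation rate k_−H;
* overall affinity: c50 = (1 + K_H)·k_off/k_on, K_H = k_H/k_−H;
* geminate partition: a photodissociated CO in the pocket either
  rebinds (k_−1) or escapes (k_out); from the geminate amplitude Φ and
  apparent rate k_gem: k_−1 = Φ·k_gem, k_out = (1−Φ)·k_gem.

Heme inserts in two orientations, giving kinetically distinct protein
populations; the shipped `cdless_like` fixture carries a 73:27
fast:slow mixture, the `wt_like` fixture a single population.

## Worked example

```python
from ngbkin import GeminatePartition, split_rates, run_lfp
from ngbkin.synthetic_data import get_fixture, make_lfp_curve

# partition the wild-type geminate phase: phi = 12%, k_gem = 2.9e7 s^-1
k_rebind, k_out = split_rates(GeminatePartition(phi=0.12, k_gem=2.9e7))
print(f"{k_rebind:.2e}  {k_out:.2e}")     # 3.48e+06  2.55e+07

# full flash-photolysis analysis of a synthetic CDless-like curve
fx = get_fixture("cdless_like")
report = run_lfp(make_lfp_curve(fx, seed=1), fx.lfp_co_conc)
print(report.geminate.percent)            # 16   (geminate amplitude, %)
print(f"{report.geminate.k_gem:.2g}")     # 5.3e+07  (apparent rate, s^-1)
```

The first block prints the microscopic pocket rates implied by the
geminate phase: rebinding at 3.5×10⁶ s⁻¹ and escape at 2.6×10⁷ s⁻¹ (two
significant figures). The second runs the pipeline end to end on a
noisy synthetic curve and recovers the generating amplitude (16%) and
apparent geminate rate (within a few percent of the 5.4×10⁷ s⁻¹ ground
truth).

The same from the shell:

```sh
ngbkin gem-partition --phi 0.12 --kgem 2.9e7
ngbkin make-synth --fixture cdless_like --seed 1 --outdir synth/
ngbkin lfp-report synth/cdless_like_lfp.csv --co 2e-4 --out report.json
```

## Analysis scripts

`analysis/01_simulate_datasets.py` … `05_raman_nu3.py` run the whole
study in order — dataset generation, stopped-flow rates and amplitude
split, flash-photolysis geminate partition and trap contrast, Hill
affinities, and the two- vs three-band ν3 comparison — printing what
each stage finds and writing JSON tables under `results/`.

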