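"""Experiment-level analyses: rapid mixing and laser flash photolysis.

Each pipeline turns raw progress curves into a :class:`KineticReport`:

* :func:`run_rapid_mixing` - per-trace mono/biexponential decomposition
  with conservative model selection, assembly of k_obs([CO]) and its
  gated-binding hyperbola fit, conversion of overall amplitudes to bound
  fractions for the Hill-plot affinity, and the average fast/slow
  amplitude split across concentrations (by convention the fast phase is
  assigned to the reversed-heme population).
* :func:`run_lfp` - segmentation of a wide progress curve into geminate
  (default t <= 10 us), bimolecular (10 us - 10 ms) and slow (> 10 ms)
  phases; the geminate phase yields the (phi, k_gem) partition and its
  microscopic split, a small component with microsecond lifetime is
  reported as a docking-site trap, and the slow-phase rate estimates the
  His64 displacement rate.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field, is_dataclass

import numpy as np

from .exceptions import DomainError, NgbKinError, SegmentationError
from .fitting import (
    AffinityResult,
    ExponentialDecomposition,
    ObservedBinding,
    TitrationPoint,
    fit_hill_affinity,
    fit_kobs_curve,
    fit_multiexponential,
)
from .geminate import GeminatePartition, split_rates
from .kinetic_core import ProgressCurve

__all__ = [
    "RapidMixingConfig",
    "LfpConfig",
    "TrapComponent",
    "KineticReport",
    "run_rapid_mixing",
    "run_lfp",
]


@dataclass(frozen=True)
class RapidMixingConfig:
    """Tunables of the stopped-flow analysis."""

    max_components: int = 2
    aicc_threshold: float = 10.0
    n_restarts: int = 8
    #: full-signal amplitude corresponding to complete binding (Y = 1)
    reference_amplitude: float = 1.0


@dataclass(frozen=True)
class LfpConfig:
    """Tunables of the flash-photolysis analysis (times in s, rates in s^-1)."""

    geminate_cut: float = 1e-5
    slow_cut: float = 1e-2
    geminate_max_components: int = 3
    bimolecular_max_components: int = 3
    slow_two_step: bool = False
    aicc_threshold: float = 10.0
    n_restarts: int = 8
    #: fitted rates inside this window are classified as the docking-site trap
    trap_rate_window: tuple[float, float] = (5e4, 5e5)
    min_trap_fraction: float = 0.02
    #: the trap search refits out to this time so a microsecond-lifetime
    #: component decays fully inside its window and its rate is identifiable
    trap_search_t_max: float = 1e-4
    #: slowest rate still considered geminate (pocket) rebinding
    min_geminate_rate: float = 1e6
    #: a curve whose total span is below this is treated as "no photolysis"
    min_span: float = 0.02


@dataclass(frozen=True)
class TrapComponent:
    """A resolved docking-site component: rate (s^-1), lifetime (s), amplitude."""

    rate: float
    lifetime: float
    amplitude: float


@dataclass
class KineticReport:
    """Structured result of one experiment-level analysis."""

    kind: str
    decompositions: dict = field(default_factory=dict)
    geminate: GeminatePartition | None = None
    geminate_rates: tuple[float, float] | None = None  # (k_gem_rebind, k_out)
    trap: TrapComponent | None = None
    kobs_fits: dict = field(default_factory=dict)
    his_off_rate: float | None = None
    affinity: AffinityResult | None = None
    population_amplitudes: dict | None = None
    phases_absent: bool = False
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in asdict(x).items()}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return {k: conv(v) for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def human_summary(self) -> str:
        """Plain key-value text rendering of the report."""
        lines = [f"experiment: {self.kind}"]
        if self.phases_absent:
            lines.append("phases: absent (degenerate input)")
        for name, dec in self.decompositions.items():
            if dec is None or dec.degenerate:
                lines.append(f"{name}: no resolvable decay")
                continue
            for i, (amp, rate) in enumerate(dec.components):
                lines.append(
                    f"{name}.component{i + 1}: rate = {_sig2(rate)} s^-1, amplitude = {amp:.3g}"
                )
        if self.geminate is not None:
            kr, ko = self.geminate_rates
            lines += [
                f"geminate.phi: {self.geminate.percent}%",
                f"geminate.k_gem: {_sig2(self.geminate.k_gem)} s^-1",
                f"geminate.k_rebind: {_sig2(kr)} s^-1",
                f"geminate.k_out: {_sig2(ko)} s^-1",
            ]
        if self.trap is not None:
            lines.append(
                f"trap: lifetime = {_sig2(self.trap.lifetime)} s, amplitude = {self.trap.amplitude:.3g}"
            )
        for name, kf in self.kobs_fits.items():
            lines.append(
                f"kobs_fit.{name}: k_his_off = {_sig2(kf.k_his_off)} s^-1, "
                f"c_half = {_sig2(kf.c_half * 1e6)} uM"
                + (" (plateau only)" if kf.plateau_only else "")
            )
        if self.his_off_rate is not None:
            lines.append(f"his_off_rate: {_sig2(self.his_off_rate)} s^-1")
        if self.affinity is not None:
            lines.append(
                f"affinity.c50: {_sig2(self.affinity.c50 * 1e6)} uM "
                f"(Hill slope {self.affinity.hill_slope:.3g})"
            )
        if self.population_amplitudes:
            for k, v in self.population_amplitudes.items():
                lines.append(f"population.{k}: {100 * v:.0f}%")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _sig2(x: float) -> float:
    """Round to 2 significant figures (the reporting convention for rates)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 1)


def _config_hash(config) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_rapid_mixing(
    traces: list[tuple[float, ProgressCurve]],
    config: RapidMixingConfig = RapidMixingConfig(),
) -> KineticReport:
    """Analyse a stopped-flow CO-concentration series end to end."""
    if not traces:
        raise DomainError("rapid-mixing analysis needs at least one trace")
    concs = sorted({c for c, _ in traces})
    if len(concs) < 3:
        raise DomainError(f"need >= 3 CO concentrations, got {len(concs)}")
    report = KineticReport(kind="rapid_mixing")
    report.provenance = {
        "config_hash": _config_hash(config),
        "co_concentrations_M": [float(c) for c in concs],
        "n_traces": len(traces),
    }

    per_trace: list[tuple[float, ExponentialDecomposition]] = []
    for conc, curve in traces:
        if conc <= 0:
            raise DomainError(f"CO concentration {conc!r} must be > 0")
        try:
            dec = fit_multiexponential(
                curve,
                max_components=config.max_components,
                aicc_threshold=config.aicc_threshold,
                n_restarts=config.n_restarts,
            )
        except NgbKinError as exc:
            report.warnings.append(f"trace at [CO]={conc}: fit failed ({exc})")
            continue
        if dec.degenerate:
            report.warnings.append(f"trace at [CO]={conc}: no resolvable decay")
            continue
        per_trace.append((conc, dec))
        report.decompositions[f"co_{conc:.6g}M"] = dec
    if not per_trace:
        raise DomainError("no trace could be decomposed")

    # k_obs([CO]) per phase rank (components are sorted fastest first)
    n_phases = max(len(d.components) for _, d in per_trace)
    labels = (
        ["only"] if n_phases == 1 else ["fast", "slow"] + [f"phase{i}" for i in range(3, n_phases + 1)]
    )
    for rank, label in enumerate(labels):
        pts = []
        for conc, dec in per_trace:
            if len(dec.components) <= rank:
                continue
            fracs = dec.amplitude_fractions
            pts.append((conc, float(dec.rates[rank]), float(fracs[rank])))
        if len({c for c, _, _ in pts}) < 2:
            continue
        # re-normalise fractions within this phase set for ObservedBinding
        norm: dict[float, float] = {}
        for c, _, f in pts:
            norm[c] = norm.get(c, 0.0) + f
        binding = ObservedBinding(
            points=tuple((c, k, f / norm[c]) for c, k, f in pts)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.kobs_fits[label] = fit_kobs_curve(binding)
        except NgbKinError as exc:
            report.warnings.append(f"k_obs fit for {label} phase failed: {exc}")

    gating = report.kobs_fits.get("slow") or report.kobs_fits.get("only")
    if gating is not None:
        report.his_off_rate = gating.k_his_off

    # bound fraction Y from the overall amplitude relative to full signal
    titration = []
    for conc, dec in per_trace:
        y = dec.total_amplitude / config.reference_amplitude
        if 0.0 < y < 1.0:
            titration.append(TitrationPoint(co_conc=conc, bound_fraction=y))
        else:
            report.warnings.append(
                f"overall amplitude at [CO]={conc} gives Y={y:.3g} outside (0,1); "
                "excluded from the Hill fit"
            )
    if len(titration) >= 3:
        try:
            report.affinity = fit_hill_affinity(titration)
        except NgbKinError as exc:
            report.warnings.append(f"Hill fit failed: {exc}")
    else:
        report.warnings.append("fewer than 3 usable bound fractions; affinity not fitted")

    # fast/slow split, averaged over biexponential traces; fast phase is
    # conventionally assigned to the reversed-heme population
    biexp = [d.amplitude_fractions[0] for _, d in per_trace if len(d.components) == 2]
    if biexp:
        fast = float(np.mean(biexp))
        report.population_amplitudes = {
            "fast_reversed_heme": fast,
            "slow_canonical_heme": 1.0 - fast,
        }
    return report


def _detect_trap(curve: ProgressCurve, config: LfpConfig):
    """Look for a microsecond-lifetime docking-site component.

    Refits the curve out to ``trap_search_t_max`` (default 100 us) so
    both the candidate trap and the bimolecular bleed decay enough for
    their rates to separate; the fastest component (geminate rebinding)
    is never a candidate.
    """
    try:
        seg = curve.window(curve.times[0], config.trap_search_t_max)
        dec = fit_multiexponential(
            seg,
            max_components=4,
            aicc_threshold=config.aicc_threshold,
            n_restarts=config.n_restarts,
        )
    except NgbKinError:
        return None
    if dec.degenerate or len(dec.components) < 2:
        return None
    lo, hi = config.trap_rate_window
    fracs = dec.amplitude_fractions
    for i in range(1, len(dec.components)):  # skip the fastest (geminate)
        amp, rate = dec.components[i]
        if lo <= rate <= hi and fracs[i] >= config.min_trap_fraction:
            return TrapComponent(rate=float(rate), lifetime=1.0 / float(rate), amplitude=float(amp))
    return None


def run_lfp(
    curve: ProgressCurve,
    co_conc: float,
    config: LfpConfig = LfpConfig(),
) -> KineticReport:
    """Analyse one flash-photolysis progress curve end to end."""
    if co_conc < 0:
        raise DomainError("CO concentration must be >= 0")
    t = curve.times
    pos = t[t > 0]
    if pos.size < 2 or math.log10(t[-1] / pos.min()) < 6.0:
        raise DomainError("LFP curve must span at least 6 decades of time")
    report = KineticReport(kind="lfp")
    report.provenance = {
        "config_hash": _config_hash(config),
        "co_conc_M": float(co_conc),
        "n_points": len(curve),
        "t_range_s": [float(t[0]), float(t[-1])],
    }

    if curve.span < config.min_span:
        report.phases_absent = True
        report.warnings.append(
            f"signal span {curve.span:.3g} below {config.min_span}: no photolysis detected; "
            "all phases flagged absent"
        )
        return report

    segments = {
        "geminate": (t[0], config.geminate_cut),
        "bimolecular": (config.geminate_cut, config.slow_cut),
        "slow": (config.slow_cut, t[-1]),
    }
    for name, (lo, hi) in segments.items():
        if np.count_nonzero((t >= lo) & (t <= hi)) < 10:
            raise SegmentationError(
                f"{name} segment [{lo:.3g}, {hi:.3g}] s holds fewer than 10 points",
                diagnostics={"segment": name, "cuts": (config.geminate_cut, config.slow_cut)},
            )

    max_comp = {
        "geminate": config.geminate_max_components,
        "bimolecular": config.bimolecular_max_components,
        "slow": 2 if config.slow_two_step else 1,
    }
    for name, (lo, hi) in segments.items():
        seg = curve.window(lo, hi)
        try:
            report.decompositions[name] = fit_multiexponential(
                seg,
                max_components=max_comp[name],
                aicc_threshold=config.aicc_threshold,
                n_restarts=config.n_restarts,
            )
        except NgbKinError as exc:
            report.decompositions[name] = None
            report.warnings.append(f"{name} segment fit failed: {exc}")

    # geminate partition: fastest pocket-scale component of the first segment
    gem_dec = report.decompositions.get("geminate")
    if gem_dec is not None and not gem_dec.degenerate:
        pocket = [(a, k) for a, k in gem_dec.components if k >= config.min_geminate_rate]
        if pocket:
            amp, k_gem = pocket[0]
            n0 = gem_dec.total_amplitude + gem_dec.offset  # model value at t = 0
            phi = min(max(amp / n0, 0.0), 1.0) if n0 > 0 else 0.0
            report.geminate = GeminatePartition(phi=phi, k_gem=float(k_gem))
            report.geminate_rates = split_rates(report.geminate)
        else:
            report.warnings.append("no geminate-scale component resolved")
    else:
        report.warnings.append("geminate segment not decomposable")

    # docking-site trap: microsecond-lifetime component across the early curve
    report.trap = _detect_trap(curve, config)

    # slow phase: His64 displacement as CO rebinds from the bulk
    slow_dec = report.decompositions.get("slow")
    if slow_dec is not None and not slow_dec.degenerate:
        idx = int(np.argmax(np.abs(slow_dec.amplitudes)))
        report.his_off_rate = float(slow_dec.rates[idx])
    else:
        report.warnings.append("slow phase not resolved")
    return report
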