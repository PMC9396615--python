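"""Kinetic-trace decomposition and binding-curve fits.

Three estimators used throughout the pipelines:

* :func:`fit_multiexponential` - decompose a trace into
  ``offset + sum_i a_i * exp(-k_i * t)`` with conservative AICc model
  selection.  Rates are optimised by variable projection (amplitudes and
  offset solved linearly given the rates), multi-started from a decade
  grid, which is robust for the ill-conditioned sums of exponentials
  typical of rebinding traces.
* :func:`fit_kobs_curve` - the gated-binding hyperbola
  ``k_obs = k_his_off * [CO] / (c_half + [CO])`` whose plateau is the
  His64 dissociation rate.
* :func:`fit_hill_affinity` - linear Hill plot,
  ``log10(Y/(1-Y))`` against ``log10[CO]``; the zero crossing is c50.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy.optimize import least_squares

from .exceptions import DomainError, FitFailureError, IdentifiabilityError
from .kinetic_core import ProgressCurve

__all__ = [
    "FitQuality",
    "ExponentialDecomposition",
    "ObservedBinding",
    "TitrationPoint",
    "AffinityResult",
    "KobsFit",
    "fit_multiexponential",
    "fit_kobs_curve",
    "fit_hill_affinity",
]


@dataclass(frozen=True)
class FitQuality:
    """Residual norm and corrected-AIC score of one candidate model."""

    rss: float
    aicc: float
    n_points: int
    n_params: int


@dataclass(frozen=True)
class ExponentialDecomposition:
    """Fitted multiexponential: components (amplitude, rate), fastest first.

    ``degenerate`` marks an offset-only result (no decay resolved);
    ``candidates`` holds (n_components, rss, aicc) for every model order
    tried, so callers can audit the selection.
    """

    components: tuple[tuple[float, float], ...]
    offset: float
    fit_quality: FitQuality
    stderr: tuple[tuple[float, float], ...] = ()
    degenerate: bool = False
    candidates: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self):
        for amp, rate in self.components:
            if not (math.isfinite(rate) and rate > 0.0):
                raise DomainError(f"fitted rate {rate!r} must be finite and > 0")
            if not math.isfinite(amp):
                raise DomainError(f"fitted amplitude {amp!r} must be finite")
        if not self.components and not self.degenerate:
            raise DomainError("a non-degenerate decomposition needs >= 1 component")

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.components])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return 1.0 / self.rates

    @property
    def amplitude_fractions(self) -> np.ndarray:
        """|a_i| / sum|a|, the relative weight of each phase."""
        a = np.abs(self.amplitudes)
        return a / a.sum()

    @property
    def total_amplitude(self) -> float:
        return float(self.amplitudes.sum())

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for amp, rate in self.components:
            out += amp * np.exp(-rate * t)
        return out


def _aicc(rss: float, n: int, p: int) -> float:
    rss = max(rss, n * 1e-300)
    score = n * math.log(rss / n) + 2 * p
    if n - p - 1 > 0:
        score += 2.0 * p * (p + 1) / (n - p - 1)
    else:
        score = math.inf
    return score


def _solve_amplitudes(t, y, rates, sw=None):
    """Linear LSQ for amplitudes + offset given the rates (variable projection).

    ``sw`` are square-root weights applied to the residual.  A component
    whose decay barely completes inside the window legitimately carries
    an amplitude much larger than the local signal span (only a*k is
    constrained there), so the linear subproblem is left unbounded.
    """
    X = np.column_stack([np.exp(-np.outer(t, rates)), np.ones_like(t)])
    Xw, yw = (X, y) if sw is None else (X * sw[:, None], y * sw)
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    return coef[:-1], coef[-1], resid


def _log_weights(t, points_per_decade):
    """Per-point weights making every decade of time weigh equally.

    Applied only to log-like grids (near-constant spacing in log10 t)
    spanning at least two decades - the sampling used for traces that
    run from nanoseconds to seconds - where points denser than
    ``points_per_decade`` are down-weighted by their local log10(t)
    spacing.  Linearly sampled traces keep uniform weights: there the
    instrument already allocates samples where the signal evolves, and
    log-weighting would only shrink the effective sample size.  Returns
    square-root weights normalised to unit mean, or None.
    """
    pos = t > 0.0
    if pos.sum() < 4 or t[pos].min() <= 0.0:
        return None
    decades = math.log10(t[-1] / t[pos].min())
    if decades < 2.0:
        return None
    logt = np.log10(np.clip(t, t[pos].min() * 0.5, None))
    dlog = np.gradient(logt)
    if dlog.std() > 0.5 * dlog.mean():  # not a log-like grid
        return None
    w = np.minimum(dlog, 1.0 / points_per_decade)
    w = np.clip(w, 1e-12, None)
    return np.sqrt(w / w.mean())


def _fit_fixed_order(t, y, n_comp, n_restarts, rng, seed_rates=None, sw=None):
    """Best variable-projection fit with exactly n_comp exponentials.

    Starts combine (i) an evenly spread log-rate base, (ii) "peeling"
    seeds - the previous-order solution plus one extra rate swept over
    every decade of the observable range - and (iii) log-uniform random
    restarts.  The decade sweep is what reliably finds well-separated
    rate combinations in traces spanning many decades of time.
    """
    t_max = t[-1]
    t_min = t[t > 0].min() if np.any(t > 0) else t_max * 1e-3
    lo, hi = math.log10(0.01 / t_max), math.log10(100.0 / t_min)
    margin = 0.1 * (hi - lo)
    base = np.linspace(lo + margin, hi - margin, n_comp + 2)[1:-1]
    starts = [base]
    decades = np.arange(math.ceil(lo + 0.5), math.floor(hi - 0.5) + 1, dtype=float)
    if seed_rates is not None and len(seed_rates) == n_comp - 1:
        prev = np.log10(np.asarray(seed_rates, dtype=float))
        for d in decades:
            starts.append(np.sort(np.append(prev, d)))
    elif n_comp == 1:
        starts.extend(np.array([d]) for d in decades)
    for _ in range(n_restarts):
        starts.append(np.sort(rng.uniform(lo, hi, size=n_comp)))

    def resid(logk):
        return _solve_amplitudes(t, y, 10.0**logk, sw)[2]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailureError(f"all {len(starts)} starts failed for {n_comp}-exponential fit")
    rates = np.sort(10.0 ** best[1])[::-1]  # fastest first
    amps, offset, resid_v = _solve_amplitudes(t, y, rates, sw)
    return rates, amps, offset, float(np.sum(resid_v**2))


def _full_param_stderr(t, y, rates, amps, offset, rss, sw=None):
    """Stderr of (amplitude, rate) pairs from the full nonlinear Jacobian."""
    n, p = t.size, 2 * rates.size + 1
    if n <= p:
        return tuple((math.nan, math.nan) for _ in rates)
    cols = []
    for a, k in zip(amps, rates):
        e = np.exp(-k * t)
        cols.append(e)  # d/da
        cols.append(-a * t * e)  # d/dk
    cols.append(np.ones_like(t))
    J = np.column_stack(cols)
    if sw is not None:
        J = J * sw[:, None]
    try:
        cov = np.linalg.pinv(J.T @ J) * (rss / (n - p))
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return tuple((math.nan, math.nan) for _ in rates)
    return tuple((float(sd[2 * i]), float(sd[2 * i + 1])) for i in range(rates.size))


def fit_multiexponential(
    curve: ProgressCurve,
    max_components: int = 2,
    *,
    aicc_threshold: float = 10.0,
    n_restarts: int = 8,
    log_resample: bool = True,
    points_per_decade: int = 50,
    restart_seed: int = 0,
) -> ExponentialDecomposition:
    """Decompose a trace into a conservative sum of exponential decays.

    Candidate models with 0 (offset only) to ``max_components``
    exponentials are fitted; a higher-order model replaces the current
    selection only when it improves the corrected Akaike criterion by at
    least ``aicc_threshold`` (default 10) - adding phases to kinetic
    traces easily produces unstable fits, so selection is deliberately
    conservative.  Equal scores keep the smaller model.

    Residuals are weighted uniformly per decade of time (nominal density
    50 points/decade, applied when the trace spans >= 2 decades of
    positive time) so nanosecond and second phases weigh comparably.
    """
    if not 1 <= max_components <= 4:
        raise DomainError("max_components must lie in [1, 4]")
    if len(curve) < 10:
        raise DomainError("need >= 10 data points to fit exponentials")
    t = curve.times.astype(float)
    y = curve.values.astype(float)
    sw = _log_weights(t, points_per_decade) if log_resample else None
    rng = np.random.default_rng(restart_seed)

    n_pts = t.size
    w2 = np.ones_like(y) if sw is None else sw**2
    # Kish effective sample size: with strongly non-uniform weights far
    # fewer points carry the fit, and the information criterion must be
    # calibrated on that count, not the raw one
    n_eff = float(np.sum(w2) ** 2 / np.sum(w2**2))
    offset0 = float(np.sum(w2 * y) / np.sum(w2))
    rss0 = float(np.sum((w2**0.5 * (y - offset0)) ** 2))
    # residuals below ~3e-5 of the span are solver noise, not signal: floor
    # the AICc comparison there so noiseless data cannot drive overfitting
    span = float(y.max() - y.min()) or 1.0
    rss_floor = n_pts * (3e-5 * span) ** 2

    def score(rss, p):
        return _aicc(max(rss, rss_floor) * n_eff / n_pts, round(n_eff), p)

    candidates: dict[int, tuple] = {0: (rss0, score(rss0, 1), (), np.array([]), offset0)}
    prev_rates = None
    for n_comp in range(1, max_components + 1):
        rates, amps, offset, rss = _fit_fixed_order(
            t, y, n_comp, n_restarts, rng, prev_rates, sw
        )
        candidates[n_comp] = (rss, score(rss, 2 * n_comp + 1), rates, amps, offset)
        prev_rates = rates

    selected = 0
    for n_comp in range(1, max_components + 1):
        if candidates[n_comp][1] <= candidates[selected][1] - aicc_threshold:
            selected = n_comp

    cand_summary = tuple((n, c[0], c[1]) for n, c in sorted(candidates.items()))
    rss, aicc, rates, amps, offset = candidates[selected]
    quality = FitQuality(rss=rss, aicc=aicc, n_points=n_pts, n_params=2 * selected + 1)
    if selected == 0:
        return ExponentialDecomposition(
            components=(), offset=offset, fit_quality=quality, degenerate=True,
            candidates=cand_summary,
        )
    stderr = _full_param_stderr(t, y, rates, amps, offset, rss, sw)
    return ExponentialDecomposition(
        components=tuple((float(a), float(k)) for a, k in zip(amps, rates)),
        offset=float(offset),
        fit_quality=quality,
        stderr=stderr,
        candidates=cand_summary,
    )


@dataclass(frozen=True)
class ObservedBinding:
    """k_obs([CO]) points with the relative amplitude of each phase.

    ``points`` is a tuple of (co_conc in M, k_obs in s^-1,
    amplitude_fraction); fractions at any one concentration sum to 1.
    """

    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.points:
            raise DomainError("ObservedBinding needs at least one point")
        sums: dict[float, float] = {}
        for conc, kobs, frac in self.points:
            if conc <= 0.0 or not math.isfinite(conc):
                raise DomainError(f"co_conc {conc!r} must be finite and > 0")
            if kobs <= 0.0 or not math.isfinite(kobs):
                raise DomainError(f"k_obs {kobs!r} must be finite and > 0")
            sums[conc] = sums.get(conc, 0.0) + frac
        for conc, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                raise DomainError(
                    f"amplitude fractions at [CO]={conc} sum to {s}, expected 1 within 1e-6"
                )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array(sorted({c for c, _, _ in self.points}))


@dataclass(frozen=True)
class KobsFit:
    """Result of the gated-binding hyperbola fit."""

    k_his_off: float
    c_half: float
    stderr_k_his_off: float
    stderr_c_half: float
    plateau_only: bool = False


def _kobs_model(c, k_his_off, c_half):
    return k_his_off * c / (c_half + c)


def fit_kobs_curve(points: ObservedBinding) -> KobsFit:
    """Fit k_obs = k_his_off*[CO]/(c_half + [CO]) to observed binding rates.

    Only the plateau ``k_his_off`` and the ratio ``c_half =
    k_his_on/k_co_on`` are identifiable from k_obs([CO]).  When every
    point sits on the plateau, c_half is unconstrained: the fit is then
    flagged ``plateau_only`` and its c_half stderr is large or NaN.
    """
    conc = np.array([p[0] for p in points.points])
    kobs = np.array([p[1] for p in points.points])
    distinct = np.unique(conc)
    if distinct.size < 2:
        raise IdentifiabilityError("all k_obs points share one concentration; cannot fit")
    if distinct.size < 3 or distinct.max() / distinct.min() < 10.0 - 1e-9:
        warnings.warn("k_obs fit prefers >= 3 concentrations spanning >= 1 decade", stacklevel=2)

    model = Model(_kobs_model)
    params = model.make_params(
        k_his_off={"value": float(kobs.max() * 1.05), "min": 0.0},
        c_half={"value": float(np.median(conc)), "min": 0.0},
    )
    result = model.fit(kobs, params, c=conc)
    k_off = float(result.params["k_his_off"].value)
    c_half = float(result.params["c_half"].value)
    sd_k = result.params["k_his_off"].stderr
    sd_c = result.params["c_half"].stderr
    sd_k = float(sd_k) if sd_k is not None else math.nan
    sd_c = float(sd_c) if sd_c is not None else math.nan
    plateau_only = (not math.isfinite(sd_c)) or sd_c >= c_half
    if k_off <= 0.0:
        raise FitFailureError("k_obs fit returned a non-positive plateau", best_so_far=result)
    return KobsFit(k_off, c_half, sd_k, sd_c, plateau_only)


@dataclass(frozen=True)
class TitrationPoint:
    """One equilibrium titration point: [CO] in M, bound fraction Y in (0, 1)."""

    co_conc: float
    bound_fraction: float

    def __post_init__(self):
        if self.co_conc <= 0.0 or not math.isfinite(self.co_conc):
            raise DomainError(f"co_conc {self.co_conc!r} must be finite and > 0")
        if not math.isfinite(self.bound_fraction):
            raise DomainError("bound fraction must be finite")


@dataclass(frozen=True)
class AffinityResult:
    """Hill-plot affinity: c50 (M), Hill slope, and their standard errors."""

    c50: float
    hill_slope: float
    stderr_c50: float
    stderr_slope: float

    def __post_init__(self):
        if not (math.isfinite(self.c50) and self.c50 > 0.0):
            raise DomainError(f"c50 {self.c50!r} must be finite and > 0")


def fit_hill_affinity(titration: list[TitrationPoint]) -> AffinityResult:
    """Linear fit of log10(Y/(1-Y)) against log10[CO]; c50 is the zero crossing.

    For a single-site isotherm Y = [CO]/([CO]+c50), the log-odds are
    exactly linear in log10[CO] with unit slope, so the abscissa of the
    zero crossing recovers c50 without bias.
    """
    if len(titration) < 3:
        raise DomainError("Hill fit needs >= 3 titration points")
    for i, p in enumerate(titration):
        if not 0.0 < p.bound_fraction < 1.0:
            raise DomainError(
                f"titration point {i} ([CO]={p.co_conc} M) has Y={p.bound_fraction}; "
                "the Hill transform needs Y strictly in (0, 1)"
            )
    x = np.log10([p.co_conc for p in titration])
    yl = np.array([p.bound_fraction for p in titration])
    y = np.log10(yl / (1.0 - yl))
    if np.unique(x).size < 2:
        raise IdentifiabilityError("all titration points share one concentration")
    (m, b), cov = np.polyfit(x, y, 1, cov="unscaled") if len(x) == 3 else np.polyfit(x, y, 1, cov=True)
    if len(x) == 3:  # rescale unscaled covariance by residual variance (1 dof)
        resid = y - (m * x + b)
        cov = cov * float(np.sum(resid**2))
    if m == 0.0 or not math.isfinite(m):
        raise IdentifiabilityError("Hill plot has zero slope; c50 undefined")
    x0 = -b / m
    grad = np.array([b / m**2, -1.0 / m])
    var_x0 = float(grad @ cov @ grad)
    c50 = 10.0**x0
    return AffinityResult(
        c50=c50,
        hill_slope=float(m),
        stderr_c50=math.log(10.0) * c50 * math.sqrt(max(var_x0, 0.0)),
        stderr_slope=float(math.sqrt(max(cov[0, 0], 0.0))),
    )
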