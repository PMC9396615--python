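"""nu3 core-size-marker band decomposition and Fe-CO conformer analysis.

The porphyrin nu3 skeletal mode near 1500 cm^-1 reports the heme core
size, so each heme conformer contributes one band in the 1450-1550
cm^-1 window.  Spectra are decomposed into a small number of Lorentzian
(or Gaussian / pseudo-Voigt) bands over a linear baseline; the corrected
Akaike criterion compares band counts.

Fe-CO adducts additionally follow the back-bonding correlation: the
nu(Fe-C) and nu(C-O) stretching frequencies are inversely related, and a
conformer's position along the line reflects distal-pocket polarity.
The A0 (open pocket), A1 and A3 (closed, H-bonded CO) classes occupy
distinct nu(C-O) zones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.stats import linregress

from .exceptions import DomainError, FitFailureError

__all__ = [
    "Spectrum",
    "SpectralBand",
    "BackbondingPoint",
    "ConformerThresholds",
    "band_profile",
    "initial_bands",
    "fit_bands",
    "classify_conformer",
    "backbonding_fit",
]

BAND_SHAPES = ("lorentzian", "gaussian", "pseudo_voigt")


@dataclass(frozen=True)
class Spectrum:
    """A baseline-corrected spectrum: wavenumbers (cm^-1, increasing) and intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or w.size < 20 or i.shape != w.shape:
            raise DomainError("spectrum needs >= 20 points with matching shapes")
        if np.any(np.diff(w) <= 0.0):
            raise DomainError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise DomainError("intensities must be finite")

    @property
    def window(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


@dataclass(frozen=True)
class SpectralBand:
    """One vibrational band: center and FWHM in cm^-1, peak height, line shape."""

    center: float
    fwhm: float
    height: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if not (math.isfinite(self.center)):
            raise DomainError("band center must be finite")
        if not (math.isfinite(self.fwhm) and self.fwhm > 0.0):
            raise DomainError(f"band fwhm {self.fwhm!r} must be > 0")
        if not (math.isfinite(self.height) and self.height > 0.0):
            raise DomainError(f"band height {self.height!r} must be > 0")
        if self.shape not in BAND_SHAPES:
            raise DomainError(f"band shape {self.shape!r} not one of {BAND_SHAPES}")

    def profile(self, w: np.ndarray) -> np.ndarray:
        return band_profile(w, self.center, self.fwhm, self.height, self.shape)


def band_profile(w, center, fwhm, height, shape="lorentzian", voigt_eta=0.5):
    """Unit-height-normalised line profile evaluated on wavenumbers ``w``."""
    w = np.asarray(w, dtype=float)
    x = (w - center) / (fwhm / 2.0)
    lor = 1.0 / (1.0 + x * x)
    if shape == "lorentzian":
        return height * lor
    gau = np.exp(-math.log(2.0) * x * x)
    if shape == "gaussian":
        return height * gau
    if shape == "pseudo_voigt":
        return height * (voigt_eta * lor + (1.0 - voigt_eta) * gau)
    raise DomainError(f"unknown band shape {shape!r}")


def initial_bands(
    spectrum: Spectrum, n_bands: int, fwhm: float = 10.0, shape: str = "lorentzian"
) -> list[SpectralBand]:
    """Heuristic initial bands: evenly spread across the intensity-weighted window."""
    w, y = spectrum.wavenumbers, spectrum.intensities
    if not 1 <= n_bands <= 4:
        raise DomainError("n_bands must lie in [1, 4]")
    peak = float(w[int(np.argmax(y))])
    spread = np.linspace(-0.75, 0.75, n_bands) * fwhm if n_bands > 1 else np.array([0.0])
    height = max(float(y.max() - y.min()), 1e-12) / max(n_bands - 0.5, 1.0)
    lo, hi = spectrum.window
    return [
        SpectralBand(center=float(np.clip(peak + s, lo, hi)), fwhm=fwhm, height=height, shape=shape)
        for s in spread
    ]


def _band_sum(params, w, n_bands, shape):
    out = params["baseline_intercept"] + params["baseline_slope"] * (w - w[0])
    for i in range(n_bands):
        out = out + band_profile(
            w, params[f"center_{i}"], params[f"fwhm_{i}"], params[f"height_{i}"], shape
        )
    return out


def fit_bands(
    spectrum: Spectrum,
    n_bands: int,
    init: list[SpectralBand],
    baseline: str = "linear",
    *,
    vary_fwhm: bool = True,
    n_restarts: int = 6,
    center_jitter: float = 1.0,
    restart_seed: int = 0,
) -> tuple[list[SpectralBand], np.ndarray, float]:
    """Least-squares band decomposition with a jointly fitted linear baseline.

    Multi-starts from ``init`` with the band centers jittered by up to
    ``center_jitter`` cm^-1.  ``vary_fwhm=False`` keeps each bandwidth
    fixed at its ``init`` value - the usual protocol when deconvolving
    heavily overlapped bands whose widths are known from better-resolved
    spectra.  Returns (bands sorted by center, residual vector, AICc
    score); the score lets callers compare band counts.
    """
    if not 1 <= n_bands <= 4:
        raise DomainError("n_bands must lie in [1, 4]")
    if len(init) != n_bands:
        raise DomainError(f"init must supply exactly {n_bands} bands, got {len(init)}")
    if baseline != "linear":
        raise DomainError("only a linear baseline is supported")
    shape = init[0].shape
    w, y = spectrum.wavenumbers, spectrum.intensities
    lo, hi = spectrum.window
    width = hi - lo
    rng = np.random.default_rng(restart_seed)

    def make_params(jitter: bool) -> Parameters:
        params = Parameters()
        params.add("baseline_intercept", value=float(y.min()))
        params.add("baseline_slope", value=0.0)
        for i, b in enumerate(init):
            c = b.center + (rng.uniform(-center_jitter, center_jitter) if jitter else 0.0)
            params.add(f"center_{i}", value=float(np.clip(c, lo, hi)), min=lo, max=hi)
            params.add(f"fwhm_{i}", value=b.fwhm, min=width * 1e-3, max=width, vary=vary_fwhm)
            params.add(f"height_{i}", value=b.height, min=0.0)
        return params

    def resid(params):
        return _band_sum(params, w, n_bands, shape) - y

    best = None
    for trial in range(1 + n_restarts):
        try:
            out = minimize(resid, make_params(jitter=trial > 0), method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(out.residual**2))
        if best is None or rss < best[0]:
            best = (rss, out)
    if best is None:
        raise FitFailureError("all restarts failed in band decomposition")
    rss, out = best
    n, n_params = w.size, out.nvarys
    aicc = n * math.log(max(rss, n * 1e-300) / n) + 2 * n_params
    if n - n_params - 1 > 0:
        aicc += 2.0 * n_params * (n_params + 1) / (n - n_params - 1)
    bands = [
        SpectralBand(
            center=float(out.params[f"center_{i}"].value),
            fwhm=float(out.params[f"fwhm_{i}"].value),
            height=max(float(out.params[f"height_{i}"].value), 1e-300),
            shape=shape,
        )
        for i in range(n_bands)
    ]
    bands.sort(key=lambda b: b.center)
    return bands, np.asarray(out.residual), float(aicc)


@dataclass(frozen=True)
class BackbondingPoint:
    """One Fe-CO adduct on the back-bonding diagram (frequencies in cm^-1)."""

    nu_fec: float
    nu_co: float
    label: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.nu_fec) and math.isfinite(self.nu_co)):
            raise DomainError("back-bonding frequencies must be finite")
        if not 450.0 <= self.nu_fec <= 560.0:
            warnings.warn(
                f"nu(Fe-C) = {self.nu_fec} cm^-1 outside the usual 450-560 range", stacklevel=2
            )
        if not 1880.0 <= self.nu_co <= 2000.0:
            warnings.warn(
                f"nu(C-O) = {self.nu_co} cm^-1 outside the usual 1880-2000 range", stacklevel=2
            )


@dataclass(frozen=True)
class ConformerThresholds:
    """nu(C-O) zone boundaries for the A0 / A1 / A3 conformer classes.

    ``closed_label`` names the strongly H-bonded low-frequency class;
    the literature labels it either A3 or A1, so it is configurable.
    """

    a0_min: float = 1955.0
    closed_max: float = 1945.0
    closed_label: str = "A3"

    def __post_init__(self):
        if not self.closed_max < self.a0_min:
            raise DomainError("thresholds must satisfy closed_max < a0_min")


def classify_conformer(
    point: BackbondingPoint, thresholds: ConformerThresholds = ConformerThresholds()
) -> str:
    """Zone an Fe-CO adduct by its nu(C-O) frequency.

    nu(C-O) >= a0_min -> "A0" (open pocket); nu(C-O) < closed_max ->
    the closed H-bonded class; in between -> "A1".  A frequency exactly
    on a boundary resolves to the higher-frequency class.  Depends only
    on frequencies, never on intensities.
    """
    if point.nu_co >= thresholds.a0_min:
        return "A0"
    if point.nu_co >= thresholds.closed_max:
        return "A1"
    return thresholds.closed_label


def backbonding_fit(points: list[BackbondingPoint]) -> tuple[float, float, float]:
    """OLS back-bonding line: nu(Fe-C) regressed on nu(C-O).

    Returns (slope, intercept, Pearson r).  The physically expected
    slope is negative (stronger back-bonding raises nu(Fe-C) and lowers
    nu(C-O)); a non-negative slope triggers a warning.
    """
    if len({(p.nu_fec, p.nu_co) for p in points}) < 2:
        raise DomainError("back-bonding fit needs >= 2 distinct points")
    x = np.array([p.nu_co for p in points])
    y = np.array([p.nu_fec for p in points])
    if np.unique(x).size < 2:
        raise DomainError("back-bonding fit needs >= 2 distinct nu(C-O) values")
    res = linregress(x, y)
    if res.slope >= 0.0:
        warnings.warn(
            f"back-bonding slope {res.slope:.3g} is non-negative; check the input points",
            stacklevel=2,
        )
    return float(res.slope), float(res.intercept), float(res.rvalue)
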