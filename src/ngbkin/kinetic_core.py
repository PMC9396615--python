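"""His64-gated reaction network for CO binding to hexacoordinate globins.

Neuroglobin-type globins keep the distal His64 bound to the heme iron in
the absence of exogenous ligands, so CO can only bind after the His64-Fe
bond breaks.  The network tracked here has five protein states, each a
population fraction:

* ``deoxy`` - pentacoordinate (5c) iron, competent for ligand binding;
* ``hexa``  - bis-histidyl hexacoordinate (6c) iron;
* ``co``    - CO-bound iron;
* ``pair``  - photodissociated CO still inside the distal pocket
  (the geminate pair produced by laser flash photolysis);
* ``trap``  - photodissociated CO parked in a temporary docking site.

Reactions (all pseudo-first order at fixed solvent CO concentration)::

    pair  --k_gem_rebind-->  co            geminate rebinding
    pair  --k_out--------->  deoxy         CO escape to solvent
    pair  <--k_trap_in/k_trap_out-->  trap docking-site exchange
    deoxy <--k_his_on/k_his_off--->  hexa  His64 gating
    deoxy --k_co_on*[CO]-->  co            bimolecular binding
    co    --k_co_off----->   deoxy         CO dissociation

The system is linear in the state, so the right-hand side is ``A @ y``
with a constant matrix ``A`` (built by :func:`rate_matrix`).  Progress
curves are reported as the unliganded fraction ``N(t) = 1 - co(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, IntegrationError, UnsupportedConfigurationError

__all__ = [
    "RateConstants",
    "SpeciesState",
    "PopulationMixture",
    "ProgressCurve",
    "rate_matrix",
    "rhs",
    "closed_form_two_state",
    "simulate_progress_curve",
    "kobs_hexacoordinate",
    "c50_overall",
    "equilibrium_bound_fraction",
]

#: canonical ordering of the state vector
SPECIES = ("deoxy", "hexa", "co", "pair", "trap")


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the gated binding scheme.

    Units: first-order rates in s^-1, ``k_co_on`` in M^-1 s^-1.

    Parameters
    ----------
    k_his_on : float
        Intramolecular His64 association to the heme iron (the field's
        k_H), s^-1.
    k_his_off : float
        His64 dissociation from the iron (k_-H), s^-1.  At saturating CO
        this is the plateau of the observed binding rate.
    k_co_on : float
        Bimolecular CO association from solvent, M^-1 s^-1.
    k_co_off : float
        CO dissociation, s^-1.
    k_gem_rebind : float
        Geminate rebinding of pocket CO to the iron (k_-1), s^-1.
    k_out : float
        Escape of pocket CO to the solvent, s^-1.
    k_trap_in, k_trap_out : float
        Exchange with a temporary docking site, s^-1.  Both zero disables
        the trap.
    """

    k_his_on: float = 0.0
    k_his_off: float = 0.0
    k_co_on: float = 0.0
    k_co_off: float = 0.0
    k_gem_rebind: float = 0.0
    k_out: float = 0.0
    k_trap_in: float = 0.0
    k_trap_out: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0.0:
                raise DomainError(f"rate constant {f.name}={v!r} must be finite and >= 0")

    def replace(self, **kwargs) -> "RateConstants":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return RateConstants(**d)

    @property
    def his_equilibrium(self) -> float:
        """K_H = k_his_on / k_his_off, the His64 binding equilibrium constant."""
        if self.k_his_on == 0.0:
            return 0.0
        if self.k_his_off == 0.0:
            raise DomainError("K_H is infinite: k_his_on > 0 with k_his_off = 0")
        return self.k_his_on / self.k_his_off


@dataclass(frozen=True)
class SpeciesState:
    """Population fractions of the five network species (sum to one)."""

    deoxy: float = 0.0
    hexa: float = 0.0
    co: float = 0.0
    pair: float = 0.0
    trap: float = 0.0

    def __post_init__(self):
        total = 0.0
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < -1e-12 or v > 1.0 + 1e-12:
                raise DomainError(f"species fraction {name}={v!r} outside [0, 1]")
            total += v
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"species fractions sum to {total!r}, expected 1 within 1e-9")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(**dict(zip(SPECIES, map(float, y))))

    @property
    def unliganded(self) -> float:
        """N = 1 - co, the deoxy-like fraction monitored optically."""
        return 1.0 - self.co


@dataclass(frozen=True)
class PopulationMixture:
    """Weighted mixture of kinetically distinct protein populations.

    Hemes insert into the pocket in two orientations (canonical and
    reversed), giving populations with distinct rate sets; observed
    signals are fraction-weighted sums.
    """

    components: tuple[tuple[float, RateConstants], ...]

    def __post_init__(self):
        comps = tuple((float(f), r) for f, r in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise DomainError("mixture must contain at least one component")
        total = 0.0
        for frac, rates in comps:
            if not 0.0 <= frac <= 1.0:
                raise DomainError(f"mixture fraction {frac!r} outside [0, 1]")
            if not isinstance(rates, RateConstants):
                raise DomainError("mixture component rates must be RateConstants")
            total += frac
        if abs(total - 1.0) > 1e-12:
            raise DomainError(f"mixture fractions sum to {total!r}, expected 1 within 1e-12")

    @classmethod
    def single(cls, rates: RateConstants) -> "PopulationMixture":
        return cls(components=((1.0, rates),))


@dataclass(frozen=True)
class ProgressCurve:
    """Unliganded fraction N(t) on a strictly increasing time grid (s)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise DomainError("progress curve needs >= 2 points with matching shapes")
        if t[0] < 0.0 or np.any(np.diff(t) <= 0.0):
            raise DomainError("time grid must be strictly increasing with first point >= 0")
        if not np.all(np.isfinite(v)):
            raise DomainError("progress-curve values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "ProgressCurve":
        """Sub-curve with t_min <= t <= t_max."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if mask.sum() < 2:
            raise DomainError(f"window [{t_min}, {t_max}] keeps fewer than 2 points")
        return ProgressCurve(self.times[mask], self.values[mask])

    @property
    def span(self) -> float:
        return float(self.values.max() - self.values.min())


def rate_matrix(rates: RateConstants, co_conc: float) -> np.ndarray:
    """Constant matrix A with d/dt [deoxy, hexa, co, pair, trap] = A @ y."""
    if not math.isfinite(co_conc) or co_conc < 0.0:
        raise DomainError(f"CO concentration {co_conc!r} must be finite and >= 0")
    kon_c = rates.k_co_on * co_conc
    kh, kmh = rates.k_his_on, rates.k_his_off
    kg, ko = rates.k_gem_rebind, rates.k_out
    kti, kto = rates.k_trap_in, rates.k_trap_out
    koff = rates.k_co_off
    A = np.zeros((5, 5))
    # deoxy
    A[0, 0] = -(kh + kon_c)
    A[0, 1] = kmh
    A[0, 2] = koff
    A[0, 3] = ko
    # hexa
    A[1, 0] = kh
    A[1, 1] = -kmh
    # co
    A[2, 0] = kon_c
    A[2, 2] = -koff
    A[2, 3] = kg
    # pair
    A[3, 3] = -(kg + ko + kti)
    A[3, 4] = kto
    # trap
    A[4, 3] = kti
    A[4, 4] = -kto
    return A


def rhs(state: SpeciesState, rates: RateConstants, co_conc: float) -> np.ndarray:
    """Time derivative of the species fractions, ordered as :data:`SPECIES`.

    The components sum to zero (mass conservation).
    """
    return rate_matrix(rates, co_conc) @ state.as_array()


def closed_form_two_state(
    rates: RateConstants,
    co_conc: float,
    t_grid: np.ndarray,
    init: SpeciesState,
) -> ProgressCurve:
    """Exact biexponential N(t) for the deoxy/hexa pair with irreversible CO capture.

    Valid only when ``k_co_off == 0`` and the pair/trap states are empty:
    the (deoxy, hexa) subsystem is then linear 2x2 with an irreversible
    loss ``k_co_on*[CO]`` from deoxy, and the eigen-solution is exact.
    Serves as the analytic oracle for the numeric integrator.
    """
    if rates.k_co_off != 0.0:
        raise UnsupportedConfigurationError("two-state closed form requires k_co_off = 0")
    if init.pair != 0.0 or init.trap != 0.0:
        raise UnsupportedConfigurationError("two-state closed form requires empty pair/trap states")
    if not math.isfinite(co_conc) or co_conc < 0.0:
        raise DomainError(f"CO concentration {co_conc!r} must be finite and >= 0")
    t = np.asarray(t_grid, dtype=float)
    c = rates.k_co_on * co_conc
    kh, kmh = rates.k_his_on, rates.k_his_off
    # d/dt [D, H] = [[-(kh+c), kmh], [kh, -kmh]] @ [D, H]
    tr = -(kh + c) - kmh
    det = (kh + c) * kmh - kh * kmh  # = c * kmh
    disc = tr * tr - 4.0 * det
    y0 = np.array([init.deoxy, init.hexa])
    if disc <= max(1e-12 * tr * tr, 1e-300):
        # (near-)degenerate eigenvalues: fall back to the matrix exponential
        from scipy.linalg import expm

        A = np.array([[-(kh + c), kmh], [kh, -kmh]])
        n = np.array([float(np.sum(expm(A * ti) @ y0)) for ti in t])
        return ProgressCurve(t, n)
    root = math.sqrt(disc)
    lam1 = 0.5 * (tr + root)
    lam2 = 0.5 * (tr - root)

    def eigvec(lam: float) -> np.ndarray:
        # rows of (A - lam I) are proportional; use whichever is non-trivial
        v = np.array([kmh, lam + kh + c])
        if np.abs(v).max() <= 1e-300 * max(1.0, abs(lam)):
            v = np.array([lam + kmh, -kh])
        if np.abs(v).max() == 0.0:
            v = np.array([1.0, 0.0])
        return v

    # decompose y0 = a1 v1 + a2 v2
    v1, v2 = eigvec(lam1), eigvec(lam2)
    V = np.column_stack([v1, v2])
    a = np.linalg.solve(V, y0)
    # N(t) = D + H = a1 (v1.sum) e^{lam1 t} + a2 (v2.sum) e^{lam2 t}
    n = a[0] * v1.sum() * np.exp(lam1 * t) + a[1] * v2.sum() * np.exp(lam2 * t)
    return ProgressCurve(t, n)


def simulate_progress_curve(
    mixture: PopulationMixture,
    co_conc: float,
    t_grid: np.ndarray,
    init_per_component: "SpeciesState | list[SpeciesState]",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ProgressCurve:
    """Integrate the full network for each population and mix the N(t) curves.

    ``init_per_component`` is either one state shared by every
    population or a sequence with one state per population.  Uses a
    stiff implicit method (BDF) with the analytic, constant Jacobian;
    traces span nanoseconds to seconds so the grid is expected to be
    logarithmic.  Integration always starts at t = 0 (the flash or
    mixing event) even when the grid starts later.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0.0):
        raise DomainError("time grid must be 1-D, strictly increasing, with >= 2 points")
    if t[0] < 0.0:
        raise DomainError("time grid must start at t >= 0")
    if isinstance(init_per_component, SpeciesState):
        inits = [init_per_component] * len(mixture.components)
    else:
        inits = list(init_per_component)
        if len(inits) != len(mixture.components):
            raise DomainError("need one initial state per mixture component")
    total = np.zeros_like(t)
    for (frac, rates), init in zip(mixture.components, inits):
        y0 = init.as_array()
        A = rate_matrix(rates, co_conc)
        sol = solve_ivp(
            lambda _t, y, A=A: A @ y,
            (0.0, float(t[-1])),
            y0,
            method="BDF",
            t_eval=t,
            rtol=rtol,
            atol=atol,
            jac=lambda _t, _y, A=A: A,
        )
        if not sol.success:
            raise IntegrationError(
                f"stiff integration failed: {sol.message}",
                diagnostics={"co_conc": co_conc, "rates": rates, "status": sol.status},
            )
        total += frac * (1.0 - sol.y[2])
    return ProgressCurve(t, total)


def kobs_hexacoordinate(
    rates: RateConstants, co_conc: float, form: str = "pre_equilibrium"
) -> float:
    """Observed stopped-flow binding rate k_obs([CO]) for a 6c globin.

    Binding is a two-step process: rupture of the His64-Fe bond followed
    by fast CO ligation.  Under the rapid pre-equilibrium treatment::

        k_obs = k_his_off * k_co_on*[CO] / (k_his_on + k_co_on*[CO])

    so k_obs saturates at the His64 dissociation rate.  ``form =
    "steady_state"`` uses the steady-state denominator
    ``k_his_on + k_his_off + k_co_on*[CO]`` instead.
    """
    if not math.isfinite(co_conc) or co_conc < 0.0:
        raise DomainError(f"CO concentration {co_conc!r} must be finite and >= 0")
    if rates.k_co_on <= 0.0:
        raise DomainError("k_co_on must be > 0 to evaluate k_obs([CO])")
    kon_c = rates.k_co_on * co_conc
    if form == "pre_equilibrium":
        denom = rates.k_his_on + kon_c
    elif form == "steady_state":
        denom = rates.k_his_on + rates.k_his_off + kon_c
    else:
        raise DomainError(f"unknown k_obs form {form!r}")
    if denom == 0.0:
        return 0.0
    return rates.k_his_off * kon_c / denom


def c50_overall(rates: RateConstants) -> float:
    """Overall CO affinity: the [CO] (M) at which half the protein is bound.

    His64 competes with CO for the iron, so the apparent affinity is
    weakened by the hexacoordination equilibrium K_H = k_his_on/k_his_off::

        c50 = (1 + K_H) * k_co_off / k_co_on
    """
    if rates.k_co_on <= 0.0:
        raise DomainError("k_co_on must be > 0 to define an affinity")
    if rates.k_co_off == 0.0:
        raise DomainError("k_co_off = 0 gives infinite affinity (c50 = 0 is undefined)")
    return (1.0 + rates.his_equilibrium) * rates.k_co_off / rates.k_co_on


def equilibrium_bound_fraction(rates: RateConstants, co_conc: float) -> float:
    """Equilibrium CO-bound fraction Y([CO]) of the deoxy/hexa/co subsystem.

    From detailed balance: co/deoxy = k_co_on*[CO]/k_co_off and
    hexa/deoxy = K_H, giving the single-site isotherm
    Y = [CO] / ([CO] + c50).
    """
    if not math.isfinite(co_conc) or co_conc < 0.0:
        raise DomainError(f"CO concentration {co_conc!r} must be finite and >= 0")
    c50 = c50_overall(rates)
    return co_conc / (co_conc + c50)
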