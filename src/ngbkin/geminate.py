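"""Three-state geminate partition model for flash-photolysis rebinding.

After photolysis the CO sits in the distal pocket and either rebinds to
the iron (rate k_-1, here ``k_gem_rebind``) or escapes to the solvent
(rate ``k_out``).  On the nanosecond window, where bimolecular rebinding
and His64 association are negligible, the observed geminate phase is a
single exponential with apparent rate ``k_gem = k_gem_rebind + k_out``
and amplitude ``phi = k_gem_rebind / k_gem``, so::

    k_out        = (1 - phi) * k_gem
    k_gem_rebind = phi * k_gem

This bijection lets the microscopic rates be read directly off the
fitted geminate amplitude and rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegeneratePartitionError, DomainError
from .kinetic_core import ProgressCurve

__all__ = [
    "GeminatePartition",
    "split_rates",
    "partition_from_rates",
    "geminate_trace",
]


@dataclass(frozen=True)
class GeminatePartition:
    """Geminate rebinding amplitude phi (in [0, 1]) and apparent rate k_gem (s^-1)."""

    phi: float
    k_gem: float

    def __post_init__(self):
        if not (math.isfinite(self.phi) and 0.0 <= self.phi <= 1.0):
            raise DomainError(f"geminate amplitude phi={self.phi!r} must lie in [0, 1]")
        if not (math.isfinite(self.k_gem) and self.k_gem > 0.0):
            raise DomainError(f"apparent geminate rate k_gem={self.k_gem!r} must be > 0")

    @property
    def percent(self) -> int:
        """Amplitude as an integer percentage (field reporting convention)."""
        return round(self.phi * 100.0)


def split_rates(p: GeminatePartition) -> tuple[float, float]:
    """Partition (phi, k_gem) into the microscopic pair (k_gem_rebind, k_out)."""
    k_rebind = p.phi * p.k_gem
    k_out = (1.0 - p.phi) * p.k_gem
    return k_rebind, k_out


def partition_from_rates(k_gem_rebind: float, k_out: float) -> GeminatePartition:
    """Inverse of :func:`split_rates`: phi = k_-1/(k_-1 + k_out), k_gem = k_-1 + k_out."""
    if not (math.isfinite(k_gem_rebind) and k_gem_rebind >= 0.0):
        raise DomainError(f"k_gem_rebind={k_gem_rebind!r} must be finite and >= 0")
    if not (math.isfinite(k_out) and k_out >= 0.0):
        raise DomainError(f"k_out={k_out!r} must be finite and >= 0")
    k_gem = k_gem_rebind + k_out
    if k_gem == 0.0:
        raise DegeneratePartitionError("both geminate rates are zero: partition undefined")
    return GeminatePartition(phi=k_gem_rebind / k_gem, k_gem=k_gem)


def geminate_trace(p: GeminatePartition, t_grid: np.ndarray) -> ProgressCurve:
    """Noiseless geminate-phase progress curve N(t) = 1 - phi*(1 - exp(-k_gem*t)).

    Valid on a window where bulk CO rebinding and His64 association are
    negligible (k_gem * t_max of order <= 20).
    """
    t = np.asarray(t_grid, dtype=float)
    n = 1.0 - p.phi * (1.0 - np.exp(-p.k_gem * t))
    return ProgressCurve(t, n)
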