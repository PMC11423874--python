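"""Bi-exponential NAD(P)H decay model and derived metabolic readouts.

The fluorescence decay of NAD(P)H recorded by TCSPC is modelled as the sum
of two exponential components plus a constant background:

    I(t) = alpha1 * exp(-t / tau1) + alpha2 * exp(-t / tau2) + C

where ``tau1`` is the short lifetime of free NAD(P)H, ``tau2`` the long
lifetime of protein-bound NAD(P)H, ``alpha1``/``alpha2`` the component
amplitudes and ``C`` a constant background-light level (counts per bin).
The instrument response function is not part of the model.

From a fitted parameter set two scalar readouts are derived:

* the amplitude-weighted mean lifetime
  ``tau_avg = (alpha1*tau1 + alpha2*tau2) / (alpha1 + alpha2)`` — higher
  values indicate dominance of oxidative phosphorylation, lower values
  a shift toward glycolysis;
* the bound fraction ``alpha2 / (alpha1 + alpha2)`` of protein-bound
  NAD(P)H.

The optical redox ratio (ORR) combines the FAD and NAD(P)H channel
intensities as ``ORR = FAD / NAD(P)H``; only FAD *intensity* enters (no
FAD lifetime fitting).

All lifetimes are carried in nanoseconds. The default time axis derives
from an 80 MHz pulsed laser: a 12.5 ns period divided into 256 bins
(~48.8 ps per bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    UndefinedLifetimeError,
    UndefinedRatioError,
    ValidationError,
)

__all__ = [
    "DecayParams",
    "TimeAxis",
    "evaluate_decay",
    "average_lifetime",
    "bound_fraction",
    "free_fraction",
    "optical_redox_ratio",
]


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the bi-exponential decay for one pixel or ROI.

    Components are canonicalised on construction so that
    ``tau1 <= tau2`` always holds: ``tau1`` is the short (free NAD(P)H)
    lifetime and ``tau2`` the long (protein-bound) lifetime, with the
    amplitudes following their components through any swap.

    Parameters
    ----------
    alpha1, alpha2
        Nonnegative component amplitudes (photon-count scale). Their sum
        must be positive. Whether they are normalised fractions or raw
        amplitudes does not matter: every derived quantity is invariant
        to their common scale.
    tau1, tau2
        Component lifetimes in nanoseconds, strictly positive. ``tau2``
        may be omitted when ``alpha2 == 0`` (mono-exponential case); it
        then defaults to ``tau1``.
    background
        Constant background light ``C`` in counts per bin, nonnegative.
    """

    alpha1: float
    tau1: float
    alpha2: float = 0.0
    tau2: float | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        tau2 = self.tau1 if self.tau2 is None else self.tau2
        vals = (self.alpha1, self.tau1, self.alpha2, tau2, self.background)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite decay parameter in {vals!r}")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValidationError("amplitudes must be nonnegative")
        if self.alpha1 + self.alpha2 <= 0:
            raise ValidationError("total amplitude alpha1 + alpha2 must be positive")
        if self.tau1 <= 0 or tau2 <= 0:
            raise ValidationError("lifetimes must be strictly positive")
        if self.background < 0:
            raise ValidationError("background must be nonnegative")
        # canonical free/bound ordering: tau1 <= tau2
        if self.tau1 > tau2:
            a1, t1 = self.alpha2, tau2
            a2, t2 = self.alpha1, self.tau1
            object.__setattr__(self, "alpha1", a1)
            object.__setattr__(self, "tau1", t1)
            object.__setattr__(self, "alpha2", a2)
            object.__setattr__(self, "tau2", t2)
        else:
            object.__setattr__(self, "tau2", tau2)

    def as_array(self) -> np.ndarray:
        """Return ``[alpha1, tau1, alpha2, tau2, background]``."""
        return np.array(
            [self.alpha1, self.tau1, self.alpha2, self.tau2, self.background],
            dtype=float,
        )


#: Laser repetition period for an 80 MHz pulsed source, nanoseconds.
DEFAULT_PERIOD_NS = 12.5
#: Default number of TCSPC time bins per pixel.
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class TimeAxis:
    """TCSPC time axis: ``n_bins`` bins spanning one laser period.

    Defaults reproduce the acquisition geometry of an 80 MHz pulsed
    laser (12.5 ns period) histogrammed into 256 bins.
    """

    n_bins: int = DEFAULT_N_BINS
    period: float = DEFAULT_PERIOD_NS
    bin_width: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("time axis needs at least 2 bins")
        if self.period <= 0:
            raise ValidationError("laser period must be positive")
        bw = self.bin_width if self.bin_width > 0 else self.period / self.n_bins
        if self.n_bins * bw > self.period * (1 + 1e-9):
            raise ValidationError(
                f"{self.n_bins} bins of {bw} ns exceed the {self.period} ns period"
            )
        object.__setattr__(self, "bin_width", bw)

    @property
    def bin_edges(self) -> np.ndarray:
        """Bin edges in ns, length ``n_bins + 1``."""
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers in ns, strictly increasing, within [0, period)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def evaluate_decay(params: DecayParams, times: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the model intensity ``I(t)`` at the given times (ns).

    ``I(t) = alpha1*exp(-t/tau1) + alpha2*exp(-t/tau2) + background``.
    At ``t = 0`` this equals ``alpha1 + alpha2 + background``; for
    ``t -> inf`` it tends to ``background``.
    """
    if not isinstance(params, DecayParams):
        raise ValidationError("params must be a DecayParams instance")
    t = np.asarray(times, dtype=float)
    out = (
        params.alpha1 * np.exp(-t / params.tau1)
        + params.alpha2 * np.exp(-t / params.tau2)
        + params.background
    )
    return float(out) if np.isscalar(times) else out


def average_lifetime(params: DecayParams) -> float:
    """Amplitude-weighted mean lifetime ``tau_avg`` in ns.

    ``tau_avg = (tau1*alpha1 + tau2*alpha2) / (alpha1 + alpha2)``.
    Always lies between ``tau1`` and ``tau2``.
    """
    total = params.alpha1 + params.alpha2
    if total <= 0:
        raise UndefinedLifetimeError("alpha1 + alpha2 must be positive")
    return (params.tau1 * params.alpha1 + params.tau2 * params.alpha2) / total


def bound_fraction(params: DecayParams) -> float:
    """Fraction of the signal amplitude in the protein-bound (long) component.

    ``alpha2 / (alpha1 + alpha2)``, in [0, 1].
    """
    total = params.alpha1 + params.alpha2
    if total <= 0:
        raise UndefinedLifetimeError("alpha1 + alpha2 must be positive")
    return params.alpha2 / total


def free_fraction(params: DecayParams) -> float:
    """Fraction of the signal amplitude in the free (short) component."""
    return 1.0 - bound_fraction(params)


def optical_redox_ratio(fad_intensity: float, nadph_intensity: float) -> float:
    """Optical redox ratio ``ORR = FAD / NAD(P)H`` for scalar intensities.

    Scale-invariant under joint rescaling of both channels. Raises
    :class:`~flimmet.errors.UndefinedRatioError` when the NAD(P)H
    intensity is not positive (such pixels are masked out upstream).
    """
    fad = float(fad_intensity)
    nadph = float(nadph_intensity)
    if not (math.isfinite(fad) and math.isfinite(nadph)):
        raise ValidationError("intensities must be finite")
    if fad < 0:
        raise ValidationError("FAD intensity must be nonnegative")
    if nadph <= 0:
        raise UndefinedRatioError("NAD(P)H intensity must be positive")
    return fad / nadph
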