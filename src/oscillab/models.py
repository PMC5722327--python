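"""Forward mechanical models of the respiratory system.

The respiratory system seen from the mouth behaves, over the 4-32 Hz
oscillometry band, approximately like a lumped mechanical network.  The
models here produce complex input impedance

    Z(f) = Rrs(f) + j * Xrs(f)      [cmH2O.s/L]

with the convention that inertial reactance is positive (pressure leads
flow) and compliant (elastic) reactance is negative:

    X(f) = 2*pi*f*I - 1 / (2*pi*f*C)

Variants
--------
``pure_resistor``
    Z = R at every frequency; useful as the simplest possible oracle.
``ric``
    Series resistance-inertance-compliance branch; the classical
    single-compartment description of respiratory mechanics.
``eric``
    RIC with a linear frequency dependence of resistance,
    Re Z(f) = R + slope*f.  A negative slope encodes ventilation
    heterogeneity (the frequency dependence of resistance seen in
    diseased lungs) in a directly controllable way.
``two_compartment``
    Two RIC branches in parallel; heterogeneity emerges from the
    topology instead of being imposed on the resistance.

All frequencies are plain Hz; angular conversion happens inside the
formulas and never leaks into interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    FrequencyDomainError,
    ModelValidationError,
    UndefinedResonanceError,
    UnsupportedModelError,
)

VARIANTS = ("pure_resistor", "ric", "eric", "two_compartment")

#: Band over which the instrument excites the system; an ``eric`` model
#: with negative slope must keep its resistance positive across it.
EXCITATION_BAND = (4.0, 32.0)


@dataclass(frozen=True)
class MechanicalModel:
    """Ground-truth lumped respiratory model.

    Parameters
    ----------
    variant
        One of ``pure_resistor``, ``ric``, ``eric``, ``two_compartment``.
    R
        Resistance, cmH2O.s/L.  Must be positive.
    I
        Inertance, cmH2O.s^2/L.  Non-negative.
    C
        Compliance, L/cmH2O.  Positive for reactive variants.
    slope
        Frequency slope of resistance, cmH2O.s/L per Hz (``eric`` only).
    branch2
        Second ``(R, I, C)`` triple (``two_compartment`` only).
    """

    variant: str
    R: float
    I: float = 0.0
    C: float = float("nan")
    slope: float = 0.0
    branch2: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ModelValidationError(f"unknown variant {self.variant!r}")
        if not self.R > 0:
            raise ModelValidationError("R must be positive")
        if self.I < 0:
            raise ModelValidationError("I must be non-negative")
        if self.variant in ("ric", "eric"):
            if not (np.isfinite(self.C) and self.C > 0):
                raise ModelValidationError("C must be positive for ric/eric")
        if self.variant == "eric" and self.slope < 0:
            # keep Re Z > 0 across the excitation band
            if self.R + self.slope * EXCITATION_BAND[1] <= 0:
                raise ModelValidationError(
                    "negative slope drives resistance non-positive within "
                    f"{EXCITATION_BAND[0]:g}-{EXCITATION_BAND[1]:g} Hz"
                )
        if self.variant == "two_compartment":
            if self.branch2 is None:
                raise ModelValidationError("two_compartment requires branch2")
            r2, i2, c2 = self.branch2
            if not r2 > 0 or i2 < 0 or not c2 > 0:
                raise ModelValidationError("branch2 requires R > 0, I >= 0, C > 0")
            if not (np.isfinite(self.C) and self.C > 0):
                raise ModelValidationError("two_compartment requires C > 0 in both branches")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on an increasing frequency grid."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=complex))
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must have matching shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def resistance(self) -> np.ndarray:
        return self.values.real

    @property
    def reactance(self) -> np.ndarray:
        return self.values.imag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"freq_hz": self.freqs, "rrs": self.resistance, "xrs": self.reactance}
        )


def _series_impedance(R: float, I: float, C: float, f: np.ndarray) -> np.ndarray:
    w = 2.0 * np.pi * f
    return R + 1j * (w * I - 1.0 / (w * C))


def eval_impedance(model: MechanicalModel, freqs: Sequence[float]) -> ImpedanceSpectrum:
    """Evaluate the model impedance at the given frequencies (Hz).

    Raises
    ------
    FrequencyDomainError
        If any frequency is non-positive.
    """
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(f <= 0):
        raise FrequencyDomainError("frequencies must be strictly positive")

    if model.variant == "pure_resistor":
        z = np.full_like(f, model.R, dtype=complex)
    elif model.variant == "ric":
        z = _series_impedance(model.R, model.I, model.C, f)
    elif model.variant == "eric":
        z = _series_impedance(model.R, model.I, model.C, f) + model.slope * f
    else:  # two_compartment
        z1 = _series_impedance(model.R, model.I, model.C, f)
        r2, i2, c2 = model.branch2  # type: ignore[misc]
        z2 = _series_impedance(r2, i2, c2, f)
        z = z1 * z2 / (z1 + z2)
    return ImpedanceSpectrum(freqs=f, values=z)


def resonance_closed_form(model: MechanicalModel) -> float:
    """Resonance frequency fr = 1 / (2*pi*sqrt(I*C)) of a series branch.

    Only defined for ``ric`` and ``eric`` (where the resistive part does
    not affect the reactance zero).  A two-compartment model has no
    closed form; locate its crossing numerically from
    :func:`eval_impedance`.
    """
    if model.variant not in ("ric", "eric"):
        raise UnsupportedModelError(
            f"closed-form resonance undefined for variant {model.variant!r}"
        )
    if model.I <= 0:
        raise UndefinedResonanceError("resonance undefined for zero inertance")
    return 1.0 / (2.0 * np.pi * np.sqrt(model.I * model.C))
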