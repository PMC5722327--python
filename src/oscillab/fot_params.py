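"""Reduction of a measured impedance to the eight oscillometry parameters.

Resistive parameters come from an ordinary least-squares line fit to
the real part of the impedance over 4-16 Hz:

    Re Z(f) = R0 + S * f

* ``R0``  intercept resistance (low-frequency limit of the fit line)
* ``S``   slope of the resistance frequency dependence, per Hz; values
          near zero are healthy, progressively negative values indicate
          heterogeneous ventilation
* ``Rm``  mean resistance over the fitted band (airway caliber)
* ``R4``  resistance at 4 Hz

Reactive parameters use the full measured band:

* ``Xm``   mean reactance over 4-32 Hz
* ``fr``   resonance frequency: the interpolated zero crossing of the
           reactance (extrapolated and flagged when the crossing lies
           above the band)
* ``Cdyn`` dynamic compliance from the lowest measured frequency,
           Cdyn = -1 / (2*pi*4*X(4)), defined only when X(4) < 0
* ``Z4``   impedance modulus at 4 Hz, sqrt(R4^2 + X4^2) — the total
           mechanical load presented to the respiratory muscles
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .spectral import MeasuredImpedance

RESISTIVE_BAND = (4.0, 16.0)
REACTIVE_BAND = (4.0, 32.0)

FEATURE_COLUMNS = ("r0", "rm", "r4", "s", "xm", "fr", "cdyn", "z4")


@dataclass(frozen=True)
class ResistiveParams:
    r0: float
    s: float
    rm: float
    r4: float
    r4_available: bool
    n_points: int


@dataclass(frozen=True)
class ReactiveParams:
    xm: float
    fr: float
    fr_status: str  # "measured" | "extrapolated" | "unavailable"
    cdyn: float
    cdyn_defined: bool
    z4: float


@dataclass(frozen=True)
class FotParameters:
    """The eight per-subject oscillometry scalars plus QC annotations."""

    r0: float
    rm: float
    r4: float
    s: float
    xm: float
    fr: float
    cdyn: float
    z4: float
    fr_status: str = "measured"
    cdyn_defined: bool = True
    r4_available: bool = True
    n_exams: int = 1

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def _usable(mi: MeasuredImpedance, band: Tuple[float, float]) -> np.ndarray:
    mask = (mi.freqs >= band[0]) & (mi.freqs <= band[1])
    if mi.qc_pass is not None:
        mask &= mi.qc_pass
    return mask


def extract_resistive(mi: MeasuredImpedance,
                      band: Tuple[float, float] = RESISTIVE_BAND) -> ResistiveParams:
    """OLS line fit of Re Z over the resistive band.

    Needs at least two QC-passing components within the band; R4 is
    flagged unavailable when the 4 Hz component is missing or failed QC.
    """
    mask = _usable(mi, band)
    f = mi.freqs[mask]
    r = mi.Z.real[mask]
    if f.size < 2:
        raise InsufficientDataError(
            f"need >= 2 usable components in [{band[0]:g}, {band[1]:g}] Hz, got {f.size}"
        )
    slope, intercept = np.polyfit(f, r, 1)
    rm = float(np.mean(r))
    at4 = np.isclose(f, 4.0)
    r4_available = bool(at4.any())
    r4 = float(r[at4][0]) if r4_available else float("nan")
    return ResistiveParams(r0=float(intercept), s=float(slope), rm=rm, r4=r4,
                           r4_available=r4_available, n_points=int(f.size))


def _zero_crossing(f: np.ndarray, x: np.ndarray,
                   allow_extrapolation: bool) -> Tuple[float, str]:
    """First upward zero crossing of the reactance, linearly interpolated."""
    for i in range(f.size - 1):
        if x[i] < 0.0 <= x[i + 1]:
            if x[i + 1] == 0.0:
                return float(f[i + 1]), "measured"
            frac = -x[i] / (x[i + 1] - x[i])
            return float(f[i] + frac * (f[i + 1] - f[i])), "measured"
    if x[0] == 0.0 and np.all(x == 0.0):
        return float("nan"), "unavailable"
    if np.all(x < 0.0) and allow_extrapolation and f.size >= 2:
        df = x[-1] - x[-2]
        if df > 0:  # reactance rising toward zero beyond the band
            return float(f[-1] + (-x[-1]) / df * (f[-1] - f[-2])), "extrapolated"
    return float("nan"), "unavailable"


def extract_reactive(mi: MeasuredImpedance,
                     band: Tuple[float, float] = REACTIVE_BAND,
                     allow_extrapolation: bool = True) -> ReactiveParams:
    """Mean reactance, resonance frequency, dynamic compliance, |Z| at 4 Hz."""
    mask = _usable(mi, band)
    f = mi.freqs[mask]
    x = mi.Z.imag[mask]
    if f.size < 2:
        raise InsufficientDataError(
            f"need >= 2 usable components in [{band[0]:g}, {band[1]:g}] Hz, got {f.size}"
        )
    xm = float(np.mean(x))
    fr, fr_status = _zero_crossing(f, x, allow_extrapolation)

    at4 = np.isclose(f, 4.0)
    if at4.any():
        x4 = float(x[at4][0])
        r4 = float(mi.Z.real[mask][at4][0])
        z4 = math.hypot(r4, x4)
        if x4 < 0:
            cdyn = -1.0 / (2.0 * np.pi * 4.0 * x4)
            cdyn_defined = True
        else:
            cdyn, cdyn_defined = float("nan"), False
    else:
        x4 = float("nan")
        z4 = float("nan")
        cdyn, cdyn_defined = float("nan"), False
    return ReactiveParams(xm=xm, fr=fr, fr_status=fr_status,
                          cdyn=cdyn, cdyn_defined=cdyn_defined, z4=z4)


def extract_all(mi: MeasuredImpedance,
                resistive_band: Tuple[float, float] = RESISTIVE_BAND,
                reactive_band: Tuple[float, float] = REACTIVE_BAND,
                allow_extrapolation: bool = True) -> FotParameters:
    """Full eight-parameter reduction of one subject's averaged impedance."""
    res = extract_resistive(mi, resistive_band)
    rea = extract_reactive(mi, reactive_band, allow_extrapolation)
    return FotParameters(
        r0=res.r0, rm=res.rm, r4=res.r4, s=res.s,
        xm=rea.xm, fr=rea.fr, cdyn=rea.cdyn, z4=rea.z4,
        fr_status=rea.fr_status, cdyn_defined=rea.cdyn_defined,
        r4_available=res.r4_available, n_exams=mi.n_exams,
    )


def features_frame(rows: Sequence[Tuple[str, str, FotParameters]]) -> pd.DataFrame:
    """Tidy per-subject feature table: (subject_id, group, params) rows."""
    out = []
    for subject_id, group, p in rows:
        row = {"subject_id": subject_id, "group": group, **p.as_dict(),
               "fr_status": p.fr_status, "cdyn_defined": p.cdyn_defined,
               "n_exams": p.n_exams}
        out.append(row)
    return pd.DataFrame(out)
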