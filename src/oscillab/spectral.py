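"""Cross-spectral impedance estimation with coherence quality control.

The estimator follows the classical block-FFT scheme: auto- and
cross-spectra are averaged over 4096-sample blocks with 50% overlap
(7 blocks for a 16 s record at 1024 Hz), impedance is read off at the
excitation component bins, and the magnitude-squared coherence gates
exam quality at gamma^2 >= 0.9.

Estimator form: the flow-referenced H1 estimator

    Z(f) = Gqp(f) / Gqq(f),       gamma^2(f) = |Gpq|^2 / (Gpp * Gqq)

where Gqp = E[Q* P].  Referencing the flow auto-spectrum attenuates
pressure-channel noise that is uncorrelated with flow.  The default
Hann taper with per-block linear detrend suppresses breathing leakage
into the 4 Hz component; a rectangular taper without detrend is exact
for bin-aligned noiseless signals and is used by the unit oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateSignalError,
    ExamQCError,
    GridError,
    RecordLengthError,
)
from .synthetic import PressureFlowRecord

COHERENCE_THRESHOLD = 0.9

_DETREND = {"none": False, "mean": "constant", "linear": "linear"}


@dataclass(frozen=True)
class WindowSpec:
    """Block-averaging parameters for the spectral estimator."""

    block_len: int = 4096
    overlap_fraction: float = 0.5
    taper: str = "hann"  # "hann" | "rectangular"
    detrend: str = "linear"  # "none" | "mean" | "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.taper not in ("hann", "rectangular"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.detrend not in _DETREND:
            raise ValueError(f"unknown detrend {self.detrend!r}")

    @property
    def noverlap(self) -> int:
        return int(round(self.block_len * self.overlap_fraction))

    @property
    def window(self):
        return "hann" if self.taper == "hann" else ("boxcar")


@dataclass(frozen=True)
class CrossSpectra:
    """Averaged auto/cross spectra on the FFT bin grid."""

    freqs: np.ndarray  # Hz, bin spacing fs / block_len
    gpp: np.ndarray  # pressure auto-spectrum
    gqq: np.ndarray  # flow auto-spectrum
    gqp: np.ndarray  # cross-spectrum E[Q* P]
    n_blocks: int


@dataclass(frozen=True)
class MeasuredImpedance:
    """Impedance and coherence at the excitation components, with QC."""

    freqs: np.ndarray
    Z: np.ndarray
    coherence: np.ndarray
    qc_pass: Optional[np.ndarray] = None
    exam_pass: Optional[bool] = None
    threshold: Optional[float] = None
    n_exams: int = 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "freq_hz": self.freqs, "rrs": self.Z.real, "xrs": self.Z.imag,
            "coherence": self.coherence,
        })
        if self.qc_pass is not None:
            df["qc_pass"] = self.qc_pass
        return df


def welch_cross_spectra(record: PressureFlowRecord,
                        window: Optional[WindowSpec] = None) -> CrossSpectra:
    """Averaged periodogram auto/cross spectra of one record.

    All maximal overlapping blocks are used; bin spacing is
    ``fs / block_len``.
    """
    window = window or WindowSpec()
    n = record.n_samples
    if n < window.block_len:
        raise RecordLengthError(
            f"record of {n} samples shorter than one {window.block_len}-sample block"
        )
    kwargs = dict(fs=record.fs, window=window.window, nperseg=window.block_len,
                  noverlap=window.noverlap, detrend=_DETREND[window.detrend],
                  return_onesided=True, scaling="density")
    f, gpp = signal.welch(record.p, **kwargs)
    _, gqq = signal.welch(record.q, **kwargs)
    _, gqp = signal.csd(record.q, record.p, **kwargs)  # conj(Q) * P
    step = window.block_len - window.noverlap
    n_blocks = (n - window.block_len) // step + 1
    return CrossSpectra(freqs=f, gpp=gpp, gqq=gqq, gqp=gqp, n_blocks=n_blocks)


def impedance_from_spectra(spectra: CrossSpectra,
                           component_freqs: Sequence[float]) -> MeasuredImpedance:
    """Read impedance and coherence off the component bins.

    ``Z(f) = Gqp(f)/Gqq(f)`` evaluated only at bins coinciding with the
    excitation components; coherence ``|Gpq|^2 / (Gpp * Gqq)``.
    """
    comps = np.asarray(component_freqs, dtype=float)
    df_bin = float(spectra.freqs[1] - spectra.freqs[0])
    idx = np.round(comps / df_bin).astype(int)
    if np.any(idx >= spectra.freqs.size) or np.any(
            np.abs(spectra.freqs[idx] - comps) > 1e-6 * max(df_bin, 1.0)):
        raise GridError("component frequency does not coincide with an FFT bin")
    gqq = spectra.gqq[idx]
    if np.any(gqq == 0):
        raise DegenerateSignalError("zero flow auto-spectrum at a component bin")
    z = spectra.gqp[idx] / gqq
    coh = np.abs(spectra.gqp[idx]) ** 2 / (spectra.gpp[idx] * gqq)
    coh = np.clip(coh.real, 0.0, 1.0)
    return MeasuredImpedance(freqs=comps, Z=z, coherence=coh)


def coherence_qc(mi: MeasuredImpedance,
                 threshold: float = COHERENCE_THRESHOLD) -> MeasuredImpedance:
    """Flag component and exam quality; the threshold is inclusive."""
    qc = mi.coherence >= threshold
    return replace(mi, qc_pass=qc, exam_pass=bool(np.all(qc)), threshold=threshold)


def average_exams(exams: Sequence[MeasuredImpedance]) -> MeasuredImpedance:
    """Complex mean of Z across QC-passing exams, per frequency.

    Exams whose ``exam_pass`` flag is false are excluded; with no
    passing exam the subject fails QC (:class:`ExamQCError`).
    """
    if not exams:
        raise ExamQCError("no exams supplied")
    freqs = exams[0].freqs
    for e in exams[1:]:
        if not np.array_equal(e.freqs, freqs):
            raise ValueError("exams must share a frequency grid")
    passing = [e for e in exams if e.exam_pass or e.exam_pass is None]
    if not passing:
        raise ExamQCError("no exam passed the coherence quality gate")
    z = np.mean([e.Z for e in passing], axis=0)
    coh = np.mean([e.coherence for e in passing], axis=0)
    threshold = passing[0].threshold
    qc = np.ones(freqs.size, dtype=bool)
    return MeasuredImpedance(freqs=freqs, Z=z, coherence=coh, qc_pass=qc,
                             exam_pass=True, threshold=threshold,
                             n_exams=len(passing))


def estimate_exam(record: PressureFlowRecord,
                  window: Optional[WindowSpec] = None,
                  component_freqs: Optional[Sequence[float]] = None,
                  threshold: float = COHERENCE_THRESHOLD) -> MeasuredImpedance:
    """Record -> QC-flagged impedance, at the record's excitation components."""
    if component_freqs is None:
        exc = record.meta.get("excitation")
        if exc is None:
            raise ValueError("component_freqs required when record has no metadata")
        component_freqs = (exc["component_freqs"] if isinstance(exc, dict)
                           else exc.component_freqs)
    cs = welch_cross_spectra(record, window)
    return coherence_qc(impedance_from_spectra(cs, component_freqs), threshold)


def estimate_subject(records: Sequence[PressureFlowRecord],
                     window: Optional[WindowSpec] = None,
                     component_freqs: Optional[Sequence[float]] = None,
                     threshold: float = COHERENCE_THRESHOLD) -> MeasuredImpedance:
    """Average the QC-passing exams of one subject."""
    return average_exams([
        estimate_exam(r, window, component_freqs, threshold) for r in records
    ])
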