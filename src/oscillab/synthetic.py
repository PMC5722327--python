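"""Multisine excitation and forward synthesis of pressure/flow records.

The measurement being emulated superimposes a pseudorandom multisine
pressure excitation (components every 2 Hz from 4 to 32 Hz, 2 cmH2O
peak-to-peak overall) on spontaneous breathing, samples pressure and
flow at 1024 Hz for 16 s, and later analyses blocks of 4096 samples.
Component frequencies are therefore required to sit exactly on the
fs/4096 bin grid so that block FFTs see them leakage-free.

Synthesis is a steady-state phasor solution: for each component the
flow is the pressure phasor divided by the model impedance, summed in
the time domain.  Spontaneous breathing is modelled as a single
low-frequency flow sinusoid plus its Ohmic pressure response, and
sensor noise as independent Gaussian white noise on each channel.  The
record is fully reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ExcitationSpecError, SingularModelError
from .models import MechanicalModel, eval_impedance

#: Default component grid, Hz: 4, 6, ..., 32 (15 tones, 2 Hz apart —
#: eight 0.25 Hz analysis bins between neighbouring tones).
DEFAULT_COMPONENTS: Tuple[float, ...] = tuple(float(f) for f in range(4, 33, 2))

ANALYSIS_BLOCK = 4096  # samples per spectral-analysis block


@dataclass(frozen=True)
class ExcitationSpec:
    """Pseudorandom multisine pressure excitation.

    ``component_freqs`` must lie in [4, 32] Hz and on the ``fs/4096``
    bin grid.  ``peak_to_peak`` is enforced exactly on the synthesized
    waveform (the equal component amplitudes are rescaled after the
    random phases are drawn).
    """

    component_freqs: Tuple[float, ...] = DEFAULT_COMPONENTS
    peak_to_peak: float = 2.0  # cmH2O
    fs: float = 1024.0  # samples/s
    duration: float = 16.0  # s
    phase_seed: int = 0

    def __post_init__(self) -> None:
        if not self.component_freqs:
            raise ExcitationSpecError("at least one component frequency required")
        if self.peak_to_peak <= 0:
            raise ExcitationSpecError("peak_to_peak must be positive")
        bin_hz = self.fs / ANALYSIS_BLOCK
        for f in self.component_freqs:
            if not (4.0 <= f <= 32.0):
                raise ExcitationSpecError(f"component {f} Hz outside [4, 32] Hz")
            if abs(f / bin_hz - round(f / bin_hz)) > 1e-9:
                raise ExcitationSpecError(
                    f"component {f} Hz is not a multiple of the {bin_hz:g} Hz bin grid"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class NoiseSpec:
    """Disturbances added on top of the deterministic excitation.

    Breathing is a single sinusoid well below the excitation band; its
    frequency must stay below the lowest component so that it occupies
    disjoint analysis bins.  Sensor noise is white Gaussian, independent
    between the pressure and flow channels.
    """

    breathing_freq: float = 0.25  # Hz
    breathing_flow_amplitude: float = 0.4  # L/s
    pressure_noise_sd: float = 0.05  # cmH2O
    flow_noise_sd: float = 0.02  # L/s

    def __post_init__(self) -> None:
        for name in ("breathing_freq", "breathing_flow_amplitude",
                     "pressure_noise_sd", "flow_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Fully deterministic synthesis: no breathing, no sensor noise."""
        return cls(breathing_flow_amplitude=0.0, pressure_noise_sd=0.0,
                   flow_noise_sd=0.0)


@dataclass
class PressureFlowRecord:
    """One oscillometry exam: paired pressure/flow series plus provenance."""

    p: np.ndarray  # cmH2O
    q: np.ndarray  # L/s
    fs: float
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.p.shape != self.q.shape:
            raise ValueError("pressure and flow must have equal length")

    @property
    def n_samples(self) -> int:
        return self.p.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "p_cmh2o": self.p, "q_lps": self.q})

    def save(self, path: str | Path) -> None:
        """Write the record as CSV with a JSON sidecar manifest."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"fs": self.fs, **_jsonable(self.meta)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PressureFlowRecord":
        path = Path(path)
        df = pd.read_csv(path)
        fs = 1.0 / float(np.median(np.diff(df["t_s"])))
        meta: Dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fs = float(meta.pop("fs", fs))
        return cls(p=df["p_cmh2o"].to_numpy(), q=df["q_lps"].to_numpy(), fs=fs, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def _excitation_components(spec: ExcitationSpec) -> Tuple[np.ndarray, np.ndarray, float]:
    """Per-component (freqs, phases, amplitude) realizing the spec exactly."""
    freqs = np.asarray(spec.component_freqs, dtype=float)
    rng = np.random.default_rng(spec.phase_seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    t = np.arange(spec.n_samples) / spec.fs
    raw = np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    amplitude = spec.peak_to_peak / (raw.max() - raw.min())
    return freqs, phases, amplitude


def make_excitation(spec: ExcitationSpec) -> np.ndarray:
    """Synthesize the multisine pressure waveform, cmH2O.

    Equal-amplitude sinusoids at the component frequencies with
    pseudorandom phases drawn from ``phase_seed``, rescaled so that
    ``max - min`` equals ``peak_to_peak`` exactly.
    """
    freqs, phases, amplitude = _excitation_components(spec)
    t = np.arange(spec.n_samples) / spec.fs
    wave = np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    return amplitude * wave


def synthesize_record(
    model: MechanicalModel,
    excitation: ExcitationSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> PressureFlowRecord:
    """Simulate one exam of the given model.

    The oscillatory flow at each component is the steady-state phasor
    solution Q(f) = P(f) / Z(f).  Breathing flow and its Ohmic pressure
    response, then independent Gaussian sensor noise, are superimposed.
    """
    excitation = excitation or ExcitationSpec()
    noise = noise or NoiseSpec()
    freqs, phases, amp = _excitation_components(excitation)
    z = eval_impedance(model, freqs).values
    if np.any(np.abs(z) == 0):
        raise SingularModelError("model impedance vanishes at an excitation component")

    t = np.arange(excitation.n_samples) / excitation.fs
    arg = 2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
    p = amp * np.cos(arg).sum(axis=0)
    # Q = P/Z: amplitude divides by |Z|, phase lags by arg(Z)
    q = (amp / np.abs(z)[:, None] * np.cos(arg - np.angle(z)[:, None])).sum(axis=0)

    if noise.breathing_flow_amplitude > 0:
        qb = noise.breathing_flow_amplitude * np.sin(2.0 * np.pi * noise.breathing_freq * t)
        r_breath = float(eval_impedance(model, [noise.breathing_freq]).values.real[0])
        q = q + qb
        p = p + r_breath * qb

    rng = np.random.default_rng(seed)
    if noise.pressure_noise_sd > 0:
        p = p + rng.normal(0.0, noise.pressure_noise_sd, size=t.size)
    if noise.flow_noise_sd > 0:
        q = q + rng.normal(0.0, noise.flow_noise_sd, size=t.size)

    meta = {
        "seed": int(seed),
        "model": {
            "variant": model.variant, "R": model.R, "I": model.I,
            "C": model.C, "slope": model.slope, "branch2": model.branch2,
        },
        "excitation": excitation,
        "noise": noise,
    }
    return PressureFlowRecord(p=p, q=q, fs=excitation.fs, meta=meta)
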