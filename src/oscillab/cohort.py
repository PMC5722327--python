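"""Synthetic cohorts with known ground truth.

A cohort mirrors the three study groups — healthy controls, patients
with a normal spirometric exam (NE) and patients with an abnormal,
restrictive exam (AE) — with default sizes 23 / 21 / 24.  Each subject
is an ``eric`` mechanical model whose parameters are drawn from
group-level normal distributions truncated at physical bounds, and is
examined three times; downstream analysis averages the three exams.

The only published anchors for the group distributions are the control
and AE resistance means (2.77 +/- 0.23 and 3.91 +/- 0.57 cmH2O.s/L).
The remaining defaults are calibration choices that reproduce the
qualitative group contrasts (resistance up, dynamic compliance down,
resonance frequency up, resistance slope more negative with disease);
see the methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GenerationError, ModelValidationError
from .models import MechanicalModel
from .synthetic import ExcitationSpec, NoiseSpec, PressureFlowRecord, synthesize_record

GROUP_LABELS = ("control", "NE", "AE")

#: Truncation bounds applied when drawing ground-truth parameters.
BOUNDS = {"R": (0.1, np.inf), "I": (0.0, np.inf), "C": (0.001, np.inf),
          "slope": (-np.inf, np.inf)}
MAX_REDRAWS = 100


@dataclass(frozen=True)
class GroupConfig:
    """Ground-truth distribution of one study group.

    Each parameter is an independent ``(mean, sd)`` normal, truncated at
    the physical bounds above; draws that cannot produce a valid model
    are rejected and redrawn.
    """

    label: str
    n: int
    R: Tuple[float, float]
    slope: Tuple[float, float]
    I: Tuple[float, float]
    C: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name in ("R", "slope", "I", "C"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be non-negative")


def default_groups() -> List[GroupConfig]:
    """Study-condition defaults for the three groups (sizes 23/21/24)."""
    return [
        GroupConfig("control", 23, R=(2.77, 0.23), slope=(-0.010, 0.010),
                    I=(0.010, 0.0015), C=(0.020, 0.003)),
        GroupConfig("NE", 21, R=(3.00, 0.40), slope=(-0.035, 0.015),
                    I=(0.010, 0.0015), C=(0.017, 0.003)),
        GroupConfig("AE", 24, R=(3.91, 0.57), slope=(-0.060, 0.020),
                    I=(0.010, 0.0015), C=(0.011, 0.0025)),
    ]


def draw_true_parameters(group: GroupConfig, rng: np.random.Generator) -> Dict[str, float]:
    """Draw one subject's ground-truth (R, slope, I, C), truncated/redrawn."""
    for _ in range(MAX_REDRAWS):
        draw = {}
        ok = True
        for name in ("R", "slope", "I", "C"):
            mean, sd = getattr(group, name)
            value = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
            lo, hi = BOUNDS[name]
            inside = (value >= lo) if name == "I" else (value > lo)
            if not inside or value >= hi:
                ok = False
                break
            draw[name] = value
        if not ok:
            continue
        try:
            MechanicalModel(variant="eric", R=draw["R"], I=draw["I"],
                            C=draw["C"], slope=draw["slope"])
        except ModelValidationError:
            continue
        return draw
    raise GenerationError(
        f"could not draw a feasible model for group {group.label!r} "
        f"after {MAX_REDRAWS} attempts"
    )


def generate_cohort(
    groups: Optional[Sequence[GroupConfig]] = None,
    master_seed: int = 0,
    n_exams: int = 3,
    excitation: Optional[ExcitationSpec] = None,
    noise: Optional[NoiseSpec] = None,
    synthesize_records: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, List[PressureFlowRecord]]]:
    """Generate a cohort table and (optionally) its raw exam records.

    Every subject is deterministic given ``(master_seed, subject index)``:
    regenerating with the same seed reproduces each record exactly.

    Returns
    -------
    table : DataFrame
        One row per subject: subject_id, group, true parameters, true
        resonance frequency, and the per-exam record seeds.
    records : dict
        subject_id -> list of ``n_exams`` :class:`PressureFlowRecord`
        (empty when ``synthesize_records`` is false).
    """
    groups = list(groups) if groups is not None else default_groups()
    excitation = excitation or ExcitationSpec()
    noise = noise or NoiseSpec()

    rows = []
    records: Dict[str, List[PressureFlowRecord]] = {}
    subject_index = 0
    for group in groups:
        for k in range(group.n):
            rng = np.random.default_rng([int(master_seed), subject_index])
            params = draw_true_parameters(group, rng)
            exam_seeds = rng.integers(0, 2**31 - 1, size=n_exams)
            subject_id = f"{group.label}_{k:03d}"
            model = MechanicalModel(variant="eric", R=params["R"], I=params["I"],
                                    C=params["C"], slope=params["slope"])
            fr_true = 1.0 / (2.0 * np.pi * np.sqrt(params["I"] * params["C"])) \
                if params["I"] > 0 else np.nan
            rows.append({
                "subject_id": subject_id, "group": group.label,
                "true_r": params["R"], "true_slope": params["slope"],
                "true_i": params["I"], "true_c": params["C"], "true_fr": fr_true,
                "exam_seeds": ",".join(str(int(s)) for s in exam_seeds),
            })
            if synthesize_records:
                records[subject_id] = [
                    synthesize_record(model, excitation, noise, seed=int(s))
                    for s in exam_seeds
                ]
            subject_index += 1
    return pd.DataFrame(rows), records


def model_for_row(row: Mapping) -> MechanicalModel:
    """Rebuild the ground-truth model of a cohort-table row."""
    return MechanicalModel(variant="eric", R=float(row["true_r"]),
                           I=float(row["true_i"]), C=float(row["true_c"]),
                           slope=float(row["true_slope"]))
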