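"""Longitudinal culture monitoring: TCF trajectories, milestones, outcomes.

Each primary sample is split into two culture arms (astrocyte basal medium,
ABM, and neural stem cell medium, NSM) and followed by ddPCR at up to four
stages: p0 (the initial dissociated suspension), p1 (after about one week in
culture), "transduced" (first passage after successful SV40-TAg infection)
and "final" (latest measurement).  Cultures end in one of two empirically
observed attractors — TCF rises to 100% (a long-term tumor cell line is
established) or falls to 0% (microenvironmental cells take over) — which
:func:`classify_outcome` calls with configurable success/failure bands.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Stage",
    "Medium",
    "Outcome",
    "CultureTimepoint",
    "Milestones",
    "CultureTrajectory",
    "OutcomeCall",
    "DEFAULT_SUCCESS_THRESHOLD",
    "DEFAULT_FAILURE_THRESHOLD",
    "build_trajectory",
    "relative_change",
    "classify_outcome",
    "milestone_table",
    "read_longitudinal_csv",
    "write_outcome_csv",
]

DEFAULT_SUCCESS_THRESHOLD = 0.95
DEFAULT_FAILURE_THRESHOLD = 0.05


class Stage(enum.IntEnum):
    """Monitoring stages in chronological order."""

    P0 = 0
    P1 = 1
    TRANSDUCED = 2
    FINAL = 3


class Medium(str, enum.Enum):
    ABM = "ABM"  # astrocyte basal medium
    NSM = "NSM"  # neural stem cell medium
    NONE = "NONE"  # pre-seeding (p0 suspension)


class Outcome(str, enum.Enum):
    ESTABLISHED = "ESTABLISHED"
    FAILED = "FAILED"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class CultureTimepoint:
    stage: Stage
    passage_index: int
    medium: Medium
    tcf: Optional[float] = None  # absent when gDNA could not be collected

    def __post_init__(self) -> None:
        if self.passage_index < 0:
            raise ValidationError("passage_index must be >= 0")
        if self.stage is Stage.P0 and self.medium is not Medium.NONE:
            raise ValidationError("the p0 suspension precedes seeding: medium must be NONE")
        if self.tcf is not None and not 0.0 <= self.tcf <= 1.0:
            raise ValidationError(f"tcf must lie in [0, 1], got {self.tcf}")


@dataclass
class Milestones:
    """Swimmer-plot milestone chain; each implies the previous."""

    viable_at_p1: bool = False
    transduced: bool = False
    line_established: Optional[bool] = None  # unset until classified

    def __post_init__(self) -> None:
        if self.transduced and not self.viable_at_p1:
            raise ValidationError("a transduced culture must have been viable at p1")
        if self.line_established and not self.transduced:
            raise ValidationError("an established line must have been transduced")


@dataclass
class CultureTrajectory:
    sample_id: str
    medium: Medium
    timepoints: list[CultureTimepoint]
    milestones: Milestones = field(default_factory=Milestones)

    def __post_init__(self) -> None:
        if self.medium is Medium.NONE:
            raise ValidationError("a trajectory belongs to a culture arm (ABM or NSM)")
        stages = [tp.stage for tp in self.timepoints]
        if stages != sorted(stages):
            raise ValidationError("timepoints must be ordered by stage")
        if len(set(stages)) != len(stages):
            raise ValidationError("duplicate stage in trajectory")

    def timepoint(self, stage: Stage) -> Optional[CultureTimepoint]:
        for tp in self.timepoints:
            if tp.stage is stage:
                return tp
        return None


@dataclass(frozen=True)
class OutcomeCall:
    outcome: Outcome
    final_tcf: float
    rationale: str


def build_trajectory(
    sample_id: str, medium: Medium, timepoints: Iterable[CultureTimepoint]
) -> CultureTrajectory:
    """Assemble and sort timepoints; derive viability/transduction milestones.

    ``line_established`` is left unset until :func:`classify_outcome` runs.
    """
    tps = sorted(timepoints, key=lambda tp: tp.stage)
    stages = [tp.stage for tp in tps]
    if len(set(stages)) != len(stages):
        dup = next(s for s in stages if stages.count(s) > 1)
        raise ValidationError(f"{sample_id}/{medium.value}: duplicate stage {dup.name}")
    transduced = Stage.TRANSDUCED in stages
    viable = Stage.P1 in stages or transduced
    return CultureTrajectory(
        sample_id=sample_id,
        medium=medium,
        timepoints=tps,
        milestones=Milestones(viable_at_p1=viable, transduced=transduced),
    )


def relative_change(tcf_p0: float, tcf_p1: float) -> float:
    """Relative change (p1 − p0) / p0 of the tumor cell fraction.

    A value of +0.5 means the tumor fraction grew by half over the first
    week of culture; −0.5 means it halved.
    """
    if tcf_p0 <= 0:
        raise ValidationError("relative change undefined for a zero baseline TCF")
    return (tcf_p1 - tcf_p0) / tcf_p0


def classify_outcome(
    traj: CultureTrajectory,
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
    failure_threshold: float = DEFAULT_FAILURE_THRESHOLD,
) -> OutcomeCall:
    """Call the terminal state of a culture from its FINAL TCF.

    ESTABLISHED requires a transduced culture whose final TCF reaches the
    success band (no line ever arose without SV40-TAg transduction); FAILED
    means the final TCF fell into the failure band; anything between is
    INDETERMINATE.  Depends only on the FINAL timepoint and the milestones,
    never on intermediate values.  Updates ``traj.milestones.line_established``.
    """
    if not 0 <= failure_threshold < success_threshold <= 1:
        raise ValidationError("need 0 <= failure_threshold < success_threshold <= 1")
    final = traj.timepoint(Stage.FINAL)
    if final is None or final.tcf is None:
        raise ValidationError(
            f"{traj.sample_id}/{traj.medium.value}: no FINAL TCF, outcome undefined"
        )
    f = final.tcf
    if traj.milestones.transduced and f >= success_threshold:
        call = OutcomeCall(
            Outcome.ESTABLISHED, f, f"transduced and final TCF {f:.2f} >= {success_threshold}"
        )
    elif f <= failure_threshold:
        call = OutcomeCall(Outcome.FAILED, f, f"final TCF {f:.2f} <= {failure_threshold}")
    elif not traj.milestones.transduced:
        call = OutcomeCall(
            Outcome.INDETERMINATE, f, "never transduced: cannot establish a line"
        )
    else:
        call = OutcomeCall(
            Outcome.INDETERMINATE,
            f,
            f"final TCF {f:.2f} between failure and success thresholds",
        )
    traj.milestones.line_established = call.outcome is Outcome.ESTABLISHED
    return call


def milestone_table(trajectories: Sequence[CultureTrajectory]) -> pd.DataFrame:
    """Swimmer-plot table: one row per (sample, medium) with milestone flags."""
    rows = [
        {
            "sample_id": t.sample_id,
            "medium": t.medium.value,
            "viable_at_p1": t.milestones.viable_at_p1,
            "transduced": t.milestones.transduced,
            "line_established": bool(t.milestones.line_established),
        }
        for t in trajectories
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "medium", "viable_at_p1", "transduced", "line_established"]
    )


def read_longitudinal_csv(path) -> list[CultureTrajectory]:
    """Read trajectories from the longitudinal CSV schema.

    Columns: ``sample_id, medium, stage, passage_index, tcf`` (tcf empty or
    ``NA`` when no gDNA was collectable).  Rows are grouped by
    (sample_id, medium); the p0 stage is shared by both arms of a sample and
    is stored with medium NONE inside each trajectory.
    """
    required = {"sample_id", "medium", "stage", "passage_index", "tcf"}
    grouped: dict[tuple[str, Medium], list[CultureTimepoint]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"longitudinal CSV missing column(s): {', '.join(sorted(missing))}")
        for row in reader:
            sid = row["sample_id"].strip()
            try:
                medium = Medium(row["medium"].strip().upper())
                stage = Stage[row["stage"].strip().upper()]
                passage = int(row["passage_index"])
            except (ValueError, KeyError):
                raise ValidationError(f"{sid}: unparseable longitudinal row {row!r}") from None
            raw_tcf = (row["tcf"] or "").strip()
            tcf = None if raw_tcf in ("", "NA") else float(raw_tcf)
            tp_medium = Medium.NONE if stage is Stage.P0 else medium
            grouped.setdefault((sid, medium), []).append(
                CultureTimepoint(stage=stage, passage_index=passage, medium=tp_medium, tcf=tcf)
            )
    return [
        build_trajectory(sid, medium, tps) for (sid, medium), tps in grouped.items()
    ]


def write_outcome_csv(calls: Sequence[tuple[CultureTrajectory, OutcomeCall]], path) -> None:
    """Write outcome calls: sample_id, medium, outcome, final_tcf."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "medium", "outcome", "final_tcf"])
        for traj, call in calls:
            writer.writerow(
                [traj.sample_id, traj.medium.value, call.outcome.value, repr(call.final_tcf)]
            )
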