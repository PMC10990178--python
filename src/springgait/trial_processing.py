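"""Ingest raw trial records and build the long-format cohort table.

Raw inputs are two plain CSVs:

``participants.csv``
    ``participant_id, sex, age_y, height_cm, mass_kg, weekly_hours,
    axis_ei, axis_sn, axis_tf, axis_jp`` with axis labels ``E/I``, ``S/N``,
    ``T/F``, ``J/P``.

``trials.csv``
    ``participant_id, requested_speed_ms, measured_speed_ms, step_index,
    tc_ms, tf_ms`` — one row per recorded step, plus an optional
    ``granularity`` column (``step`` or ``aggregated``) for inputs that are
    already trial means.

A trial is accepted when its measured speed is within +/- 5 % of the
requested speed (inclusive); accepted trials are averaged over their steps
and pushed through the forward spring-mass model to give one row per
participant per speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, InvalidInputError
from .gait_model import Anthropometrics, ModelConfig, StepTiming, spring_mass_arrays

__all__ = [
    "SPEED_TOLERANCE",
    "AXIS_LABELS",
    "TrialRecord",
    "ParticipantProfile",
    "CohortTable",
    "validate_trial_speed",
    "aggregate_trial",
    "build_cohort_table",
    "read_participants_csv",
    "write_participants_csv",
    "read_trials_csv",
    "write_trials_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Relative speed-acceptance tolerance (inclusive).
SPEED_TOLERANCE = 0.05

#: Permitted category labels per personality axis, in reporting order.
AXIS_LABELS: dict[str, tuple[str, str]] = {
    "axis_ei": ("E", "I"),
    "axis_sn": ("S", "N"),
    "axis_tf": ("T", "F"),
    "axis_jp": ("J", "P"),
}

#: Derived columns of the cohort table, SI units.
DERIVED_COLUMNS = ("sf", "ts", "df", "fmax", "dz", "dl", "kleg")

#: cohort.csv column order (reporting units).
COHORT_CSV_COLUMNS = (
    "participant_id",
    "speed_ms",
    "tc_ms",
    "tf_ms",
    "sf_hz",
    "ts_ms",
    "df_frac",
    "fmax_n",
    "dz_cm",
    "dl_cm",
    "kleg_knm",
)


@dataclass(frozen=True)
class TrialRecord:
    """All steps recorded for one participant at one requested speed."""

    participant_id: str
    requested_speed: float  # m/s
    measured_speed: float  # m/s
    steps: tuple[StepTiming, ...]

    def __post_init__(self) -> None:
        if self.measured_speed <= 0 or self.requested_speed <= 0:
            raise InvalidInputError("speeds must be positive")


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    sex: str
    age: float  # years
    anthropometrics: Anthropometrics
    axes: dict[str, str] = field(default_factory=dict)  # axis_* -> label
    weekly_hours: float = 0.0

    def __post_init__(self) -> None:
        for axis, labels in AXIS_LABELS.items():
            value = self.axes.get(axis)
            if value not in labels:
                raise DataIntegrityError(
                    f"participant {self.participant_id}: {axis} label {value!r} "
                    f"not in {labels}"
                )


@dataclass
class CohortTable:
    """Long-format participants x speeds table with derived variables.

    ``data`` has one row per accepted participant-speed pair; profile columns
    are joined in; ``complete`` marks participants with every protocol speed.
    """

    data: pd.DataFrame
    speeds: tuple[float, ...]
    n_trials_accepted: int
    n_trials_rejected: int
    incomplete_participants: tuple[str, ...]

    @property
    def complete_data(self) -> pd.DataFrame:
        """Rows of participants measured at all protocol speeds."""
        return self.data[self.data["complete"]].reset_index(drop=True)


def validate_trial_speed(requested: float, measured: float) -> bool:
    """Accept a trial iff the measured speed is within +/- 5 % (inclusive).

    A tiny relative epsilon keeps the inclusive boundary robust to binary
    float representation (far below any speed-measurement resolution).
    """
    if requested <= 0 or measured <= 0:
        raise InvalidInputError("speeds must be positive")
    return abs(measured - requested) <= SPEED_TOLERANCE * requested * (1 + 1e-9)


def aggregate_trial(trial: TrialRecord) -> StepTiming:
    """Arithmetic mean of contact and flight times over the trial's steps."""
    if not trial.steps:
        raise InvalidInputError(
            f"trial {trial.participant_id}@{trial.requested_speed} has no steps"
        )
    t_c = float(np.mean([s.t_c for s in trial.steps]))
    t_f = float(np.mean([s.t_f for s in trial.steps]))
    return StepTiming(t_c=t_c, t_f=t_f)


def build_cohort_table(
    profiles: Iterable[ParticipantProfile],
    trials: Iterable[TrialRecord],
    cfg: ModelConfig = ModelConfig(),
    speeds: Sequence[float] | None = None,
) -> CohortTable:
    """Filter, aggregate and derive: one row per accepted participant-speed.

    Trials failing the speed-acceptance rule are dropped (and counted).
    Participants missing any protocol speed are kept in the table but flagged
    ``complete=False`` so repeated-measures analyses can be complete-case.

    Raises :class:`DataIntegrityError` on unknown participant ids or more
    than one accepted trial per participant-speed.
    """
    profile_map = {p.participant_id: p for p in profiles}
    accepted: list[TrialRecord] = []
    n_rejected = 0
    for trial in trials:
        if trial.participant_id not in profile_map:
            raise DataIntegrityError(
                f"trial references unknown participant {trial.participant_id!r}"
            )
        if validate_trial_speed(trial.requested_speed, trial.measured_speed):
            accepted.append(trial)
        else:
            n_rejected += 1

    seen: set[tuple[str, float]] = set()
    for trial in accepted:
        key = (trial.participant_id, trial.requested_speed)
        if key in seen:
            raise DataIntegrityError(
                f"duplicate accepted trial for participant {key[0]!r} at "
                f"{key[1]} m/s"
            )
        seen.add(key)

    if speeds is None:
        speeds = sorted({t.requested_speed for t in accepted})
    speeds = tuple(float(s) for s in speeds)

    rows = []
    for trial in accepted:
        timing = aggregate_trial(trial)
        prof = profile_map[trial.participant_id]
        rows.append(
            {
                "participant_id": trial.participant_id,
                "speed": trial.requested_speed,
                "measured_speed": trial.measured_speed,
                "tc": timing.t_c,
                "tf": timing.t_f,
                "mass": prof.anthropometrics.mass,
                "height": prof.anthropometrics.height,
                "leg_length": prof.anthropometrics.leg_length,
                "sex": prof.sex,
                "age": prof.age,
                "weekly_hours": prof.weekly_hours,
                **prof.axes,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise InvalidInputError("no accepted trials")

    derived = spring_mass_arrays(
        df["tc"].to_numpy(),
        df["tf"].to_numpy(),
        df["mass"].to_numpy(),
        df["leg_length"].to_numpy(),
        df["speed"].to_numpy(),
        g=cfg.g,
    )
    for name in DERIVED_COLUMNS:
        df[name] = derived[name]

    per_participant = df.groupby("participant_id")["speed"].apply(set)
    incomplete = tuple(
        sorted(pid for pid, got in per_participant.items() if got != set(speeds))
    )
    df["complete"] = ~df["participant_id"].isin(incomplete)
    df = df.sort_values(["participant_id", "speed"], kind="stable").reset_index(
        drop=True
    )
    return CohortTable(
        data=df,
        speeds=speeds,
        n_trials_accepted=len(accepted),
        n_trials_rejected=n_rejected,
        incomplete_participants=incomplete,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_participants_csv(path: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    required = {
        "participant_id",
        "sex",
        "age_y",
        "height_cm",
        "mass_kg",
        "weekly_hours",
        *AXIS_LABELS,
    }
    missing = required - set(df.columns)
    if missing:
        raise DataIntegrityError(f"participants.csv missing columns: {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise DataIntegrityError(f"duplicate participant_id {dup!r}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            ParticipantProfile(
                participant_id=str(row["participant_id"]),
                sex=str(row["sex"]),
                age=float(row["age_y"]),
                anthropometrics=Anthropometrics(
                    mass=float(row["mass_kg"]), height=float(row["height_cm"]) / 100.0
                ),
                axes={axis: str(row[axis]) for axis in AXIS_LABELS},
                weekly_hours=float(row["weekly_hours"]),
            )
        )
    return profiles


def write_participants_csv(
    profiles: Iterable[ParticipantProfile], path: str | Path
) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "sex": p.sex,
            "age_y": p.age,
            "height_cm": p.anthropometrics.height * 100.0,
            "mass_kg": p.anthropometrics.mass,
            "weekly_hours": p.weekly_hours,
            **p.axes,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Parse step-level (or pre-aggregated) trial rows into records.

    Rows are grouped by (participant, requested speed, measured speed); a
    ``granularity`` value of ``aggregated`` marks rows that are already trial
    means, in which case exactly one row per trial is expected.
    """
    df = pd.read_csv(path)
    required = {
        "participant_id",
        "requested_speed_ms",
        "measured_speed_ms",
        "step_index",
        "tc_ms",
        "tf_ms",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataIntegrityError(f"trials.csv missing columns: {sorted(missing)}")
    if "granularity" not in df.columns:
        df = df.assign(granularity="step")

    trials = []
    keys = ["participant_id", "requested_speed_ms", "measured_speed_ms"]
    for (pid, req, meas), grp in df.groupby(keys, sort=False):
        gran = set(grp["granularity"])
        if len(gran) != 1:
            raise DataIntegrityError(
                f"trial {pid!r}@{req}: mixed granularity values {sorted(gran)}"
            )
        if gran == {"aggregated"} and len(grp) != 1:
            raise DataIntegrityError(
                f"trial {pid!r}@{req}: aggregated trials must be single rows"
            )
        grp = grp.sort_values("step_index", kind="stable")
        steps = tuple(
            StepTiming(t_c=tc / 1000.0, t_f=tf / 1000.0)
            for tc, tf in zip(grp["tc_ms"], grp["tf_ms"])
        )
        trials.append(
            TrialRecord(
                participant_id=str(pid),
                requested_speed=float(req),
                measured_speed=float(meas),
                steps=steps,
            )
        )
    return trials


def write_trials_csv(trials: Iterable[TrialRecord], path: str | Path) -> None:
    rows = []
    for trial in trials:
        for i, step in enumerate(trial.steps):
            rows.append(
                {
                    "participant_id": trial.participant_id,
                    "requested_speed_ms": trial.requested_speed,
                    "measured_speed_ms": trial.measured_speed,
                    "step_index": i,
                    "tc_ms": step.t_c * 1000.0,
                    "tf_ms": step.t_f * 1000.0,
                    "granularity": "step",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write the derived table in reporting units (ms, cm, kN/m)."""
    df = cohort.data
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "speed_ms": df["speed"],
            "tc_ms": df["tc"] * 1000.0,
            "tf_ms": df["tf"] * 1000.0,
            "sf_hz": df["sf"],
            "ts_ms": df["ts"] * 1000.0,
            "df_frac": df["df"],
            "fmax_n": df["fmax"],
            "dz_cm": df["dz"] * 100.0,
            "dl_cm": df["dl"] * 100.0,
            "kleg_knm": df["kleg"] / 1000.0,
        }
    )
    out.to_csv(path, index=False, columns=list(COHORT_CSV_COLUMNS))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read cohort.csv back into SI units (inverse of :func:`write_cohort_csv`)."""
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "speed": df["speed_ms"],
            "tc": df["tc_ms"] / 1000.0,
            "tf": df["tf_ms"] / 1000.0,
            "sf": df["sf_hz"],
            "ts": df["ts_ms"] / 1000.0,
            "df": df["df_frac"],
            "fmax": df["fmax_n"],
            "dz": df["dz_cm"] / 100.0,
            "dl": df["dl_cm"] / 100.0,
            "kleg": df["kleg_knm"] * 1000.0,
        }
    )
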