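"""Trial-level data container, CSV round-trip and validation reporting.

A session is one experiment's worth of trials: per trial the participant,
which target was inspected foveally (a face or a phase-scrambled noise
patch), whether that target had been visible in the periphery beforehand
(preview) or masked by an outline, which selection target the second
saccade chose, and the fixation duration on the inspection target in
milliseconds.

Durations are stored in milliseconds in files and DataFrames; the
diffusion machinery works in seconds, and the conversion happens exactly
once, in the fitting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

IDENTITIES = ("face", "noise")
PREVIEWS = ("preview", "outline")
CHOICES = ("face", "noise")
LOCATIONS = ("up", "down")
SIDES = ("left", "right")

#: condition label from (inspection_identity, preview)
CONDITION_OF = {
    ("face", "preview"): "FP",
    ("face", "outline"): "FO",
    ("noise", "preview"): "NP",
    ("noise", "outline"): "NO",
}

REQUIRED_COLUMNS = [
    "participant_id",
    "inspection_identity",
    "preview",
    "choice",
    "fixation_duration_ms",
]
OPTIONAL_COLUMNS = ["inspection_location", "face_side", "trial_index"]
ALL_COLUMNS = (
    REQUIRED_COLUMNS[:3] + ["condition"] + REQUIRED_COLUMNS[3:] + OPTIONAL_COLUMNS
)


class SchemaError(ValueError):
    """A trial table is missing a required column."""


class TrialValidationError(ValueError):
    """A trial table row violates the schema's value constraints."""


@dataclass
class Session:
    """An ordered collection of trials plus provenance metadata."""

    trials: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trials = _validate_trials(self.trials)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.trials["participant_id"]))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def for_participant(self, pid) -> pd.DataFrame:
        return self.trials[self.trials["participant_id"] == pid]


def derive_condition(identity: pd.Series, preview: pd.Series) -> pd.Series:
    key = list(zip(identity, preview))
    return pd.Series([CONDITION_OF[k] for k in key], index=identity.index)


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    for col, allowed in [
        ("inspection_identity", IDENTITIES),
        ("preview", PREVIEWS),
        ("choice", CHOICES),
    ]:
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialValidationError(
                f"column {col!r}, row {row}: value {df[col].iloc[row]!r} "
                f"not in {allowed}"
            )
    dur = pd.to_numeric(df["fixation_duration_ms"], errors="coerce")
    bad = ~np.isfinite(dur) | (dur <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrialValidationError(
            f"fixation_duration_ms, row {row}: must be finite and > 0, "
            f"got {df['fixation_duration_ms'].iloc[row]!r}"
        )
    df["fixation_duration_ms"] = dur.astype(float)

    derived = derive_condition(df["inspection_identity"], df["preview"])
    if "condition" in df.columns and df["condition"].notna().any():
        stored = df["condition"].astype(str)
        mism = stored.to_numpy() != derived.to_numpy()
        if mism.any():
            row = int(np.flatnonzero(mism)[0])
            raise TrialValidationError(
                f"condition, row {row}: stored {stored.iloc[row]!r} contradicts "
                f"identity={df['inspection_identity'].iloc[row]!r} / "
                f"preview={df['preview'].iloc[row]!r} (expected {derived.iloc[row]!r})"
            )
    df["condition"] = derived

    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    if df["trial_index"].notna().any():
        idx = pd.to_numeric(df["trial_index"], errors="coerce")
        dup = df.loc[idx.notna()].groupby("participant_id")["trial_index"].apply(
            lambda s: s.duplicated().any()
        )
        if dup.any():
            raise TrialValidationError(
                f"duplicate trial_index for participant(s) "
                f"{list(dup[dup].index)}"
            )
        df["trial_index"] = idx.astype("Int64")
    return df[ALL_COLUMNS].reset_index(drop=True)


def read_trials(path, dialect: dict | None = None) -> Session:
    """Read a trial table CSV into a validated :class:`Session`.

    The file must carry a header row with at least the required columns
    (see :data:`REQUIRED_COLUMNS`). Any stored ``condition`` column is
    checked against the identity x preview combination, never trusted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **(dialect or {}))
    return Session(df, metadata={"source": str(path)})


def write_trials(session: Session, path) -> Path:
    """Write the session to CSV in the documented schema; returns the path."""
    path = Path(path)
    df = session.trials[ALL_COLUMNS]
    df.to_csv(path, index=False)
    return path


@dataclass
class ValidationReport:
    """Per-participant bookkeeping of trial counts, choices and durations."""

    condition_counts: pd.DataFrame  # participants x conditions
    cell_counts: pd.DataFrame  # participant x (condition, choice) counts
    duration_range: pd.DataFrame  # participant -> (min, max) ms
    empty_cells: list  # (participant, condition, choice) with zero trials
    n_trials: int

    def summary(self) -> str:
        lines = [f"{self.n_trials} trials, {len(self.condition_counts)} participants"]
        lines.append("trials per condition:")
        lines.append(self.condition_counts.to_string())
        if self.empty_cells:
            lines.append(f"empty condition x choice cells: {self.empty_cells}")
        else:
            lines.append("no empty condition x choice cells")
        return "\n".join(lines)


def validate_session(session: Session) -> ValidationReport:
    """Tabulate per-participant design cells and flag empty choice cells.

    Downstream repeated-measures analyses on condition x outcome cells need
    every participant to have at least one trial per cell; missing cells
    are listed here so exclusions are explicit.
    """
    df = session.trials
    conds = ["FP", "FO", "NP", "NO"]
    cond_counts = (
        df.groupby(["participant_id", "condition"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=conds, fill_value=0)
    )
    cell = (
        df.groupby(["participant_id", "condition", "choice"], observed=True)
        .size()
        .unstack(["condition", "choice"], fill_value=0)
    )
    full_cols = pd.MultiIndex.from_product([conds, list(CHOICES)])
    cell = cell.reindex(columns=full_cols, fill_value=0)
    dur = df.groupby("participant_id")["fixation_duration_ms"].agg(["min", "max"])
    empty = [
        (pid, cond, choice)
        for pid in cell.index
        for (cond, choice) in cell.columns
        if cell.loc[pid, (cond, choice)] == 0
    ]
    return ValidationReport(
        condition_counts=cond_counts,
        cell_counts=cell,
        duration_range=dur,
        empty_cells=empty,
        n_trials=len(df),
    )
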