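"""Trial-level datasets: one row per 2AFC trial, grouped by subject and test.

The canonical on-disk representation is a comma-separated table with header
``subject,test,group,session,global_trial,contrast,response,staircase_id``.
Contrast is linear Michelson contrast in (0, 1]; response is 0/1; the global
trial number is 1-based and cumulative over pre-training and all sessions
(pre-training trials belong to session 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SessionStructure

__all__ = ["COLUMNS", "TrialRecord", "SubjectData", "TrialDataset"]

COLUMNS = [
    "subject",
    "test",
    "group",
    "session",
    "global_trial",
    "contrast",
    "response",
    "staircase_id",
]


@dataclass(frozen=True)
class TrialRecord:
    """A single observed trial."""

    subject: int
    group: int
    global_trial: int
    session: int
    contrast: float
    response: int
    test: int = 1
    staircase_id: str = ""

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        if self.global_trial < 1:
            raise ValueError("global_trial is 1-based")


@dataclass(frozen=True)
class SubjectData:
    """One subject/test's trials packed as aligned arrays for the likelihood."""

    subject: int
    test: int
    group: int
    tglobal: np.ndarray
    session: np.ndarray
    tprime: np.ndarray
    contrast: np.ndarray
    response: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.tglobal.size)


class TrialDataset:
    """A collection of trials for one or more subjects.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical columns,
    providing validated construction, per-subject packed views, and
    truncation (for partial-data prediction).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns and c != "staircase_id"]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.copy()
        if "staircase_id" not in df.columns:
            df["staircase_id"] = ""
        df["staircase_id"] = df["staircase_id"].fillna("").astype(str)
        for col in ("subject", "test", "group", "session", "global_trial", "response"):
            df[col] = df[col].astype(int)
        df["contrast"] = df["contrast"].astype(float)
        bad = df.index[df["contrast"] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive contrast at rows {bad[:5]}")
        bad = df.index[~df["response"].isin([0, 1])].tolist()
        if bad:
            raise ValueError(f"non-binary response at rows {bad[:5]}")
        bad = df.index[df["global_trial"] < 1].tolist()
        if bad:
            raise ValueError(f"global_trial must be >= 1, bad rows {bad[:5]}")
        df = df.sort_values(["subject", "test", "global_trial"], kind="stable")
        self.df = df.reset_index(drop=True)[COLUMNS]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: list[TrialRecord]) -> "TrialDataset":
        rows = [
            {
                "subject": r.subject,
                "test": r.test,
                "group": r.group,
                "session": r.session,
                "global_trial": r.global_trial,
                "contrast": r.contrast,
                "response": r.response,
                "staircase_id": r.staircase_id,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrialDataset":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps contrast bit-exact across a write/read cycle
        self.df.to_csv(path, index=False, float_format="%.17g")

    # -- access ------------------------------------------------------------

    @property
    def subjects(self) -> list[int]:
        return sorted(self.df["subject"].unique().tolist())

    @property
    def groups(self) -> dict[int, int]:
        """Mapping subject id -> group id."""
        return (
            self.df.drop_duplicates("subject").set_index("subject")["group"].to_dict()
        )

    def subject_frame(self, subject: int, test: int = 1) -> pd.DataFrame:
        mask = (self.df["subject"] == subject) & (self.df["test"] == test)
        return self.df.loc[mask]

    def packed(self, subject: int, test: int = 1) -> SubjectData:
        """Arrays ordered by global trial, with the 0-based within-session
        index derived from each session's first observed trial."""
        sub = self.subject_frame(subject, test)
        tglobal = sub["global_trial"].to_numpy()
        session = sub["session"].to_numpy()
        tprime = np.empty_like(tglobal)
        for s in np.unique(session):
            idx = session == s
            tprime[idx] = tglobal[idx] - tglobal[idx].min()
        return SubjectData(
            subject=subject,
            test=test,
            group=int(sub["group"].iloc[0]) if len(sub) else 0,
            tglobal=tglobal,
            session=session,
            tprime=tprime,
            contrast=sub["contrast"].to_numpy(),
            response=sub["response"].to_numpy(),
        )

    def packed_all(self, test: int = 1) -> list[SubjectData]:
        return [self.packed(s, test) for s in self.subjects]

    def structure_for(self, subject: int, test: int = 1) -> SessionStructure:
        """Reconstruct a :class:`SessionStructure` from one subject's table.

        Pre-training length is inferred as the excess of session 1 over the
        modal session length.
        """
        sub = self.subject_frame(subject, test)
        counts = sub.groupby("session").size()
        n_sessions = int(counts.index.max())
        lengths = [int(counts.get(s, 0)) for s in range(1, n_sessions + 1)]
        base = int(np.median(lengths[1:])) if n_sessions > 1 else lengths[0]
        pretrain = max(lengths[0] - base, 0)
        tps = [lengths[0] - pretrain] + lengths[1:]
        return SessionStructure(
            n_sessions=n_sessions, trials_per_session=tps, pretrain_trials=pretrain
        )

    def truncate_subject(self, subject: int, n_sessions: int, test: int = 1) -> "TrialDataset":
        """Drop all of ``subject``'s trials beyond the first ``n_sessions``
        sessions (``n_sessions=0`` removes the subject's data entirely while
        keeping everyone else's)."""
        mask = (self.df["subject"] == subject) & (self.df["test"] == test) & (
            self.df["session"] > n_sessions
        )
        return TrialDataset(self.df.loc[~mask])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrialDataset) and self.df.equals(other.df)
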