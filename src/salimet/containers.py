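"""Core in-memory containers: sample-by-feature matrices and study metadata.

The study design has three groups of saliva samples: periodontitis patients at
baseline (``B``), the same patients after non-surgical therapy (``AT``, paired
with ``B`` by subject), and independent healthy individuals (``HI``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("B", "AT", "HI")


@dataclass
class FeatureMatrix:
    """A samples x features table of spectral buckets or metabolite integrals.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Real-valued, finite intensities/integrals.
    sample_ids, feature_ids : sequences of str
        Row and column labels; lengths must match ``values``.
    normalized : bool
        True once each row has been scaled to a common total area.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, normalized: bool = False) -> "FeatureMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            normalized=normalized,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, normalized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df, normalized=normalized)

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return FeatureMatrix(
            self.values[rows], list(sample_ids), list(self.feature_ids),
            normalized=self.normalized,
        )


@dataclass
class SampleMetadata:
    """Sample ↔ subject ↔ group mapping encoding the paired design.

    Each row maps one sample to its subject and group (one of ``B``, ``AT``,
    ``HI``). Paired analyses require that every subject with an ``AT`` sample
    also has a ``B`` sample.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "subject_id", "group")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("metadata is empty")
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        df["group"] = df["group"].astype(str)
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValueError(
                f"unknown group token(s) {bad}; allowed: {list(GROUPS)}"
            )
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicated sample_id(s): {dups}")
        self.table = df.reset_index(drop=True)

    def check_pairing(self) -> None:
        """For paired analyses: every AT sample's subject must have a B
        sample. (Shuffled-label null metadata is exempt from this.)"""
        df = self.table
        at_subj = set(df.loc[df["group"] == "AT", "subject_id"])
        b_subj = set(df.loc[df["group"] == "B", "subject_id"])
        orphan = sorted(at_subj - b_subj)
        if orphan:
            raise ValueError(
                f"AT sample(s) whose subject lacks a B sample: {orphan}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    @property
    def subjects(self) -> pd.Series:
        return self.table.set_index("sample_id")["subject_id"]

    def pairing_map(self) -> dict[str, tuple[str, str]]:
        """subject_id -> (B sample_id, AT sample_id) for paired subjects."""
        df = self.table
        pairs: dict[str, tuple[str, str]] = {}
        for subj, sub in df[df["group"].isin(["B", "AT"])].groupby("subject_id"):
            b = sub.loc[sub["group"] == "B", "sample_id"]
            at = sub.loc[sub["group"] == "AT", "sample_id"]
            if len(b) == 1 and len(at) == 1:
                pairs[str(subj)] = (b.iloc[0], at.iloc[0])
        return pairs

    def group_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        g = self.groups
        return np.asarray([g[s] for s in sample_ids], dtype=object)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, dtype=str)
        if df.empty:
            raise ValueError(f"metadata file {path} is empty")
        md = cls(df)
        md.check_pairing()
        return md

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "SampleMetadata":
        return cls(pd.DataFrame.from_records(records))
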