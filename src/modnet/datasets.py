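"""Participant-level symptom dataset container and CSV round-trip.

The core unit of data is a participant x item table of ordinal symptom
scores (0 = never ... 3 = very often), one group label per participant
(e.g. non-ADHD controls vs. stimulant-naive vs. stimulant-exposed ADHD),
and the covariates age, sex and study site. Missing item scores are kept
as NaN; the missingness mask is derived, never stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 18 DSM-IV ADHD symptom items of the parent-rated Conners scale,
#: nine inattentive followed by nine hyperactive-impulsive.
ITEMS: tuple[str, ...] = (
    "closeatt", "susatt", "listen", "instruct", "org",
    "avoid", "lose", "distract", "forget",
    "fidget", "seat", "run", "quiet", "motor",
    "talk", "blurt", "turn", "interrupt",
)

#: Default moderator levels: non-ADHD controls (reference, largest group),
#: stimulant-naive ADHD, stimulant-exposed ADHD.
DEFAULT_GROUPS: tuple[str, ...] = ("NAC", "ADHD-nostim", "ADHD-stim")

COVARIATE_COLUMNS: tuple[str, ...] = ("age", "sex", "site")

VALID_SCORES = frozenset({0.0, 1.0, 2.0, 3.0})


@dataclass
class SymptomDataset:
    """Ordinal symptom-score table with group labels and covariates.

    Parameters
    ----------
    items : DataFrame, shape (n_participants, n_items)
        Ordinal scores in {0,1,2,3}; NaN marks a missing score. The index
        holds participant ids (unique).
    groups : Series
        Group label per participant, aligned with ``items``.
    covariates : DataFrame
        Columns ``age`` (years), ``sex`` (0 female / 1 male), ``site``.
    group_levels : tuple of str
        Declared ordered set of admissible group labels.
    """

    items: pd.DataFrame
    groups: pd.Series
    covariates: pd.DataFrame
    group_levels: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if self.items.index.has_duplicates:
            raise ValueError("duplicate participant ids")
        observed = self.items.values[~np.isnan(self.items.values)]
        bad = set(np.unique(observed)) - VALID_SCORES
        if bad:
            raise ValueError(f"observed item scores outside {{0,1,2,3}}: {sorted(bad)}")
        unknown = set(self.groups.unique()) - set(self.group_levels)
        if unknown:
            raise ValueError(f"group labels not in declared levels: {sorted(unknown)}")
        if not self.groups.index.equals(self.items.index):
            raise ValueError("groups not aligned with item table")

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def item_labels(self) -> list[str]:
        return list(self.items.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where an item score is missing."""
        return self.items.isna()

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts().reindex(list(self.group_levels)).fillna(0).astype(int)

    def copy(self) -> "SymptomDataset":
        return SymptomDataset(
            items=self.items.copy(),
            groups=self.groups.copy(),
            covariates=self.covariates.copy(),
            group_levels=self.group_levels,
        )

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """One row per participant; missing scores as empty cells."""
        out = pd.concat(
            [self.groups.rename("group"), self.covariates, self.items], axis=1
        )
        out.index.name = "participant_id"
        out.to_csv(path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        group_levels: tuple[str, ...] = DEFAULT_GROUPS,
        item_columns: tuple[str, ...] = ITEMS,
    ) -> "SymptomDataset":
        df = pd.read_csv(path, index_col="participant_id")
        missing_cols = [c for c in item_columns if c not in df.columns]
        if missing_cols:
            raise ValueError(f"item columns absent from CSV: {missing_cols}")
        covs = df[[c for c in COVARIATE_COLUMNS if c in df.columns]]
        return cls(
            items=df[list(item_columns)].astype(float),
            groups=df["group"],
            covariates=covs,
            group_levels=group_levels,
        )
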