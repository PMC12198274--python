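"""Exclusion rules and multiple imputation of missing item scores.

Network estimation requires complete data, so participants missing at
least half of their item scores are excluded and the remaining gaps are
filled by chained-equations multiple imputation with predictive mean
matching (PMM): each incomplete item is regressed on all other items,
and a missing value is replaced by the observed value of one of the
``donors`` cases whose predictions lie nearest. PMM only ever draws from
the observed support, so imputed scores stay in {0,1,2,3} by
construction. Several independent chains yield m completed copies whose
observed entries are identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import SymptomDataset


@dataclass
class ExclusionLog:
    """Participants removed by the missingness filter."""

    excluded: pd.DataFrame  # columns: participant_id, n_missing
    threshold: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class CompletedDatasets:
    """m completed copies of a symptom dataset plus imputation metadata."""

    datasets: list[SymptomDataset]
    m: int
    iterations: int
    seed: int | None

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, k: int) -> SymptomDataset:
        return self.datasets[k]


def apply_missingness_filter(
    dataset: SymptomDataset, max_missing_fraction: float = 0.5
) -> tuple[SymptomDataset, ExclusionLog]:
    """Drop participants with >= ``max_missing_fraction`` of items missing.

    Returns the filtered dataset and a log of excluded participants with
    their missing-item counts. Raises if no participant survives.
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    n_items = dataset.items.shape[1]
    n_missing = dataset.missing_mask.sum(axis=1)
    drop = n_missing / n_items >= max_missing_fraction
    if drop.all():
        raise ValueError(
            f"all {dataset.n} participants excluded at threshold {max_missing_fraction}"
        )
    log = ExclusionLog(
        excluded=pd.DataFrame(
            {"participant_id": dataset.items.index[drop], "n_missing": n_missing[drop].values}
        ),
        threshold=max_missing_fraction,
    )
    keep = ~drop
    filtered = SymptomDataset(
        items=dataset.items.loc[keep],
        groups=dataset.groups.loc[keep],
        covariates=dataset.covariates.loc[keep],
        group_levels=dataset.group_levels,
    )
    return filtered, log


class ChainedImputer(BaseEstimator):
    """Multiple imputation by chained equations with PMM draws.

    Parameters
    ----------
    m : int
        Number of independent imputation chains (completed copies).
    iterations : int
        Sweeps over the incomplete items per chain.
    donors : int
        Size of the donor pool for predictive mean matching.
    seed : int or None
        Seeds the chain initialisation and donor draws.
    """

    def __init__(self, m: int = 5, iterations: int = 10, donors: int = 5,
                 seed: int | None = None):
        self.m = m
        self.iterations = iterations
        self.donors = donors
        self.seed = seed

    def fit_transform(self, dataset: SymptomDataset) -> CompletedDatasets:
        X = dataset.items.values.astype(float)
        mask = np.isnan(X)
        col_missing = mask.sum(axis=0)
        all_missing = np.flatnonzero(col_missing == len(X))
        if all_missing.size:
            names = [dataset.items.columns[j] for j in all_missing]
            raise ValueError(f"items missing for all participants: {names}")

        rng = np.random.default_rng(self.seed)
        completed = []
        for _ in range(self.m):
            Xc = self._run_chain(X, mask, rng)
            items = pd.DataFrame(Xc, index=dataset.items.index, columns=dataset.items.columns)
            completed.append(
                SymptomDataset(
                    items=items,
                    groups=dataset.groups.copy(),
                    covariates=dataset.covariates.copy(),
                    group_levels=dataset.group_levels,
                )
            )
        self.n_missing_ = int(mask.sum())
        return CompletedDatasets(
            datasets=completed, m=self.m, iterations=self.iterations, seed=self.seed
        )

    def _run_chain(self, X: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        Xc = X.copy()
        p = X.shape[1]
        incomplete = [j for j in range(p) if mask[:, j].any()]
        # hot-deck start: fill each gap with a random observed value of its item
        for j in incomplete:
            obs = X[~mask[:, j], j]
            Xc[mask[:, j], j] = rng.choice(obs, size=mask[:, j].sum(), replace=True)
        for _ in range(self.iterations):
            for j in incomplete:
                Xc[:, j] = self._pmm_step(Xc, X[:, j], mask[:, j], j, rng)
        return Xc

    def _pmm_step(
        self,
        Xc: np.ndarray,
        y_orig: np.ndarray,
        miss: np.ndarray,
        j: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        others = np.delete(Xc, j, axis=1)
        A = np.column_stack([np.ones(len(Xc)), others])
        obs = ~miss
        beta, *_ = np.linalg.lstsq(A[obs], y_orig[obs], rcond=None)
        pred = A @ beta
        y_new = y_orig.copy()
        obs_pred, obs_vals = pred[obs], y_orig[obs]
        k = min(self.donors, obs_vals.size)
        for i in np.flatnonzero(miss):
            d = np.abs(obs_pred - pred[i])
            donors = np.argpartition(d, k - 1)[:k]
            y_new[i] = obs_vals[rng.choice(donors)]
        return y_new


def impute_items(
    dataset: SymptomDataset,
    m: int = 5,
    iterations: int = 10,
    donors: int = 5,
    seed: int | None = None,
) -> CompletedDatasets:
    """Chained-equations multiple imputation of missing item scores.

    With no missing values, returns ``m`` identical copies of the input.
    Observed entries are never altered; imputed values are PMM draws from
    the observed support {0,1,2,3}.
    """
    return ChainedImputer(m=m, iterations=iterations, donors=donors, seed=seed).fit_transform(
        dataset
    )
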