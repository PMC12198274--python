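"""Local network metrics of group-conditioned symptom networks.

Node strength is the sum of absolute incident edge weights. The weighted
local clustering coefficient follows the Zhang-Horvath form by default:
on weights scaled to [0, 1] by the network maximum, the ratio of the
triple product around each node to the sum of its open-triple weight
products. Onnela and Barrat variants are available; all three reduce to
the unweighted clustering coefficient on binary graphs. Metrics are
computed on absolute weights and reported raw and z-scored across the
nodes of one network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocalMetrics",
    "node_strength",
    "local_clustering",
    "compare_metrics",
    "compute_local_metrics",
]


def _check_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got {W.shape}")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("weight matrix must have zero diagonal")
    return W


def node_strength(W: np.ndarray) -> np.ndarray:
    """Per-node sum of absolute incident edge weights."""
    W = _check_symmetric(W)
    return np.abs(W).sum(axis=1)


def local_clustering(W: np.ndarray, variant: str = "zhang") -> np.ndarray:
    """Weighted local clustering coefficient, in [0, 1] per node.

    Weights are taken in absolute value and scaled by the network
    maximum (identity when the maximum is 0). 'zhang' computes
    sum_jk w_ij w_jk w_ik / (s_i^2 - sum_j w_ij^2); 'onnela' averages
    cube-rooted triangle intensities over binary-degree pairs; 'barrat'
    weights the binary triangle indicator by incident edge weights.
    Nodes with fewer than two neighbors get 0.
    """
    W = _check_symmetric(W)
    A = np.abs(W)
    mx = A.max()
    if mx > 0:
        A = A / mx
    bin_ = (A > 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "zhang":
            num = np.diag(A @ A @ A)
            denom = A.sum(axis=1) ** 2 - (A**2).sum(axis=1)
            C = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
        elif variant == "onnela":
            cube = np.cbrt(A)
            num = np.diag(cube @ cube @ cube)
            k = bin_.sum(axis=1)
            denom = k * (k - 1)
            C = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
        elif variant == "barrat":
            s = A.sum(axis=1)
            k = bin_.sum(axis=1)
            # per-node sum over neighbor pairs of (w_ij + w_ik)/2 * a_ij a_jk a_ik
            num = ((A[:, :, None] + A[:, None, :]) / 2 * bin_[:, :, None] * bin_[:, None, :] * bin_[None, :, :]).sum(axis=(1, 2))
            denom = s * (k - 1)
            C = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
        else:
            raise ValueError(f"unknown clustering variant {variant!r}")
    return np.clip(C, 0.0, 1.0)


def compare_metrics(metrics_a: np.ndarray, metrics_b: np.ndarray) -> float:
    """Pearson correlation of one local metric between two networks."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must share the node set and order")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance in a metric vector")
    return float(stats.pearsonr(a, b).statistic)


def _zscore_nodes(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


@dataclass
class LocalMetrics:
    """Strength and clustering of one group's network, raw and z-scored."""

    group: str
    nodes: tuple[str, ...]
    strength: np.ndarray
    clustering: np.ndarray
    strength_z: np.ndarray
    clustering_z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "node": list(self.nodes),
                "strength": self.strength,
                "clustering": self.clustering,
                "strength_z": self.strength_z,
                "clustering_z": self.clustering_z,
            }
        )

    def summary(self) -> dict[str, float]:
        """Mean and SD per metric, the printed reporting format."""
        return {
            "strength_mean": float(self.strength.mean()),
            "strength_sd": float(self.strength.std(ddof=1)),
            "clustering_mean": float(self.clustering.mean()),
            "clustering_sd": float(self.clustering.std(ddof=1)),
        }


def compute_local_metrics(
    W: np.ndarray, nodes: tuple[str, ...], group: str, variant: str = "zhang"
) -> LocalMetrics:
    s = node_strength(W)
    c = local_clustering(W, variant=variant)
    return LocalMetrics(
        group=group,
        nodes=tuple(nodes),
        strength=s,
        clustering=c,
        strength_z=_zscore_nodes(s),
        clustering_z=_zscore_nodes(c),
    )
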