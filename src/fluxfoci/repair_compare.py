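"""Cross-cell-line comparison of DNA double-strand-break repair kinetics.

Each cell line is summarized by a five-dimensional repair vector: the
posterior medians of the focus probability per unit area p_t at
t = (0, 0.5, 2, 6, 24) h. Pairwise Euclidean distances between repair
vectors are clustered agglomeratively for the heatmap presentation, and
residual damage is reported per replicate as the percentage of the mean
focus density at 24 h relative to the 30 min time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .foci_dynamics import FociModelPosterior

REPAIR_TIMES = (0.0, 0.5, 2.0, 6.0, 24.0)


@dataclass
class RepairVector:
    cell_line: str
    q: np.ndarray                   # posterior median p_t, fixed time order
    times: tuple = REPAIR_TIMES
    valid: bool = True

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.times),):
            raise ValueError(f"repair vector must have length {len(self.times)}")
        if np.any(self.q <= 0) or np.any(self.q >= 1):
            raise ValueError("repair-vector entries must lie in (0, 1)")


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray

    def validate(self, atol: float = 1e-12) -> None:
        d = self.d
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=atol, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        n = len(self.labels)
        for i in range(n):
            if np.any(d[i][None, :] > d[i][:, None] + d + atol):
                raise ValueError("triangle inequality violated")


def repair_vector(post: FociModelPosterior,
                  times: Sequence[float] = REPAIR_TIMES) -> RepairVector:
    """Posterior-median p_t at the five repair time points, in fixed order."""
    have = {float(t): j for j, t in enumerate(post.times)}
    missing = [t for t in times if float(t) not in have]
    if missing:
        raise ValueError(
            f"posterior is missing time(s) {missing}; has {sorted(have)}")
    q = np.array([np.median(post.p_t[:, have[float(t)]]) for t in times])
    return RepairVector(cell_line=post.cell_line, q=q, times=tuple(times),
                        valid=post.valid)


def distance_matrix(vectors: Sequence[RepairVector]) -> DistanceMatrix:
    """Pairwise Euclidean distances d_ij = ||q_i - q_j|| between repair vectors.

    Each pair is computed once (condensed form), so the result is exactly
    symmetric with a zero diagonal.
    """
    if len(vectors) < 2:
        raise ValueError("need >= 2 repair vectors")
    labels = [v.cell_line for v in vectors]
    Q = np.stack([v.q for v in vectors])
    dm = DistanceMatrix(labels=labels, d=squareform(pdist(Q, metric="euclidean")))
    dm.validate()
    return dm


@dataclass
class ClusterResult:
    leaf_order: np.ndarray
    labels_ordered: List[str]
    Z: np.ndarray                   # scipy linkage matrix
    dendrogram: dict


def cluster_order(dm: DistanceMatrix, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of the precomputed distances.

    The linkage criterion is configurable (single/complete/average/ward;
    ward on precomputed non-Euclidean-embedded distances is heuristic and
    documented as such). Leaf order is deterministic: scipy breaks merge
    ties by the lowest cluster index.
    """
    dm.validate()
    if np.any(~np.isfinite(dm.d)):
        raise ValueError("NaN/inf distances cannot be clustered")
    if method not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage {method!r}")
    Z = linkage(squareform(dm.d, checks=False), method=method)
    order = leaves_list(Z)
    dend = dendrogram(Z, no_plot=True)
    return ClusterResult(
        leaf_order=order, labels_ordered=[dm.labels[i] for i in order],
        Z=Z, dendrogram=dend)


def reorder(dm: DistanceMatrix, result: ClusterResult) -> DistanceMatrix:
    """Rows/columns of the distance matrix in clustered leaf order."""
    idx = result.leaf_order
    return DistanceMatrix(labels=[dm.labels[i] for i in idx],
                          d=dm.d[np.ix_(idx, idx)])


def plot_heatmap(dm: DistanceMatrix, result: Optional[ClusterResult] = None,
                 path=None):
    """Convenience heatmap of (clustered) distances; not bit-reproducible."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is not None:
        dm = reorder(dm, result)
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(dm.labels),) * 2)
    im = ax.imshow(dm.d, cmap="viridis")
    ax.set_xticks(range(len(dm.labels)), dm.labels, rotation=90)
    ax.set_yticks(range(len(dm.labels)), dm.labels)
    fig.colorbar(im, ax=ax, label="repair-vector distance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def residual_damage(records: pd.DataFrame, t_ref: float = 0.5,
                    t_final: float = 24.0) -> pd.DataFrame:
    """Residual damage percentage per cell line and replicate.

    100 * (mean focus density at t_final) / (mean density at t_ref), where a
    nucleus's density is foci_count / area_units. The reference time is the
    30 min post-irradiation peak by default.
    """
    dens = records.assign(density=records["foci_count"] / records["area_units"])
    rows = []
    for (cell, rep), sub in dens.groupby(["cell_line", "replicate"], sort=True):
        ref = sub.loc[sub["time_h"] == t_ref, "density"]
        fin = sub.loc[sub["time_h"] == t_final, "density"]
        if ref.empty or fin.empty:
            raise ValueError(
                f"{cell} replicate {rep}: need records at both {t_ref} h and "
                f"{t_final} h")
        mref = float(ref.mean())
        if mref <= 0:
            raise ValueError(
                f"{cell} replicate {rep}: zero reference density at {t_ref} h")
        rows.append({"cell_line": cell, "replicate": rep,
                     "residual_pct": 100.0 * float(fin.mean()) / mref})
    return pd.DataFrame(rows)
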