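"""Monte Carlo density-peak clustering of fiber orientations.

Thin-bin components of every bootstrap solution are clustered on the
projective sphere (antipodal directions are identified, as fibers have
no polarity) by density-peak clustering: cluster centers combine a high
local density with a large distance to any denser point.  Clusters are
matched across bootstraps by orientation proximity, yielding
per-cluster, per-bootstrap means of Diso, DDelta^2, R1 and T1 whose
medians and interquartile ranges quantify fiber-population-specific
properties and their uncertainty.  E[T1] is computed as the weighted
mean of 1/R1, not as 1/E[R1]; the two differ whenever R1 varies within
a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .descriptors import THIN_BIN, filter_bin
from .mc_inversion import VoxelEnsemble

__all__ = [
    "OrientationCluster",
    "ClusterSummary",
    "angular_distance",
    "density_peak_cluster",
    "geometric_median_orientation",
    "cluster_stats",
    "assign_bundle",
    "significance_tier",
    "compare_bundles",
]

CHI_NAMES = ("d_iso", "d_delta2", "r1", "t1")


def angular_distance(u, v):
    """Antipodally symmetric angle arccos(|u.v|) in [0, pi/2] (rad)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("zero vector has no direction")
    dots = np.abs(np.sum(u * v, axis=-1) / (nu * nv))
    return np.arccos(np.clip(dots, 0.0, 1.0))


def _pairwise_angles(orientations: np.ndarray) -> np.ndarray:
    dots = np.abs(orientations @ orientations.T)
    return np.arccos(np.clip(dots, 0.0, 1.0))


def density_peak_cluster(orientations, weights=None, dc_deg: float = 20.0):
    """Density-peak clustering on the projective sphere.

    For each point, the local density is the total weight of points
    closer than the cutoff ``dc_deg``, and delta is the distance to the
    nearest point of higher density (the maximal distance for the
    global density maximum).  Cluster centers are points whose product
    density * delta stands above the largest gap in its sorted values;
    every other point joins the cluster of its nearest denser neighbor.

    Returns ``(labels, center_indices)`` with labels in
    ``range(len(center_indices))``.
    """
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    n = len(orientations)
    if n == 0:
        raise ValueError("need at least one component")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if n == 1:
        return np.zeros(1, dtype=int), np.array([0])

    dc = np.deg2rad(dc_deg)
    dist = _pairwise_angles(orientations)
    within = dist < dc
    np.fill_diagonal(within, False)
    rho = within @ weights  # local density excludes the point itself

    order = np.argsort(-rho, kind="stable")  # density-descending
    delta = np.empty(n)
    nearest_denser = np.full(n, -1, dtype=int)
    delta[order[0]] = dist[order[0]].max()
    for rank in range(1, n):
        i = order[rank]
        denser = order[:rank]
        j = denser[np.argmin(dist[i, denser])]
        nearest_denser[i] = j
        delta[i] = dist[i, j]

    gamma = rho * delta
    centers = _centers_by_gap(gamma, order)

    labels = np.full(n, -1, dtype=int)
    for k, c in enumerate(centers):
        labels[c] = k
    for rank in range(n):
        i = order[rank]
        if labels[i] == -1:
            labels[i] = labels[nearest_denser[i]]
    return labels, np.asarray(centers)


def _centers_by_gap(gamma: np.ndarray, density_order: np.ndarray):
    """Centers = points before the largest gap in sorted gamma values."""
    n = len(gamma)
    order = np.argsort(-gamma, kind="stable")
    g = gamma[order]
    if n == 1 or g[0] <= 0:
        return [density_order[0]]
    # largest absolute drop between consecutive sorted values
    drops = g[:-1] - g[1:]
    n_centers = int(np.argmax(drops)) + 1
    centers = list(order[:n_centers])
    # the global density maximum is always a center
    if density_order[0] not in centers:
        centers.append(density_order[0])
    return centers


def geometric_median_orientation(
    orientations, weights=None, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Weighted geometric median on the projective sphere.

    Weiszfeld iterations on sign-aligned vectors: at each step every
    orientation is flipped to the hemisphere of the current estimate,
    then the estimate moves to the weighted geometric median update and
    is renormalized to the unit sphere.
    """
    v = np.atleast_2d(np.asarray(orientations, dtype=float))
    n = len(v)
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    # initialize from the weighted dominant eigenvector (antipodally safe)
    scatter = (v * w[:, None]).T @ v
    _, vecs = np.linalg.eigh(scatter)
    m = vecs[:, -1]
    for _ in range(max_iter):
        signs = np.where(v @ m < 0, -1.0, 1.0)
        aligned = v * signs[:, None]
        d = np.linalg.norm(aligned - m, axis=1)
        if np.any(d < 1e-12):  # median sits on a data point
            coincident = aligned[d < 1e-12][0]
            m = coincident / np.linalg.norm(coincident)
            break
        coef = w / d
        new = (aligned * coef[:, None]).sum(axis=0) / coef.sum()
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - m) < tol:
            m = new
            break
        m = new
    if m[2] < 0:
        m = -m
    return m


@dataclass
class OrientationCluster:
    """One orientational aggregate matched across bootstraps."""

    index: int
    median_orientation: np.ndarray  # unit vector (consensus)
    per_bootstrap: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: nb, weight, e[d_iso], e[d_delta2], e[r1], e[t1]

    @property
    def weight_median(self) -> float:
        return float(self.per_bootstrap["weight"].median())


@dataclass
class ClusterSummary:
    """Medians/IQRs across bootstraps for every matched cluster."""

    clusters: list
    table: pd.DataFrame  # one row per cluster x chi: median, iqr, w_norm

    def __len__(self):
        return len(self.clusters)


def cluster_stats(
    ensemble: VoxelEnsemble,
    dc_deg: float = 20.0,
    bin_def=THIN_BIN,
    min_bootstrap_fraction: float = 0.5,
) -> ClusterSummary:
    """Density-peak clustering per bootstrap, matched across bootstraps.

    Each bootstrap's thin-bin components are clustered independently;
    per-bootstrap clusters are matched greedily (by antipodal angular
    distance, within ``dc_deg``) to the consensus orientations seeded by
    the first non-empty bootstrap, new consensus entries being created
    for unmatched clusters.  Clusters present in fewer than
    ``min_bootstrap_fraction`` of the bootstraps are dropped as spurious.

    Cluster weights are medians across bootstraps, normalized so that
    the retained medians sum to one.
    """
    dc = np.deg2rad(dc_deg)
    consensus = []  # consensus unit vectors
    rows = []

    for sol in ensemble:
        comps = filter_bin(sol.components, bin_def)
        if len(comps) == 0 or np.sum(comps.w) <= 0:
            continue
        labels, _ = density_peak_cluster(
            comps.orientations, comps.w, dc_deg=dc_deg
        )
        for k in np.unique(labels):
            members = comps[labels == k]
            gm = geometric_median_orientation(members.orientations, members.w)
            # match against consensus orientations
            if consensus:
                angles = angular_distance(
                    np.asarray(consensus), gm[None, :].repeat(len(consensus), 0)
                )
                best = int(np.argmin(angles))
                if angles[best] < dc:
                    nc = best
                else:
                    consensus.append(gm)
                    nc = len(consensus) - 1
            else:
                consensus.append(gm)
                nc = 0
            wsum = float(np.sum(members.w))
            wn = members.w / wsum
            rows.append(
                {
                    "nc": nc,
                    "nb": sol.bootstrap_index,
                    "weight": wsum,
                    "e[d_iso]": float(members.d_iso @ wn),
                    "e[d_delta2]": float((members.d_delta ** 2) @ wn),
                    "e[r1]": float(members.r1 @ wn),
                    "e[t1]": float((1.0 / members.r1) @ wn),
                    "gm_x": gm[0], "gm_y": gm[1], "gm_z": gm[2],
                }
            )

    if not rows:
        return ClusterSummary([], pd.DataFrame())

    df = pd.DataFrame(rows)
    n_bootstraps_present = df["nb"].nunique()
    clusters = []
    records = []
    for nc, sub in df.groupby("nc"):
        # a bootstrap can contribute at most one instance per cluster:
        # keep the heaviest if the greedy matching doubled up
        sub = sub.sort_values("weight", ascending=False).drop_duplicates("nb")
        if len(sub) < min_bootstrap_fraction * n_bootstraps_present:
            continue
        gm = geometric_median_orientation(
            sub[["gm_x", "gm_y", "gm_z"]].to_numpy(), sub["weight"].to_numpy()
        )
        cluster = OrientationCluster(len(clusters), gm, sub.reset_index(drop=True))
        clusters.append(cluster)
        for chi in CHI_NAMES:
            vals = sub[f"e[{chi}]"]
            records.append(
                {
                    "cluster": cluster.index,
                    "chi": chi,
                    "median": float(vals.median()),
                    "iqr": float(vals.quantile(0.75) - vals.quantile(0.25)),
                    "n_bootstraps": len(sub),
                    "weight_median": float(sub["weight"].median()),
                }
            )

    table = pd.DataFrame(records)
    if len(table):
        per_cluster = table.drop_duplicates("cluster")
        total = per_cluster["weight_median"].sum()
        table["w_norm"] = table["weight_median"] / total if total > 0 else 0.0
    return ClusterSummary(clusters, table)


_DEFAULT_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


def assign_bundle(cluster: OrientationCluster, axes=None, names=None) -> str:
    """Label a cluster by the laboratory axis nearest its orientation.

    ``axes`` maps axis labels to unit vectors (default x/y/z); ``names``
    optionally maps axis labels to anatomical bundle names (e.g. x ->
    corpus callosum for an axial crossing ROI).  Ties resolve with
    precedence x > y > z (dict order).
    """
    axes = axes or _DEFAULT_AXES
    gm = cluster.median_orientation
    best_label, best_angle = None, np.inf
    for label, axis in axes.items():
        ang = float(angular_distance(gm, axis))
        if ang < best_angle - 1e-12:  # strict improvement: earlier axis wins ties
            best_label, best_angle = label, ang
    if names:
        return names.get(best_label, best_label)
    return best_label


def significance_tier(p: float) -> str:
    """Star tier: *** for p<0.01, ** for p in [0.01,0.05), * for [0.05,0.1)."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def compare_bundles(group_a, group_b, exact_max_n: int = 20) -> dict:
    """Two-sided Mann-Whitney U test between two bundles' E-values.

    Uses the exact null distribution when the pooled sample size is at
    most ``exact_max_n`` and there are no ties, the tie-corrected normal
    approximation otherwise.  Returns a dict with the U statistic, the
    p-value and the significance tier.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: every value identical
        return {"u": len(a) * len(b) / 2.0, "p": 1.0, "tier": ""}
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return {"u": float(res.statistic), "p": p, "tier": significance_tier(p)}
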