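"""Group-level covariance networks from regional SUV with permutation nulls.

Edges are Pearson correlations of per-region z-scored SUV across animals.
Edge significance comes from a random-shift null: each region's values are
independently permuted across animals, destroying inter-regional covariance
while preserving marginals; positive and negative correlations are assessed
against the matching null tail separately.  Thresholded networks (entries
failing p < alpha set to 0) feed signed weighted graph metrics: density,
degree, positive/negative strength, signed clustering, and top-quartile hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "CovarianceNetwork",
    "NetworkProperties",
    "build_covariance_network",
    "signed_clustering",
    "network_properties",
    "compare_edge_distributions",
    "compare_edges_between_groups",
]

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclass
class CovarianceNetwork:
    group: str
    labels: list[str]
    r_matrix: np.ndarray
    edge_p: np.ndarray
    n_perm: int
    seed: int | None
    thresholded: dict[float, np.ndarray] = field(default_factory=dict)
    edge_p_pos: np.ndarray | None = None
    edge_p_neg: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self, alpha: float | None = None) -> np.ndarray:
        """Off-diagonal upper-triangle edge weights (thresholded if alpha given)."""
        m = self.r_matrix if alpha is None else self.thresholded[alpha]
        iu = np.triu_indices(self.n, k=1)
        return m[iu]


@dataclass
class NetworkProperties:
    labels: list[str]
    density: int
    degree: np.ndarray
    strength_pos: np.ndarray
    strength_neg: np.ndarray
    clustering: np.ndarray
    hubs_strength: list[str]
    hubs_degree: list[str]


def _validate_group_table(table: pd.DataFrame, min_animals: int = 4) -> np.ndarray:
    X = table.to_numpy(dtype=float)
    if X.shape[0] < min_animals:
        raise ValidationError(f"need at least {min_animals} animals per group")
    if not np.isfinite(X).all():
        raise ValidationError("SUV table contains missing/non-finite values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(table.columns, sd) if s == 0]
        raise DegenerateInputError(f"zero-variance region(s): {bad}")
    return X


def _zscore(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def build_covariance_network(
    group_table: pd.DataFrame,
    n_perm: int = 10_000,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    seed: int | None = None,
    group: str = "",
) -> CovarianceNetwork:
    """Pearson covariance network with per-edge random-shift permutation p.

    The null assesses positive and negative correlations separately: the
    upper-tail p for positive observed edges and the lower-tail p for
    negative ones, each with add-one correction so p is never exactly 0.
    The working ``edge_p`` is the sign-matched one-tailed p doubled (capped
    at 1), making it two-sided and calibrated under independence; the raw
    tail matrices are kept in ``edge_p_pos`` / ``edge_p_neg``.  Thresholded
    variants zero every entry with p >= alpha (diagonal included).
    """
    X = _validate_group_table(group_table)
    labels = list(group_table.columns)
    Z = _zscore(X)
    r = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(r, 1.0)

    rng = np.random.default_rng(seed)
    n_animals, n_regions = Z.shape
    exceed_pos = np.zeros_like(r)
    exceed_neg = np.zeros_like(r)
    for _ in range(n_perm):
        Zp = np.empty_like(Z)
        for j in range(n_regions):
            Zp[:, j] = Z[rng.permutation(n_animals), j]
        rn = np.corrcoef(Zp, rowvar=False)
        exceed_pos += rn >= r
        exceed_neg += rn <= r
    p_pos = (1.0 + exceed_pos) / (n_perm + 1.0)
    p_neg = (1.0 + exceed_neg) / (n_perm + 1.0)
    edge_p = np.minimum(1.0, 2.0 * np.where(r >= 0, p_pos, p_neg))
    net = CovarianceNetwork(
        group=group,
        labels=labels,
        r_matrix=r,
        edge_p=edge_p,
        n_perm=n_perm,
        seed=seed,
        edge_p_pos=p_pos,
        edge_p_neg=p_neg,
    )
    for alpha in alphas:
        thr = np.where(edge_p < alpha, r, 0.0)
        np.fill_diagonal(thr, 0.0)
        net.thresholded[alpha] = thr
    return net


def signed_clustering(W: np.ndarray) -> np.ndarray:
    """Signed weighted clustering coefficient per node.

    Generalisation of the Zhang-Horvath weighted clustering to signed
    networks: weights are rescaled by the maximum magnitude, triangle weights
    multiply with their signs, and the sum is normalised by the total
    two-path weight magnitude,

        C_i = sum_{j!=k} w_ij w_ik w_jk / sum_{j!=k} |w_ij w_ik|.

    Lies in [-1, 1]; equals 1 on complete positive unit-weight graphs and
    reduces to the standard weighted clustering when no edge is negative.
    Nodes with fewer than two incident edges get 0.
    """
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    mx = np.abs(W).max()
    if mx > 0:
        W = W / mx
    A = np.abs(W)
    numer = np.diag(W @ W @ W)
    s = A.sum(axis=1)
    denom = s**2 - (A**2).sum(axis=1)
    out = np.zeros(W.shape[0])
    ok = denom > 0
    out[ok] = numer[ok] / denom[ok]
    return out


def _quartile_hubs(labels: list[str], x: np.ndarray) -> list[str]:
    # top quartile with midpoint interpolation; ties all included
    thr = np.percentile(x, 75, method="midpoint")
    return [lab for lab, v in zip(labels, x) if v >= thr]


def network_properties(net: CovarianceNetwork, alpha: float) -> NetworkProperties:
    """Signed weighted metrics of the thresholded network at ``alpha``."""
    if alpha not in net.thresholded:
        raise ValidationError(f"no thresholded variant at alpha={alpha}")
    W = net.thresholded[alpha]
    A = W != 0
    degree = A.sum(axis=1)
    density = int(A.sum() // 2)
    if density == 0:
        warnings.warn(f"thresholded network at alpha={alpha} has no edges")
        zeros = np.zeros(net.n)
        return NetworkProperties(
            labels=list(net.labels),
            density=0,
            degree=np.zeros(net.n, dtype=int),
            strength_pos=zeros,
            strength_neg=zeros.copy(),
            clustering=zeros.copy(),
            hubs_strength=[],
            hubs_degree=[],
        )
    strength_pos = np.clip(W, 0, None).sum(axis=1)
    strength_neg = np.abs(np.clip(W, None, 0)).sum(axis=1)
    clustering = signed_clustering(W)
    total = strength_pos + strength_neg
    return NetworkProperties(
        labels=list(net.labels),
        density=density,
        degree=degree.astype(int),
        strength_pos=strength_pos,
        strength_neg=strength_neg,
        clustering=clustering,
        hubs_strength=_quartile_hubs(net.labels, total),
        hubs_degree=_quartile_hubs(net.labels, degree.astype(float)),
    )


def compare_edge_distributions(
    netA: CovarianceNetwork,
    netB: CovarianceNetwork,
    alpha: float | None = None,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on edge-weight distributions."""
    if netA.labels != netB.labels:
        raise ValidationError("networks are defined on different region sets")
    a = netA.upper_triangle(alpha)
    b = netB.upper_triangle(alpha)
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_edges_between_groups(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "r",
) -> pd.DataFrame:
    """Per-edge two-sided permutation test of the group correlation difference.

    The null reassigns animals to groups at random (preserving group sizes)
    and recomputes the per-edge correlation difference.  ``statistic`` is the
    plain correlation difference ``"r"`` (default) or the Fisher-z
    difference ``"fisher"``.  Returns a labelled symmetric p-value matrix
    (uncorrected).
    """
    if list(tableA.columns) != list(tableB.columns):
        raise ValidationError("groups must share an identical region set")
    if statistic not in ("r", "fisher"):
        raise ValidationError("statistic must be 'r' or 'fisher'")
    nA, nB = len(tableA), len(tableB)
    if min(nA, nB) < 4:
        warnings.warn("group size < 4; permutation p-values will be unstable")
    XA = _validate_group_table(tableA, min_animals=3)
    XB = _validate_group_table(tableB, min_animals=3)

    def edge_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ra = np.corrcoef(a, rowvar=False)
        rb = np.corrcoef(b, rowvar=False)
        if statistic == "fisher":
            ra = np.arctanh(np.clip(ra, -1 + 1e-12, 1 - 1e-12))
            rb = np.arctanh(np.clip(rb, -1 + 1e-12, 1 - 1e-12))
        return ra - rb

    obs = np.abs(edge_stat(XA, XB))
    pooled = np.vstack([XA, XB])
    # canonical row order (by animal label) so that swapping the two group
    # arguments reproduces the identical permutation null
    order = np.argsort(
        np.asarray(list(tableA.index) + list(tableB.index), dtype=str),
        kind="stable",
    )
    pooled = pooled[order]
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        idx = rng.permutation(nA + nB)
        d = np.abs(edge_stat(pooled[idx[:nA]], pooled[idx[nA:]]))
        exceed += d >= obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=tableA.columns, columns=tableA.columns)
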