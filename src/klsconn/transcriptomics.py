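"""Imaging-transcriptomics: expression preprocessing and PLS inference.

Probe-level microarray expression is reduced to one probe per gene by
differential stability (mean inter-donor Spearman correlation of a probe's
regional profile), intensity-filtered against background, and normalised per
gene with a scaled robust sigmoid (SRS).  The regional response map (ROI
t-values from the group comparison) is then regressed on the regions x genes
matrix with partial least squares; component-1 gene weights are z-scored by
bootstrap over regions and the component's score-response correlation is
tested by permutation of the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "PLSResult",
    "GeneSets",
    "filter_probes_intensity",
    "differential_stability",
    "collapse_probes_differential_stability",
    "srs_normalize",
    "build_expression_matrix",
    "fit_pls",
    "permutation_test_component",
    "bootstrap_gene_z",
    "select_gene_sets",
    "gene_map_correlation",
]

PROBE_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "donor_id",
    "region_id",
    "intensity",
    "background",
]


def _check_probe_table(t: pd.DataFrame) -> None:
    missing = [c for c in PROBE_COLUMNS if c not in t.columns]
    if missing:
        raise ValidationError(f"probe table missing columns: {missing}")
    if not np.isfinite(t["intensity"].to_numpy(dtype=float)).all():
        raise ValidationError("probe table: non-finite intensity values")
    if t.duplicated(["probe_id", "donor_id", "region_id"]).any():
        raise ValidationError("probe table: duplicated (probe, donor, region) rows")


def filter_probes_intensity(t: pd.DataFrame, factor: float = 1.5) -> pd.DataFrame:
    """Drop probes whose intensity is below ``factor`` x background everywhere.

    A probe is removed iff ``intensity < factor * background`` in ALL of its
    samples (strict inequality, so a probe at exactly the threshold is kept).
    """
    _check_probe_table(t)
    below = t["intensity"] < factor * t["background"]
    all_below = below.groupby(t["probe_id"]).transform("all")
    return t.loc[~all_below].reset_index(drop=True)


def differential_stability(t: pd.DataFrame) -> pd.DataFrame:
    """Mean inter-donor Spearman correlation of each probe's regional profile.

    For every probe, each donor pair sharing >= 2 regions contributes the
    Spearman correlation of the probe's profile over the shared regions; the
    probe's differential stability (DS) is the mean over donor pairs.  Probes
    with no valid donor pair get DS = NaN.
    """
    _check_probe_table(t)
    recs = []
    for (probe, gene), sub in t.groupby(["probe_id", "gene_symbol"], sort=True):
        wide = sub.pivot(index="region_id", columns="donor_id", values="intensity")
        donors = list(wide.columns)
        cors = []
        for i in range(len(donors)):
            for j in range(i + 1, len(donors)):
                pair = wide[[donors[i], donors[j]]].dropna()
                if len(pair) < 2:
                    continue
                rho = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
                if np.isfinite(rho):
                    cors.append(rho)
        recs.append((probe, gene, float(np.mean(cors)) if cors else np.nan))
    return pd.DataFrame(recs, columns=["probe_id", "gene_symbol", "ds"])


def collapse_probes_differential_stability(t: pd.DataFrame) -> pd.DataFrame:
    """Retain, per gene, the probe with the highest differential stability.

    Exact DS ties break to the lexicographically smallest probe_id.  Genes
    whose probes all lack a measurable DS are dropped with a warning.
    """
    ds = differential_stability(t)
    keep: list[str] = []
    for gene, sub in ds.groupby("gene_symbol", sort=True):
        valid = sub.dropna(subset=["ds"])
        if valid.empty:
            warnings.warn(f"gene {gene}: no probe measurable in >= 2 donors; dropped")
            continue
        best = valid["ds"].max()
        winners = valid.loc[valid["ds"] == best, "probe_id"]
        keep.append(sorted(winners)[0])
    return t[t["probe_id"].isin(keep)].reset_index(drop=True)


def srs_normalize(x) -> np.ndarray:
    """Scaled robust sigmoid: outlier-robust normalisation to [0, 1].

    s_i = 1 / (1 + exp(-(x_i - median(x)) / (IQR(x) / 1.35))), then min-max
    rescaled to [0, 1].  The 1.35 constant makes IQR/1.35 a normal-consistent
    scale estimate.  Requires a nonconstant input with positive IQR.
    """
    x = np.asarray(x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise DegenerateInputError("srs_normalize: IQR is zero")
    s = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / (iqr / 1.35)))
    return (s - s.min()) / (s.max() - s.min())


def build_expression_matrix(
    t: pd.DataFrame, intensity_factor: float = 1.5
) -> pd.DataFrame:
    """Probe table -> regions x genes matrix, normalised per gene to [0, 1].

    Pipeline: intensity filter -> differential-stability probe collapse ->
    per-donor SRS normalisation per gene -> average across donors -> final
    per-gene min-max rescale.  SRS is applied once per donor profile; the
    provenance of that single application is carried in ``attrs``.
    """
    t = filter_probes_intensity(t, intensity_factor)
    t = collapse_probes_differential_stability(t)
    donor_frames = []
    for donor, sub in t.groupby("donor_id"):
        wide = sub.pivot(index="region_id", columns="gene_symbol", values="intensity")
        normed = wide.apply(lambda col: srs_normalize(col.to_numpy()), axis=0)
        donor_frames.append(normed)
    combined = sum(donor_frames) / len(donor_frames)
    mat = combined.apply(
        lambda col: (col - col.min()) / (col.max() - col.min()), axis=0
    )
    mat.index.name = "region"
    mat.attrs["srs_applied"] = True
    return mat


@dataclass
class PLSResult:
    """Component-1 PLS fit of a regional response on gene expression."""

    region_labels: list[str]
    gene_labels: list[str]
    pls1_scores: np.ndarray
    gene_weights: np.ndarray
    gene_loadings: np.ndarray
    component_r: float
    gene_z: np.ndarray | None = None
    component_p: float | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class GeneSets:
    pls_plus: list[str]
    pls_minus: list[str]
    z_threshold: float = 3.0


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        regions = list(X.index)
        genes = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        regions = [f"R{i + 1:03d}" for i in range(Xv.shape[0])]
        genes = [f"g{i + 1}" for i in range(Xv.shape[1])]
    if isinstance(y, pd.Series):
        if list(y.index) != regions:
            raise ValidationError("response regions do not align with X rows")
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if yv.shape != (Xv.shape[0],):
        raise ValidationError("response length must equal number of regions")
    return Xv, yv, regions, genes


def _pls1(Xz: np.ndarray, yz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First PLS component for a single response.

    With one response, the NIPALS component-1 weight vector is the
    (normalised) covariance X'y; the score is the projection Xw.
    """
    w = Xz.T @ yz
    nrm = np.linalg.norm(w)
    if nrm == 0:
        return w, Xz @ w
    w = w / nrm
    return w, Xz @ w


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def fit_pls(X, y, n_components: int = 1) -> PLSResult:
    """Fit PLS of the regional response on gene expression; keep component 1.

    Columns of X and y are z-scored before fitting.  The component sign is
    fixed so that corr(pls1_scores, y) >= 0.  ``gene_weights`` are the
    component-1 X-weights; X-loadings are exposed alongside.
    """
    Xv, yv, regions, genes = _as_xy(X, y)
    if Xv.shape[0] <= n_components:
        raise ValidationError("need more regions than components")
    Xz = _standardize(Xv)
    yz = _standardize(yv.reshape(-1, 1)).ravel()
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xz, yz)
    scores = pls.x_scores_[:, 0]
    weights = pls.x_weights_[:, 0]
    loadings = pls.x_loadings_[:, 0]
    r = _pearson(scores, yv)
    if r < 0:
        scores, weights, loadings, r = -scores, -weights, -loadings, -r
    return PLSResult(
        region_labels=regions,
        gene_labels=genes,
        pls1_scores=scores,
        gene_weights=weights,
        gene_loadings=loadings,
        component_r=r,
    )


def permutation_test_component(
    X, y, n_perm: int = 5000, seed: int | None = None
) -> float:
    """Permutation p-value for the component-1 score-response correlation.

    The response is permuted over regions ``n_perm`` times, the first PLS
    component refitted each time, and

        p = (1 + #{permuted r >= observed r}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    Xv, yv, _, _ = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    Xz = _standardize(Xv)
    yz = _standardize(yv.reshape(-1, 1)).ravel()
    _, scores = _pls1(Xz, yz)
    r_obs = abs(_pearson(scores, yz))
    count = 0
    chunk = 512
    n_done = 0
    while n_done < n_perm:
        k = min(chunk, n_perm - n_done)
        Yp = np.column_stack([rng.permutation(yz) for _ in range(k)])
        W = Xz.T @ Yp
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        T = Xz @ (W / norms)
        Tc = T - T.mean(axis=0)
        Yc = Yp - Yp.mean(axis=0)
        denom = np.linalg.norm(Tc, axis=0) * np.linalg.norm(Yc, axis=0)
        denom[denom == 0] = 1.0
        r_perm = np.abs(np.sum(Tc * Yc, axis=0) / denom)
        count += int(np.sum(r_perm >= r_obs))
        n_done += k
    return (1 + count) / (n_perm + 1)


def bootstrap_gene_z(
    X, y, n_boot: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Bootstrap z-scores of the component-1 gene weights.

    Regions are resampled with replacement ``n_boot`` times; each bootstrap
    weight vector is sign-aligned to the original by the sign of their inner
    product, and z_g = original weight_g / bootstrap SD of weight_g.

    Weights enter on the covariance scale (X'y without the unit-norm
    rescaling).  The norm of X'y systematically grows under resampling when
    many null genes are present, so dividing each bootstrap replicate by its
    own norm would shrink all replicates in common and inflate |z| for null
    genes; the covariance scale leaves the gene ranking identical and keeps
    null z-scores approximately standard normal.
    """
    Xv, yv, _, _ = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    Xz = _standardize(Xv)
    yz = _standardize(yv.reshape(-1, 1)).ravel()
    w0 = Xz.T @ yz
    R = Xz.shape[0]
    boot = np.empty((n_boot, w0.size))
    for b in range(n_boot):
        idx = rng.integers(0, R, R)
        yb_raw = yv[idx]
        if yb_raw.std() == 0:
            boot[b] = w0
            continue
        Xb = _standardize(Xv[idx])
        yb = _standardize(yb_raw.reshape(-1, 1)).ravel()
        wb = Xb.T @ yb
        if wb @ w0 < 0:
            wb = -wb
        boot[b] = wb
    sd = boot.std(axis=0, ddof=1)
    z = np.zeros_like(w0)
    ok = sd > 0
    if not ok.all():
        warnings.warn("degenerate bootstrap SD for some genes; their z set to 0")
    z[ok] = w0[ok] / sd[ok]
    return z


def select_gene_sets(
    gene_z: np.ndarray, gene_labels, z_threshold: float = 3.0
) -> GeneSets:
    """Split genes into PLS+ (z > threshold) and PLS- (z < -threshold)."""
    z = np.asarray(gene_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("gene_z must be finite")
    labels = list(gene_labels)
    plus = [g for g, zg in zip(labels, z) if zg > z_threshold]
    minus = [g for g, zg in zip(labels, z) if zg < -z_threshold]
    return GeneSets(pls_plus=plus, pls_minus=minus, z_threshold=z_threshold)


def gene_map_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p between one gene's map and the response."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValidationError("need aligned vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input to gene_map_correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
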