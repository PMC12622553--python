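"""Nodal connectivity strength and covariate-adjusted group inference.

Nodal strength of node i is the sum of its off-diagonal edge weights.  Group
differences per ROI are assessed with an ordinary-least-squares model

    strength ~ group + age + sex

where group is coded 0 (control) / 1 (case), so positive t means higher
strength in cases.  P-values are two-sided; the false-discovery rate across
ROIs is controlled with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "NodalStrengthVector",
    "GroupDifferenceMap",
    "nodal_strength",
    "compare_groups",
]


@dataclass(frozen=True)
class NodalStrengthVector:
    labels: list[str]
    strength: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.strength, dtype=float)
        if s.shape != (len(self.labels),):
            raise ValidationError("strength length must match labels")
        object.__setattr__(self, "strength", s)


@dataclass
class GroupDifferenceMap:
    """Per-ROI covariate-adjusted case-minus-control comparison."""

    labels: list[str]
    t_value: np.ndarray
    p: np.ndarray
    q: np.ndarray
    covariates: list[str]
    fdr_alpha: float

    @property
    def significant(self) -> list[str]:
        return [lab for lab, qv in zip(self.labels, self.q) if qv < self.fdr_alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.labels,
                "t": self.t_value,
                "p": self.p,
                "q": self.q,
                "significant": self.q < self.fdr_alpha,
            }
        )


def nodal_strength(m: SimilarityMatrix) -> NodalStrengthVector:
    """Sum of off-diagonal edge weights per node."""
    v = m.values
    strength = v.sum(axis=1) - np.diag(v)
    return NodalStrengthVector(labels=list(m.labels), strength=strength)


GROUP_CODES = {"control": 0.0, "case": 1.0}


def _encode_group(groups: pd.Series) -> np.ndarray:
    vals = set(groups.unique())
    if vals <= set(GROUP_CODES):
        return groups.map(GROUP_CODES).to_numpy(dtype=float)
    if vals <= {0, 1}:
        return groups.to_numpy(dtype=float)
    raise ValidationError(
        f"group column must contain 'case'/'control' or 0/1, got {sorted(map(str, vals))}"
    )


def compare_groups(
    strengths: Sequence[NodalStrengthVector],
    design: pd.DataFrame,
    fdr_alpha: float = 0.01,
    covariates: Sequence[str] = ("age", "sex"),
) -> GroupDifferenceMap:
    """Per-ROI OLS of nodal strength on group with covariate adjustment.

    ``design`` rows are matched to ``strengths`` by ``subject_id`` order and
    must contain ``subject_id``, ``group`` and the requested covariates.
    Requires at least 3 subjects per group and a full-rank design.
    """
    if "group" not in design.columns:
        raise ValidationError("design table must contain a 'group' column")
    if len(design) != len(strengths):
        raise ValidationError("design rows must match number of subjects")
    labels = list(strengths[0].labels)
    for s in strengths:
        if list(s.labels) != labels:
            raise ValidationError("all subjects must share the same ROI labels")
    S = np.vstack([s.strength for s in strengths])  # subjects x ROI

    g = _encode_group(design["group"])
    counts = np.bincount(g.astype(int), minlength=2)
    if counts.min() < 3:
        raise ValidationError("need at least 3 subjects per group")

    X_cols = [np.ones(len(design)), g]
    names = ["const", "group"]
    for cov in covariates:
        if cov not in design.columns:
            raise ValidationError(f"covariate {cov!r} missing from design table")
        col = design[cov]
        if col.dtype == object:
            levels = sorted(col.unique())
            if len(levels) == 1:
                raise ValidationError(f"covariate {cov!r} is constant")
            if len(levels) != 2:
                raise ValidationError(f"covariate {cov!r} must be binary or numeric")
            col = (col == levels[1]).astype(float)
        X_cols.append(np.asarray(col, dtype=float))
        names.append(cov)
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient (confounded covariates); "
            f"columns: {names}"
        )

    t = np.empty(len(labels))
    p = np.empty(len(labels))
    for j in range(len(labels)):
        fit = sm.OLS(S[:, j], X).fit()
        t[j] = fit.tvalues[1]
        p[j] = fit.pvalues[1]
    q = multipletests(p, method="fdr_bh")[1]
    return GroupDifferenceMap(
        labels=labels,
        t_value=t,
        p=p,
        q=q,
        covariates=list(covariates),
        fdr_alpha=fdr_alpha,
    )
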