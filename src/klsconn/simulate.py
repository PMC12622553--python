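"""Seeded synthetic cohorts with planted structure.

Three generators emulate the data every downstream stage consumes:

* a two-group human PET cohort — per-subject, per-ROI voxel uptake samples
  (SUVR scale) in which a chosen set of ROIs carries a location shift in the
  case group;
* a regions x genes expression matrix in which a planted minority of genes
  correlates (positively or negatively) with a supplied regional map, with an
  optional donor/probe-level long table for the probe-collapse stage;
* two rodent groups of regional SUV means with block-structured inter-regional
  covariance.

All randomness flows from a single integer seed expanded through
``numpy.random.SeedSequence`` substreams, so a fixed seed gives bit-identical
output and adding subjects never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "HumanCohortSpec",
    "GeneMatrixSpec",
    "MouseCohortSpec",
    "ROISampleSet",
    "generate_human_cohort",
    "generate_gene_matrix",
    "generate_mouse_cohort",
]

# cohort-level constants for the SUVR-like baseline: ROI means are drawn once
# per cohort around a plausible grey-matter SUVR with moderate regional spread
BASELINE_MEAN = 1.5
BASELINE_ROI_SD = 0.15
AGE_RANGE = (18.0, 60.0)


def roi_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class HumanCohortSpec:
    """Parameters of the synthetic two-group human PET cohort.

    ``effect_shift`` is expressed in units of the control voxel SD
    (``noise_sd``); negative values plant uptake deficits in ``effect_rois``
    of the case group.  ``age_confound`` (years added to case ages) is off by
    default and exists to exercise covariate adjustment.
    """

    n_cases: int
    n_controls: int
    n_roi: int = 246
    voxels_per_roi: int = 200
    effect_rois: frozenset[int] = field(default_factory=frozenset)
    effect_shift: float = 0.0
    noise_sd: float = 0.15
    seed: int = 0
    age_confound: float = 0.0
    family: str = "normal"  # "normal" or "lognormal"

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValidationError("n_cases must be >= 2")
        if self.n_controls < 2:
            raise ValidationError("n_controls must be >= 2")
        if self.n_roi < 2:
            raise ValidationError("n_roi must be >= 2")
        if self.voxels_per_roi < 10:
            raise ValidationError("voxels_per_roi must be >= 10")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        rois = frozenset(self.effect_rois)
        if not rois <= set(range(self.n_roi)):
            raise ValidationError("effect_rois must be a subset of {0..n_roi-1}")
        object.__setattr__(self, "effect_rois", rois)
        if self.family not in ("normal", "lognormal"):
            raise ValidationError("family must be 'normal' or 'lognormal'")


@dataclass(frozen=True)
class ROISampleSet:
    """One subject's map from ROI label to a vector of voxel uptake values."""

    subject_id: str
    group: str
    samples: dict[str, np.ndarray]

    def labels(self) -> list[str]:
        return list(self.samples.keys())


def _draw_roi_sample(
    rng: np.random.Generator, mean: float, sd: float, n: int, family: str
) -> np.ndarray:
    if family == "normal":
        return rng.normal(mean, sd, n)
    # lognormal matched to the requested mean and SD
    var = sd**2
    sigma2 = np.log(1.0 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def generate_human_cohort(
    spec: HumanCohortSpec,
) -> tuple[list[ROISampleSet], pd.DataFrame]:
    """Generate case/control subjects and their design table.

    Control voxels in ROI r are drawn around a cohort-level baseline mean
    mu_r; case voxels in ``effect_rois`` are shifted by
    ``effect_shift * noise_sd``.  The design table has columns
    ``subject_id, group, age, sex`` with age uniform on [18, 60] and sex
    Bernoulli(1/2), independent of group unless ``age_confound`` is set.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_subjects = spec.n_cases + spec.n_controls
    cohort_ss, *subject_ss = ss.spawn(n_subjects + 1)
    cohort_rng = np.random.default_rng(cohort_ss)
    mu = cohort_rng.normal(BASELINE_MEAN, BASELINE_ROI_SD, spec.n_roi)
    labels = roi_labels(spec.n_roi)
    effect = np.zeros(spec.n_roi)
    for r in spec.effect_rois:
        effect[r] = spec.effect_shift * spec.noise_sd

    subjects: list[ROISampleSet] = []
    rows = []
    for k in range(n_subjects):
        is_case = k < spec.n_cases
        group = "case" if is_case else "control"
        sid = f"{'case' if is_case else 'ctrl'}{(k if is_case else k - spec.n_cases) + 1:03d}"
        rng = np.random.default_rng(subject_ss[k])
        samples = {}
        for r, lab in enumerate(labels):
            mean = mu[r] + (effect[r] if is_case else 0.0)
            samples[lab] = _draw_roi_sample(
                rng, mean, spec.noise_sd, spec.voxels_per_roi, spec.family
            )
        age = rng.uniform(*AGE_RANGE) + (spec.age_confound if is_case else 0.0)
        sex = "M" if rng.random() < 0.5 else "F"
        subjects.append(ROISampleSet(subject_id=sid, group=group, samples=samples))
        rows.append({"subject_id": sid, "group": group, "age": age, "sex": sex})
    design = pd.DataFrame(rows)
    return subjects, design


@dataclass(frozen=True)
class GeneMatrixSpec:
    """Parameters of the synthetic regions x genes expression matrix.

    ``n_planted_pos``/``n_planted_neg`` genes are constructed to correlate
    about ``+planted_r``/``-planted_r`` with a supplied regional target map;
    the rest are independent noise.  When ``probes_per_gene > 1`` and
    ``n_donors > 1`` a probe-level long table with donor offsets and
    probe-specific noise is emitted for the probe-collapse stage.
    """

    n_regions: int
    n_genes: int
    n_planted_pos: int = 0
    n_planted_neg: int = 0
    planted_r: float = 0.8
    noise_sd: float = 1.0
    n_donors: int = 1
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValidationError("n_regions must be >= 4")
        if self.n_planted_pos < 0 or self.n_planted_neg < 0:
            raise ValidationError("planted gene counts must be >= 0")
        if self.n_planted_pos + self.n_planted_neg >= self.n_genes:
            raise ValidationError("n_planted_pos + n_planted_neg must be < n_genes")
        if not 0.0 < self.planted_r < 1.0:
            raise ValidationError("planted_r must be strictly between 0 and 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.probes_per_gene < 1:
            raise ValidationError("probes_per_gene must be >= 1")
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")


def gene_names(spec: GeneMatrixSpec) -> list[str]:
    pos = [f"genePOS{i + 1:04d}" for i in range(spec.n_planted_pos)]
    neg = [f"geneNEG{i + 1:04d}" for i in range(spec.n_planted_neg)]
    n_noise = spec.n_genes - spec.n_planted_pos - spec.n_planted_neg
    noise = [f"gene{i + 1:05d}" for i in range(n_noise)]
    return pos + neg + noise


EXPRESSION_BASELINE = 7.0  # log2-microarray-like intensity scale
BACKGROUND_LEVEL = 4.0
DONOR_SD = 0.3


def generate_gene_matrix(
    spec: GeneMatrixSpec, target_map: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Regions x genes matrix with planted map-correlated genes.

    Returns ``(matrix, probe_table)``; ``probe_table`` is ``None`` unless
    both ``probes_per_gene > 1`` and ``n_donors > 1``.
    """
    t = np.asarray(target_map, dtype=float)
    if t.shape != (spec.n_regions,):
        raise ValidationError(
            f"target_map must have length n_regions={spec.n_regions}"
        )
    if np.ptp(t) == 0:
        raise ValidationError("target_map is constant")
    z = (t - t.mean()) / t.std()

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    names = gene_names(spec)
    r = spec.planted_r
    cols = np.empty((spec.n_regions, spec.n_genes))
    for g in range(spec.n_genes):
        e = rng.standard_normal(spec.n_regions)
        if g < spec.n_planted_pos:
            profile = r * z + np.sqrt(1 - r**2) * e
        elif g < spec.n_planted_pos + spec.n_planted_neg:
            profile = -r * z + np.sqrt(1 - r**2) * e
        else:
            profile = e
        cols[:, g] = EXPRESSION_BASELINE + spec.noise_sd * profile
    regions = [f"R{i + 1:03d}" for i in range(spec.n_regions)]
    matrix = pd.DataFrame(cols, index=regions, columns=names)
    matrix.index.name = "region"

    probe_table = None
    if spec.probes_per_gene > 1 and spec.n_donors > 1:
        donors = [f"D{d + 1:02d}" for d in range(spec.n_donors)]
        donor_offset = rng.normal(0.0, DONOR_SD, spec.n_donors)
        recs = []
        for g, gene in enumerate(names):
            for k in range(spec.probes_per_gene):
                probe_id = f"{gene}_p{k + 1}"
                probe_noise = 0.1 * (k + 1)  # later probes are noisier
                for d, donor in enumerate(donors):
                    vals = (
                        cols[:, g]
                        + donor_offset[d]
                        + rng.normal(0.0, probe_noise, spec.n_regions)
                    )
                    for reg, v in zip(regions, vals):
                        recs.append((probe_id, gene, donor, reg, v, BACKGROUND_LEVEL))
        probe_table = pd.DataFrame(
            recs,
            columns=[
                "probe_id",
                "gene_symbol",
                "donor_id",
                "region_id",
                "intensity",
                "background",
            ],
        )
    return matrix, probe_table


@dataclass(frozen=True)
class MouseCohortSpec:
    """Parameters of the synthetic two-group rodent SUV cohort.

    ``block_structure`` lists covarying region blocks as
    ``(region_indices, correlation)`` pairs, either one list applied to both
    groups or a mapping from group name to such a list; regions outside any
    block are independent.
    """

    n_per_group: int = 12
    n_regions: int = 22
    block_structure: tuple = ()
    suv_mean: float = 1.0
    suv_sd: float = 0.1
    seed: int = 0
    group_names: tuple[str, str] = ("groupA", "groupB")

    def __post_init__(self) -> None:
        if self.n_per_group < 4:
            raise ValidationError("n_per_group must be >= 4")
        if self.n_regions < 3:
            raise ValidationError("n_regions must be >= 3")
        if self.suv_sd <= 0:
            raise ValidationError("suv_sd must be > 0")


def _blocks_for_group(spec: MouseCohortSpec, group: str):
    bs = spec.block_structure
    if isinstance(bs, Mapping):
        return bs.get(group, ())
    return bs


def _build_correlation(n_regions: int, blocks) -> np.ndarray:
    corr = np.eye(n_regions)
    for regions, rho in blocks:
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"block correlation {rho} must have magnitude < 1")
        idx = np.asarray(list(regions), dtype=int)
        if idx.min() < 0 or idx.max() >= n_regions:
            raise ValidationError("block region index out of range")
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = rho
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValidationError("block_structure implies a non-PSD covariance matrix")
    return corr


def generate_mouse_cohort(spec: MouseCohortSpec) -> dict[str, pd.DataFrame]:
    """Two animals x regions SUV tables with planted covariance blocks."""
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(len(spec.group_names))
    regions = [f"R{i + 1:02d}" for i in range(spec.n_regions)]
    out: dict[str, pd.DataFrame] = {}
    for group, stream in zip(spec.group_names, streams):
        corr = _build_correlation(spec.n_regions, _blocks_for_group(spec, group))
        # small jitter keeps Cholesky stable at |rho| near 1
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_regions))
        rng = np.random.default_rng(stream)
        zmat = rng.standard_normal((spec.n_per_group, spec.n_regions))
        suv = spec.suv_mean + spec.suv_sd * (zmat @ chol.T)
        idx = [f"{group}_a{i + 1:02d}" for i in range(spec.n_per_group)]
        df = pd.DataFrame(suv, index=idx, columns=regions)
        df.index.name = "animal_id"
        out[group] = df
    return out
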