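"""TSV/JSON readers and writers for every pipeline artifact.

All tables are UTF-8 tab-separated with dot decimals.  Square matrices carry
their labels in the header row and first column.  Long-format voxel sample
files have columns (subject_id, roi_id, voxel_value).  Each written artifact
can carry a JSON sidecar recording the generating spec/config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .similarity import SimilarityMatrix

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled square matrix TSV, validating shape and content."""
    df = _read_tsv(path)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicated row/column labels")
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ (not square)")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ParseError(f"{path}: non-numeric cells present")
    bad = np.argwhere(~np.isfinite(vals))
    if bad.size:
        i, j = bad[0]
        # +2: one for the header line, one for 1-based numbering
        raise ParseError(
            f"{path}: NaN/inf at row {df.index[i]!r} column {df.columns[j]!r} "
            f"(line {i + 2})"
        )
    return df


def write_similarity(m: SimilarityMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.index.name = "roi"
    write_matrix(df, path)
    write_json_summary(m.meta, path.with_suffix(path.suffix + ".json"))


def read_similarity(path) -> SimilarityMatrix:
    path = Path(path)
    df = read_matrix(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SimilarityMatrix(labels=list(df.index), values=df.to_numpy(), meta=meta)


def write_samples(subjects, path) -> None:
    """Write ROI sample sets in long format (subject_id, roi_id, voxel_value)."""
    recs = []
    for s in subjects:
        for roi, vals in s.samples.items():
            for v in vals:
                recs.append((s.subject_id, roi, v))
    pd.DataFrame(recs, columns=["subject_id", "roi_id", "voxel_value"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_samples(path) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "roi_id", "voxel_value"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    if df["voxel_value"].isna().any():
        line = int(df["voxel_value"].isna().idxmax()) + 2
        raise ParseError(f"{path}: missing voxel_value (line {line})")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (sid, roi), sub in df.groupby(["subject_id", "roi_id"], sort=False):
        out.setdefault(sid, {})[roi] = sub["voxel_value"].to_numpy(dtype=float)
    return out


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: design table needs subject_id and group columns")
    if df["subject_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated subject_id")
    return df


def write_gene_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gene_matrix(path) -> pd.DataFrame:
    """Regions x genes matrix; constant gene columns are flagged with a warning."""
    df = _read_tsv(path)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicated region labels")
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: missing expression values")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"{path}: constant gene column(s) {constant[:5]}... flagged for rejection"
        )
        df.attrs["constant_columns"] = constant
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json_summary(obj: Mapping, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))


def write_sidecar(artifact_path, spec, seed: int | None = None) -> None:
    """Record the generating spec and seed next to a data file."""
    artifact_path = Path(artifact_path)
    payload = {"spec": spec, "seed": seed}
    write_json_summary(payload, artifact_path.with_suffix(artifact_path.suffix + ".json"))


def extract_roi_samples(parcellation_path, pet_path) -> dict[str, np.ndarray]:
    """Per-ROI voxel vectors from a NIfTI label image and a matching PET image.

    Labels are 1-based integers; label 0 is background.  Both images must
    share the same voxel grid.
    """
    import nibabel as nib  # optional heavyweight dependency, imported lazily

    labels_img = nib.load(str(parcellation_path))
    pet_img = nib.load(str(pet_path))
    lab = np.asarray(labels_img.dataobj).astype(int)
    pet = np.asarray(pet_img.dataobj, dtype=float)
    if lab.shape != pet.shape:
        raise ParseError("parcellation and PET images are not on the same grid")
    out = {}
    for value in np.unique(lab):
        if value == 0:
            continue
        out[f"ROI{value:03d}"] = pet[lab == value].ravel()
    return out
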