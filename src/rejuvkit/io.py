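"""Readers and writers for the package's file formats.

Conventions: matrices are TSV with samples in rows (first column sample ids,
header row of feature ids; a ``transpose`` flag covers the other layout);
intervals are BED-style 0-based half-open; TSS and CpG-manifest positions
are 0-based.  Clock coefficients are CSV with columns ``feature_id,weight``
(one reserved ``(Intercept)`` row, optional ``training_mean`` column) plus a
metadata JSON sidecar.  All writes go through a temp-file + atomic-rename
contract so partial outputs are never left behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .clocks import AgeTransform, ClockModel
from .errors import FormatError
from .synthetic import LabelMask, MaskSeries

MISSING_TOKENS = {"", "NA", "NaN", "nan", "null"}


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def load_matrix(path, kind: str = "beta", transpose: bool = False) -> pd.DataFrame:
    """Load a samples x features TSV matrix with validation.

    ``kind`` is ``beta`` (values must lie in [0, 1]) or ``expression``
    (values must be >= 0).  Missing-value tokens become NaN; out-of-range or
    non-numeric cells raise :class:`FormatError` naming the cell.
    """
    if kind not in ("beta", "expression"):
        raise FormatError(f"unknown matrix kind {kind!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate column ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate feature ids")
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, col in enumerate(df.columns):
        for i, sample in enumerate(df.index):
            tok = raw[i, j].strip()
            if tok in MISSING_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                v = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {tok!r} at sample {sample!r}, "
                    f"feature {col!r}"
                ) from None
            if kind == "beta" and not (0.0 <= v <= 1.0):
                raise FormatError(
                    f"{path}: beta value {v} out of [0,1] at sample {sample!r}, "
                    f"feature {col!r}"
                )
            if kind == "expression" and v < 0:
                raise FormatError(
                    f"{path}: negative expression {v} at sample {sample!r}, "
                    f"feature {col!r}"
                )
            out[i, j] = v
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    res.index.name = "sample_id"
    res.attrs["n_missing"] = int(np.isnan(out).sum())
    return res


def write_matrix(df: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index_label="sample_id")


def load_table(path, index_col=0) -> pd.DataFrame:
    """Generic TSV table loader (sample tables, TSS tables, manifests)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index_label=index_label or df.index.name)


def load_tss_table(path) -> pd.DataFrame:
    """TSS TSV: gene_id, chrom, tss (0-based), optional strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in TSS table")
    return df.set_index("gene_id")


def load_cpg_manifest(path) -> pd.DataFrame:
    """CpG manifest TSV: cpg_id, chrom, pos (0-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"cpg_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    if df["cpg_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate CpG ids in manifest")
    return df.set_index("cpg_id")


def load_elements_bed(path) -> pd.DataFrame:
    """Regulatory elements BED: chrom start end element_id class activity_fib activity_ipsc."""
    names = ["chrom", "start", "end", "element_id", "class",
             "activity_fibroblast", "activity_ipsc"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    if df["element_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate element ids")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: element with start >= end")
    return df.set_index("element_id")


def write_elements_bed(elements: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("class", "activity_fibroblast", "activity_ipsc")
             if c in elements.columns]
    out = elements.reset_index()[["chrom", "start", "end", "element_id", *extra]]
    with atomic_write(path) as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        regions[["chrom", "start", "end", "n_sites"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# clock models
# ---------------------------------------------------------------------------


def load_clock_model(coeff_csv, meta_json=None) -> ClockModel:
    """Load a clock from a coefficient CSV (+ optional metadata sidecar)."""
    df = pd.read_csv(coeff_csv)
    if "feature_id" not in df.columns or "weight" not in df.columns:
        raise FormatError(f"{coeff_csv}: need columns feature_id, weight")
    is_int = df["feature_id"] == "(Intercept)"
    if int(is_int.sum()) != 1:
        raise FormatError(
            f"{coeff_csv}: expected exactly one '(Intercept)' row, found {int(is_int.sum())}"
        )
    intercept = float(df.loc[is_int, "weight"].iloc[0])
    feats = df.loc[~is_int]
    if feats["feature_id"].duplicated().any():
        raise FormatError(f"{coeff_csv}: duplicate feature ids")
    weights = pd.Series(feats["weight"].to_numpy(float),
                        index=feats["feature_id"].to_numpy())
    training_means = None
    if "training_mean" in feats.columns and feats["training_mean"].notna().any():
        training_means = pd.Series(feats["training_mean"].to_numpy(float),
                                   index=feats["feature_id"].to_numpy())
    meta = {}
    if meta_json is not None:
        with open(meta_json) as fh:
            meta = json.load(fh)
    kind = meta.get("output_kind", "transformed_age")
    transform = AgeTransform(
        adult_age=float(meta.get("adult_age", 20.0)),
        log_base=float(meta.get("log_base", 2.0)),
    )
    return ClockModel(
        name=meta.get("name", Path(str(coeff_csv)).stem),
        intercept=intercept,
        weights=weights,
        output_kind=kind,
        training_means=training_means,
        transform=transform,
    )


def save_clock_model(model: ClockModel, coeff_csv, meta_json=None) -> None:
    rows = [{"feature_id": "(Intercept)", "weight": model.intercept,
             "training_mean": np.nan}]
    means = model.training_means
    for feat, w in model.weights.items():
        rows.append({
            "feature_id": feat,
            "weight": w,
            "training_mean": (means.get(feat, np.nan) if means is not None else np.nan),
        })
    with atomic_write(coeff_csv) as fh:
        pd.DataFrame(rows).to_csv(fh, index=False)
    if meta_json is not None:
        meta = {
            "name": model.name,
            "output_kind": model.output_kind,
            "adult_age": model.transform.adult_age,
            "log_base": model.transform.log_base,
        }
        with atomic_write(meta_json) as fh:
            json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# masks and images
# ---------------------------------------------------------------------------


def save_mask_png(mask: np.ndarray, path) -> None:
    """Save a binary mask as an 8-bit 0/255 PNG."""
    arr = (np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
    with atomic_write(path, "wb") as fh:
        Image.fromarray(arr, mode="L").save(fh, format="PNG")


def load_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def save_label_mask(mask: LabelMask, path) -> None:
    """Save an integer label mask as 16-bit PNG."""
    arr = mask.labels.astype(np.uint16)
    with atomic_write(path, "wb") as fh:
        Image.fromarray(arr).save(fh, format="PNG")


def load_label_mask(path, pixel_size: float = 1.0) -> LabelMask:
    arr = np.asarray(Image.open(path)).astype(np.int32)
    return LabelMask(arr, pixel_size=pixel_size)


def save_mask_series_tiff(series: MaskSeries, path) -> None:
    """Save a mask series as a multi-page 8-bit TIFF (0/255)."""
    arr = (series.frames.astype(np.uint8)) * 255
    # tifffile needs a named file, not an anonymous descriptor; emulate the
    # atomic-write pattern with a sibling temp path plus rename.
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, arr, photometric="minisblack")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_mask_series_tiff(path, pixel_size: float, frame_interval: float) -> MaskSeries:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return MaskSeries(arr >= 128, pixel_size=pixel_size, frame_interval=frame_interval)


def write_json(obj, path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
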