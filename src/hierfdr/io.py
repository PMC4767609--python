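"""File formats and report writers.

Two input surfaces feed the procedures: a delimited table of (id, family, p)
rows for generic grouped hypotheses, and a pair of co-registered volumes (a
p-value map plus an integer label map) for voxel data.  Volumes are NIfTI-1
(.nii / .nii.gz) via nibabel, with a plain-text fallback (a ``# shape:``
header followed by the flattened values) that keeps the pipeline testable
without binary files.  Label 0 marks background / excluded voxels.
"""

from __future__ import annotations

import json
import os
import sys
import tempfile
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import TestResult
from .procedures import FamilyPartition, HierarchicalResult

__all__ = [
    "read_pvalue_table",
    "read_volume",
    "write_volume",
    "read_volume_pair",
    "write_reports",
]


def read_pvalue_table(path) -> Tuple[np.ndarray, FamilyPartition]:
    """Read a delimited text file with columns id, family, p.

    Families are coded in first-appearance order.  Malformed rows and p-values
    outside [0, 1] raise a parse error naming the offending line (1-based,
    counting the header).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"{path}: could not parse delimited table: {exc}") from exc
    if table.empty:
        raise ValueError(f"{path}: file contains no data rows")
    cols = {c.lower(): c for c in table.columns}
    for need in ("id", "family", "p"):
        if need not in cols:
            raise ValueError(f"{path}: missing required column {need!r}")
    p_raw = pd.to_numeric(table[cols["p"]], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(p_raw) | (p_raw < 0) | (p_raw > 1))
    if bad.size:
        line = int(bad[0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"{path}: invalid p-value {table[cols['p']].iloc[bad[0]]!r} on line {line}")
    family = table[cols["family"]]
    if family.isna().any():
        line = int(np.flatnonzero(family.isna())[0]) + 2
        raise ValueError(f"{path}: empty family label on line {line}")
    return p_raw.to_numpy(float), FamilyPartition.from_labels(family.to_numpy())


def read_volume(path) -> np.ndarray:
    """Read a 3-D volume from NIfTI-1 or the plain-text fallback format."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# shape:"):
            raise ValueError(f"{path}: expected a '# shape: nx ny nz' header line")
        shape = tuple(int(v) for v in header.split(":")[1].split())
        values = np.loadtxt(fh)
    if values.size != int(np.prod(shape)):
        raise ValueError(f"{path}: value count does not match declared shape {shape}")
    return values.reshape(shape)


def write_volume(array: np.ndarray, path) -> None:
    """Write a 3-D volume as NIfTI-1 or the plain-text fallback, by suffix."""
    path = Path(path)
    array = np.asarray(array)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(array.astype(np.float64), np.eye(4)), str(path))
    else:
        with open(path, "w") as fh:
            fh.write("# shape: " + " ".join(str(s) for s in array.shape) + "\n")
            np.savetxt(fh, array.ravel()[:, None], fmt="%.17g")


def read_volume_pair(p_path, label_path
                     ) -> Tuple[np.ndarray, FamilyPartition, np.ndarray, Tuple[int, ...]]:
    """Load a p-value map and a co-registered integer label map.

    Analysis is restricted to voxels with positive labels.  Returns the flat
    p-values, the family partition, the flat voxel indices of the retained
    voxels (for writing rejection maps back), and the grid shape.
    """
    pmap = read_volume(p_path)
    labels = read_volume(label_path)
    if pmap.shape != labels.shape:
        raise ValueError(
            f"grid mismatch: p-map {pmap.shape} vs label map {labels.shape}")
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label map must contain integers")
    labels = np.round(labels).astype(np.int64)
    flat_idx = np.flatnonzero(labels.ravel() > 0)
    if flat_idx.size == 0:
        raise ValueError("no labelled voxels (all labels are <= 0)")
    p = pmap.ravel()[flat_idx]
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-value map contains values outside [0, 1]")
    part = FamilyPartition.from_labels(labels.ravel()[flat_idx])
    return p, part, flat_idx, pmap.shape


def _per_hypothesis_frame(result, part: FamilyPartition, p: np.ndarray) -> pd.DataFrame:
    reject = result.global_reject if isinstance(result, HierarchicalResult) else result.reject
    return pd.DataFrame({
        "index": np.arange(p.size),
        "family": part.labels,
        "p": p,
        "rejected": np.asarray(reject, dtype=bool),
    })


def _per_family_frame(result, part: FamilyPartition) -> pd.DataFrame:
    rows = []
    hier = isinstance(result, HierarchicalResult)
    for code in range(part.k):
        label = part.label(code)
        if hier:
            selected = label in result.per_family_results
            rows.append({
                "family": label,
                "m_ell": int(part.sizes[code]),
                "u_ell": result.u_values[label],
                "stage1_p": result.stage1_pvalues[label],
                "selected": selected,
                "R_ell": result.per_family_results[label].num_rejections if selected else 0,
            })
        else:
            idx = part.indices(code)
            rows.append({
                "family": label,
                "m_ell": int(part.sizes[code]),
                "u_ell": "",
                "stage1_p": "",
                "selected": "",
                "R_ell": int(np.asarray(result.reject)[idx].sum()),
            })
    return pd.DataFrame(rows)


def write_reports(result: Union[HierarchicalResult, TestResult],
                  part: FamilyPartition, p: np.ndarray, out_dir,
                  run_info: Optional[Dict] = None,
                  voxel_indices: Optional[np.ndarray] = None,
                  grid: Optional[Tuple[int, ...]] = None,
                  volume_suffix: str = ".nii.gz") -> Dict[str, Path]:
    """Write per-hypothesis and per-family TSVs plus a run log; optionally a
    0/1 rejection map for volume inputs.

    Files are staged in a temporary directory and moved into place only after
    every file has been written, so a failure leaves no partial outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reject = result.global_reject if isinstance(result, HierarchicalResult) else result.reject

    staged: Dict[str, Path] = {}
    with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
        tmp = Path(tmp)
        per_hyp = tmp / "per_hypothesis.tsv"
        _per_hypothesis_frame(result, part, p).to_csv(per_hyp, sep="\t", index=False)
        staged["per_hypothesis"] = per_hyp

        per_fam = tmp / "per_family.tsv"
        _per_family_frame(result, part).to_csv(per_fam, sep="\t", index=False)
        staged["per_family"] = per_fam

        log = dict(run_info or {})
        log["num_rejections"] = int(np.asarray(reject).sum())
        log["k"] = int(part.k)
        log["m"] = int(part.m)
        if isinstance(result, HierarchicalResult):
            log["R"] = result.R
            log["selected_families"] = [str(x) for x in result.selected_families]
        log["versions"] = {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        log_path = tmp / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, default=str))
        staged["run_log"] = log_path

        if voxel_indices is not None and grid is not None:
            volume = np.zeros(int(np.prod(grid)))
            volume[np.asarray(voxel_indices)] = np.asarray(reject, dtype=float)
            map_path = tmp / f"rejection_map{volume_suffix}"
            write_volume(volume.reshape(grid), map_path)
            staged["rejection_map"] = map_path

        written = {}
        for key, src in staged.items():
            dst = out_dir / src.name
            os.replace(src, dst)
            written[key] = dst
    return written
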