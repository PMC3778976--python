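"""Tabular and volumetric exports (TSV, NIfTI)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

FLOAT_FMT = "%.8g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def source_map_frame(source_map) -> pd.DataFrame:
    g = source_map.grid
    return pd.DataFrame({
        "x_mm": g.voxels_mni[:, 0], "y_mm": g.voxels_mni[:, 1],
        "z_mm": g.voxels_mni[:, 2],
        "t": source_map.t, "p": source_map.p,
        "flag": source_map.flag.astype(int),
    })


def roi_frame(roi_set) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(roi_set.rois, start=1):
        for coord, hemi in ((r.mni_mm, "R" if r.mni_mm[0] > 0 else "L"),
                            (r.mirror_mni_mm,
                             "R" if r.mirror_mni_mm[0] > 0 else "L")):
            rows.append((i, coord[0], coord[1], coord[2], hemi,
                         r.mean_abs_t, r.peak_t, len(r.cluster_voxels)))
    return pd.DataFrame(rows, columns=[
        "roi", "x_mm", "y_mm", "z_mm", "hemisphere", "mean_abs_t",
        "peak_t", "cluster_size"])


def export_nifti(source_map, values: np.ndarray, path: str | Path) -> Path:
    """Write voxel values on the grid as a NIfTI volume in MNI space."""
    g = source_map.grid
    vol = g.rasterize(values)
    corner = g.voxels_mni.min(axis=0)
    affine = np.diag([g.spacing_mm, g.spacing_mm, g.spacing_mm, 1.0])
    affine[:3, 3] = corner
    img = nib.Nifti1Image(np.nan_to_num(vol).astype(np.float32), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
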