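"""Readers and writers for the pipeline's on-disk formats.

TIFF images carry their physical pixel size (um/px) in ImageJ-style
resolution metadata; tables travel as plain CSV/TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import TissueImage, CellTable
from .meta2x2 import ContingencyTable2x2, StudyResult
from .gene_screen import ExpressionMatrix

__all__ = [
    "write_tissue_tiff", "read_tissue_tiff",
    "write_cells_csv", "read_cells_csv",
    "write_contingency_csv", "read_contingency_csv",
    "write_forest_csv",
    "write_expression_tsv", "read_expression_tsv",
]


def write_tissue_tiff(path: str | Path, img: TissueImage) -> None:
    """Write a TissueImage as a multi-channel TIFF with um/px resolution.

    Channels are stacked along the first axis; channel names and z_step go
    into the ImageJ metadata block.
    """
    arrs = [np.asarray(img.channels[k], dtype=np.float32) for k in img.channels]
    data = np.stack(arrs)  # (C, Y, X) or (C, Z, Y, X)
    ppu = 1.0 / img.pixel_size  # pixels per micrometre
    meta = {"unit": "um", "channel_names": list(img.channels)}
    if img.z_step is not None:
        meta["spacing"] = img.z_step
    tifffile.imwrite(path, data, resolution=(ppu, ppu),
                     metadata=meta, imagej=False,
                     photometric="minisblack")


def read_tissue_tiff(path: str | Path,
                     channel_names: list[str] | None = None,
                     pixel_size: float | None = None) -> TissueImage:
    """Read a TIFF written by write_tissue_tiff (or any TIFF given explicit
    channel names and pixel size)."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        if pixel_size is None:
            res = page.tags.get("XResolution")
            if res is None:
                raise ValueError("TIFF has no resolution tag; pass pixel_size")
            num, den = res.value
            pixel_size = den / num
        z_step = None
        names = channel_names
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            import json
            try:
                meta = json.loads(desc.value)
                names = names or meta.get("channel_names")
                z_step = meta.get("spacing")
            except (ValueError, TypeError):
                pass
    if data.ndim == 2:
        data = data[None]
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError("channel_names length does not match channel axis")
    return TissueImage(channels={n: data[i] for i, n in enumerate(names)},
                       pixel_size=float(pixel_size), z_step=z_step)


def write_cells_csv(path: str | Path, cells: CellTable) -> None:
    cells.to_dataframe().to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> CellTable:
    return CellTable.from_dataframe(pd.read_csv(path))


def write_contingency_csv(path: str | Path,
                          tables: list[ContingencyTable2x2]) -> None:
    pd.DataFrame([
        {"study_id": t.study_id, "exp_pos": t.a, "exp_neg": t.b,
         "unexp_pos": t.c, "unexp_neg": t.d}
        for t in tables
    ]).to_csv(path, index=False)


def read_contingency_csv(path: str | Path) -> list[ContingencyTable2x2]:
    df = pd.read_csv(path)
    return [
        ContingencyTable2x2(study_id=str(r.study_id), a=int(r.exp_pos),
                            b=int(r.exp_neg), c=int(r.unexp_pos),
                            d=int(r.unexp_neg))
        for r in df.itertuples()
    ]


def write_forest_csv(path: str | Path, results: list[StudyResult],
                     exclusions: list[StudyResult] | None = None) -> None:
    rows = [
        {"study_id": r.study_id, "or": r.or_point, "ci_low": r.ci_low,
         "ci_high": r.ci_high, "p": r.p_exact, "included": r.included,
         "reason": r.reason}
        for r in results + list(exclusions or [])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_expression_tsv(path: str | Path, expr: ExpressionMatrix) -> None:
    """Gene x sample TSV with a group header row above the data."""
    df = expr.values.copy()
    header = pd.DataFrame(
        [[expr.groups[s] for s in df.columns]], index=["__group__"],
        columns=df.columns,
    )
    pd.concat([header, df]).to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path,
                        gene_list: list[str] | None = None) -> ExpressionMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0)
    groups = raw.loc["__group__"]
    values = raw.drop(index="__group__").astype(float)
    return ExpressionMatrix(values=values, groups=groups,
                            gene_list=gene_list or list(values.index))
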