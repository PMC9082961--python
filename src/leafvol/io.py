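"""CSV and PNG schemas for specimens, weighing records and results.

All tables are plain UTF-8 CSV with a header row and '.' decimals.  Units:
lengths/thicknesses mm, volumes mm^3, areas mm^2, weights g, temperature
deg C; dpi is stored as an integer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthesis import LeafShapeParams, LeafSpecimen, ScanImage
from .volumetry import SGBRecord, SuspensionRecord

__all__ = [
    "specimens_to_frame",
    "specimens_from_frame",
    "suspension_records_to_frame",
    "suspension_records_from_frame",
    "sgb_records_to_frame",
    "sgb_records_from_frame",
    "write_scan_png",
    "read_scan_png",
]

_SHAPE_COLS = [
    "length_mm", "max_width_mm", "thickness_base_mm", "thickness_middle_mm",
    "thickness_tip_mm", "midrib_base_mm", "midrib_middle_mm", "midrib_tip_mm",
    "width_exponent", "width_mode", "is_complete_leaf",
]


def specimens_to_frame(specimens: list[LeafSpecimen]) -> pd.DataFrame:
    rows = []
    for s in specimens:
        row = {"specimen_id": s.specimen_id}
        row.update({c: getattr(s.shape, c) for c in _SHAPE_COLS})
        row["piece_x0"], row["piece_x1"] = s.piece_interval
        row["midrib_mismatch"] = s.midrib_mismatch
        rows.append(row)
    return pd.DataFrame(rows)


def specimens_from_frame(df: pd.DataFrame) -> list[LeafSpecimen]:
    specimens = []
    for _, row in df.iterrows():
        shape = LeafShapeParams(**{
            c: (str(row[c]) if c == "width_mode" else
                bool(row[c]) if c == "is_complete_leaf" else float(row[c]))
            for c in _SHAPE_COLS
        })
        specimens.append(LeafSpecimen(
            shape=shape,
            piece_interval=(float(row["piece_x0"]), float(row["piece_x1"])),
            specimen_id=str(row["specimen_id"]),
            midrib_mismatch=float(row.get("midrib_mismatch", 1.0)),
        ))
    return specimens


def suspension_records_to_frame(records: dict[str, list[SuspensionRecord]]
                                ) -> pd.DataFrame:
    rows = [
        {"specimen_id": sid, "replicate": r.replicate, "dw_r_g": r.dw_r,
         "dw_t_g": r.dw_t, "temp_c": r.temp_c}
        for sid, recs in records.items() for r in recs
    ]
    return pd.DataFrame(rows)


def suspension_records_from_frame(df: pd.DataFrame
                                  ) -> dict[str, list[SuspensionRecord]]:
    out: dict[str, list[SuspensionRecord]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["specimen_id"]), []).append(SuspensionRecord(
            dw_r=float(row["dw_r_g"]), dw_t=float(row["dw_t_g"]),
            temp_c=float(row["temp_c"]), replicate=int(row["replicate"])))
    return out


def sgb_records_to_frame(records: dict[str, list[SGBRecord]]) -> pd.DataFrame:
    rows = [
        {"specimen_id": sid, "replicate": r.replicate, "w_r1_g": r.w_r1,
         "w_l1_g": r.w_l1, "w_t2_g": r.w_t2,
         "w_r2_g": r.w_r2 if r.w_r2 is not None else np.nan,
         "temp_c": r.temp_c}
        for sid, recs in records.items() for r in recs
    ]
    return pd.DataFrame(rows)


def sgb_records_from_frame(df: pd.DataFrame) -> dict[str, list[SGBRecord]]:
    out: dict[str, list[SGBRecord]] = {}
    for _, row in df.iterrows():
        w_r2 = row.get("w_r2_g", np.nan)
        out.setdefault(str(row["specimen_id"]), []).append(SGBRecord(
            w_r1=float(row["w_r1_g"]), w_l1=float(row["w_l1_g"]),
            w_t2=float(row["w_t2_g"]), temp_c=float(row["temp_c"]),
            w_r2=None if pd.isna(w_r2) else float(w_r2),
            replicate=int(row["replicate"])))
    return out


def write_scan_png(img: ScanImage, path: str | Path) -> Path:
    """Write a scan as PNG with its dpi in the metadata and filename."""
    path = Path(path)
    if path.suffix != ".png":
        path = path.with_name(f"{path.name}_{int(img.dpi)}dpi.png")
    if img.rgb is not None:
        pil = Image.fromarray(img.rgb, mode="RGB")
    else:
        pil = Image.fromarray(
            np.where(img.mask, 0, 255).astype(np.uint8), mode="L")
    pil.save(path, dpi=(img.dpi, img.dpi))
    return path


def read_scan_png(path: str | Path, dpi: float | None = None,
                  specimen_id: str = "") -> ScanImage:
    """Read a PNG/TIFF scan; dpi from metadata unless overridden."""
    pil = Image.open(path)
    if dpi is None:
        meta = pil.info.get("dpi")
        if not meta:
            raise ValueError(f"{path}: no dpi metadata; pass dpi explicitly")
        dpi = float(meta[0])
    arr = np.asarray(pil)
    if arr.ndim == 3:
        mask = arr[..., :3].mean(axis=-1) < 128
        return ScanImage(mask=mask, dpi=dpi, specimen_id=specimen_id,
                         rgb=arr[..., :3])
    return ScanImage(mask=arr < 128, dpi=dpi, specimen_id=specimen_id)
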