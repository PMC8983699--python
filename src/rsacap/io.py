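"""File readers and writers for the pipeline's delimited-text formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .qcmd import Normalization, QCMDTrace
from .sem import ImageRecord

__all__ = [
    "read_qcmd_csv",
    "write_qcmd_csv",
    "read_image",
    "write_image",
    "read_standards_csv",
    "read_readings_csv",
    "write_json_report",
]

_QCMD_COLS = ["time_s"] + [f"f{n}" for n in (1, 3, 5, 7, 9, 11)] \
    + [f"D{n}" for n in (1, 3, 5, 7, 9, 11)]


def read_qcmd_csv(path, normalization: Normalization | str,
                  metadata: dict | None = None) -> QCMDTrace:
    """Read a QCM-D trace CSV (``time_s,f1,...,D11``; missing overtones ok).

    The frequency-shift convention is a required argument — files of
    unknown origin carry no reliable declaration.
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in _QCMD_COLS]
    if unknown:
        raise ValueError(f"unrecognized QCM-D columns: {unknown}")
    return QCMDTrace(data=df, normalization=Normalization(normalization),
                     metadata=metadata or {"source": str(path)})


def write_qcmd_csv(trace: QCMDTrace, path) -> None:
    trace.data.to_csv(path, index=False)


def read_image(path, nm_per_px: float) -> ImageRecord:
    """Read an 8-bit grayscale TIFF/PNG with its calibration."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        from PIL import Image

        px = np.asarray(Image.open(path).convert("L"))
    return ImageRecord(pixels=np.asarray(px, dtype=np.uint8),
                       nm_per_px=nm_per_px, provenance=str(path))


def write_image(record: ImageRecord, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, record.pixels)
    else:
        from PIL import Image

        Image.fromarray(record.pixels).save(path)


def read_standards_csv(path) -> pd.DataFrame:
    """Calibration standards: columns concentration_g_L, intensity."""
    df = pd.read_csv(path)
    need = {"concentration_g_L", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"standards CSV must have columns {sorted(need)}")
    return df


def read_readings_csv(path) -> pd.DataFrame:
    """Before/after readings: columns intensity_before, intensity_after."""
    df = pd.read_csv(path)
    need = {"intensity_before", "intensity_after"}
    if not need <= set(df.columns):
        raise ValueError(f"readings CSV must have columns {sorted(need)}")
    return df


def write_json_report(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
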