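"""Reading and writing masks, feature tables and score tables.

Image filenames follow ``<cell_line>__<well>__<quadrant>__t<hours>.<ext>``
(double underscore separated, e.g. ``B16__W1__Q3__t25.0.png``), which is
enough metadata to place every mask in the long-format feature table.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

FEATURE_COLUMNS = ["cell_line", "well", "quadrant", "time_h", "object", "value"]

_NAME_RE = re.compile(
    r"^(?P<cell_line>[^_]+(?:_[^_]+)*?)__(?P<well>[^_]+)__(?P<quadrant>[^_]+)__t(?P<time>[0-9.]+)$"
)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit single channel (0 background, 255 foreground)."""
    path = Path(path)
    img = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img)


def parse_image_name(path: str | Path) -> dict:
    """Extract (cell_line, well, quadrant, time_h) from a mask filename."""
    stem = Path(path).stem
    m = _NAME_RE.match(stem)
    if not m:
        raise ValueError(
            f"cannot parse {stem!r}: expected <cell_line>__<well>__<quadrant>__t<hours>")
    return {"cell_line": m["cell_line"], "well": m["well"],
            "quadrant": m["quadrant"], "time_h": float(m["time"])}


def image_name(cell_line: str, well: str, quadrant: str, time_h: float,
               ext: str = "png") -> str:
    return f"{cell_line}__{well}__{quadrant}__t{time_h:g}.{ext}"


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table[FEATURE_COLUMNS + [c for c in table.columns if c not in FEATURE_COLUMNS]]


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_windows(path: str | Path) -> dict[str, tuple[float, float]]:
    """Windows CSV with columns cell_line, t_l, t_u."""
    df = pd.read_csv(path)
    missing = {"cell_line", "t_l", "t_u"} - set(df.columns)
    if missing:
        raise ValueError(f"windows file missing columns: {sorted(missing)}")
    return {r.cell_line: (float(r.t_l), float(r.t_u)) for r in df.itertuples()}
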