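"""Format plumbing: multi-page TIFF images and schema-headed CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TiffReadError",
    "read_multichannel_tiff",
    "write_multichannel_tiff",
    "write_table",
    "read_table",
]


class TiffReadError(IOError):
    """The TIFF file is unreadable or its pages are inconsistent."""


def read_multichannel_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF as a (C, H, W) array (one page per channel).

    8/16-bit integer and float pages are accepted; a single-page file
    yields a 1-channel image. Ragged pages or a truncated file raise
    :class:`TiffReadError`.
    """
    try:
        pages = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises a zoo of exception types
        raise TiffReadError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise TiffReadError(f"{path}: expected 2D pages, got shape {arr.shape}")
    return arr


def write_multichannel_tiff(path, image: np.ndarray) -> None:
    """Write a (C, H, W) array as a multi-page TIFF, one page per channel."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W), got {arr.shape}")
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def write_table(df: pd.DataFrame, path, description: str = "") -> None:
    """Write a CSV with a one-line ``#`` schema header above the columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# columns: {', '.join(map(str, df.columns))}"
    if description:
        header += f" | {description}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips ``#`` lines)."""
    return pd.read_csv(path, comment="#")
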