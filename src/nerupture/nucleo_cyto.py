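"""Nuclear segmentation and nuclear/cytoplasmic intensity ratios.

The nucleus is segmented from the chromatin (DAPI) channel; a cytoplasmic
proxy is built per nucleus by expanding the nuclear object and subtracting
all nuclear pixels, yielding a ring of configurable depth (50 px default).
Per-nucleus, per-channel mean intensities over nucleus and ring give the
N/C ratio. Intensities are raw channel means — no background subtraction —
so the ratio is invariant under global intensity scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = ["segment_nuclei", "cytoplasmic_ring", "measure_nc_ratio"]


def segment_nuclei(
    chromatin_channel: np.ndarray,
    min_area: float = 200.0,
    max_area: float = 50_000.0,
    sigma: float = 2.0,
    split_touching: bool = True,
    exclude_border: bool = True,
) -> np.ndarray:
    """Label nuclear objects in the chromatin channel.

    Gaussian smoothing (``sigma``) + Otsu threshold + hole filling, with an
    optional watershed split of touching nuclei seeded on local maxima of
    the Euclidean distance transform. Objects outside [min_area, max_area]
    and, by default, objects touching the image border are removed.
    An all-zero (or constant) image yields an empty label map.
    """
    img = np.asarray(chromatin_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True)
    mask = smoothed > filters.threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)

    if split_touching:
        dist = ndimage.distance_transform_edt(mask)
        # seeds at distance maxima separated by at least a small-nucleus radius
        min_dist = max(int(np.sqrt(min_area / np.pi)), 3)
        seeds_xy = peak_local_max(dist, min_distance=min_dist, labels=mask)
        seeds = np.zeros(mask.shape, dtype=np.int32)
        seeds[tuple(seeds_xy.T)] = np.arange(1, len(seeds_xy) + 1)
        labels = segmentation.watershed(-dist, seeds, mask=mask)
    else:
        labels = cc_label(mask)

    if exclude_border:
        labels = segmentation.clear_border(labels)

    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


def cytoplasmic_ring(nuclei: np.ndarray, expansion: int = 50) -> np.ndarray:
    """Per-nucleus cytoplasmic ring by Euclidean expansion.

    Each nucleus is expanded by ``expansion`` pixels (Euclidean distance);
    the union of all nuclear pixels is then subtracted, so a ring never
    contains any nucleus. Pixels reachable from two nuclei go to the
    nearer one (ties to the lower label, the behaviour of
    :func:`skimage.segmentation.expand_labels`).
    """
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    expanded = segmentation.expand_labels(nuclei, distance=expansion)
    rings = expanded.copy()
    rings[nuclei > 0] = 0
    return rings


def measure_nc_ratio(
    image: np.ndarray,
    nuclei: np.ndarray,
    rings: np.ndarray,
    channel_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-nucleus, per-channel mean intensities and N/C ratios.

    ``image`` is (C, H, W) or (H, W). Returns one row per (nucleus,
    channel) with columns nucleus_id, area_px2, channel, mean_nuc,
    mean_cyto, nc_ratio, flagged. A record whose ring is empty or has zero
    mean is flagged and its ratio set to NaN; flagged records should be
    excluded from summaries.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if img.shape[1:] != nuclei.shape or nuclei.shape != rings.shape:
        raise ValueError("image and label maps must be aligned")
    names = channel_names or [f"ch{c}" for c in range(img.shape[0])]

    rows = []
    for nid in np.unique(nuclei[nuclei > 0]):
        nuc_mask = nuclei == nid
        ring_mask = rings == nid
        area = int(nuc_mask.sum())
        for ci, name in enumerate(names):
            mean_nuc = float(img[ci][nuc_mask].mean())
            if ring_mask.any():
                mean_cyto = float(img[ci][ring_mask].mean())
            else:
                mean_cyto = np.nan
            flagged = not np.isfinite(mean_cyto) or mean_cyto <= 0
            rows.append(
                {
                    "nucleus_id": int(nid),
                    "area_px2": area,
                    "channel": name,
                    "mean_nuc": mean_nuc,
                    "mean_cyto": mean_cyto,
                    "nc_ratio": mean_nuc / mean_cyto if not flagged else np.nan,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id", "area_px2", "channel",
            "mean_nuc", "mean_cyto", "nc_ratio", "flagged",
        ],
    )
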