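"""Top-level pipeline: chain the image stages over a directory of fields.

The runner consumes a :class:`RunConfig` (YAML/JSON on disk), applies
nuclear segmentation, N/C ratio measurement, bleb detection/scoring and
focus radial analysis to every multi-channel TIFF in the input directory,
and writes one CSV per stage plus a manifest recording the software
version, the config hash and per-stage record counts. Output is
deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blebs import UnusableFieldError, detect_blebs, enrichment_fraction, score_blebs
from .io import read_multichannel_tiff, write_table
from .nucleo_cyto import cytoplasmic_ring, measure_nc_ratio, segment_nuclei
from .pla import detect_foci, radial_fractions, radial_partition

logger = logging.getLogger("nerupture")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; every field is echoed into the manifest."""

    input_dir: str = "."
    output_dir: str = "results"
    channels: dict = field(
        default_factory=lambda: {"chromatin": 0, "laminb1": 1, "protein": 2}
    )
    condition: str = "default"
    seed: int = 0
    # segmentation
    min_nucleus_area: float = 200.0
    max_nucleus_area: float = 50_000.0
    smoothing_sigma: float = 2.0
    # N/C ratio
    ring_expansion: int = 50
    # blebs
    min_bleb_area: float = 20.0
    edge_margin: int = 2
    enrichment_threshold: float = 1.5
    # foci
    focus_channel: str | None = None
    shrink: float = 10.0
    min_focus_area: float = 4.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run all image stages over ``config.input_dir``; returns the output dir.

    Any stage failure aborts with the stage name and the offending input in
    the raised error's message. An empty input directory succeeds with
    empty tables and a warning.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiffs = sorted(Path(config.input_dir).glob("*.tif*"))
    if not tiffs:
        logger.warning("no TIFF inputs in %s", config.input_dir)

    nc_rows, bleb_rows, foci_rows, radial_rows = [], [], [], []
    for path in tiffs:
        try:
            image = read_multichannel_tiff(path)
            chrom_idx = config.channels["chromatin"]
            names = sorted(config.channels, key=config.channels.get)
            nuclei = segment_nuclei(
                image[chrom_idx],
                min_area=config.min_nucleus_area,
                max_area=config.max_nucleus_area,
                sigma=config.smoothing_sigma,
            )
        except Exception as exc:
            raise RuntimeError(f"stage=segment input={path.name}: {exc}") from exc

        try:
            rings = cytoplasmic_ring(nuclei, expansion=config.ring_expansion)
            nc = measure_nc_ratio(image, nuclei, rings, channel_names=names)
            nc.insert(0, "field", path.name)
            nc_rows.append(nc)
        except Exception as exc:
            raise RuntimeError(f"stage=nc_ratio input={path.name}: {exc}") from exc

        if "laminb1" in config.channels:
            try:
                blebs = detect_blebs(
                    nuclei,
                    image[config.channels["laminb1"]],
                    min_bleb_area=config.min_bleb_area,
                    edge_margin=config.edge_margin,
                )
                scored = score_blebs(image, blebs, nuclei, channel_names=names)
                scored.insert(0, "field", path.name)
                bleb_rows.append(scored)
            except UnusableFieldError as exc:
                logger.warning("field %s skipped for blebs: %s", path.name, exc)
            except Exception as exc:
                raise RuntimeError(f"stage=blebs input={path.name}: {exc}") from exc

        if config.focus_channel is not None:
            try:
                fchan = image[config.channels[config.focus_channel]]
                foci = detect_foci(fchan, nuclei, min_focus_area=config.min_focus_area)
                regions = radial_partition(nuclei, shrink=config.shrink)
                radial = radial_fractions(foci, regions, nuclei)
                foci.insert(0, "field", path.name)
                radial.insert(0, "field", path.name)
                foci_rows.append(foci)
                radial_rows.append(radial)
            except Exception as exc:
                raise RuntimeError(f"stage=foci input={path.name}: {exc}") from exc

    tables = {
        "nc_ratios": pd.concat(nc_rows, ignore_index=True) if nc_rows else pd.DataFrame(),
        "blebs": pd.concat(bleb_rows, ignore_index=True) if bleb_rows else pd.DataFrame(),
        "foci": pd.concat(foci_rows, ignore_index=True) if foci_rows else pd.DataFrame(),
        "radial": pd.concat(radial_rows, ignore_index=True) if radial_rows else pd.DataFrame(),
    }
    counts = {}
    for name, df in tables.items():
        write_table(df, out / f"{name}.csv")
        counts[name] = len(df)

    summary: dict = {"condition": config.condition}
    blebs_df = tables["blebs"]
    if len(blebs_df):
        enr_cols = [c for c in blebs_df.columns if c.startswith("enrichment_")]
        for col in enr_cols:
            vals = blebs_df[col].dropna()
            if len(vals):
                summary[f"fraction_{col}_gt_{config.enrichment_threshold}"] = (
                    enrichment_fraction(vals, config.enrichment_threshold)
                )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "n_fields": len(tiffs),
        "record_counts": counts,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
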