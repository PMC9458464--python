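"""Synthetic microscopy fields, rupture traces and ITC isotherms.

Every generator draws from a seeded :class:`numpy.random.Generator` and
returns, next to the rendered data, a :class:`GroundTruth` record of what was
drawn — object labels, true areas, true per-channel means, true event lists,
true binding parameters — so each downstream quantification stage can be
tested by parameter recovery with no external data.

Image geometry: nuclei are ellipses with a low-order Fourier boundary wobble
(real nuclei are not circles); blebs are disc protrusions straddling the
nucleus boundary. The chromatin channel covers nucleus ∪ blebs, the lamin-B1
channel covers the nucleus only (bleb pixels carry exactly zero lamin-B1
signal), and the protein channel multiplies the nuclear level by a
per-channel bleb enrichment. Noise is additive Gaussian, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .biophys import BindingParams, InjectionSchedule, ItcExperiment, itc_model_heats

__all__ = [
    "GenerationError",
    "GroundTruth",
    "SyntheticNucleusSpec",
    "SyntheticTraceSpec",
    "SyntheticFociSpec",
    "generate_nucleus_image",
    "generate_rupture_trace",
    "generate_foci_field",
    "generate_itc_experiment",
]

CHANNELS = ("chromatin", "laminb1", "protein")


class GenerationError(RuntimeError):
    """Objects could not be placed within the bounded number of retries."""


@dataclass
class GroundTruth:
    """What the generator actually drew; the oracle for every recovery test."""

    nuclei: pd.DataFrame = field(default_factory=pd.DataFrame)
    blebs: pd.DataFrame = field(default_factory=pd.DataFrame)
    foci: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: list = field(default_factory=list)
    binding: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass(frozen=True)
class SyntheticNucleusSpec:
    """Parameters of one rendered multi-channel field.

    Intensities are arbitrary units per channel in the order
    (chromatin, lamin-B1, protein). ``bleb_count_per_nucleus`` may be a
    fixed int or an inclusive (low, high) range sampled per nucleus.
    ``bleb_channel_enrichment`` multiplies the nuclear level on bleb pixels
    per channel (the lamin-B1 entry is ignored: bleb lamin-B1 is zero by
    construction); when ``bleb_enrichment_range`` is set, the protein-channel
    enrichment is instead drawn per bleb from that uniform range (recorded in
    the truth table). ``boundary_wobble`` is the relative amplitude of the
    low-order Fourier perturbation of the elliptical boundary.
    """

    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 5
    nucleus_axes: tuple[float, float] = (25.0, 40.0)
    nuclear_intensity: tuple[float, ...] = (200.0, 150.0, 180.0)
    cytoplasm_intensity: tuple[float, ...] = (20.0, 0.0, 90.0)
    bleb_count_per_nucleus: int | tuple[int, int] = 0
    bleb_area: tuple[float, float] = (80.0, 300.0)
    bleb_channel_enrichment: tuple[float, ...] = (1.0, 0.0, 2.0)
    bleb_enrichment_range: tuple[float, float] | None = None
    boundary_wobble: float = 0.04
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.nuclear_intensity + self.cytoplasm_intensity):
            raise ValueError("intensities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nucleus_axes[0] > self.nucleus_axes[1]:
            raise ValueError("nucleus_axes must be (min, max)")


def _bleb_count(spec: SyntheticNucleusSpec, rng: np.random.Generator) -> int:
    c = spec.bleb_count_per_nucleus
    if isinstance(c, tuple):
        return int(rng.integers(c[0], c[1] + 1))
    return int(c)


def _render_nucleus_mask(
    shape: tuple[int, int],
    center: np.ndarray,
    axes: tuple[float, float],
    theta: float,
    wobble_amp: np.ndarray,
    wobble_phase: np.ndarray,
) -> np.ndarray:
    """Rasterize one wobbled ellipse as a boolean mask."""
    h, w = shape
    a, b = axes
    r_max = int(np.ceil(max(a, b) * 1.6))
    y0, x0 = int(center[0]), int(center[1])
    ys = slice(max(0, y0 - r_max), min(h, y0 + r_max + 1))
    xs = slice(max(0, x0 - r_max), min(w, x0 + r_max + 1))
    yy, xx = np.mgrid[ys, xs]
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v / b, u / a)
    boundary = 1.0
    for k, (amp, ph) in enumerate(zip(wobble_amp, wobble_phase), start=2):
        boundary = boundary + amp * np.cos(k * phi + ph)
    mask = np.zeros(shape, dtype=bool)
    mask[ys, xs] = rho <= boundary
    return mask


def generate_nucleus_image(
    spec: SyntheticNucleusSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a 3-channel field of nuclei with optional blebs.

    Returns
    -------
    image : (3, H, W) float array
        Channels (chromatin, lamin-B1, protein).
    labels : (H, W) int array
        Truth label map of chromatin objects (nucleus ∪ its blebs), one
        label per nucleus, labelled 1..n.
    truth : GroundTruth
        Per-nucleus and per-bleb true areas and per-channel means measured
        on the truth masks of the noiseless rendering.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    bleb_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_only = np.zeros((h, w), dtype=np.int32)

    if len(spec.nuclear_intensity) != 3 or len(spec.cytoplasm_intensity) != 3:
        raise ValueError("intensities must have one entry per channel (3)")

    # margin keeps nuclei (and their blebs) off the border
    bleb_r_max = np.sqrt(2.0 * spec.bleb_area[1] / np.pi)
    margin = spec.nucleus_axes[1] * (1 + 3 * spec.boundary_wobble) + bleb_r_max + 3
    min_sep = 2 * margin + 4

    centers: list[np.ndarray] = []
    nuc_rows = []
    bleb_rows = []
    bleb_id = 0
    for nid in range(1, spec.n_nuclei + 1):
        placed = False
        for _ in range(200):
            c = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {nid} without overlap after 200 tries"
            )
        centers.append(c)
        axes = tuple(rng.uniform(*spec.nucleus_axes, size=2))
        theta = rng.uniform(0, np.pi)
        amps = rng.uniform(-spec.boundary_wobble, spec.boundary_wobble, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        nmask = _render_nucleus_mask((h, w), c, axes, theta, amps, phases)
        nmask &= labels == 0
        labels[nmask] = nid
        nucleus_only[nmask] = nid

        n_blebs = _bleb_count(spec, rng)
        for _ in range(n_blebs):
            for _ in range(50):
                area = rng.uniform(*spec.bleb_area)
                r = np.sqrt(2.0 * area / np.pi)  # half-disc protrudes
                ang = rng.uniform(0, 2 * np.pi)
                # walk outward from the centre to the boundary along ang
                direction = np.array([np.sin(ang), np.cos(ang)])
                t_vals = np.arange(0, margin, 0.5)
                pts = (c[None, :] + t_vals[:, None] * direction).astype(int)
                pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)]
                inside = nmask[pts[:, 0], pts[:, 1]]
                if not inside.any():
                    continue
                edge = pts[np.flatnonzero(inside)[-1]]
                yy, xx = np.mgrid[
                    max(0, edge[0] - int(r) - 1) : min(h, edge[0] + int(r) + 2),
                    max(0, edge[1] - int(r) - 1) : min(w, edge[1] + int(r) + 2),
                ]
                disc = (yy - edge[0]) ** 2 + (xx - edge[1]) ** 2 <= r * r
                cand = np.zeros((h, w), dtype=bool)
                cand[
                    max(0, edge[0] - int(r) - 1) : min(h, edge[0] + int(r) + 2),
                    max(0, edge[1] - int(r) - 1) : min(w, edge[1] + int(r) + 2),
                ] = disc
                cand &= labels == 0
                cand &= bleb_labels == 0
                if cand.sum() < 0.2 * area:
                    continue
                # keep blebs separated so each stays an individually
                # resolvable object with unambiguous ground truth
                near = ndimage.binary_dilation(cand, iterations=4)
                if (near & (bleb_labels > 0)).any():
                    continue
                bleb_id += 1
                bleb_labels[cand] = bleb_id
                labels[cand] = nid
                if spec.bleb_enrichment_range is not None:
                    enr = float(rng.uniform(*spec.bleb_enrichment_range))
                else:
                    enr = spec.bleb_channel_enrichment[2]
                bleb_rows.append(
                    {
                        "bleb_id": bleb_id,
                        "parent_nucleus": nid,
                        "area": int(cand.sum()),
                        "programmed_enrichment": enr,
                    }
                )
                break

    image = np.empty((3, h, w), dtype=float)
    nuc_mask = nucleus_only > 0
    bleb_mask = bleb_labels > 0
    for ci in range(3):
        chan = np.full((h, w), spec.cytoplasm_intensity[ci], dtype=float)
        chan[nuc_mask] = spec.nuclear_intensity[ci]
        if ci == 1:
            chan[bleb_mask] = 0.0  # blebs are devoid of lamin B1
        elif ci == 0:
            chan[bleb_mask] = spec.nuclear_intensity[ci]
        else:
            for row in bleb_rows:
                chan[bleb_labels == row["bleb_id"]] = (
                    spec.nuclear_intensity[ci] * row["programmed_enrichment"]
                )
        image[ci] = chan

    # truth measured on the noiseless rendering
    for nid in range(1, spec.n_nuclei + 1):
        m_nuc = nucleus_only == nid
        m_obj = labels == nid
        row = {
            "nucleus_id": nid,
            "centroid_y": centers[nid - 1][0],
            "centroid_x": centers[nid - 1][1],
            "area_nucleus": int(m_nuc.sum()),
            "area_chromatin": int(m_obj.sum()),
        }
        for ci, name in enumerate(CHANNELS):
            row[f"mean_nuc_{name}"] = float(image[ci][m_nuc].mean())
            row[f"mean_obj_{name}"] = float(image[ci][m_obj].mean())
        nuc_rows.append(row)
    for row in bleb_rows:
        m = bleb_labels == row["bleb_id"]
        rest = (nucleus_only == row["parent_nucleus"])
        for ci, name in enumerate(CHANNELS):
            row[f"mean_{name}"] = float(image[ci][m].mean())
            rest_mean = float(image[ci][rest].mean())
            row[f"enrichment_{name}"] = (
                row[f"mean_{name}"] / rest_mean if rest_mean > 0 else np.nan
            )

    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0, spec.noise_sd, image.shape), 0, None)

    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows),
        blebs=pd.DataFrame(bleb_rows),
    )
    truth.bleb_labels = bleb_labels  # type: ignore[attr-defined]
    truth.nucleus_labels = nucleus_only  # type: ignore[attr-defined]
    return image, labels, truth


# ---------------------------------------------------------------------------
# Rupture traces


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """One nuclear reporter-intensity time trace.

    ``events`` is a list of (onset_frame, fractional_loss, leak_tau_frames,
    recovery_tau_frames). The noiseless trace is background + baseline ×
    the product of per-event factors: each event decays exponentially from
    the pre-event level toward 1 − loss (instantaneous onset), then, once
    within 2% of the floor, recovers exponentially toward 1. ``noise_sd``
    is a fraction of baseline.
    """

    n_frames: int = 160
    frame_interval_min: float = 3.0
    baseline: float = 100.0
    background: float = 10.0
    events: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(not (0 < e[1] <= 1.0) for e in self.events):
            raise ValueError("fractional loss must be in (0, 1]")
        if onsets != sorted(onsets) or len(set(onsets)) != len(onsets):
            raise ValueError("event onsets must be strictly increasing")
        if any(o < 0 or o >= self.n_frames for o in onsets):
            raise ValueError("event onsets must lie within [0, n_frames)")


def _event_factor(
    t: np.ndarray, onset: int, loss: float, leak_tau: float, rec_tau: float
) -> np.ndarray:
    """Multiplicative trace factor of one leak/recovery event."""
    floor = 1.0 - loss
    # leak reaches within 2% of the floor after ~ln(50) leak time-constants
    leak_frames = int(np.ceil(leak_tau * np.log(50.0)))
    nadir = onset + leak_frames
    f = np.ones_like(t, dtype=float)
    leak_phase = (t >= onset) & (t < nadir)
    f[leak_phase] = floor + loss * np.exp(-(t[leak_phase] - onset) / leak_tau)
    at_nadir = floor + loss * np.exp(-leak_frames / leak_tau)
    rec_phase = t >= nadir
    f[rec_phase] = 1.0 - (1.0 - at_nadir) * np.exp(-(t[rec_phase] - nadir) / rec_tau)
    return f


def generate_rupture_trace(
    spec: SyntheticTraceSpec,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one trace; truth lists each event's onset, loss and taus.

    Overlapping events — the next onset arriving before the previous event
    has recovered half its loss — are rendered as programmed but flagged
    with a warning in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames)
    factor = np.ones(spec.n_frames, dtype=float)
    truth = GroundTruth()
    for onset, loss, leak_tau, rec_tau in spec.events:
        factor_e = _event_factor(t, int(onset), float(loss), float(leak_tau), float(rec_tau))
        if truth.events:
            prev = truth.events[-1]
            # recovered fraction of the previous event at this onset
            prev_f = _event_factor(
                np.array([onset]), prev["onset"], prev["loss"],
                prev["leak_tau"], prev["recovery_tau"],
            )[0]
            if prev_f < 1.0 - 0.5 * prev["loss"]:
                truth.warnings.append(
                    f"event at frame {onset} overlaps unrecovered event at "
                    f"frame {prev['onset']}"
                )
        factor *= factor_e
        truth.events.append(
            {
                "onset": int(onset),
                "loss": float(loss),
                "leak_tau": float(leak_tau),
                "recovery_tau": float(rec_tau),
                "major": loss > 0.30,
            }
        )
    trace = spec.background + spec.baseline * factor
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0, spec.noise_sd * spec.baseline, spec.n_frames)
    return trace, truth


# ---------------------------------------------------------------------------
# Nuclear foci


@dataclass(frozen=True)
class SyntheticFociSpec:
    """Foci scattered in a disc nucleus with a programmable radial profile.

    ``radial_density_profile`` gives relative densities (foci per unit
    area) for (outer ring 1, outer ring 2, centre), where the rings are
    successive ``shrink``-pixel deep shells from the boundary inward.
    """

    nucleus_radius: float = 60.0
    n_foci: int = 30
    radial_density_profile: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shrink: float = 10.0
    focus_radius: float = 2.0
    min_separation: float | None = None
    focus_intensity: float = 500.0
    nucleus_intensity: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.radial_density_profile
        if any(x < 0 for x in w) or sum(w) == 0:
            raise ValueError("radial weights must be >= 0 and not all zero")
        if self.nucleus_radius <= 2 * self.shrink:
            raise ValueError("nucleus radius must exceed twice the shrink depth")


def generate_foci_field(
    spec: SyntheticFociSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a focus channel over one disc nucleus.

    Regions are defined analytically on the continuous radius (distance
    from boundary d = R − r: ring1 d ≤ shrink, ring2 shrink < d ≤ 2·shrink,
    centre beyond), independent of any label-image morphology. Foci are
    drawn region-first (multinomial with probability ∝ weight × area) and
    placed uniformly inside their region with a minimum pairwise
    separation so that detections stay resolvable.

    Returns (focus image, nucleus label map, truth); truth.foci has one row
    per focus with centre coordinates and true region (1 = outermost ring).
    """
    rng = np.random.default_rng(spec.seed)
    r_nuc = spec.nucleus_radius
    size = int(np.ceil(2.5 * r_nuc))
    cy = cx = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy - cy, xx - cx)
    nucleus = (rr <= r_nuc).astype(np.int32)

    w = np.asarray(spec.radial_density_profile, dtype=float)
    radii = [  # (r_inner, r_outer) per region, outermost first
        (r_nuc - spec.shrink, r_nuc),
        (r_nuc - 2 * spec.shrink, r_nuc - spec.shrink),
        (0.0, r_nuc - 2 * spec.shrink),
    ]
    areas = np.array([np.pi * (ro**2 - ri**2) for ri, ro in radii])
    probs = w * areas
    probs = probs / probs.sum()
    counts = rng.multinomial(spec.n_foci, probs)

    min_sep = (
        spec.min_separation
        if spec.min_separation is not None
        else 2.0 * spec.focus_radius + 2.0
    )
    pts: list[tuple[float, float, int]] = []
    for region, ((ri, ro), k) in enumerate(zip(radii, counts), start=1):
        placed = 0
        for _ in range(500 * max(k, 1)):
            if placed == k:
                break
            # uniform in annulus: radius via inverse CDF, margin keeps the
            # rendered disc inside its region
            ri_eff = ri + (spec.focus_radius if ri > 0 else 0.0)
            ro_eff = ro - spec.focus_radius
            if ro_eff <= ri_eff:
                raise GenerationError("region too thin for the focus radius")
            u = rng.uniform(ri_eff**2, ro_eff**2)
            rad, ang = np.sqrt(u), rng.uniform(0, 2 * np.pi)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if all(np.hypot(y - p[0], x - p[1]) >= min_sep for p in pts):
                pts.append((y, x, region))
                placed += 1
        if placed < k:
            raise GenerationError(
                f"could not place {k} foci in region {region} without overlap"
            )

    image = np.where(nucleus > 0, spec.nucleus_intensity, 0.0)
    for y, x, _ in pts:
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= spec.focus_radius**2
        image[disc] = spec.focus_intensity
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0, spec.noise_sd, image.shape), 0, None)

    truth = GroundTruth(
        foci=pd.DataFrame(pts, columns=["y", "x", "region"]).assign(nucleus_id=1)
    )
    return image, nucleus, truth


# ---------------------------------------------------------------------------
# ITC isotherms


def generate_itc_experiment(
    params: BindingParams,
    schedule: InjectionSchedule,
    cell_concentration_M: float,
    syringe_concentration_M: float,
    noise_sd_ucal: float = 0.0,
    seed: int | None = None,
) -> tuple[ItcExperiment, GroundTruth]:
    """Simulate a titration: model heats plus Gaussian heat noise.

    ``noise_sd_ucal`` is an absolute per-injection heat SD in μcal (use
    e.g. 2% of the largest model heat for a realistic instrument noise
    floor). Truth stores the generating KD, ΔH and n.
    """
    heats = itc_model_heats(
        params, schedule, cell_concentration_M, syringe_concentration_M
    )
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0, noise_sd_ucal, len(heats))
    truth = GroundTruth(
        binding={
            "kd_M": params.kd_M,
            "dh_kcal": params.dh_kcal,
            "n": params.n,
            "temperature_K": params.temperature_K,
            "noise_sd_ucal": noise_sd_ucal,
        }
    )
    experiment = ItcExperiment(
        schedule=schedule,
        cell_concentration_M=cell_concentration_M,
        syringe_concentration_M=syringe_concentration_M,
        heats_ucal=heats,
    )
    return experiment, truth
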