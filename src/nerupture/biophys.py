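"""Binding thermodynamics and structural comparison.

Implements the single-set-of-sites isothermal titration calorimetry (ITC)
isotherm for a perfusion cell, a stoichiometry-constrained least-squares fit
returning KD / ΔH / ΔG / TΔS, per-residue NMR peak-intensity ratios with
neighbour interpolation of unassigned residues, and Cα RMSD by least-squares
rigid superposition (Kabsch) of two coordinate sets.

The binding model here treats the BAF dimer as the binding unit: one dimer
engages one lamin A/C Ig-fold domain, expressed as n = 0.5 sites per BAF
monomer in the cell. Concentrations are molar, heats are μcal, enthalpies
kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

__all__ = [
    "R_KCAL",
    "InjectionSchedule",
    "BindingParams",
    "ItcExperiment",
    "ThermoResult",
    "FitError",
    "itc_model_heats",
    "fit_itc",
    "kd_to_thermo",
    "nmr_intensity_ratios",
    "load_ca_coordinates",
    "kabsch_superpose",
    "kabsch_rmsd",
    "SuperpositionResult",
]


class FitError(RuntimeError):
    """Raised when the isotherm fit fails to converge from any start."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Injection programme of a perfusion-cell titration.

    Defaults follow the VP-ITC protocol used throughout: 29 injections of
    10 μl into a 1.4 ml cell, 180 s apart (spacing is informational only).
    """

    n_injections: int = 29
    injection_volume_ul: float = 10.0
    cell_volume_ul: float = 1400.0
    spacing_s: float = 180.0

    def __post_init__(self) -> None:
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if self.injection_volume_ul <= 0 or self.cell_volume_ul <= 0:
            raise ValueError("volumes must be positive")


@dataclass(frozen=True)
class BindingParams:
    """True or fitted single-site binding parameters.

    kd_M
        Dissociation constant, molar.
    dh_kcal
        Binding enthalpy, kcal per mole of injectant bound.
    n
        Sites per cell macromolecule; 0.5 encodes a dimeric injectant
        partner (one BAF dimer per Ig-fold domain, counted per monomer).
    temperature_K
        Experiment temperature (288 K for the reference titrations).
    """

    kd_M: float
    dh_kcal: float
    n: float = 0.5
    temperature_K: float = 288.0

    def __post_init__(self) -> None:
        if self.kd_M <= 0:
            raise ValueError("KD must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ItcExperiment:
    """One titration: schedule, concentrations and observed heats (μcal)."""

    schedule: InjectionSchedule
    cell_concentration_M: float
    syringe_concentration_M: float
    heats_ucal: np.ndarray

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.cell_concentration_M <= 0 or self.syringe_concentration_M <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.heats_ucal) != self.schedule.n_injections:
            raise ValueError(
                f"expected {self.schedule.n_injections} heats, "
                f"got {len(self.heats_ucal)}"
            )


@dataclass
class ThermoResult:
    """Fitted thermodynamic parameters.

    ΔG = R·T·ln(KD) and TΔS = ΔH − ΔG by construction. ``offset_ucal`` is
    the fitted constant per-injection dilution heat. ``c_value`` is the
    Wiseman parameter n·M0/KD; fits outside [0.01, 1000] are flagged as
    poorly constrained via ``c_warning``.
    """

    kd_M: float
    kd_se_M: float
    dh_kcal: float
    dh_se_kcal: float
    dg_kcal: float
    tds_kcal: float
    offset_ucal: float
    temperature_K: float
    c_value: float
    c_warning: bool
    n: float
    residual_rms_ucal: float


def _running_concentrations(
    schedule: InjectionSchedule,
    cell_concentration_M: float,
    syringe_concentration_M: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-macromolecule and titrant concentrations after each injection.

    Perfusion-cell dilution: each injection displaces v/V0 of the cell
    content, so M_t,i = M0·(1−v/V0)^i and X_t,i = Xsyr·[1−(1−v/V0)^i].
    """
    v = schedule.injection_volume_ul
    v0 = schedule.cell_volume_ul
    i = np.arange(1, schedule.n_injections + 1)
    dilution = (1.0 - v / v0) ** i
    m_t = cell_concentration_M * dilution
    x_t = syringe_concentration_M * (1.0 - dilution)
    return m_t, x_t


def itc_model_heats(
    params: BindingParams,
    schedule: InjectionSchedule,
    cell_concentration_M: float,
    syringe_concentration_M: float,
) -> np.ndarray:
    """Per-injection heats (μcal) of the single-set-of-sites isotherm.

    The cumulative heat after injection i follows the closed-form solution
    of the 1:n mass-action equilibrium in the (diluting) cell,

        Q_i = (n·M_t,i·ΔH·V0 / 2) · [1 + X/(nM) + KD/(nM)
              − sqrt((1 + X/(nM) + KD/(nM))² − 4·X/(nM))],

    and the observed heat of injection i corrects for the displaced volume:

        δQ_i = Q_i − Q_{i−1} + (v/V0)·(Q_i + Q_{i−1})/2.
    """
    if cell_concentration_M <= 0 or syringe_concentration_M <= 0:
        raise ValueError("concentrations must be positive")
    m_t, x_t = _running_concentrations(
        schedule, cell_concentration_M, syringe_concentration_M
    )
    n = params.n
    kd = params.kd_M
    sites = n * m_t
    a = 1.0 + x_t / sites + kd / sites
    disc = a * a - 4.0 * x_t / sites
    if np.any(disc < 0):
        raise ArithmeticError("negative discriminant in isotherm (invalid input)")
    v0_l = schedule.cell_volume_ul * 1e-6
    # cumulative heat in kcal, then μcal
    q = 0.5 * sites * params.dh_kcal * v0_l * (a - np.sqrt(disc)) * 1e9
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv_frac = schedule.injection_volume_ul / schedule.cell_volume_ul
    return q - q_prev + dv_frac * (q + q_prev) / 2.0


def fit_itc(
    experiment: ItcExperiment,
    fixed_n: float = 0.5,
    temperature_K: float = 288.0,
    fit_offset: bool = False,
) -> ThermoResult:
    """Least-squares fit of KD, ΔH and a dilution offset at fixed n.

    KD is fitted on a log10 scale; multi-start over KD decades 0.1–100 μM
    protects against the shallow-isotherm regime (low c-value) where a
    single start can stall. Standard errors come from the Gauss-Newton
    curvature at the optimum (delta method for KD).

    ``fit_offset=True`` adds a constant per-injection dilution-heat
    nuisance. It is off by default: in the shallow (low-c) regime the
    offset is nearly collinear with ΔH and inflates the KD variance
    several-fold, so it should be enabled only for real titrations with
    no blank to subtract.
    """
    heats = experiment.heats_ucal
    if np.count_nonzero(np.isfinite(heats)) < 5:
        raise FitError("need at least 5 informative injections")
    schedule = experiment.schedule
    m0 = experiment.cell_concentration_M
    xs = experiment.syringe_concentration_M

    moles_per_injection = xs * schedule.injection_volume_ul * 1e-6
    dh0 = heats[0] * 1e-9 / moles_per_injection  # assume first injection binds fully
    if not np.isfinite(dh0) or dh0 == 0.0:
        dh0 = -1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        log10_kd, dh, offset = theta
        params = BindingParams(
            kd_M=10.0**log10_kd, dh_kcal=dh, n=fixed_n, temperature_K=temperature_K
        )
        model = itc_model_heats(params, schedule, m0, xs)
        return model + offset - heats

    best = None
    for kd_start_uM in (0.1, 1.0, 10.0, 100.0):
        theta0 = np.array([math.log10(kd_start_uM * 1e-6), dh0, 0.0])
        try:
            sol = least_squares(
                residuals, theta0, method="trf",
                bounds=([-12.0, -1e4, -1e6], [0.0, 1e4, 1e6]),
                x_scale=[1.0, max(abs(dh0), 1.0), max(abs(heats).max(), 1.0)],
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("isotherm fit did not converge from any start")
    if not fit_offset:
        # refit with offset pinned at zero, keeping the best start
        def residuals_no_off(theta: np.ndarray) -> np.ndarray:
            return residuals(np.array([theta[0], theta[1], 0.0]))

        sol = least_squares(residuals_no_off, best.x[:2], method="trf")
        best = sol
        theta = np.array([sol.x[0], sol.x[1], 0.0])
    else:
        theta = best.x

    log10_kd, dh, offset = theta
    kd = 10.0**log10_kd
    dof = max(len(heats) - len(best.x), 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    kd_se = kd * math.log(10.0) * se[0]  # delta method for log10 scale
    dh_se = se[1]

    dg = kd_to_thermo(kd, temperature_K)
    c_value = fixed_n * m0 / kd
    return ThermoResult(
        kd_M=kd,
        kd_se_M=kd_se,
        dh_kcal=dh,
        dh_se_kcal=dh_se,
        dg_kcal=dg,
        tds_kcal=dh - dg,
        offset_ucal=offset,
        temperature_K=temperature_K,
        c_value=c_value,
        c_warning=not (0.01 <= c_value <= 1000.0),
        n=fixed_n,
        residual_rms_ucal=math.sqrt(2.0 * best.cost / len(heats)),
    )


def kd_to_thermo(
    kd_M: float, temperature_K: float, dh_kcal: float | None = None
):
    """ΔG = R·T·ln(KD) in kcal/mol; with ΔH also returns TΔS = ΔH − ΔG."""
    if kd_M <= 0 or temperature_K <= 0:
        raise ValueError("KD and temperature must be positive")
    dg = R_KCAL * temperature_K * math.log(kd_M)
    if dh_kcal is None:
        return dg
    return dg, dh_kcal - dg


# ---------------------------------------------------------------------------
# NMR intensity ratios


def nmr_intensity_ratios(
    residue_numbers: Sequence[int],
    volumes: Sequence[float],
    reference_volumes: Sequence[float],
    assigned: Sequence[bool] | None = None,
):
    """Per-residue I/I₀ peak-volume ratios with neighbour interpolation.

    For each assigned residue the ratio is volume / reference volume.
    Residues that could not be assigned in the bound-state spectrum are
    filled with the mean of the nearest preceding and following assigned
    ratios; unassigned residues at either terminus stay missing (flagged).

    Returns
    -------
    profile : pandas.DataFrame
        Columns ``residue``, ``ratio``, ``interpolated`` (bool),
        ``assigned`` (bool). Ratio is NaN where no neighbour pair exists.
    mean_retained_percent : float
        Mean ratio over assigned residues, as a percentage of the free
        reference signal.
    """
    import pandas as pd

    res = np.asarray(residue_numbers, dtype=int)
    vol = np.asarray(volumes, dtype=float)
    ref = np.asarray(reference_volumes, dtype=float)
    if assigned is None:
        assigned_arr = np.isfinite(vol)
    else:
        assigned_arr = np.asarray(assigned, dtype=bool)
    if len(res) != len(vol) or len(vol) != len(ref):
        raise ValueError("residue, volume and reference arrays must align")
    if np.any(ref[assigned_arr] <= 0):
        raise ValueError("reference volumes must be positive for assigned residues")

    order = np.argsort(res)
    res, vol, ref, assigned_arr = res[order], vol[order], ref[order], assigned_arr[order]

    ratio = np.full(len(res), np.nan)
    ratio[assigned_arr] = vol[assigned_arr] / ref[assigned_arr]
    interpolated = np.zeros(len(res), dtype=bool)

    assigned_idx = np.flatnonzero(assigned_arr)
    for i in np.flatnonzero(~assigned_arr):
        prev = assigned_idx[assigned_idx < i]
        nxt = assigned_idx[assigned_idx > i]
        if len(prev) and len(nxt):
            ratio[i] = 0.5 * (ratio[prev[-1]] + ratio[nxt[0]])
            interpolated[i] = True

    profile = pd.DataFrame(
        {
            "residue": res,
            "ratio": ratio,
            "interpolated": interpolated,
            "assigned": assigned_arr,
        }
    )
    mean_retained = float(np.mean(ratio[assigned_arr]) * 100.0) if assigned_arr.any() else float("nan")
    return profile, mean_retained


# ---------------------------------------------------------------------------
# Rigid superposition


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of B onto A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    keys: list = field(default_factory=list)


def load_ca_coordinates(path, chains: Sequence[str] | None = None) -> dict:
    """Read Cα positions from a PDB/mmCIF file, keyed by (chain, resnum).

    Alternate locations are resolved to the highest-occupancy conformer;
    waters and heteroatoms without a CA atom are skipped.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    coords: dict[tuple[str, int], np.ndarray] = {}
    model = structure[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            cas = [a for a in residue if a.name == "CA"]
            if not cas:
                continue
            ca = max(cas, key=lambda a: a.occ)
            coords[(chain.name, residue.seqid.num)] = np.array(
                [ca.pos.x, ca.pos.y, ca.pos.z]
            )
    return coords


def kabsch_superpose(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``b`` onto ``a``.

    Returns (rotation, translation, rmsd) such that ``b @ R.T + t`` best
    matches ``a``. A proper rotation (det = +1) is enforced by flipping the
    smallest singular direction when the raw solution is a reflection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected two equal-shaped (N, 3) arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


def kabsch_rmsd(
    coords_a: Mapping,
    coords_b: Mapping,
    chain_map: Mapping[str, str] | None = None,
) -> SuperpositionResult:
    """Cα RMSD between two labelled coordinate sets.

    Atoms are paired on the intersection of (chain, residue-number) keys
    after applying ``chain_map`` (maps chains of B onto chains of A).
    """
    if chain_map:
        coords_b = {
            (chain_map.get(chain, chain), num): xyz
            for (chain, num), xyz in coords_b.items()
        }
    keys = sorted(set(coords_a) & set(coords_b))
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} paired atoms; need >= 3")
    a = np.array([coords_a[k] for k in keys])
    b = np.array([coords_b[k] for k in keys])
    rot, trans, rmsd = kabsch_superpose(a, b)
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd=rmsd, n_pairs=len(keys), keys=keys
    )
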