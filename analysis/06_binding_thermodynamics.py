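#!/usr/bin/env python
"""Binding thermodynamics: ITC fits, NMR intensity ratios, Cα RMSD.

Fits the duplicate simulated titrations of both geometries with the
stoichiometry held at n = 0.5 (one BAF dimer per lamin A/C Ig-fold
domain) and reports mean KD with the thermodynamic decomposition at
288 K. Demonstrates the per-residue NMR I/I₀ pipeline, including
neighbour interpolation of unassigned residues, on a simulated bound-state
profile, and the Cα-RMSD superposition on a synthetic coordinate pair
(a stand-in structure perturbed by ~0.4 Å coordinate noise — the deposited
experimental structures are not bundled). Writes results/itc_fits.csv and
results/nmr_profile.csv.

Run after 01_simulate_inputs.py.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nerupture.biophys import (
    InjectionSchedule,
    ItcExperiment,
    fit_itc,
    kabsch_rmsd,
    nmr_intensity_ratios,
)
from nerupture.io import read_table, write_table

IN = Path("results/synthetic")


def fit_titrations():
    geometries = json.loads((IN / "itc_geometries.json").read_text())
    rows = []
    for name, geom in geometries.items():
        kds = []
        for rep in (1, 2):
            heats = read_table(IN / f"itc_{name}_rep{rep}.csv").heat_ucal
            experiment = ItcExperiment(
                schedule=InjectionSchedule(),
                cell_concentration_M=geom["cell_uM"] * 1e-6,
                syringe_concentration_M=geom["syringe_uM"] * 1e-6,
                heats_ucal=heats.to_numpy(),
            )
            res = fit_itc(experiment, fixed_n=0.5)
            kds.append(res.kd_M * 1e6)
            rows.append({
                "geometry": name, "replicate": rep,
                "kd_uM": res.kd_M * 1e6, "kd_se_uM": res.kd_se_M * 1e6,
                "dh_kcal": res.dh_kcal, "dg_kcal": res.dg_kcal,
                "tds_kcal": res.tds_kcal, "c_value": res.c_value,
            })
        print(f"{name.upper():5s} mean KD = {np.mean(kds):.1f} uM "
              f"(replicates {kds[0]:.1f}, {kds[1]:.1f}; "
              f"true {geom['kd_uM']} uM)")
    table = pd.DataFrame(rows)
    write_table(table, "results/itc_fits.csv")
    fold = (table[table.geometry == "a12t"].kd_uM.mean()
            / table[table.geometry == "wt"].kd_uM.mean())
    print(f"affinity ratio (mutant/wild-type): {fold:.1f}-fold weaker")


def nmr_profile():
    # simulate a bound-state spectrum in which 70% of residues broaden
    # beyond detection and the remainder retain ~27% of the free-state
    # signal; a few residues are unassignable and get interpolated
    rng = np.random.default_rng(7)
    n = 80
    residues = np.arange(401, 401 + n)
    reference = rng.uniform(0.8, 1.2, n)
    retained = rng.uniform(0.05, 0.49, n)  # mean 0.27 by construction
    assigned = rng.uniform(size=n) > 0.15
    volumes = np.where(assigned, retained * reference, np.nan)
    profile, mean_pct = nmr_intensity_ratios(residues, volumes, reference,
                                             assigned=assigned)
    write_table(profile, "results/nmr_profile.csv")
    n_interp = int(profile.interpolated.sum())
    print(f"NMR: {assigned.sum()} assigned residues, {n_interp} interpolated; "
          f"mean retained signal {mean_pct:.0f}% of the free reference")


def rmsd_demo():
    # synthetic stand-in: a folded-like Cα trace and the same trace with
    # small coordinate noise, superposed after a random rigid transform
    rng = np.random.default_rng(11)
    t = np.linspace(0, 6 * np.pi, 150)
    ca = np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t]
    a = {("A", i + 1): p for i, p in enumerate(ca)}
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    perturbed = ca + rng.normal(0, 0.4 / np.sqrt(3), ca.shape)
    b = {("A", i + 1): p @ rot.T + 15.0 for i, p in enumerate(perturbed)}
    res = kabsch_rmsd(a, b)
    print(f"Calpha RMSD on the synthetic stand-in pair: {res.rmsd:.2f} A "
          f"over {res.n_pairs} atoms (0.40 A coordinate noise injected)")


def main():
    fit_titrations()
    nmr_profile()
    rmsd_demo()


if __name__ == "__main__":
    main()
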