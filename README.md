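# nerupture

Quantification of nuclear-envelope (NE) rupture phenotypes and BAF–lamin A/C
binding thermodynamics, for cell biologists studying laminopathies and
progeroid syndromes (e.g. Néstor–Guillermo progeria, caused by the BAF A12T
substitution). The package turns raw multi-channel microscopy, live-cell
reporter traces, calorimetry series and coordinate files into the numbers
such a study reports — and ships a seeded synthetic-data generator that
renders all of those inputs with known ground truth, so every stage is
testable by parameter recovery without any experimental data.

## What it computes

**Image quantification** (`nucleo_cyto`, `blebs`, `pla`)

- *N/C ratio*: nuclei segmented from the DAPI/chromatin channel; the
  cytoplasmic proxy is the ring obtained by expanding each nuclear mask by
  50 px (Euclidean) and subtracting all nuclear pixels. N/C = mean nuclear /
  mean ring intensity per channel.
- *Bleb detection*: blebs are chromatin regions devoid of lamin B1 —
  per nucleus, the chromatin object minus the lamin-B1 object, cleaned by a
  2-px opening (edge artefacts) and a 20-px² area filter. Per-bleb protein
  enrichment = bleb mean / rest-of-nucleus mean, and the summary fraction of
  blebs with enrichment > 1.5 is reported.
- *Focus radial analysis*: foci (e.g. proximity-ligation signals) detected
  inside nuclei by per-nucleus thresholding; each nucleus partitioned into
  two successive 10-px peripheral shells (ring1, ring2) and the centre;
  per-region density fractions = (count/area) normalized to sum to 1.

**Rupture kinetics** (`rupture`): reporter traces (NLS-GFP mean nuclear
intensity) are background-subtracted and normalized to the 5 frames before
rupture; events are drops ≥ 0.05 below the rolling baseline, classified
*major* when the fractional loss exceeds 0.30; major-event recoveries are
aligned at onset (mean ± SD); re-rupture intervals (major → next event of
any class, given ≥ 30 frames of follow-up) are binned to 15 min with a
\>90 min overflow bin and conditions compared by a two-sided Fisher exact
test on the (>90 min vs ≤90 min) table.

**Binding thermodynamics** (`biophys`): the single-set-of-sites isotherm
for a perfusion calorimeter cell,

```
Q_i = (n·M_i·ΔH·V0/2) · [1 + X_i/(nM_i) + K_D/(nM_i)
      − sqrt((1 + X_i/(nM_i) + K_D/(nM_i))² − 4·X_i/(nM_i))]
δQ_i = Q_i − Q_{i−1} + (v/V0)·(Q_i + Q_{i−1})/2
```

fitted by least squares with the stoichiometry fixed at n = 0.5 (one BAF
dimer per lamin A/C Ig-fold domain), returning K_D, ΔH, ΔG = RT·ln K_D and
TΔS = ΔH − ΔG at 288 K. Also: per-residue NMR I/I₀ peak-volume ratios with
neighbour interpolation of unassigned residues, and Cα RMSD by Kabsch
rigid superposition of two labelled coordinate sets (PDB input via gemmi).

## Worked example

```python
import numpy as np
from nerupture import synthetic, biophys

params = biophys.BindingParams(kd_M=33e-6, dh_kcal=-5.0, n=0.5)
schedule = biophys.InjectionSchedule()          # 29 x 10 ul, 1.4 ml cell
clean = biophys.itc_model_heats(params, schedule, 40e-6, 200e-6)
exp, truth = synthetic.generate_itc_experiment(
    params, schedule, 40e-6, 200e-6,
    noise_sd_ucal=0.02 * np.abs(clean).max(), seed=42)
res = biophys.fit_itc(exp, fixed_n=0.5)
print(f"KD = {res.kd_M*1e6:.1f} uM, dH = {res.dh_kcal:.2f} kcal/mol, "
      f"dG = {res.dg_kcal:.2f}, TdS = {res.tds_kcal:.2f} kcal/mol")
```

prints

```
KD = 31.8 uM, dH = -4.91 kcal/mol, dG = -5.93, TdS = 1.01 kcal/mol
```

i.e. from a 29-injection isotherm simulated at the mutant titration
geometry (200 μM Ig-fold into 40 μM BAF A12T, true K_D 33 μM) with 2% heat
noise, the constrained fit recovers the dissociation constant within a few
percent; ΔG and TΔS follow from K_D and ΔH at 288 K.

## Analysis scripts

The study-style analyses live under `analysis/` as numbered drivers that
generate synthetic inputs and run every quantification, writing tables to
`results/`:

```
python analysis/01_simulate_inputs.py      # fields, traces, isotherms + truth
python analysis/02_nc_ratios.py            # N/C ratios per condition
python analysis/03_bleb_enrichment.py      # blebs, enrichment > 1.5 fraction
python analysis/04_pla_radial.py           # foci counts + radial fractions
python analysis/05_rupture_kinetics.py     # events, recovery, Fisher test
python analysis/06_binding_thermodynamics.py  # ITC fits, NMR ratios, RMSD
```

A `nerupture` CLI exposes the same stages for use on real TIFF/CSV/PDB
inputs (`nerupture --help`).

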