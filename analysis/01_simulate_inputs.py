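#!/usr/bin/env python
"""Simulate the study's raw inputs with known ground truth.

Renders multi-channel fields for two imaging conditions (a control-like
condition with nuclear protein enrichment and blebs carrying variable
protein accumulation, and a patient-like condition with reduced nuclear
enrichment), reporter time traces for two rupture-frequency conditions,
and duplicate ITC isotherms at both titration geometries. Everything is
written under results/synthetic/ together with the truth tables that the
downstream steps are judged against.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nerupture import synthetic
from nerupture.biophys import BindingParams, InjectionSchedule, itc_model_heats
from nerupture.io import write_multichannel_tiff, write_table

OUT = Path("results/synthetic")
SEED = 2026

# imaging conditions: nuclear/cytoplasmic protein contrast per condition
CONDITIONS = {
    "control": dict(nuclear=200.0, cytoplasm=100.0),  # N/C 2.0
    "patient": dict(nuclear=120.0, cytoplasm=120.0),  # N/C 1.0
}

# rupture conditions: (n traces, mean events per trace, re-rupture gap in
# frames). Patient-like nuclei re-rupture quickly after a major event
# (gaps well inside 90 min at 3 min/frame); control nuclei rarely do.
TRACE_CONDITIONS = {
    "control": (40, 1.3, (34, 46)),
    "patient": (40, 2.6, (19, 30)),
}

ITC_GEOMETRIES = {
    "wt": dict(kd_uM=2.7, cell_uM=20.0, syringe_uM=100.0),
    "a12t": dict(kd_uM=33.0, cell_uM=40.0, syringe_uM=200.0),
}


def simulate_fields(rng):
    for condition, levels in CONDITIONS.items():
        cond_dir = OUT / "fields" / condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        truth_rows, bleb_rows = [], []
        for k in range(4):
            spec = synthetic.SyntheticNucleusSpec(
                image_size=(512, 512),
                n_nuclei=4,
                nucleus_axes=(22.0, 32.0),
                nuclear_intensity=(200.0, 150.0, levels["nuclear"]),
                cytoplasm_intensity=(20.0, 0.0, levels["cytoplasm"]),
                bleb_count_per_nucleus=(0, 2),
                bleb_area=(80.0, 250.0),
                bleb_enrichment_range=(0.5, 3.0),
                noise_sd=5.0,
                seed=int(rng.integers(2**31)),
            )
            image, labels, truth = synthetic.generate_nucleus_image(spec)
            write_multichannel_tiff(cond_dir / f"field_{k:02d}.tif", image)
            truth.nuclei["field"] = f"field_{k:02d}"
            truth_rows.append(truth.nuclei)
            if len(truth.blebs):
                truth.blebs["field"] = f"field_{k:02d}"
                bleb_rows.append(truth.blebs)
        write_table(pd.concat(truth_rows), cond_dir / "truth_nuclei.csv")
        if bleb_rows:
            write_table(pd.concat(bleb_rows), cond_dir / "truth_blebs.csv")
        print(f"fields[{condition}]: 4 fields, "
              f"{sum(len(t) for t in truth_rows)} nuclei, "
              f"{sum(len(b) for b in bleb_rows)} blebs")


def simulate_foci(rng):
    rows, truth_rows = [], []
    foci_dir = OUT / "foci"
    foci_dir.mkdir(parents=True, exist_ok=True)
    for k in range(10):  # ten nuclei, peripherally biased foci
        spec = synthetic.SyntheticFociSpec(
            nucleus_radius=70.0,
            n_foci=int(rng.integers(8, 20)),
            radial_density_profile=(3.0, 1.5, 1.0),
            seed=int(rng.integers(2**31)),
        )
        image, nucleus, truth = synthetic.generate_foci_field(spec)
        write_multichannel_tiff(foci_dir / f"nucleus_{k:02d}.tif",
                                np.stack([nucleus * 120.0, image]))
        truth.foci["nucleus_file"] = f"nucleus_{k:02d}"
        truth_rows.append(truth.foci)
    write_table(pd.concat(truth_rows), foci_dir / "truth_foci.csv")
    print(f"foci: 10 nuclei, {sum(len(t) for t in truth_rows)} foci")


def simulate_traces(rng):
    for condition, (n_traces, mean_events, gap_frames) in TRACE_CONDITIONS.items():
        rows, truth_rows = [], []
        for nid in range(n_traces):
            n_events = min(rng.poisson(mean_events), 4)
            onsets = []
            t = int(rng.integers(20, 60))
            for _ in range(n_events):
                if t >= 145:
                    break
                onsets.append(t)
                t += int(rng.integers(*gap_frames))
            events = tuple(
                (int(o), float(rng.uniform(0.15, 0.7)), 1.0,
                 float(rng.uniform(3.0, 7.0)))
                for o in onsets
            )
            spec = synthetic.SyntheticTraceSpec(
                n_frames=160, frame_interval_min=3.0, events=events,
                noise_sd=0.02, seed=int(rng.integers(2**31)),
            )
            trace, truth = synthetic.generate_rupture_trace(spec)
            rows.extend(
                {"nucleus_id": nid, "frame": f, "raw": v,
                 "background": spec.background}
                for f, v in enumerate(trace)
            )
            truth_rows.extend({"nucleus_id": nid, **ev} for ev in truth.events)
        write_table(pd.DataFrame(rows), OUT / f"traces_{condition}.csv")
        write_table(pd.DataFrame(truth_rows), OUT / f"traces_{condition}.truth.csv")
        print(f"traces[{condition}]: {n_traces} traces, "
              f"{len(truth_rows)} programmed events")


def simulate_itc(rng):
    for name, geom in ITC_GEOMETRIES.items():
        params = BindingParams(kd_M=geom["kd_uM"] * 1e-6, dh_kcal=-5.0, n=0.5)
        schedule = InjectionSchedule()
        clean = itc_model_heats(params, schedule, geom["cell_uM"] * 1e-6,
                                geom["syringe_uM"] * 1e-6)
        for rep in (1, 2):  # each titration performed twice
            experiment, _ = synthetic.generate_itc_experiment(
                params, schedule, geom["cell_uM"] * 1e-6,
                geom["syringe_uM"] * 1e-6,
                noise_sd_ucal=0.02 * np.abs(clean).max(),
                seed=int(rng.integers(2**31)),
            )
            df = pd.DataFrame({
                "injection_index": np.arange(1, 30),
                "heat_ucal": experiment.heats_ucal,
            })
            write_table(df, OUT / f"itc_{name}_rep{rep}.csv",
                        description=f"true KD {geom['kd_uM']} uM")
        print(f"itc[{name}]: 2 x 29 injections at true KD {geom['kd_uM']} uM")
    (OUT / "itc_geometries.json").write_text(json.dumps(ITC_GEOMETRIES, indent=2))


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    simulate_fields(rng)
    simulate_foci(rng)
    simulate_traces(rng)
    simulate_itc(rng)
    print(f"all synthetic inputs written under {OUT}/")


if __name__ == "__main__":
    main()
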