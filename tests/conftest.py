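"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from nerupture import rupture, synthetic


# ---------------------------------------------------------------------------
# Independent oracles


def fisher_two_sided_oracle(table) -> Fraction:
    """Exact two-sided Fisher p by enumeration of all same-margin tables.

    Works entirely in rational arithmetic (binomial coefficients), so tie
    comparison with the observed table's probability is exact.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, aa) * comb(r2, c1 - aa), denom)
        if p <= p_obs:
            total += p
    return total


def itc_equilibrium_heats_oracle(params, schedule, cell_M, syringe_M):
    """Per-injection heats from a numerical mass-action solver.

    Independently of the closed-form isotherm: for every injection the
    bound-complex concentration solves (S − C)(X − C)/C = KD by bisection,
    with S = n·M_t and X = X_t the running (diluted) totals; the heat is
    the increment of complex·ΔH·V0 with the same displaced-volume
    correction. Agreement validates the closed form.
    """
    from scipy.optimize import brentq

    v = schedule.injection_volume_ul
    v0 = schedule.cell_volume_ul
    v0_l = v0 * 1e-6
    qs = []
    for i in range(1, schedule.n_injections + 1):
        dil = (1.0 - v / v0) ** i
        m_t = cell_M * dil
        x_t = syringe_M * (1.0 - dil)
        s = params.n * m_t
        if x_t == 0:
            c_bound = 0.0
        else:
            f = lambda c: (s - c) * (x_t - c) / c - params.kd_M
            c_bound = brentq(f, 1e-30, min(s, x_t) * (1 - 1e-15),
                             xtol=1e-30, rtol=8.9e-16)
        qs.append(c_bound * params.dh_kcal * v0_l * 1e9)  # μcal
    qs = np.asarray(qs)
    q_prev = np.concatenate(([0.0], qs[:-1]))
    return qs - q_prev + (v / v0) * (qs + q_prev) / 2.0


def brute_force_rmsd_oracle(a, b) -> float:
    """Minimum RMSD by numerical optimization over rotation vectors."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)

    def cost(rv):
        moved = Rotation.from_rotvec(rv).apply(b)
        return np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1)))

    best = np.inf
    for rv0 in [np.zeros(3), [3, 0, 0], [0, 3, 0], [0, 0, 3], [1.5, 1.5, 1.5]]:
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return best


# ---------------------------------------------------------------------------
# Shared synthetic inputs


@pytest.fixture(scope="session")
def noiseless_field():
    """3 separated, bleb-free nuclei rendered without noise."""
    spec = synthetic.SyntheticNucleusSpec(
        n_nuclei=3,
        nuclear_intensity=(200.0, 150.0, 200.0),
        cytoplasm_intensity=(20.0, 0.0, 100.0),
        noise_sd=0.0,
        seed=11,
    )
    image, labels, truth = synthetic.generate_nucleus_image(spec)
    return spec, image, labels, truth


@pytest.fixture(scope="session")
def bleb_field():
    """One nucleus per small field, two blebs each, across 100 fields (5% noise)."""
    fields = []
    for k in range(100):
        spec = synthetic.SyntheticNucleusSpec(
            image_size=(200, 200),
            n_nuclei=1,
            nucleus_axes=(22, 30),
            nuclear_intensity=(200.0, 150.0, 100.0),
            cytoplasm_intensity=(10.0, 0.0, 20.0),
            bleb_count_per_nucleus=2,
            bleb_area=(80.0, 200.0),
            bleb_enrichment_range=(0.5, 3.0),
            noise_sd=5.0,
            seed=1000 + k,
        )
        fields.append(synthetic.generate_nucleus_image(spec))
    return fields


def classifier_performance(n_traces: int, seed: int, noise_sd: float = 0.02,
                           loss_range=(0.15, 0.7)):
    """Event-level sensitivity/precision of the rupture detector.

    Each trace carries one programmed event; a detection within 5 frames of
    the true onset is a true positive, anything else a false positive.
    """
    rng = np.random.default_rng(seed)
    tp = fp = fn = 0
    for _ in range(n_traces):
        onset = int(rng.integers(20, 100))
        loss = float(rng.uniform(*loss_range))
        spec = synthetic.SyntheticTraceSpec(
            n_frames=160,
            events=((onset, loss, 1.0, 10.0),),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        trace, _ = synthetic.generate_rupture_trace(spec)
        pre = rupture.preprocess_trace(trace, spec.background)
        events = rupture.detect_ruptures(pre.normalized)
        matched = [e for e in events if abs(e.onset_frame - onset) <= 5]
        tp += min(len(matched), 1)
        fn += 1 - min(len(matched), 1)
        fp += len(events) - min(len(matched), 1)
    return tp / (tp + fn), tp / (tp + fp)
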