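# Methods

This note documents the models and procedures implemented in `nerupture`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Image quantification

### Nuclear segmentation

Nuclei are segmented from the chromatin (DAPI) channel by Gaussian
smoothing (σ = 2 px default) → Otsu threshold → hole filling → optional
watershed split of touching nuclei seeded on Euclidean-distance-transform
maxima. Objects outside a configurable area window (200–50 000 px²
default) are removed, as are objects touching the image border: a
border-clipped nucleus has a biased area and an incomplete cytoplasmic
ring, so excluding it is the safer default (it is a flag, not a law). An
all-zero or constant image yields an empty label map rather than an error.

### N/C ratio

The cytoplasmic compartment is approximated by a ring: each nuclear mask
expanded by 50 px (Euclidean disc semantics, via nearest-label expansion)
minus the union of all nuclear pixels, contested pixels going to the
nearer nucleus (ties to the lower label). Channel means are measured raw —
no background subtraction — because the ratio of two means from the same
image is invariant under any global gain and offset-free background would
have to be estimated anyway; traces, where background matters physically,
handle it explicitly. Records whose ring is empty or has non-positive mean
are flagged and excluded from summaries.

### Bleb detection and enrichment

The bleb candidate mask is chromatin-object minus lamin-B1-object. The
lamin-B1 object is an Otsu threshold restricted to a 10-px dilation of the
chromatin objects (so that empty background does not dominate the
histogram), hole-filled. Two filters follow, both config-exposed because
only their existence, not their values, is dictated by the measurement
principle: a morphological opening with a 2-px disc removes the thin rim
left by chromatin/lamin misregistration along the whole nuclear edge, and
candidates below 20 px² are discarded. Each surviving bleb is assigned to
the chromatin object containing it.

Per-bleb enrichment is the bleb mean divided by the mean of the rest of
the parent chromatin object. The reference region additionally excludes a
3-px dilation of all detected blebs: segmentation places the bleb boundary
only to within a pixel or two, and rim pixels that actually belong to a
strongly enriched (or depleted) bleb would otherwise contaminate the
reference mean — with typical geometries this contamination alone shifts
recovered enrichments by ~0.1. Normalized intensity divides the bleb mean
by a caller-supplied per-channel reference; the intended reference is the
mean nucleoplasmic intensity of the control condition of the same batch,
which keeps values comparable across conditions. The summary statistic is
the fraction of blebs with enrichment strictly above 1.5.

### Focus radial analysis

Foci are connected supra-threshold components inside a nucleus, using a
per-nucleus Otsu threshold (per-nucleus because focus density and
background vary between nuclei) and a 4-px² minimum area to suppress
single-pixel noise. Each component is reduced to its intensity-weighted
centroid; two foci whose discs merge count once — a stated limitation of
connectivity-based counting. A constant-positive (saturated) nucleus makes
the threshold degenerate and raises a flagged error; a constant-zero
nucleus simply has no foci.

The radial partition interprets "shrinking the nucleus by 10 pixels" as
Euclidean erosion depth applied twice: with d the distance transform of
the nucleus mask, ring1 is 0 < d ≤ 10, ring2 is 10 < d ≤ 20, centre is
d > 20. The three regions tile the nucleus exactly for every shape; a
small nucleus simply has an empty centre (and possibly ring2). A focus
belongs to the region containing its centroid, which is unambiguous for
foci straddling boundaries. Densities are count/area; density fractions
normalize densities over the regions with non-zero area. The shell depth
is a parameter — whether the original two rings were each 10 px deep or
jointly 10 px is ambiguous, and both readings are reachable by setting
`shrink`.

## Rupture kinetics

### Preprocessing

Traces are background-subtracted (scalar ROI value, per-frame series, or —
when nothing is supplied — the caller can use the 5th percentile of the
full field per frame) and normalized to the mean of the 5 frames
immediately preceding the first rupture when the onset is known, else the
first 5 frames; fewer pre-rupture frames are used when 5 are not
available. A non-positive reference mean marks the trace unusable.
Negative normalized values are preserved — background can exceed signal.

### Event detection and classification

The detector maintains a rolling baseline (median of the last 5 non-event
frames). An event opens when the series falls ≥ 0.05 below the baseline
and closes at the first frame back at 95% of it. The magnitude is the
baseline-relative loss at the nadir, 1 − min/baseline; events with
magnitude > 0.30 are major, the remainder minor. Candidates that recover
in fewer than 3 frames are rejected: at 3-min sampling a genuine
leak/recovery cycle spans tens of frames, while 1–2-frame excursions are
overwhelmingly noise (at 2% trace noise they would otherwise contribute
roughly one false minor event per ten traces). All four thresholds (drop,
recovery fraction, minimum duration, major cut-off) are parameters; the
0.30 major cut-off is the study's definition, the others are detector
design choices made here because the original identification was manual.

Mitotic or grossly deformed nuclei are excluded upstream by the caller
(inclusion masks); automatic mitosis detection is out of scope.

### Recovery alignment and re-rupture statistics

Major-event recoveries are aligned with onset at t = 0; per-timepoint mean
and SD are computed over the contributing events, with SD undefined at
n = 1. Re-rupture intervals run onset-to-onset from each major event to
the next event of any class. A major event qualifies only with ≥ 30 frames
of subsequent observation, so that "no further event" is itself
informative and lands in the overflow bin rather than being censored.
Intervals are binned half-open to [0,15), …, [75,90) minutes plus
[90, ∞); the histogram total therefore always equals the number of
qualifying major events. Conditions are compared with a two-sided Fisher
exact test on the 2×2 table (>90 min vs ≤90 min) × condition, the
two-sided p-value being the sum of hypergeometric probabilities of all
same-margin tables no more probable than the observed one.

Tracking (for extracting traces from label-map movies) is deliberately
simple nearest-centroid linking with a displacement gate; ambiguous
assignments terminate tracks instead of guessing. It suffices for the slow
drifts this data shows; crossing or dividing nuclei are out of scope.

## Binding thermodynamics

### ITC model

The single-set-of-sites isotherm for a perfusion cell uses running totals
M_i = M₀(1−v/V₀)^i and X_i = X_syr[1−(1−v/V₀)^i], the closed-form bound
fraction from the mass-action quadratic, and the displaced-volume
correction δQ_i = Q_i − Q_{i−1} + (v/V₀)(Q_i+Q_{i−1})/2. Units:
concentrations molar, heats μcal, ΔH kcal/mol, R = 1.9872×10⁻³ kcal/(mol·K).
The cell volume defaults to 1.4 ml (the perfusion-cell class of instrument
used; config-exposed) with a 29 × 10 μl injection programme.

The stoichiometry is held at n = 0.5 sites per cell-macromolecule: the
injected Ig-fold domain binds one BAF **dimer**, and cell concentrations
count BAF monomers. No dimerization equilibrium is modelled — BAF is
treated as constitutively dimeric at these concentrations.

### Fitting

`fit_itc` runs trust-region least squares over (log₁₀ K_D, ΔH), with
multi-start over K_D ∈ {0.1, 1, 10, 100} μM because the shallow
(low-c-value) regime — c = n·M₀/K_D ≈ 0.6 at the mutant geometry — stalls
single-start fits; ΔH is initialized from the first-injection heat under
the tight-binding assumption. Standard errors come from the Gauss–Newton
curvature (delta method for K_D); ΔG = RT·ln K_D and TΔS = ΔH − ΔG are
derived at 288 K. A c-value outside [0.01, 1000] flags the result as
poorly constrained.

A constant per-injection dilution-heat offset is available
(`fit_offset=True`) but off by default: in the low-c regime the offset is
nearly collinear with ΔH, and profiling over synthetic titrations at 2%
heat noise shows it inflates the K_D sampling spread several-fold (from
~6% to ~50% SD at the mutant geometry) while the simulated experiments
contain no dilution heat. For real titrations without a blank to subtract
the offset should be enabled and the wider uncertainty accepted.

### NMR intensity ratios

Per-residue I/I₀ divides each bound-state peak volume by the free-state
reference volume. Residues unassignable in the bound state are filled with
the mean of the nearest preceding and following assigned ratios — so an
interpolated value always lies in the convex hull of its two neighbours —
and unassigned residues at either terminus stay missing, flagged. The
summary statistic is the mean ratio over assigned residues as a
percentage of the free-state signal.

### Cα superposition

`kabsch_rmsd` pairs atoms on the intersection of (chain, residue-number)
keys after an optional chain mapping, resolves alternate locations to the
highest-occupancy conformer, and computes the least-squares rigid
superposition via SVD with a proper rotation enforced (reflection
corrected through the smallest singular direction); collinear geometry or
fewer than 3 pairs is an error. All paired Cα atoms contribute — no
outlier-rejection cycles — so values can sit slightly above those from
viewers that iteratively trim poorly fitting atoms.

## Synthetic data: what it emulates, and what it does not

The generator renders (i) fields of wobbled-ellipse nuclei (low-order
Fourier boundary perturbation, because real — especially progeroid —
nuclei are not ellipses) with flat nuclear and cytoplasmic intensities per
channel; (ii) blebs as disc protrusions straddling the nuclear boundary,
covered by the chromatin channel, excluded from the lamin-B1 channel
(exactly zero lamin-B1 signal), and carrying a per-bleb protein-enrichment
multiplier, optionally drawn uniformly per bleb; blebs are kept a few
pixels apart so each remains an individually resolvable object with
unambiguous truth; (iii) nuclear foci with a programmable radial density
profile, assigned to analytically defined shells of the continuous radius
(independent of the label-image morphology under test) and placed with a
minimum pairwise separation; (iv) reporter traces as
background + baseline × a product of per-event factors, each an
instantaneous-onset exponential leak toward 1 − loss followed, once within
2% of that floor, by exponential recovery toward baseline — matching the
qualitative shape of observed rupture traces without asserting a kinetic
model; and (v) ITC isotherms as model heats plus Gaussian noise. Noise is
additive Gaussian everywhere, clipped at zero for images.

Identical spec + seed gives bit-identical output, and at zero noise every
truth quantity (areas, means, enrichments, event magnitudes, heats) equals
its programmed value up to stated discretization, which is what the
recovery tests exploit.

Deliberately **not** emulated: photon (Poisson) noise, point-spread
blurring, uneven illumination, 3-D stacks, photobleaching, cell motility
beyond small drift, chromatin texture, overlapping nuclei, and bleb shapes
other than discs. Passing recovery tests therefore demonstrates that the
measurement logic is correct and unbiased under idealized imaging, not
that segmentation is robust to the full pathology of real microscopy; on
real data the segmentation and threshold parameters are the knobs that
matter.

Default study conditions follow the source protocols where stated
(3-min frame interval, 8-h movies ≈ 160 frames, 29 × 10 μl injections at
288 K, 20/40 μM cell and 100/200 μM syringe concentrations, 2% heat
noise); distributions the protocols do not pin down (bleb sizes 80–300 px²,
rupture losses 0.15–0.7, recovery constants of minutes-scale) were chosen
once as plausible for 20× imaging of fibroblast-like cells and are spec
fields, not constants.

## Problem sizes and runtime

The test suite and analysis scripts run on a single CPU in well under two
minutes total. Recovery statistics use 30–200 synthetic objects per check
(e.g. 200 traces for detector sensitivity/precision, ~60 rendered blebs
for enrichment RMSE, 500–1200 foci for radial fractions) — sizes at which
the binomial/sampling error is comfortably below the asserted tolerances.
The exhaustive Fisher cross-check enumerates every 2×2 table with all
margins ≤ 12 against an exact rational-arithmetic oracle.

## Known limitations

- Bleb/micronucleus discrimination is out of scope; a lamin-B1-negative
  micronucleus overlapping a chromatin object would be scored as a bleb.
- The rupture detector assumes an approximately stable baseline; slow
  drifts larger than the drop threshold between events would need
  detrending upstream.
- `align_recovery` aligns at detected onset, not at the nadir; with very
  slow leaks the early averaged frames mix leak and recovery phases.
- The ITC fit assumes a single class of independent sites and fixed
  active concentrations; concentration errors map directly onto ΔH and
  K_D as in any calorimetric analysis.
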