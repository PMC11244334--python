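# Methods

## Scientific setting

Cultures started from "purified" mature adipocytes (ceiling culture, or
replated *ex vivo*-differentiated stromal vascular fraction) are routinely
overgrown by proliferative fibroblast-like cells.  Whether those cells are
dedifferentiated adipocytes or contaminating non-adipocyte cells can be
decided by Cre/lox lineage tracing: in *Adipoq:Cre* reporter mice, adipocytes
and all their descendants irreversibly switch from tdTomato to GFP.  The
package quantifies such experiments in two ways:

1. an **imaging pipeline** that segments nuclei from the DNA counterstain,
   measures reporter and proliferation-marker signals per nucleus, gates
   cells into GFP⁺/GFP⁻ and marker⁺/marker⁻ classes with fixed cutoffs, and
   reduces the gated cells to per-well replicate statistics; and
2. a **population-composition model** showing that a tiny proliferative
   contaminant suffices to dominate the culture, so overgrowth alone is no
   evidence of adipocyte cell-cycle re-entry.

## The composition model

Two compartments evolve in daily steps: post-mitotic adipocyte-derived cells
and proliferative "other" cells, with equal daily survival *s* and a daily
growth factor *g* = 1 + 24/*T_d* (*T_d* = doubling time in hours) applied to
the proliferative compartment only:

    adipocyte_{n+1} = adipocyte_n · s
    other_{n+1}     = other_n · s · g
    fraction_n      = other_n / (other_n + adipocyte_n) · 100 %

Defaults: *s* = 0.99 per 24 h, *T_d* = 24 h, initial composition 99:1,
horizon 26 days.  Because *s* multiplies both compartments it cancels from
the fraction, giving the closed form
f_n = f₀·gⁿ / (f₀·gⁿ + 1 − f₀) and the exact inversion
f₀ = F / (gⁿ(1 − F) + F) for the minimal initial fraction reaching a target
F.  `simulate_composition` iterates the recurrence verbatim;
`closed_form_fraction`/`minimal_initial_fraction` use the algebra; tests and
the acceptance script verify the two routes agree to ~1e-15 relative and
that the fraction is survival-invariant.

The daily factor 1 + 24/*T_d* is a *linear* within-day approximation of
doubling (it equals exact doubling only at *T_d* = 24 h).  It is kept as the
defining contract of the model; an exponential alternative
g = 2^(24/*T_d*) is available behind `growth="exponential"` (default off)
for sensitivity analyses.  Time is discrete in 24 h steps; there is no
continuous-time ODE variant and no fitting of the model to observed wells —
it is a forward estimation tool only.

With the defaults, a 1 % contaminant reaches 99.9999 % of the population by
day 26, and the minimal initial fraction needed to reach 95 % by day 26 is
2.8·10⁻⁵ % — both far past the "even 1 % suffices" threshold.  The final
percentage is strictly decreasing in doubling time (the `model` CLI writes
the sweep table and an optional plot).

## Synthetic data generator

`adipotrace.simulate` renders four-channel fields (nuclear stain, GFP, RFP,
marker) with exact per-cell ground truth, so every downstream stage is
testable without real images.

* **Geometry.** Nuclei are flat-intensity disks (radius ~N(8, 1) px, clipped
  below at max(2, r̄/4)) placed by dart throwing with a minimum
  centre-to-centre distance (default 24 px) and a one-radius border margin,
  so areas and means have analytic oracles.  A configurable `clump_fraction`
  deliberately violates the distance rule to exercise watershed splitting.
  Real nuclei are neither perfectly circular nor flat; passing tests
  therefore certify the measurement contract, not robustness to irregular
  morphology.
* **Populations.** Each cell is GFP⁺ with probability `frac_gfp_pos`
  (default 0.06, a minority adipocyte-derived lineage) and marker⁺ with a
  GFP-conditional probability (defaults: 0 given GFP⁺, 0.04 given GFP⁻ —
  proliferation confined to the non-adipocyte lineage).
* **Intensities.** Per-channel background plus per-population log-normal
  foreground medians (16-bit defaults: nuclear 8000, GFP 6000 vs 150,
  RFP 150 vs 6000, marker 20000 vs background-only; log-sigma 0.2–0.3).
  Each cell's drawn intensity is rounded to an integer *before* rendering
  and stored as the ground-truth value, so on noise-free fields per-nucleus
  means equal ground truth to machine precision while images remain genuine
  8/16-bit rasters.  Foreground replaces background inside a nucleus.
* **Reporter modes.** `nuclear_ratio` (nT/nG-style) puts the reporters in the
  nucleus, enabling nGFP/nTomato ratio gating; `membrane` (mT/mG-style)
  renders a 2 px ring at twice the nuclear radius and exists only to check
  that nuclear-stain segmentation ignores off-nucleus fluorescence.
* **Noise.** Gaussian read noise (default sd 30) plus optional Poisson shot
  noise; no photobleaching, illumination gradients or PSF blur.
* **Determinism.** Identical config (including seed) gives bit-identical
  images and truth; experiment designs spawn per-field child seeds via
  `numpy.random.SeedSequence`.

Free parameters with no external reference (field density, nucleus size,
intensity levels, noise sd) were fixed once at the values above as
representative of 10× epifluorescence imaging of sub-confluent cultures.

## Segmentation and measurement

`segment_nuclei`: Gaussian smooth (σ = 1 px) → threshold (Otsu by default,
or fixed) → fill holes → Euclidean distance transform → `peak_local_max`
seeds (minimum separation ≈ 0.8× expected nuclear radius, default 6 px) →
watershed → area filter (default 30–2000 px²) → optional border exclusion
(default on, since clipped nuclei have truncated areas/integrals) → dense
relabelling 1..K.  Blank images yield an empty label map.  The pipeline is
assembled from scikit-image/scipy primitives; no claim is made of
equivalence with any specific proprietary segmentation package.

`measure_nuclei`: per label — pixel area, geometric centroid, **mean** GFP
and RFP, **integrated** (summed) marker signal, and the ratio
(mean_gfp + ε)/(mean_rfp + ε) with ε = 10⁻⁶ × the larger reporter-channel
maximum (division-by-zero guard; negligible at real signal levels).

`match_to_ground_truth`: greedy nearest-centroid one-to-one matching within
a radius (default 5 px), reporting recall, precision and mean centroid
error.  On 20 default-noise synthetic fields the pipeline achieves
recall/precision ≥ 0.95 (measured ≈ 1.00) and ≈ 0.08 px centroid error.

## Gating and statistics

* Gating uses one `GateConfig` per experiment — cutoff constancy across
  samples is enforced programmatically.  The convention is strictly-greater:
  a value exactly at a cutoff is negative (ties are rare for continuous
  signals; the choice is arbitrary but fixed).
* Default cutoffs (ratio 1.0; integrated marker 2·10⁵) sit in the wide gap
  between the default intensity model's populations.  `suggest_cutoff`
  offers reproducible automatic alternatives (valley of a smoothed log₁₀
  histogram between the two dominant modes, or Otsu on log values) and
  refuses unimodal input rather than guessing.
* Well-level summaries report counts and percentages; a zero-denominator
  percentage is `None`/NaN (flagged undefined), never silently 0.
* Replicate statistics: mean ± SEM (sample sd with n−1 denominator over
  replicate wells; SEM undefined at n = 1) and a pooled-variance Student t
  test (df = n_a + n_b − 2, two-tailed p) implemented from the explicit
  formula, with a Welch option.  Zero pooled variance with equal means is
  defined as t = 0, p = 1; with unequal means the result is flagged
  degenerate with p = 0.  The biological replicate is the well/mouse; cells
  are never treated as independent replicates.
* phospho-H3 (mitotic marker) uses the same code path as EdU — it is simply
  another integrated marker channel with its own cutoff.

## Pipeline and reproducibility

`run_pipeline` executes simulate → segment → gate → summarize → stats →
model from one `RunConfig`; supplying `input_fields` (TIFFs with a full
channel-role map, validated before any computation) skips simulation.  A
single global seed fans out to per-stage/per-field child seeds, so identical
config + seed reproduces every output byte-for-byte.  The manifest (SHA-256
config hash, package version, per-stage file lists and timings) is written
even on partial failure.  CSV outputs use `%.17g` floats so record tables
round-trip losslessly.

## Problem sizes

Tests and the acceptance script use 512×512 fields with 60 nuclei (20 seeds)
for segmentation recovery, 1000-cell samples (20 seeds) for gating recovery,
and three 120-cell wells for the end-to-end lineage result; these sizes give
binomial error bars comfortably inside the asserted bounds while keeping a
full run in seconds.

## Known limitations

* Disk-shaped, flat-intensity nuclei and the absence of illumination/PSF
  artefacts make segmentation easier than on real data; the recovery bounds
  certify the algorithmic contract, not field performance.
* The membrane reporter mode is not an mT/mG whole-cell scorer; whole-cell
  membrane segmentation is out of scope.
* Heavy clumping can fully occlude a cell in the reference raster; such
  cells are dropped from the ground truth (only possible when
  `clump_fraction` > 0).
* The composition model ignores density limitation, senescence and
  stochastic extinction of small clones.
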