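# Methods

This note records the models, parameter choices and numerical conventions
behind `oppscreen`, the reasoning where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Synthetic screen model

The generator emulates the *statistical* structure of a 384-well OPP
translation screen, not its optics. Per plate p, well w (role r with
multiplicative OPP effect `e_r`), the true mean cytoplasmic intensity is

```
µ_pw = baseline_opp · e_r · f_plate(p) · f_rep(p,w) · f_well(p,w)
```

with log-normal factors `f_plate ~ LN(0, plate_effect_cv)` (a global plate
level shift the DMSO normalization must remove), `f_rep ~ LN(0,
replicate_noise_cv)` (per-compound, per-plate irreproducibility feeding the
CV gate) and `f_well ~ LN(0, well_effect_cv)` (well-to-well biological/
technical spread; for small σ the log-normal σ is numerically the CV). The
well's cell count is Poisson with mean `cells_per_well · toxicity`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_plates | 3 | triplicate plate sets |
| n_rows × n_cols | 16 × 24 | 384-well plate |
| fields_per_well | 4 | four images per well |
| baseline_opp | 2000 ADU | mid-range of a 16-bit camera with headroom |
| torin_effect | 0.5 | intermediate mTOR-inhibition knockdown |
| chx_effect | 0.05 | near-total elongation arrest; keeps the control ordering CHX ≪ Torin < DMSO |
| plate_effect_cv / well_effect_cv | 0.05 | typical plate-reader-scale variation; gives vehicle-well CV ≈ 5% |
| noise_sd | 40 ADU | per-pixel additive camera noise, ~2% of baseline |
| nucleus_radius | 5 ± 0.8 px | a ~10 µm nucleus at 10× binned acquisition |
| cyto_expansion | 2.0 | cytoplasm annulus out to twice the nuclear radius |
| cell_intensity_cv | 0.10 | per-cell spread around the well mean |
| dmso/torin/chx layout | col 23 / col 24 top / col 24 bottom | control counts per plate are not standardized; all three lists are configurable |

Image mode renders each cell as a disk nucleus (stain channel) plus an
annular cytoplasm at the cell's intensity (OPP channel; nuclear interior at
0.6× the cytoplasmic level), placed by rejection sampling so cells never
overlap and never touch the field border, with additive Gaussian noise and
clipping to [0, 65535] (clip fraction reported). Fast mode emits the same
per-well draws directly as a well table. Because both modes share one draw
hierarchy — `SeedSequence(seed, spawn_key=(stage, plate, well, field))` —
any subset of the screen is reproducible in isolation, a fixed seed is
bit-reproducible, and the rendered-and-remeasured well means track the
fast-mode values up to per-cell sampling spread (≈ cv/√n_cells).

What the generator deliberately does **not** emulate: real nuclear
morphology and declumping, illumination falloff, focus failures,
cell-cycle intensity structure, spatial (row/column/edge) plate effects,
and segmentation-error-correlated intensity bias. Tests passing on this
generator show the *analysis* is correct under its stated statistical
assumptions; they do not certify nucleus detection on real micrographs.

## Segmentation

Nucleus detection is Gaussian smoothing (σ = 1 px) → global Otsu → 8-connected
components → area gate [min_area, max_area] = [20, 2000] px (a 2.5 px
radius nucleus up to large aggregates) → renumbering 1..K by raster-scan
first occurrence. A constant image returns zero nuclei; NaN pixels raise.

Propagation uses the established seeded-propagation formulation: step cost
`sqrt(ΔI² + λ)` between 4-adjacent pixels, λ = 0.05 by default (in squared
intensity units: with unit-scale intensities it makes the cost mildly
distance-like in flat regions while contrast dominates at edges),
best-first expansion from all seeds simultaneously, tie-break by
(cost, label, scan order) so results are deterministic. Expansion is
restricted to pixels above a background threshold (Otsu of the OPP channel
unless given, clamped from below by `threshold_floor`) and to at most
`max_distance` = 40 steps. Two semantics in the step limit were possible;
we fix: the step count attached to a pixel is that of the minimum-cost path
that first finalizes it, and expansion stops at `max_distance` steps. With
the limit effectively unbounded the result is exactly the multi-source
shortest-path labeling, which is what the oracle tests assert on random
grids; the bounded behavior is checked against BFS geodesic distance on
uniform images.

Two consequences worth knowing. First, at *exact* cost ties the label
tie-break is by label number, so relabeling seeds can move a
measure-zero set of boundary pixels; on continuous intensities ties do not
occur and the partition is invariant to seed renumbering (tested). Second,
intensity-scale invariance of the label maps holds when the background
threshold scales with the image and λ scales with its square — λ has
squared-intensity units; with λ fixed, rescaling the image reweights
contrast against the regularizer by design.

Measurement computes per-label pixel means of the OPP channel over the
nucleus/cell/cytoplasm masks by exact accumulation, so
`cell_area = nucleus_area + cytoplasm_area` and the area-weighted
recomposition identity hold to rounding. Cells touching the field border
are flagged and excluded from well summaries (truncated cytoplasm), never
silently dropped; a cell that never expanded past its nucleus keeps its
record with a NaN cytoplasm mean.

## Plate analytics and hit calling

Well summaries pool cells across the well's fields (each cell weighted
equally); a per-field-mean variant exists behind `method="field_mean"`
because the two differ when fields have unequal cell counts — pooling is
the default as the lower-variance estimator under the generative model.
Normalization divides by the same-plate DMSO mean (DMSO wells included in
their own reference), so per plate the DMSO `opp_norm` mean is exactly 1
and any well-independent multiplicative plate factor cancels exactly.
Empty wells propagate as missing, never as zero. Triplicate aggregation
uses simple means and CV with the sample SD (n−1); compounds not present
exactly once per plate on all plates are excluded as
`incomplete_triplicate`.

Hit calling applies four gates with strict inequalities: (1)
triplicate-mean deviation > k·SD using the *pooled* DMSO distribution over
the three plates; (2) viability ≥ 0.70 of vehicle — failing compounds are
excluded outright, whatever their OPP effect, since toxicity confounds the
translation readout; (3) per-plate deviation > k·SD using each plate's
*own* DMSO SD, same sign on all plates; (4) CV < 20% for both OPP and
nuclei counts. Whether the SD scale should be per-plate or pooled is
underdetermined; using the plate's own SD for per-plate flags and the
pooled SD for the mean criterion is robust to plate-level variance
differences while keeping the mean test well-powered. Significant-but-
irreproducible compounds are excluded as `high_cv`; compounds failing the
effect criteria are `null`. No further multiple-testing control is applied
beyond this SD/concordance scheme — under the global null the probability
of a 3-SD same-sign triple is ≈ 2·(0.00135)³, negligible per library.

## Dose-response validation

A series (assay × plate, doses 1/3/10 µM, responses as fractions of DMSO)
passes in down-regulator mode when it is non-increasing within additive
tolerance `mono_tol` = 0.05 and the top-dose response is ≤ 1 − `min_effect`
= 0.75; mirrored for up-regulators. Validation requires all four series of
both assays by default — the conservative reading of "dose-dependent in
either assay" — with `require_both_assays=False` for the lenient one. No
sigmoidal fitting: three doses cannot constrain a 4-parameter logistic, so
the rule is explicitly threshold-based and configurable.

## Proteomics statistics

The differential test is a per-protein two-sided two-sample t-test on log2
intensities with BH adjustment across all proteins; regulated = raw
p < 0.05 AND |log2FC| > 0.3 (the q-value is reported alongside, not used in
the flag). The default pools the within-group variance: labeled-
quantification replicates are near-homoscedastic on the log scale, and at
3-vs-3 the pooled t is exactly calibrated while the Welch–Satterthwaite
approximation is measurably conservative (simulated type-I ≈ 0.034 at
nominal 0.05, versus ≈ 0.049 pooled). `test="welch"` switches to the
unequal-variance form; the choice is recorded in the result's metadata.
Degenerate rows (zero variance in both groups) get p = 1 when the means are
equal and p = 0 otherwise, logged.

Ranking is by descending log2 ratio with lexicographic protein-id
tie-breaks. Enrichment follows the preRanked weighted scheme: along the
ranked list the running sum gains `|metric|^p / Σ_members |metric|^p`
(p = 1 default) at members and loses `1/(N − N_set)` at non-members; ES is
the signed extremum (exact positive/negative magnitude ties resolve
positive; an all-zero member weight sum falls back to equal weights). The
null is random same-size memberships (n_perm = 1000 default, seeded;
`exhaustive=True` enumerates all C(N, k) memberships when feasible), the
p-value is the same-sign null fraction with |ES| at least as large, NES
divides ES by the mean |null ES| of its sign, and FDR q uses the pooled
sign-stratified null with a monotonicity cleanup toward extreme NES. Sets
are intersected with the ranked universe; below `min_size` = 5 (or empty,
or universe-covering) they are skipped with a log message.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
these scales, chosen to estimate each quantity tightly while keeping the
default run light: 200-compound triplicate screens (five seeds) for recall
and null false-positive rates; 100 random ≤ 9×9 grids against the
exhaustive propagation oracle; 20 rendered fields for the conservation
identities; 2,000 proteins × 10 seeds for test calibration; an 8-gene
universe for exact permutation enumeration; a 16-field rendered plate for
image-vs-fast agreement.

## Known limitations

- No nucleus declumping: touching nuclei merge (the generator never places
  them, real images do).
- No illumination correction or spatial plate-effect polish (B-score);
  normalization is strictly percent-of-DMSO.
- The propagation oracle equivalence is exact on random instances but the
  label tie-break at exact cost ties is a convention, not a biological
  statement.
- Moderated-variance (limma-style) testing is out of scope for the
  proteomics stage; with only three replicates a moderated test would
  change individual calls.
- The dose-response rule is a screening heuristic, not a potency estimate.
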