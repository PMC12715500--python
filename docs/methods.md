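# Methods

This note documents the models, defaults and design choices behind
`pchscaffold`, in the spirit of a statistical-software methods section:
what each stage assumes, which knobs matter, and what the synthetic
data do and do not establish about real data.

## Scaffold screen

**Consensus vote.** Each predictor contributes a candidate set: the
top-*n* ranks of a numeric score table (default *n* = 1000 at proteome
scale; 60 in the demo configuration, scaled to its 400-protein
universe), or a downloaded membership list for the predictor that
publishes one. The two assembly scores of the self/partner predictor
count as a single tool (union of their top ranks) so that no predictor
votes twice. Proteins in ≥ `min_support` = 2 sets are consensus
candidates; published scaffolds are merged in with provenance flags.
Tie-breaking in `top_n_candidates` is by (score descending, protein id
ascending) with boundary ties cut, so the result always has exactly
*n* members and is reproducible.

**Nuclear filter.** The source annotation only says proteins were kept
"based on subcellular localization", so the vocabulary is an explicit,
configurable default: {nucleus, nuclear, nucleolus, chromosome,
chromatin}, case-insensitive substring over localization + GO text.

**Compartment keywords.** The 15-category keyword map ships as editable
YAML (`data/compartment_keywords.yaml`). Matching is plain substring,
not word-boundary, because several terms are multiword phrases or
deliberate fragments ("MBD", "MeCP", "cbx5"); a consequence is that
nested vocabularies overlap by construction ("histone deacetylase
corepressor" also matches the deacetylase category), which mirrors how
such keyword screens behave on real annotation text. Classification is
idempotent and row-order independent.

**Assembly mode.** "High" in a score means membership in its top-*n*
rank list. High self + high partner, or high self alone, maps to SaPS
(self-sufficiency implies self-assembly); high partner alone maps to
PdPS; both cuts are configurable.

## Partition proteomics

Raw DIA protein-group intensities are assumed positive where observed,
with missingness meaningful (never zero). The processing order is:
detection filter (≥ 3 samples overall) → log2 → per-sample median
subtraction (post-normalization column medians are exactly 0, and the
median step is idempotent) → downshifted-Gaussian imputation
(μ_col − 1.8 σ_col, width 0.3 σ_col — the de-facto label-free
convention for values missing because they fall below detection; both
parameters configurable). Imputed values never count as detections.

Group tests are two-sided pooled-variance Student *t*-tests (the
default of the widespread analysis tools this mirrors), not Welch;
differential abundance reports raw *p* < 0.05 with no multiplicity
correction — the BH correction is applied only in the imaging stage's
pairwise family, where the corresponding analysis uses it. Zero
within-group variance in both groups leaves *p* undefined and flagged.

Percentage summaries are reported to one decimal plus a round-half-up
integer for "~x %" rendering (14/25 → 56.0; 25/34 → 73.5 → "~74 %").

**Native MS.** For an ascending peak series the charge assignment
`z, z−1, …` minimizing the relative spread of `z_i (mz_i − 1.00728)`
is selected; an assignment is accepted only if that spread is below a
0.5 % tolerance, which cleanly separates the correct assignment (0 for
noiseless peaks, ~0.1 % at 0.05 % m/z jitter) from the nearest wrong
one (~2 % at z ≈ 50). Oligomer order is the rounded mass ratio, with
ratios > 0.25 from an integer flagged ambiguous.

## Imaging

**Nucleus segmentation** takes the *lowest* cut of a three-class Otsu
threshold (falling back to two-class Otsu when the histogram has too
few levels), then the largest connected component with holes filled.
Plain two-class Otsu fails on chromocenter-bearing images: with a
bright third mode the cut lands above the nucleoplasm level and only
the foci survive. **Focus segmentation** thresholds at μ + k·σ of the
intra-nuclear intensity (k = 2, minimum area 5 px); both knobs are
configurable defaults, since the source procedure is stated only as
"segmented based on DAPI intensities".

**Percent in PCH** is `100 · Σ_foci(area × mean) / (S_N × I_N)` — the
per-focus generalization of `S_PCH × n × I_PCH` that stays exact for
heterogeneous foci; it equals the per-pixel intensity ratio to
numerical precision and equals the area fraction exactly on uniform
images.

**Compaction classes** use seeded k-means (k = 7, 10 restarts, best
inertia kept) on masked voxel intensities, centers sorted ascending so
class 1 is interchromatin and class 7 the densest heterochromatin; the
per-class percentages of total DAPI intensity sum to 100 by
construction. Only the contract of the original classifier (7 intensity
classes, DAPI percentage per class) is reproduced, not its internals.

**Calibration.** Standard curves are ordinary least squares; inversion
is `(reading − intercept)/slope` and a flat curve is a hard error.
Blot-derived concentration uses a default nuclear volume of
4.0 × 10⁻¹³ L (≈ 400 µm³), configurable, because the volume used for
the molar conversion is otherwise unstated. Tissue scaling is plain
proportionality to the reference tissue's ppm abundance.

## Half-FRAP model

The exchange model has three well-mixed pools: bleached half B,
non-bleached half N (unit volumes) and surroundings S (relative volume
`v_surround`, default 20 — nucleoplasm much larger than half a
chromocenter). Halves exchange at `k_intra` (s⁻¹); each half exchanges
with the surroundings at `k_boundary` (s⁻¹). Total fluorescence
B + N + v·S is conserved. Bleaching multiplies B by (1 − depth)
instantaneously at frame `n_pre` (default 9 pre-bleach and 130
post-bleach frames, 1.3 s apart).

The dip is computed on raw normalized frames — no smoothing — against
the fixed pre-bleach baseline of 1.0 (not a refitted plateau); this is
a deliberate simplification of analysis scripts that smooth first.
Useful limits: `k_boundary = 0` gives a closed two-pool system with
equilibrium dip = depth/2; `k_boundary → ∞` (with large surroundings)
washes the dip out; the dip decreases monotonically in
`k_boundary/k_intra`. The trace generator integrates the system
numerically (tight-tolerance RK); `simulate_two_compartment` solves it
exactly via matrix exponential, so the two constitute an internal
cross-check rather than one code path. The concentration window for
cell selection is the closed interval [15, 35] µM. The per-molecule
energy-barrier (kT) fit of the original half-bleach analysis tool is
intentionally out of scope.

## Synthetic data: what it emulates, and what it does not

Each generator draws from an independent named random stream derived
from (seed, generator name), so adding a generator never shifts
another's output, and embeds (params, seed) in a provenance block.

* Annotations embed compartment keywords verbatim inside longer
  sentences, with distractor sentences, to exercise substring matching;
  domain flags are Bernoulli (p_cc = 0.25, p_znf = 0.2) and disorder
  fractions Beta(2, 3) — plausible proteome-scale marginals, not fits.
* Predictor scores are standard normal with the planted scaffolds
  shifted by +effect; real predictor scores are neither Gaussian nor
  independent across tools, so recall results here bound only the
  set-algebra and ranking logic, not real-predictor accuracy.
* DIA intensities are log-normal (baseline log2 ≈ N(20, 2), replicate
  noise 0.5) with logistic intensity-dependent dropout (midpoint 16,
  slope 1) and per-(class, fraction) log2 shifts recorded as truth.
  No peptide-level structure, shared-peptide ambiguity or batch drift
  is simulated. The +2 log2 recovery experiment plants the shift in a
  ~5 % subset of a 2000-protein background because median
  normalization presumes a mostly-unchanged proteome; planting a large
  fraction visibly attenuates recovered fold changes (measured ~1.4 of
  2.0 at a 27 % planted fraction) — an inherent property of median
  normalization, not an implementation artifact.
* Nuclei are noisy elliptical phantoms with non-overlapping disk foci
  and no point-spread function or illumination gradient; segmentation
  accuracy on them is an upper bound for real micrographs.
* FRAP traces add Gaussian read noise (σ = 0.02 of the normalized
  scale) to the exact exchange dynamics; real traces also contain
  acquisition bleaching and diffusion gradients the three-pool model
  averages away.

Consequently, green tests establish the correctness of the
computations and their calibration under the stated generative
conditions — not the biological performance of the screen on real
proteomes or images.

## Problem sizes

The demo pipeline uses a 400-protein universe, 30 planted scaffolds,
3 replicates per fraction, three 96×96 2-D nuclei, one 16×64×64 3-D
stack and 8 traces per FRAP condition; the test suite uses further
reduced sizes. These are the package's default study conditions and
keep the full demo deterministic and fast while leaving every statistic
well above its noise floor.
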