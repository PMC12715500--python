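# pchscaffold

A reusable, tested implementation of a computational screen for
**phase-separation scaffold proteins of pericentric heterochromatin
(PCH)**, together with the downstream quantifications such a screen
feeds: condensate partition proteomics, chromocenter image analysis,
and half-bleach (half-FRAP) interfacial-barrier statistics.

## The scientific problem

Pericentric heterochromatin forms dense, membraneless nuclear
compartments (chromocenters). One proposed organizing principle is
liquid–liquid phase separation (LLPS) driven by *scaffold* proteins —
proteins able to demix on their own and to recruit or exclude other
factors across the condensate boundary. Identifying which of the
~1000 proteins found in reconstituted heterochromatin condensates are
genuine scaffolds requires combining several independent lines of
evidence. This package implements that combination as a pipeline:

1. **Predictor consensus** — three proteome-wide phase-separation
   predictors are consumed as score tables; the top-*n* of each votes,
   and proteins supported by ≥ 2 predictors (or published as scaffolds)
   enter the candidate catalog. A two-score predictor additionally
   labels candidates as self-assembling (SaPS) or partner-dependent
   (PdPS) phase separators.
2. **Compartment classification** — candidates are restricted to
   nuclear proteins and assigned to 15 subnuclear compartments /
   protein families by case-insensitive substring matching of a
   curated keyword vocabulary over description, localization and GO
   text.
3. **Triple intersection** — predicted PCH scaffolds ∩ condensate
   pellet proteome (HC\_P) ∩ PCH proteome gives the final candidates,
   reported with the full 7-region Venn tabulation.
4. **Partition proteomics** — DIA intensity matrices are detection-
   filtered (≥ 3 samples), log2-transformed, median-normalized per
   sample, and missing values imputed from a downshifted Gaussian
   (μ − 1.8σ, width 0.3σ). Proteins present in ≥ 2 replicates per group
   are classified as pellet-and-supernatant (P&S), pellet-only or
   supernatant-only; adding scaffold condensates partitions the pellet
   proteome into retained / excluded / recruited sets, summarized per
   functional class as `100·count/denominator` (e.g. 14/25 → 56.0 %).
   Per-protein unpaired Student *t*-tests give log2 fold changes with
   raw *p* < 0.05 significance.
5. **Native MS** — a consecutive charge-state series at m/z values
   `mz_i` is assigned charges `z, z−1, …` minimizing the spread of the
   implied neutral masses `M_i = z_i (mz_i − m_proton)`; oligomer order
   is `round(M / M_monomer)`.
6. **Imaging** — nuclei are segmented from the DAPI channel (lowest cut
   of a three-class Otsu), chromocenter foci thresholded at μ + 2σ
   inside the nucleus, and the fraction of a channel in PCH computed as
   the percent ratio `100 · (S_PCH × n × I_PCH) / (S_N × I_N)`.
   A linear standard curve calibrates fluorescence to µM; nuclei fall
   into expression classes I ([2, 3] µM, endogenous), II ([10, 30) µM),
   III ([30, 50) µM) and IV (≥ 50 µM). Seven k-means intensity classes
   describe chromatin compaction from interchromatin (class 1) to the
   densest heterochromatin (class 7), and pairwise *t*-tests are
   Benjamini–Hochberg corrected.
7. **Half-FRAP / FLIP** — after bleaching one half of a chromocenter,
   both halves are normalized to their pre-bleach means (9 pre-bleach
   frames by default). The **Dip** is the maximum transient drop of the
   non-bleached half below 1: large dips indicate preferential
   intra-condensate exchange, i.e. an interfacial barrier. A barrier is
   called when a Student *t*-test against dips in free solution gives
   *p* < 0.01 with a larger condition mean. Cells are selected in the
   physiological 15–35 µM window. A three-pool exchange model (bleached
   half ↔ non-bleached half at rate `k_intra`, each half ↔ surroundings
   at `k_boundary`) is solved exactly by matrix exponential and serves
   as the oracle for all trace simulations.

Because the original raw inputs (predictor downloads, DIA search
output, microscopy, photobleaching series) are external, the package
ships a first-class synthetic-data module (`pchscaffold.synthio`) that
generates every input with planted, recoverable ground truth — planted
scaffold score shifts, fraction-specific log2 enrichments with
abundance-dependent missingness, nuclei with bright foci, and
two-compartment exchange traces with a tunable boundary.

## Worked example

Run the synthetic end-to-end demo:

```sh
pchscaffold report --seed 1 --outdir runs/demo
cat runs/demo/report.txt
```

```
pipeline run (config 2ce8bef861ab8b3e, seed 1)

consensus scaffolds: 40
catalog entries (nuclear): 38
PCH-predicted scaffolds: 30
triple-intersection candidates: 30
planted-scaffold recall: 1.0
partition P&S/P-only/S-only: 368/13/12
mean %DAPI in PCH: 33.2
barrier: True (p=1.41e-22)
```

Reading the numbers: 40 proteins won the ≥ 2-predictor vote, 38 of the
merged candidates are nuclear, 30 carry PCH keywords, and all 30 planted
scaffolds survive the triple intersection (recall 1.0). Most detected
proteins partition into both pellet and supernatant (368 P&S). The
segmented chromocenters hold 33.2 % of nuclear DAPI intensity, and the
simulated condensate condition shows a clear interfacial barrier
against the free-solution control.

The same operations are available as a library:

```python
from pchscaffold import synthio, frap

traces = synthio.gen_frap_traces({"k_boundary": 0.02, "noise_sd": 0.0,
                                  "base_intensity": 1.0}, seed=1)
dip = frap.compute_dip(frap.normalize_halves(traces.traces[0]))
print(dip.dip, dip.time_of_dip)   # 0.3626 at t = 14.3 s
```

A boundary exchange 25× slower than the internal mixing rate produces a
36 % transient drop of the non-bleached half — a strong barrier.

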