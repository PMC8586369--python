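# Methods

## Clonal abundance model

A sorted sample's barcode amplicon reads estimate each clone's share of the
barcoded (GFP+) human graft; two FACS fractions rescale that share to the
whole mononuclear-cell (MNC) compartment:

    abundance_b  [% of MNC] = 100 · (n_b / N) · f_human · f_gfp

where `n_b` is the read count of barcode b, `N` the total barcode reads,
`f_human` the human fraction of MNC and `f_gfp` the GFP+ fraction of human
cells. Before any filtering the per-sample abundances therefore sum exactly
to `100 · f_human · f_gfp`; this conservation identity is enforced to 1e-9
relative tolerance in the tests.

Barcode extraction requires an exact match of both vector flanks with the
barcode of the configured length in between (first qualifying occurrence,
forward strand; reverse-complement scanning is opt-in since amplicon
sequencing is directional). No error correction is applied by default; an
optional greedy collapse absorbs barcodes within a configurable Hamming
distance of a higher-count neighbour (`max_hamming=0`, i.e. off, by
default), ties broken deterministically by count then sequence.

Detection uses a strict threshold: clones with abundance > 0.01% of MNC are
detected, applied per sample, so a clone may be detected in the spleen and
undetected in the blood. Filtering is idempotent.

## Bridge mapping

A molecular bridge read links a droplet cell index (16 nt) to a clone
barcode. Matching is exact — no mismatches tolerated — against both
whitelists, scanning the read and its reverse complement (consensus reads
have arbitrary strand). A read is informative only if it names exactly one
cell and exactly one clone across both orientations; reads naming two cells
or two clones are discarded outright. One informative molecule assigns a
cell (`min_support=1`, configurable upward); cells whose reads name two or
more distinct clones are excluded as multimapped and never re-enter any
analysis; whitelisted cells with no informative read stay unmapped. The
three sets partition the cell whitelist. The read architecture is not
assumed: the cell index and clone barcode may appear in any order and at any
offset.

## Expression preprocessing

Order matters and is fixed: cells first, then genes, then normalization.

1. Cells with mitochondrial UMI fraction strictly above 10% are removed,
   the fraction computed on raw counts before any gene filtering.
   Mitochondrial genes default to the human "MT-" symbol prefix; an
   explicit list overrides. Cells with zero total UMIs are removed with a
   warning (their fraction is undefined).
2. Genes are kept iff they have more than 2 UMIs in more than 5% of the
   remaining cells (both strict).
3. Expression is `10,000 · count / cellsum + 1` per cell, with `cellsum`
   the sum over *retained* genes — removed genes take no further part in
   the analysis; a flag restores the pre-filter denominator. Hence
   `Σ_genes (value − 1) = 10,000` per cell. No log transform is applied by
   default (expression is defined as the TPM-like value + 1); a `log`
   option exists. The downstream rank tests are invariant to monotone
   transforms, so this choice affects reported magnitudes, never
   significance.

Multi-channel experiments are filtered per channel and concatenated on the
gene intersection.

## Clone-group differential expression and the false-positive score

Cells are partitioned by the behaviour class of their assigned clone
(`CloneGrouping`: two disjoint clone sets plus a direction). Per retained
gene, a one-sided Mann–Whitney U test compares the two cell groups, midrank
tie handling throughout; for `min(n_a, n_b) ≤ 8` with no ties the p-value is
exact by enumeration of the U null, otherwise the normal approximation with
tie and continuity corrections is used. Genes whose values are identical
across both groups are degenerate: p = 0.5, flagged.

False discovery is controlled empirically. The cell→clone map is scrambled
S = 5 times (clone labels permuted uniformly across assigned cells, so every
clone keeps its cell count; scramble seeds are `seed+1 … seed+S`), the tests
re-run per scramble, and per gene

    FPS(g) = median_s |{g′ : p_s(g′) ≤ p(g)}|  /  |{g′ : p(g′) ≤ p(g)}|

with the median taken as the exact middle order statistic (3rd of 5; lower
middle for even S, no interpolation), both comparisons inclusive, and the
denominator ≥ 1 since g counts itself. Significance requires `p < 0.05` and
`FPS < 0.05`, both strict. Because the tests are one-sided, up- and
down-regulated genes are found by running the two directions as separate
families, each with its own scrambles. A clone-level scramble mode (permuting
clone identities while keeping each clone's cell block intact) is available
for sensitivity analysis; cell-level permutation is the default and the
calibrated contract. Comparisons are within one patient sample; no
adjustment across groupings or samples is attempted.

Calibration measured by the test suite and acceptance script: on null data
(500 genes, 200 mapped cells, no planted effect) the mean number of
significant genes over 100 simulations is ≈ 0.6 (required ≤ 1); with 10
genes planted at 2-fold between groups of ≥ 50 cells, ≥ 8/10 are recovered
in ≈ 96% of 50 runs (required ≥ 80%).

## Clonal statistics

* **Shannon diversity** H = −Σ p_i log2 p_i in bits (base configurable;
  base 2 chosen because the index's common convention must be pinned down
  for comparability), over detected clones renormalized to proportions;
  0 ≤ H ≤ log2(S).
* **Cross-tissue Pearson correlation** per sample pair over the union of
  clones detected in either sample, absent = 0, on raw percentages
  (log-space optional); zero-variance vectors yield missing entries.
* **Tissue bias**: unbiased clones are assumed equally abundant across
  tissues, so the spread of d_i = log2((a_spleen + φ)/(a_blood + φ)) over
  clones detected in blood or spleen — two well-mixed compartments —
  calibrates a null band `mean(d) ± 2.576 · sd(d)` (99% normal interval; an
  empirical 0.5%/99.5% quantile band is the config alternative). A clone
  whose target-vs-blood log2 ratio exceeds the band is tissue-biased; below
  it, blood-biased. The pseudo-abundance floor φ = 0.001% (one tenth of the
  detection threshold) keeps ratios of undetected clones finite while
  preserving order.
* **Trajectory classes**: k-means (k = 2, fixed seed, scikit-learn
  defaults otherwise) on log10(mean abundance + φ) per passage — abundances
  span orders of magnitude, so log features; the cluster whose centroid
  gains more from first to last passage is "expanding". Identical
  trajectories degenerate to a single class with a warning.
* **Treatment response**: per clone, log2((mean_A + φ)/(mean_B + φ)) of
  mean abundances across mice within a tissue; and a two-sided
  Kruskal–Wallis test across treatment arms with Bonferroni correction by
  the number of clones tested (capped at 1). Arms with fewer than 2
  observations are dropped; clones left with fewer than 2 arms are skipped
  with a warning; all-identical inputs report H = 0, p = 1.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis assumes —
never transcriptome biology (no pathways, cell cycle, doublets or batch
effects). Passing tests therefore demonstrate the correctness and
calibration of the procedures under their own model assumptions, not
robustness to real-data artefacts such as ambient RNA, index hopping, or
PCR jackpotting.

Defaults are the study conditions and are not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_clones | 50 | clones per cohort; log-normal(0, 1) sizes |
| n_biased_clones / bias_multiplier | 5 / 10× | planted tissue-tropic clones |
| tissue_noise_sigma | 0.25 | within-mouse biological tissue jitter (log-normal) |
| mouse_jitter_sigma | 0.3 | clone-size variation between mice |
| read_depth | 100,000 | amplicon reads per sorted sample |
| f_human · f_gfp | 0.6 · 0.5 | baseline FACS fractions |
| n_cells / n_genes | 1000 / 500 | 10x channel scale |
| nb_dispersion | 2 | NB dispersion θ, variance = μ + μ²/θ (shared across genes) |
| libsize_sigma | 0.3 | log-normal per-cell library size |
| frac_high_mito | 5% | planted cells above the mito filter |
| bridge_coverage | 0.2 | fraction of cells with a bridge read (the mapped fraction seen in practice) |
| bridge_multimap_rate | 0.02 | covered cells also emitting a wrong-clone read |

Three generator design choices deserve explanation:

* **FACS fractions carry clone mass.** Read proportions are compositional:
  planting a 10× clone would otherwise deflate every neutral clone's share
  and make all of them look blood-biased. In the real assay the expansion
  shows up in the FACS fractions (abundance is % of MNC), so each sample's
  fractions are scaled by the tissue's total clone-mass factor, and neutral
  clones keep equal abundance across tissues — exactly the null the bias
  band assumes.
* **Biological tissue jitter dominates read noise.** Multinomial read noise
  is heteroscedastic (small clones are far noisier in log-ratio), which
  breaks the normal-band calibration; real blood–spleen scatter is
  dominated by biological variation. The per-tissue log-normal jitter
  (σ = 0.25) restores approximately homoscedastic normal log-ratios, and
  the measured neutral-clone call rate is ≈ 1.3% against the 99% band.
* **Mito fractions are planted exactly.** Each cell's mitochondrial UMI
  total is derived from a drawn target fraction — clipped strictly below 9%
  for normal cells and at least 12% for planted high-mito cells — so
  ground truth at the 10% boundary is unambiguous.

Serial-transplant trajectories draw per-clone fitness from two log-normal
modes (centres 4× and 1/4×, σ = 0.3): the expanding/diminishing dichotomy
that k-means is asked to recover is only well defined for a bimodal fitness
family; a continuous unimodal family leaves near-neutral clones with
arbitrary truth labels.

**Noise-free mode.** For round-trip validation every sampling channel can be
silenced: reads are apportioned to clones by largest remainder instead of a
multinomial draw, bridge coverage 1 with no contamination, and — with
`expression_noise=False` — UMI counts equal their rounded expected values
with unit library sizes and identical mito load. In this regime null genes
are exactly tied (degenerate p = 0.5), planted genes separate
deterministically, and the full pipeline reproduces the generator truth
exactly: clone read counts, every cell→clone assignment, and the planted
DE-call sets in both directions.

## Numerical choices and degenerate inputs

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; scramble seeds derive as seed+1…seed+S;
  k-means uses a fixed `random_state`. Re-runs are byte-identical.
* FPS counting uses sorted arrays and binary search; exact equality with
  the brute-force double loop is asserted over random instances.
* Strictness at every stated boundary (0.01% abundance, 10% mito, 2 UMIs,
  5% prevalence, p and FPS at 0.05) is strict inequality, with the
  at-threshold case tested on each.
* Degenerate cases: all-zero abundance vectors, zero-UMI cells, zero-spread
  blood–spleen references, identical trajectories, all-identical
  Kruskal–Wallis inputs and all-tied genes are handled explicitly (error or
  flagged result, as documented per function) rather than propagating NaNs.
* DGE result tables are sorted by p with stable gene-name tie-breaks, so
  output order is reproducible.

## Problem sizes

Statistical surfaces are measured at desk scale, chosen so the full suite
and the acceptance script each run in well under a minute on one CPU: 100
null and 50 planted-effect DGE simulations (500 genes, 200–300 cells), 200
tissue-bias cohorts (50 clones, 3 tissues, 1e5 reads each via the
counts-only generator path), and a 400-cell noise-free round trip. The
read-level generators are exercised at 10³–10⁵ reads where the string round
trip itself is under test.

## Known limitations

* Exact flank sequences and barcode length of a given construct are
  required configuration; no default vector model is shipped.
* No barcode error correction beyond the optional Hamming collapse; no
  quality-aware parsing.
* Bridge matching is exact by contract — a single sequencing error in the
  cell index or barcode discards the molecule; with consensus long reads
  this is the intended trade of sensitivity for zero mismatch tolerance.
* The Mann–Whitney normal approximation is used whenever `min(n) > 8` or
  ties exist; for very small tied samples the p-values are approximate.
* No doublet detection, batch correction, clustering or survival analysis;
  those belong to upstream/companion tools.
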