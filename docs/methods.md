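# Methods

This note records the models and procedures drivernet implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Analysis model

The pipeline treats each species' expression matrix (genes × arrays, log2
intensities) as a realization of modular co-expression: groups of genes
driven by common latent regulatory activity, partially conserved between
species through 1:1 homologs, with a two-group (X vs Y library) mean
contrast on a subset of genes. The stages and their estimands:

1. **Quantile normalization** forces every array onto the vector of
   rank-wise means of the column-sorted matrix. Assumption: arrays share
   one global intensity distribution and differences in it are technical.
   Ties receive the mean of the target values over the tied ranks, which
   makes the operation idempotent. A single-array matrix is returned
   unchanged (with a warning) — there is nothing to normalize between.
2. **Homolog intersection** keeps 1:1 pairs present in both matrices and
   re-indexes species B's rows by the species-A gene name, so both shared
   matrices live in one namespace. Unmatched pairs are dropped and counted.
   Many-to-many orthology is out of scope; the first occurrence of a
   duplicated pair member wins. Duplicate gene rows read from a file are
   collapsed by keeping the highest-mean-intensity row — a stated choice,
   since probe-level information is not modeled.
3. **Module detection** (per species, on the shared genes): unsigned
   correlation, soft-threshold power β selected at the first scale-free fit
   r² ≥ 0.9 with negative slope (fallback: the β with maximal r², warned),
   topological overlap, average-linkage clustering, static cut, minimum
   module size 30. Unsigned similarity means a module can contain genes of
   opposite regulation sign; this is intentional and matches the screen's
   mixed up/down outcome.
4. **Consensus overlap**: one-sided hypergeometric upper tail per module
   pair over the shared universe; no correction across pairs for the
   primary p < 0.05 selection (a Benjamini–Hochberg column is emitted for
   transparency). Depletion is not tested.
5. **DEG screen**: per-gene Welch t-test (unequal variances) plus the mean
   log2 difference; strict thresholds p < 0.05 and |log2FC| > 0.585. Welch
   replaces a moderated (empirical-Bayes) t deliberately: it is fully
   specified, assumption-light, and adequate at ≥ 2 samples per group. With
   a single-sample group the screen refuses to fabricate p-values and runs
   in fold-change-only mode, flagged loudly.
6. **Dual-feature selection and network**: intersection of passing DEGs
   with the consensus union; signed correlation network at |r| ≥ 0.8 over
   all samples of the species-A matrix; isolated genes dropped. The
   magnitude (not the signed value) is thresholded, since negative edges
   are part of the output.
7. **Over-representation**: plain hypergeometric against GMT term sets,
   universe defaulting to all genes of the analyzed matrix; minimum overlap
   2 to suppress singleton terms; optional EASE variant (tests k − 1),
   more conservative.
8. **CpG islands**: 100 bp windows, step 1; a window passes with GC > 60%
   and Obs/Exp = N_CpG·N/(N_C·N_G) > 0.6 (both strict); overlapping or
   touching passing windows merge; merged ranges < 200 bp are discarded and
   survivors re-scored over their full extent. Window length, step and
   minimum length follow the classic island-definition defaults; only the
   two ratio criteria are fixed by the protocol this mirrors.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| candidate powers | 1–20 | – | standard soft-threshold grid |
| scale-free r² cutoff | 0.9 | – | conventional first-crossing rule |
| connectivity bins | 10 | – | equal-width; empty bins dropped, ≥ 3 required |
| cut height | 0.9 | fraction of merge-height range | see numerical notes |
| min module size | 30 | genes | protocol default |
| overlap α | 0.05 | – | raw p, per protocol |
| fold-change cutoff | 1.5 (log2 ≈ 0.585) | fold / log2 | protocol default |
| DEG p threshold | 0.05 | – | protocol default |
| network threshold | 0.8 | \|r\| | protocol default |
| CpG window / min length | 100 / 200 | bp | classic island definition |

## Numerical choices

* **Dendrogram cut.** The protocol's dynamic hybrid tree cut is replaced by
  a deterministic static cut plus minimum-size filter. The cut height is
  interpreted **relative to the dendrogram's merge-height range** (5th
  percentile to maximum), the same convention the dynamic-cut family uses
  for its `cutHeight`. This matters numerically: within-module topological
  overlap scales like corᵝ, so TOM dissimilarities compress toward 1 as β
  grows and any fixed absolute cut dissolves all modules at the powers the
  scale-free criterion actually selects. An `cut_mode="absolute"` option
  retains the literal fixed-height semantics. The cut is strict, with a
  1e-6 guard band so branches merging exactly at the cut height separate
  despite floating-point summation fuzz.
* **Hypergeometric tail** is accumulated in log space
  (`logsumexp` over log pmf terms) and clipped into (0, 1]; it is shared by
  the consensus and enrichment modules and validated against an exact
  rational-arithmetic oracle for all configurations with N ≤ 25.
* **TOM diagonal convention**: a_mm is excluded from the k and l sums;
  w_mm ≔ 1. Entries are clipped into [0, 1] after the vectorized evaluation
  (they are bounded analytically; clipping removes 1e-16-scale excursions).
* **Degenerate inputs**: zero-variance genes are removed before correlation
  (warned); genes with zero pooled variance get p = 1 in the Welch screen
  (warned); correlation requires ≥ 3 arrays — a 2-array design yields ±1
  correlations identically and is refused rather than guessed at.
* **Ties and determinism**: module labels are ordered by decreasing size
  with ties broken by the lowest member gene index; all generators are
  bit-reproducible from (config, seed).

## The synthetic-data generator

Each module q has one latent per-sample factor f_q; member gene g with
loading sign s_g is

    x_gs = b_g + noise_sd · (s_g · ρ · f_qs + √(1 − ρ²) · ε_gs),   ρ = √within_module_cor,

so two member genes have expected |correlation| `within_module_cor`.
Background genes are pure noise around their baseline. A configurable
fraction of modules is *shared*: both species reuse the same factor and the
same (homologous) membership and loading signs. Factors are group-centered
and standardized to unit sample variance; with 16 arrays the raw factor's
chance sample variance (sd ≈ 0.37) and chance X-vs-Y imbalance would
otherwise dominate seed-to-seed behaviour and break the generator's stated
calibration (realized within-module correlation within ±0.1 of the target;
realized DE shift within ±3·noise_sd/√n of the planted effect).

Differential expression is planted at module level first: a DE module's
factor carries a group offset μ = effect/(noise_sd·ρ), giving every member
a ±effect group-mean log2 difference (sign = loading sign) without touching
within-group variances or module membership — the group contrast rides on
the co-expression structure, as it does when a regulatory program differs
between the X and Y libraries. A per-gene additive shift large enough for
the Welch screen (≥ 2 SD) would instead double a member gene's variance and
halve its correlation to its module, which the soft threshold amplifies
into certain expulsion; that regime is neither realistic nor usable.
Residual DE count is placed on background genes as direct shifts. Both
mechanisms are conserved into species B across the homolog prefix.

Defaults (600 genes/species, 400 homologs, 8+8 arrays, modules of 50/50/50/
40/40 with three shared, correlation 0.8, 100 DE genes at 1 log2 unit
against noise SD 0.5) are a desk-scale rendition of the motivating study
(≈11000/10445 genes, 555 homologs, 9 and 11 modules, module sizes 31–114).
Note that in DE modules the realized within-module correlation exceeds the
target (the group offset adds shared variance); the correlation calibration
is therefore stated for non-DE modules.

Sequence fixtures: AT-rich background (60% A/T) with CG dinucleotides
suppressed by rejection sampling, and planted islands built from ~35% CG
dinucleotide units plus GC-biased singles, giving GC well above 70% and
Obs/Exp > 1.

**What passing tests do and do not show.** The generator produces Gaussian,
single-factor, 1:1-homolog data with exact group labels: no probe-level
effects, batch structure, dye bias, heavy tails, correlated background, or
many-to-many orthology. Recovery and type-I results on it validate the
*implementation* and the internal consistency of the pipeline, not the
biological sensitivity of the workflow on real arrays.

## Known limitations

* Dynamic hybrid tree cutting, module eigengene merging, signed networks,
  biweight midcorrelation and block-wise decomposition for very large gene
  sets are out of scope.
* The overlap test's universe N includes unassigned shared genes by default
  (`--universe assigned-only` provided); the test is one-sided and
  uncorrected by design.
* The moderated-t (empirical Bayes) screen is intentionally not
  implemented; at very small replicate counts Welch is conservative.
* The enrichment module does not propagate ontology graphs or use pathway
  topology; terms are flat gene sets.
* CpG scanning assumes uppercase A/C/G/T with incidental N bases (windows
  with > 20% N are skipped); soft-masked repeat annotation is ignored.
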