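# Methods

This note documents the models, rules and numerical choices behind
`senprof`, and what the synthetic benchmark does and does not show.

## Expression handling

Bulk profiles are TPM-normalized from raw counts and explicit gene
lengths: per sample, rpk = count/(length/1000) and
tpm = rpk·10⁶/Σrpk, so columns sum to 10⁶ exactly. TMM-style
compositional correction is not applied; TPM is computed directly from
counts, which marginally affects absolute expression gates but not the
pipeline's logic. The "expressed" gate is strict — a gene counts as
expressed only when its *population-mean* TPM exceeds 1. The mean (not
a per-replicate majority) was chosen for continuity with the
interaction score, which is likewise a product of population means;
the gate threshold is configurable.

Differential-expression tables are inputs, not something this package
fits: direction calls use adjusted *p* < 0.05 with the sign of log₂FC.
The lipid-panel extraction keeps panel genes significant in ≥ 3 of the
12 Sen-vs-NSen comparisons and returns the log₂FC heat-map matrix.

## Enrichment statistics

All over-representation tests are one-sided hypergeometric upper tails
computed through log-gamma-based routines, so gene universes of tens
of thousands of genes cannot overflow. One-sidedness is a deliberate
reading of "enrichment"; a two-sided Fisher's exact (point-probability
method) is provided for contingency uses. Benjamini–Hochberg is the
step-up q_(i) = min_(j≥i) p_(j)·m/j, capped at one, returned in input
order.

The minimum-hypergeometric (mHG) statistic takes the minimum
enrichment tail over all list prefixes n′ ∈ [1, N−1]; ties resolve to
the smallest prefix (the literature leaves this open; smallest is the
conservative, deterministic choice). Its exact p-value counts lattice
paths from (0,0) to (N,B) that avoid cells whose tail is ≤ the
observed minimum, using exact integer arithmetic — feasible to
N = 10,000 — and is validated in the tests against complete
enumeration of all orderings for N ≤ 12. Fisher's product method for
two p-values is the χ²₄ tail of −2(ln p₁ + ln p₂); zero inputs are
clamped to the smallest positive float with a warning.

## SASP definition and profiling

A SASP gene for one comparison is upregulated (adjusted *p* < 0.05,
log₂FC > 0) *and* supported by at least one secreted/extracellular
evidence source. Evidence is a plain boolean table (the original
sources — GO:CC, protein-knowledge bases, experimental SASP reports —
are database-version-dependent, so no live queries are made; the
synthetic generator emits its own evidence table). Selection is
monotone in both the significance threshold and the evidence columns.
GO:MF classification uses a fixed 12-category vocabulary (adhesion
molecule, chemokine, complement component, cytokine, enzyme, enzyme
regulator, extracellular matrix constituent, growth factor, hormone,
ligand, proteinase, receptor); unmapped genes are "unclassified" and
counts are conserved.

For the ageing comparison, genes are ranked by sign(log₂FC)·(−log₁₀ p)
descending (the ranking metric is configurable; the protocol leaves it
open) and the ageing set's membership vector feeds the mHG machinery.

## TF activity consensus

Evidence streams per TF and comparison:

1. *Regulon over-representation* — hypergeometric tail of DE genes
   (up ∪ down; joint by default, split available) among regulon
   targets, BH across TFs.
2. *Upstream-regulator z* — Fisher's exact overlap p plus an
   activation z in which each called target is weighted by its |log₂FC|
   rank (w ∈ (0,1]); with equal weights this reduces exactly to the
   unweighted statistic. If > 90% of called targets share one DE
   direction, the stream is flagged biased and only counts when
   |z| > 2 — the analysis-bias guard of upstream-regulator tools.
3. *Own differential expression* of the TF.
4. *Chromatin accessibility* — a pooled two-proportion z of motif
   frequency in opened vs closed differential peaks, with a motif
   q-value from Fisher's exact + BH.

The signed activation statistic is z = (n_cons − n_incons)/√n over
called targets, where consistency means up-with-activating or
down-with-inhibiting edges. The 5-level status map: both streams
agreeing with |z| > 2 each give the full call; agreement with weaker
support, or a single stream with |z| > 1, gives "possibly"; sign
disagreement or uniformly weak evidence (all |z| ≤ 1) is
unknown/contradictory. The "possibly" band (1 < |z| ≤ 2) and the
one-level downgrade on own-expression discordance are documented
interpretations — the protocol names only the |z| > 2 criterion and a
narrative correction step.

Trust adds one point each for: stream-1 adjusted p < 0.05, stream-2
p < 0.05, full status, both z streams unidirectional with |z| > 2,
concordant own DE, and accessibility validation (|z_a| > 2, motif
q < 0.05, concordant direction). Retention requires average trust
strictly > 1 across comparisons. Cluster mapping keeps (TF, cluster)
pairs enriched (FDR < 0.05) in ≥ 8 of 12 comparisons and scores one
point per attribute strictly above the within-cluster 75th percentile
(linear-interpolation quantile; with all-equal attributes no points
are possible), plus a literature flag that is always an explicit input
column, never inferred. The SASP variant scores % secreted among
targets, comparison counts at raw and adjusted p < 0.05, −log₁₀ mean
p and average trust, plus a motif-in-SASP-promoter point, and selects
score ≥ 2 with ≥ 3 adjusted-significant comparisons.

## Ligand–receptor reconstruction

The receptor→TF step is an absorbing random walk on the expressed
subgraph: nodes with mean TPM ≤ 1 are removed, expressed TFs absorb,
and from node u the walk moves to out-neighbour v with probability
proportional to v's mean TPM. Absorption mass is accumulated for at
most 10 steps; a receptor regulates a TF when its absorption
probability reaches 0.1. The walk formulation, TPM-proportional
transitions, 10-step cap and 0.1 threshold are this package's explicit
parameterization of the single-cell method it adapts (the original
leaves them to its implementation); all are config keys, and the
operation is isolated so an alternative kernel can be swapped in.

Interactions require (1) an expressed receptor that regulates ≥ 1 TF,
(2) an expressed ligand, (3) scaffold membership. The score is
mean-ligand × mean-receptor TPM. The null permutes population labels
across the entire sample collection (not merely within the
sender/receiver pair): each of the 100 permutations draws pseudo
sender and receiver groups of the original sizes from the relabelled
pool, and significance requires the observed score to be at least
2 s.d. (ddof = 1) above the permutation mean. A zero-spread null with
observed equal to the mean is not significant. Under exchangeable
populations the flagged fraction sits near the one-sided 2 s.d. normal
tail (measured ≈ 2.4% across 2,400 interactions).

## Pathway impact

Perturbation factors solve PF = (I − B)⁻¹ΔE with
B(g,u) = β(u→g)/N_ds(u); a singular system (unit-weight cycle) is
reported as an error naming the pathway. ΔE is the log₂FC of the
interaction's DE target TFs (non-DE genes are zero). pNDE is the
hypergeometric tail of the interaction's DE-target overlap with the
pathway inside the reference universe — the target TFs of all
reconstructed interactions, so the universe does not collapse onto the
few DE-rich channels. pPERT is the (count + 1)/(n + 1)-smoothed
two-sided bootstrap tail of |tA| under random re-assignment of the
observed ΔE values to pathway genes (2,000 draws by default), uniform
under a null assignment by construction. pG combines the two by
Fisher's product; pGFdr applies BH across pathways per interaction.
Ratios divide each pathway's activating/inhibiting interaction counts
by all analysed interactions, and top-8 selection breaks ties by
pathway id for determinism.

## ATAC promoter accessibility

Peak scores follow the three-step TPM computation exactly; promoter
selection demands the "promoter-TSS" annotation *and* a nearest
covered base within TSS ± 1,000 bp under 0-based half-open
coordinates. The MA filter takes the mean of the two group means
(strictly > 5; the "either group" alternative is a config switch), and
M = log₂((B + ε)/(A + ε)) with ε = 0.5 pseudo-score to guard zero
scores. The group average precedes the MA filter — the protocol is
ambiguous on the order, and filtering on group-averaged scores is the
stabler choice. Differential peaks use the consumed peak-level DE
table at adjusted *p* < 0.1 and |log₂FC| > 1, both strict.

## Synthetic world

Counts are negative binomial in the mean–dispersion parameterization
(variance μ + φμ²), matching the model family behind the consumed DE
tables. Defaults: 1,200 genes; 36 population conditions (3 cell types ×
{Sen, NSen, basal} × 2 timepoints × 2 ages) × 4 replicates; dispersion
0.05 (typical of homogeneous sorted bulk populations at moderate
depth) with mean counts in the hundreds-to-thousands per gene; planted
effects at log₂FC = 2 (secreted SASP program of 40 genes, 6 activated
and 6 inhibited TFs with concordantly shifted regulons and concordant
own expression) and log₂FC = 3 for the 8 planted channel ligands.
Planted TF regulons avoid the planted SASP genes (except the
designated driver, which regulates them with activating edges) so the
planted programs cannot cancel one another. The signalling graph is a
receptors → 3 intermediate sublayers → TFs DAG with forward skip
edges; planted channel receptors signal directly into a planted TF
program (alternating activating/inhibiting, emulating dedicated
inflammatory channels), and other receptors also carry a few shallow
receptor→TF routes so reconstructed interactions span the TF layer.
ATAC promoter peaks sit within ±1 kb of their gene's TSS by
construction; 30 promoters carry ±2 log₂FC accessibility shifts tied
to planted TF targets, and motif hits of planted TFs concentrate in
the correspondingly shifted peaks. The DE stand-in is Welch's t on
log₂(TPM + 1) with BH — generator-internal plumbing, not a DE method.

All generators are pure functions of (config, seed); serialization is
byte-identical under a fixed seed.

What the benchmark shows: the pipeline's rules are implemented
faithfully (oracle equivalence, rule tables), its permutation null is
calibrated, and under strong, cleanly planted effects it recovers
≥ 90% of planted channels, TF activities, SASP genes and promoter
shifts with few false calls. What it does not show: robustness to
batch effects, compositional distortion beyond what TPM induces,
regulon misannotation, or the weaker and correlated effect sizes of
real tissue data — the generator's populations are exchangeable up to
the planted shifts, which real sorted populations are not.

## Problem sizes

The default test-and-acceptance configuration uses 1,200-gene worlds,
20-seed replications for calibration/recovery studies, 100
permutations for the interaction null and 200–2,000 bootstrap draws
for pPERT; the full suite plus the acceptance script completes in a
few minutes on one CPU. These sizes are the package's chosen
benchmark scale; every routine accepts larger configurations
unchanged.

## Known limitations

* The Markov-chain kernel is one documented formulation of the cited
  single-cell method's transduction step; absorption probabilities at
  threshold 0.1 are sensitive to hub TFs with high expression.
* pPERT carries little information when an interaction's DE targets
  cover a whole pathway (every re-assignment reproduces the observed
  accumulation); pNDE dominates in that regime, as in the original
  SPIA when a pathway is saturated.
* The upstream-regulator stream is an open, documented equivalent of a
  commercial tool; on real data its TF lists will differ from that
  tool's.
* Evidence, scaffold, regulon, pathway-topology and literature-flag
  tables are consumed as-is; their curation quality bounds the
  biology, and none are fetched from live services.
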