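# senprof

Downstream profiling of in-vivo senescent cells from bulk expression,
chromatin accessibility and network data.

During tissue regeneration, senescent cells (Sen) arise in several cell
populations — satellite cells (SC), fibro-adipogenic progenitors (FAP)
and myeloid cells (MC) — and reshape their niche through the
senescence-associated secretory phenotype (SASP). Characterizing this
state from sorted bulk profiles requires a chain of bespoke downstream
computations that no single package provides. `senprof` implements that
chain as a tested, reusable library with a CLI, exercisable end to end
on a built-in synthetic-data generator with planted ground truth:

* **SASP definition and profiling** — per Sen-vs-NSen comparison, the
  SASP is the set of upregulated genes (adjusted *p* < 0.05,
  log₂FC > 0) with secreted/extracellular evidence from at least one
  source, classified into 12 GO:MF categories and profiled by
  hypergeometric over-representation (BH, FDR < 0.05).
* **Consensus TF activity** — four evidence streams per transcription
  factor (regulon over-representation, a weighted upstream-regulator
  activation *z* with a direction-bias guard, the TF's own differential
  expression, and motif prevalence in opened vs closed chromatin)
  combine into a 5-level activity call and a 0–6 "trust" score; TFs
  with average trust > 1 survive, and recurrent TF–cluster mappings
  (≥ 8 of 12 comparisons) are ranked by upper-quartile points.
  The signed-regulon statistic is
  *z* = (n₊ − n₋)/√(n₊ + n₋), where n₊ counts targets whose DE
  direction matches the edge sign.
* **Ligand–receptor networks from bulk profiles** — an interaction
  (sender, ligand, receptor, receiver) is reconstructed when the ligand
  and receptor exceed the strict 1 TPM gate and the receptor regulates
  at least one expressed TF under a Markov-chain random walk on the
  signalling graph (transitions proportional to target TPM, expressed
  TFs absorbing). Scores are products of population-mean expressions;
  significance requires the observed score to sit ≥ 2 s.d. above the
  mean of 100 label-permutation scores.
* **Pathway impact (SPIA-style)** — per interaction, DE target TFs
  perturb signed pathway topologies:
  PF(g) = ΔE(g) + Σᵤ β(u→g)·PF(u)/N_ds(u), tA = Σ(PF − ΔE);
  pNDE (hypergeometric) and pPERT (2,000-draw bootstrap of |tA|)
  combine by Fisher's product, pathways pass at pGFdr < 0.05, and
  per-pathway activating/inhibiting interaction ratios are reported
  (top 8 per direction).
* **Promoter accessibility** — ATAC peak counts are TPM-normalized
  (reads per kilobase over a per-million scaling factor), peaks
  annotated "promoter-TSS" within TSS ± 1 kb are group-averaged, and MA
  summaries count |log₂FC| > 1 peaks among those with average signal > 5.
* **Ageing comparison** — the minimum-hypergeometric (mHG) statistic
  over the DE-ranked gene list, with an exact path-counting p-value,
  quantifies overlap with ageing signatures.

## Worked example

Simulate a world (1,200 genes, 36 population conditions × 4 replicates,
40 TFs with 6 planted activated and 6 planted inhibited, 8 planted
communication channels, planted promoter shifts) and run the chain:

```bash
senprof simulate --out demo/ --seed 1
senprof sasp     --data demo/ --seed 1
senprof ligrec   --data demo/ --seed 1
senprof tf-consensus --data demo/ --seed 1
senprof spia     --data demo/ --seed 1
senprof atac     --data demo/ --seed 1
senprof aging-mhg --data demo/ --seed 1
senprof report   --data demo/
```

On seed 1 this prints (via the stage logs and output tables):

* `sasp` — 56 SASP genes for the `SenVsNSen.SC.3dpi.old` comparison
  (the 40 planted secreted genes plus collateral regulon targets that
  genuinely carry secreted evidence).
* `ligrec` — 120 candidate interactions, 21 significant; the top
  record `FAP.Sen.3dpi.old → (G0068, G0057)` scores 1.01e7 against a
  permutation null of 1.73e6 ± 5.4e5, i.e. > 15 s.d. above the mean.
* `tf-consensus` — 13 TFs retained at average trust > 1, covering all
  12 planted TFs.
* `spia` — pathway `PW01` (the planted activated program) is top
  activated with interaction ratio 0.32; `PW02` (the planted inhibited
  program) is top inhibited at 0.37.
* `atac` — of 300 promoter peaks, 15 open (M > 1) and 10 close
  (M < −1) at signal > 5, matching the planted shifts.
* `aging-mhg` — the synthetic ageing signature reaches mHG = 1.8e-9 at
  rank 123 with exact p = 4.4e-8.

Every stage writes a JSON manifest; identical config and seed reproduce
byte-identical outputs.

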