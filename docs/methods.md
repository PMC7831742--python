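# Methods

## The screening model

The pipeline operationalizes a three-part definition of a candidate
cis-acting lncRNA: (i) the lncRNA is significantly deregulated in tumors
versus matched normals in two independent cohorts, in the same direction;
(ii) its gene body lies within 1.5 kb of a protein-coding gene (or
overlaps it); (iii) that neighbor is also deregulated in both cohorts with
its own consistent direction. Discordant pairs (lncRNA and neighbor moving
in opposite directions) are ranked first because region-level passenger
events — copy-number alterations, large-scale epigenetic changes — tend to
move neighboring genes *together*; discordance is therefore the signature
least compatible with a passenger explanation and most suggestive of
direct cis-regulation. Concordant and mixed pairs are retained and
labeled rather than dropped, since they remain interpretable (mixed pairs
can only arise if the direction-consistency requirement is relaxed; the
class is kept for completeness).

## Statistical procedures

**Paired test.** The primary test is the two-sided Wilcoxon signed-rank
test on matched tumor/normal values. Zero differences are dropped
(classic Wilcoxon; Pratt's treatment of zeros is out of scope) and tied
absolute differences receive average ranks. For ≤ 25 nonzero differences
the p-value is exact: average ranks are halves of integers, so doubling
them makes every achievable W⁺ an integer and a subset-sum dynamic program
counts the sign assignments reaching each value — the same distribution
full enumeration would produce, at polynomial cost. Larger samples use
the normal approximation with continuity correction and the standard tie
correction of the null variance (delegated to scipy). A paired t-test is
available behind a switch for comparison with analyses that used it; the
rank test is the default because expression units are heavy-tailed and
the test is invariant to monotone transforms, making the RPKM-vs-log2
question moot for inference.

**Fold change.** FC = (mean(tumor) + c) / (mean(normal) + c) on the
linear scale with pseudocount c = 0.01 RPKM. Ratio-of-means is the most
common convention; the pseudocount guarantees finiteness for genes
unexpressed in one condition and is far below biologically meaningful
expression, so it does not distort calls. Both the convention and c are
configurable; per-pair ratio averaging was considered and rejected as the
default because single dropout pairs dominate it at low expression.

**Multiple testing.** Benjamini–Hochberg step-up q-values
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1), computed once across all genes in
a cohort — lncRNA and protein-coding together, since the deregulation
test is applied to both classes jointly; per-biotype adjustment is
available via the `bh_groups` argument. Deregulation requires q < α
strictly (α = 0.05) *and* |log2 FC| ≥ log2 1.5.

**Two-group contrasts.** Stage (I vs II) and tertile comparisons use the
two-sided Mann–Whitney U test: exact by enumeration of all C(n, n₁) group
assignments when n ≤ 12, tie-corrected normal approximation with
continuity correction otherwise. Two-sided p-values for all exact tests
are twice the smaller tail probability, capped at 1 — the convention that
matches doubling-based tables and keeps the p-value well defined under
asymmetric tie structures.

**Correlation.** Spearman's ρ is the Pearson correlation of average
ranks. For n ≤ 9 the p-value is exact from the permutation distribution
of ρ over all n! orderings; above that, the t-approximation. Correlation
and tertile contrasts are computed over tumor samples only by default
(the question is co-variation *within* tumors); an all-samples mode
exists behind a flag but conflates the tumor/normal shift with
within-group association.

**Tertiles.** Samples are ranked by the splitting variable; the bottom
and top floor(n/3) form the contrast groups and the middle is discarded.
Ties are broken by sample identifier so the split is deterministic; a tie
spanning a tertile boundary triggers a warning since membership then
hinges on that arbitrary order.

**qPCR.** Replicate Ct values are averaged per (gene, condition) before
differencing — the standard 2^−ΔΔCt convention (per-replicate RQ
averaging differs only at second order in the noise and is not
implemented). ΔΔCt is taken against the non-targeting siRNA condition,
not untreated cells, so the baseline controls for transfection itself.
Fold reduction is reported as 1/rq when rq < 1.

## Genomic conventions

GTF coordinates are 1-based inclusive and kept so internally. The gap
between two gene bodies is the number of bases strictly between the
intervals: overlapping intervals have gap 0, as do immediately adjacent
ones (no bases separate them), and that case is classified as `overlap`
so that gap 0 and the overlap relation coincide exactly. The 1.5 kb rule
is applied to gene bodies, not promoters: the screening criterion is
interval proximity ("overlap or closely neighbor"), and a TSS-anchored
variant would need strand-aware promoter definitions that the criterion
does not specify. Strand is recorded for reporting but never used as a
filter — cis-regulation operates at same- and opposite-strand loci alike.
Biotypes are collapsed to {lncRNA, protein_coding, other} with
{lncRNA, lincRNA, antisense, sense_intronic, sense_overlapping} → lncRNA;
`processed_transcript` is excluded by default (it also covers non-lnc
fragments) but the set is configurable because annotation releases
differ. A lncRNA with several qualifying neighbors yields several pairs;
no best-partner collapsing.

## Synthetic data generator

The generator emulates the statistical structure the screen assumes, with
defaults chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients_a`, `n_patients_b` | 36, 54 | tumor/normal pairs per cohort (discovery/validation sizes) |
| `n_genes` | 500 | annotation size |
| `frac_lnc` | 0.3 | lncRNA fraction (plus 5% "other" biotypes) |
| `n_planted_pairs` / `n_decoy_pairs` | 3 / 3 | discordant cis-pairs with effects / neighbor pairs without |
| `n_planted_singletons` | 20 | isolated deregulated genes (background hits) |
| `effect_fold` | 4 | planted tumor fold change |
| `coupling` | 0.8 | within-tumor anti-correlation strength |
| `noise_sd` | 0.5 | residual log2 sd per gene and sample |
| `methyl_coupling` | 0.8 | logit-scale beta↔lncRNA coupling |
| `gap_range` | [0, 1500] bp | planted neighbor gaps |
| `stage_effect` | 0.5 log2 | extra shift in stage-II tumors |

Baseline log2 means are N(5, 1.5²) per gene — a typical RPKM dynamic
range — and are drawn from a child seed independent of the cohort label,
so planted effects replicate across cohorts by construction. Normal
samples are log2-normal around the baseline; tumor samples add
±log2(effect_fold) for planted genes (lncRNA down, partner up, mirroring
the locus that motivated the screen). Anti-correlation is induced by a
per-tumor latent factor z ~ N(0,1) loading the two pair members with
opposite signs, scaled λ = noise_sd·√(c/(1−c)) so the expected
within-tumor correlation magnitude equals the coupling c independently of
the marginal effect size (at c = 1 the residual noise on pair members is
dropped instead). Stage labels are balanced I/II per patient; stage-II
tumors shift planted pair genes a further `stage_effect` in their planted
direction, so the lncRNA decreases and the partner increases with stage.
Methylation betas are logistic(a + methyl_coupling·z(lnc) + ε) with
a = logit(0.3) and ε ~ N(0, 0.3) for planted partners, and
logistic(a + ε) for all other genes — betas are guaranteed in [0,1] and
high-lncRNA tumors carry higher partner methylation. qPCR plates are
back-constructed: Ct(gene, condition) = base + per-condition shift +
ΔΔCt(gene, condition) + replicate noise, with the reference gene at Ct 12
(ribosomal-RNA territory), targets at 25, triplicates, noise sd 0.05
cycles, and a per-condition shift that cancels in ΔCt as pipetting/load
differences would. The default knockdown fixture plants a 3.42-fold
knockdown and a 1.57-fold readout increase at the high siRNA dose, with
weaker effects at the low dose and a suppressed GAPDH in the
positive-control condition.

All randomness derives from one global seed; each stage hashes a text
label (`"annotation"`, `"cohort:a"`, …) into a child seed, so adding a
stage never perturbs earlier draws and outputs are byte-identical across
runs.

**What the generator does not emulate:** mean–variance coupling and
count noise of real RNA-seq, correlated gene programs beyond the planted
pairs, batch and purity effects, realistic methylation probe structure,
copy-number-driven concordant neighbors, or primer-efficiency deviations
from the ideal doubling assumed by 2^−ΔΔCt. Passing tests therefore show
the pipeline's logic and statistics are correct under its stated
assumptions, not that those assumptions hold for any particular real
cohort.

## Numerical and design notes

- Exact-test tails use an absolute tolerance of 1e-9 when counting
  assignments "as extreme", guarding against float jitter in average
  ranks; the dynamic program itself is integer-exact.
- The proximity join runs through pyranges with slack = max_gap + 1 and
  re-filters on the exactly computed gap, so the library's half-open
  convention cannot introduce boundary errors.
- All-zero difference vectors yield p = 1 with a warning (no evidence,
  not an error); constant inputs to Spearman yield ρ = NaN with a warning.
- Analysis stages are seed-free and deterministic; the only randomness in
  the package lives in the generator. Run outputs (TSV/JSON) avoid
  timestamps — only the audit log carries them — so reruns are bitwise
  reproducible.
- Problem sizes in the test suite and acceptance script (500–1000 genes,
  20 replicate seeds, 30–54 pairs) were chosen as the smallest sizes at
  which the planted effects and error rates are meaningfully estimable.

## Known limitations

- The screen is marginal per gene: no joint model across the pair, no
  copy-number covariate; discordance is a heuristic filter for passenger
  effects, not a causal test.
- Gene-body distance is a proxy for regulatory reach; enhancer-like
  lncRNAs acting at longer range are out of scope by design.
- With multiple probes per gene the methylation input must already be
  summarized to one beta per gene (mean by convention, median if the
  caller prefers); probe-level array processing is not implemented.
- The exact Wilcoxon branch is quadratic in the number of pairs via the
  dynamic program and switches to the asymptotic test above 25 nonzero
  differences; for cohorts in between, exact and asymptotic p-values can
  differ in the third decimal.
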