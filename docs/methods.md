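# Methods

This note documents the models, rules and numerical choices behind
`lineagespec`, and what the synthetic study does and does not emulate.

## Study design and quantification

The pipeline analyses cell-type transcriptomes of early embryogenesis: egg
cell (EC), zygote at 14 h and 24 h after pollination (Zy14, Zy24), apical
and basal daughter cells of the zygote (AC, BC), and embryo proper /
suspensor of the 32-cell proembryo (32E, 32S), each with ≥ 2 (default 3)
biological replicates. Inputs are gene-level integer counts with transcript
lengths; expression is FPKM:

    FPKM(g, s) = count(g, s) · 10⁹ / (length(g) · total(s)).

A gene is "expressed" in a cell type when its mean FPKM over replicates
reaches 1. Both the strict (>) and non-strict (≥) reading of that cutoff
occur in practice, so strictness is a flag (`strict`, default ≥); the mean
over replicates (rather than a per-replicate rule) is used because the
classifications downstream are defined on mean profiles. All-zero genes are
never expressed regardless of the threshold.

Size factors are median-of-ratios: per gene the geometric mean across
samples (genes with any zero excluded, the zero-safe convention), per
sample the median ratio to it, rescaled to geometric mean 1. This is used
only by the DE test; FPKM uses raw totals.

## Negative-binomial Wald test

Counts are modelled as NB with Var(K) = μ + αμ². For a contrast A:B:

- **Dispersion.** Per gene, method-of-moments on size-factor-normalized
  counts within each group, α̂ = (s² − μ̄)/μ̄², averaged across the two
  groups and floored at α_min = 10⁻⁸. A per-gene estimate at 3 replicates
  has ~4 degrees of freedom; plugging it into a normal-reference Wald
  statistic is badly anticonservative (the t-versus-normal effect yields a
  type-I rate of ~0.12 at nominal 0.05). Each gene-wise estimate is
  therefore additionally floored at the across-gene median estimate
  (`global_floor=True`). This is a conservative data-driven floor in the
  spirit of the max(gene-wise, pooled) rule of early NB DE methods — not
  empirical-Bayes shrinkage: large dispersions are never pulled down. With
  it, the measured null fraction of p < 0.05 at α = 0.1, 5000 genes, 3 vs 3
  is ≈ 0.05 (the acceptance script recomputes this).
- **Statistic.** log₂FC = log₂((m_A + c)/(m_B + c)) on normalized group
  means with pseudo-mean c = 0.5 (bounds the fold change at zero means
  without dropping genes); SE by the delta method from
  Var(mean of K_s/f_s) = (μ·Σ1/f_s + n·αμ²)/n²; p from the two-sided normal
  tail of z = log₂FC/SE. In the α→0 limit this reduces to a Poisson Wald
  test (tested).
- **Calling.** DEG = fold change ≥ 2 (ratio scale, i.e. |log₂FC| ≥ 1) and
  BH-FDR < 0.01. The fold-change scale is normalized counts; whether the
  original analyses thresholded FPKM or normalized-count ratios is not
  determinable, and for equal gene length the two coincide.

No shrinkage, covariates, outlier replacement or independent filtering.

## Lineage-maintained genes, fate classes, profile groups

- ACL-maintained = up(AC:BC) ∩ up(32E:32S); BCL-maintained =
  down ∩ down. The definition does not additionally require a floor of
  expression in the favored lineage; none is imposed.
- Each AC:BC DEG (favored daughter D, other daughter O, mean FPKM profiles)
  is assigned one mechanism, first match wins:
  1. inherited_asymmetric: Zy24 ≥ high ∧ max(32E, 32S) < negligible;
  2. de_novo: Zy24 < negligible ∧ D ≥ high;
  3. selective_deletion: Zy24 ≥ high ∧ D ≥ high ∧ O < negligible;
  4. unclassified otherwise.
  "High" and "negligible" have no standard numeric values; the defaults
  high = 5 FPKM and negligible = 1 FPKM (the expressed cutoff) are
  config-exposed (`--fate-high`, `--fate-negligible`). Class membership is
  monotone in each threshold (tested by sweep).
- Profile groups: per-gene mean-FPKM profiles over the seven cell types are
  z-scored (shape, not level) and clustered by average linkage on Euclidean
  distance, cut at k = 4 (ACL), 3 (BCL), 3 (embryo-activated) by default.

## Global structure

Pearson correlation on log₂(FPKM+1) across the union of expressed genes;
UHC by average linkage on 1 − r; PCA of gene-centered transformed values
with samples as observations. The transform, linkage and distance are the
common defaults for transcriptome QC and are overridable. The sample set
for structure plots is the five DE cell types (Zy24, AC, BC, 32E, 32S — 15
samples at 3 replicates), matching the contrasts analysed.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for k query hits of a K-member term
in an N-gene universe with query size n, BH step-up across tested terms.
The universe defaults to genes expressed in any relevant cell type, the
defensible choice when no universe is given with the annotation. Terms with K < 2 in the
universe are skipped (untestable singletons only inflate the correction).
"FDR method" is read as Benjamini–Hochberg.

## TF networks

Promoter window −500..+100 nt around the TSS (1-based inclusive
coordinates internally; BED output is 0-based half-open). On the − strand
the window mirrors the + strand definition. PWMs in probability form are
scanned as log₂-odds against a uniform background on both strands; N
contributes 0; the default per-motif cutoff is 80% of the maximum
attainable score (common PWM practice, config-exposed). Per-TF enrichment
tests {genes with ≥ 1 window hit} against the DEG set within the universe,
BH across TFs. An edge tf→gene requires TF enrichment FDR < 0.05 (the
conventional cutoff), a window hit, and Pearson r > 0.87 between
the TF's and the target's mean-FPKM profiles — 0.87 is the
cluster-coexpression cutoff, reused for TF–target similarity. Removing any evidence source can only add edges
(anti-monotone; tested).

## lncRNA and alternative splicing

Candidate filter: transcripts < 200 nt are removed; single-exon
transcripts overlapping a same-strand coding exon are removed; multi-exon
sense-overlapping transcripts are retained and later classed "sense" —
a filter that removed every coding-overlapping transcript outright would
contradict the existence of a sense lncRNA class, hence this resolution. Context: sense (same-strand exonic
overlap with a coding gene), antisense (opposite strand only), intergenic.

Consensus call: noncoding iff ≥ 4 of 5 scorers vote noncoding. Three
scorers are built in:

- **ORF**: noncoding iff the longest ATG-initiated ORF over 6 frames is
  < 100 codons (stop codon included in the count);
- **hexamer**: noncoding iff the mean log-ratio of hexamer frequencies
  (coding vs noncoding training tables, trainable from any sequence sets)
  is < 0;
- **stop density**: noncoding iff the in-frame stop density of the best
  forward frame (the frame holding the longest forward ORF; frame 0 when
  no ORF exists) exceeds 0.03 stops/codon — a coding transcript's ORF
  frame is nearly stop-free while random sequence runs at ≈ 3/64 ≈ 0.047.

External per-tool calls can be supplied as extra boolean TSV columns; the
pipeline combines the three built-ins with two external columns to reach
the 5-vote rule.

AS events are classified pairwise between expressed isoforms (FPKM ≥ 1)
of one gene within their shared genomic span: differing introns are grouped
into overlap-connected components and each component is classified as exon
skipping (one intron of one isoform spanning two introns plus the skipped
exon of the other, outer boundaries matching), intron retention (an intron
of one entirely exonic in the other), alternative donor / acceptor (a
shared intron differing only at its 5′ / 3′ boundary — donor and acceptor
are defined in transcription orientation, so the genomic side flips with
strand), and complex otherwise (this is the fifth observed category).
Classification is invariant to isoform order, and strand mirroring swaps
donor and acceptor (both tested). Pairwise comparison (rather than
comparison against a merged reference model) was chosen as the simpler,
well-defined convention.

## Synthetic-data generator

The generator is the package's test bed: it emulates the study design and
plants every structure the pipeline is supposed to find.

- **Counts.** NB via gamma-Poisson: K ~ Poisson(Gamma(1/α, αμ)). Null genes
  have flat count means ~ LogNormal(log 100, 1). Planted classes are
  specified as expected-FPKM profiles so the fate thresholds hold by
  construction; the library size T solves
  T = Σ_null(baseline) / (1 − Σ_planted(f·len)/10⁹), which makes planted
  count means f·len·T/10⁹ realize the planted FPKM in expectation. Gene
  lengths are uniform 500–5000 nt (exercising length normalization);
  per-sample size factors are log-uniform in [0.7, 1.4] (exercising
  normalization); per-gene multiplicative jitter (lognormal, σ = 0.25)
  varies planted levels without changing profile shape.
- **States.** The canonical "on" state is 150 FPKM, "off" 0.1 FPKM and the
  post-turnover "deleted" state 0.15 FPKM — chosen a priori well clear of
  the fate cutoffs (5 and 1 FPKM) so each class's defining inequalities
  hold with margin for 3-replicate means. Maintained-group asymmetry is
  2^planted_log2fc (default 8-fold); planted_log2fc = 0 produces flat
  profiles (the null case). Fate-class genes are AC:BC DEGs but designedly
  not 32E:32S DEGs, keeping the fate classes disjoint from the maintained
  intersection rule, as their definitions require.
- **Noise level.** The default dispersion is α = 0.03, calibrated so that
  within-cell-type replicate correlation of log₂(FPKM+1) profiles matches
  the r ≥ 0.95 replicate agreement expected of high-quality isogenic
  libraries (measured ≈ 0.96 across
  seeds). This is low-dispersion territory appropriate for isogenic,
  tightly staged material; calibration simulations for the DE test use
  their own α explicitly.
- **Promoters and motifs.** Every gene gets a 601-nt window; each planted
  TF's sharp consensus PWM (match probability 0.91, so only the exact
  consensus clears the 80% cutoff) is embedded exactly once per target
  window, in transcription orientation, at a uniform random offset. With
  `clean_background` (default) the background is redrawn until no motif
  consensus occurs anywhere else on either strand — including matches
  straddling insert boundaries — so planted hits are provably the only
  hits and network recovery can be checked exactly. Decoy TFs carry motifs
  but no targets. Background mode (`clean_background=False`) reproduces
  the closed-form exact-match rate 2·(L−w+1)/4^w per window (tested).
- **Transcripts.** AS genes carry two isoforms differing by exactly one
  planted event of a known type (donor/acceptor constructions mirrored on
  the − strand); lncRNAs are planted per context with filter-fodder (short
  and single-exon sense transcripts) that the candidate filter must
  remove; a subset of minor isoforms is expressed only in one lineage at
  both stages. Transcript sequences are generated directly (coding: a
  ≥ 150-codon GC-biased ORF; noncoding: rejection-sampled to < 100
  codons); hexamer tables are trained on separate sequence sets drawn the
  same way. A synthetic external-votes table (two stand-in coding-potential
  tools, truth flipped at 2% error) completes the 5-vote rule.
- **Annotation.** One planted enriched term per lineage (60 maintained
  genes + 15 random) among random background terms.

**What passing tests do and do not show.** The generator's planted effects
are strong, its noise is idealized NB with independent genes, promoter
background is i.i.d. uniform, and sequence composition is not genomic.
Recovery at these settings demonstrates correctness of the inference rules
and their implementation — not that the thresholds would achieve the same
sensitivity on real libraries, where dispersion varies per gene, effects
are graded, motifs are degenerate, and coding potential is harder to call.
Absolute set sizes in any real dataset (e.g. counts of maintained genes or
lncRNAs) depend on that data and external databases and are out of scope.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in well under a minute on one core: 2000 genes × 21 samples, 8 TF
regulons × 20 targets, 38 AS genes, 32 lncRNA candidates; calibration
simulations use 5000 genes at 3 vs 3. All sizes are config-exposed for
larger power studies.

## Known limitations

- The Wald test's median dispersion floor trades a little power at
  genuinely low-dispersion genes for type-I control; with many replicates
  (`global_floor=False`) the pure per-gene estimator is appropriate.
- Fate classification uses hard thresholds on mean FPKM; genes near a
  cutoff flip classes under resampling (the generator's margin analysis in
  the tests quantifies this).
- AS classification is pairwise; a reference-based (merged-model) analysis
  would report different event counts for genes with > 2 isoforms.
- The enrichment module does not propagate annotations up an ontology.
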