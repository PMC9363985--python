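# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the places where the design was genuinely open.
No empirical number appears here that the test suite or the pipeline does
not itself compute.

## 1. Count model and differential expression

Counts are modelled as negative binomial, y_gj ~ NB(μ_gj, φ_g), with
log μ_gj = β_g,k(j) + log(N_j · f_j), where N_j is the library size
(column sum), f_j the TMM normalization factor, and k(j) the sample's
group (nuclear composition, stage, ...). Group means are fitted per gene
by Newton iterations on the log scale, vectorized across genes; contrasts
are tested by likelihood-ratio chi-squared statistics (df = number of
groups − 1).

**Dispersion.** φ_g is estimated by method of moments from within-group
residuals on the effective-library-size scale (Var = μ + φμ², pooled over
replicated groups with an n/(n−1) small-sample correction), then shrunk
toward an abundance trend — the mean raw dispersion in 20 quantile bins of
log mean CPM — with weight prior_df/(prior_df + residual df), prior_df =
10, and floored at 1e-6. This is deliberately simpler than
quasi-likelihood machinery; its adequacy is established behaviourally: the
test suite verifies type-I error at nominal p < 0.05 within [0.03, 0.07]
and near-uniform null p-values on 5000 simulated null genes, rather than
matching any external tool's internals.

**Multiple testing.** BH FDR at α = 0.05 wherever a "significant" call
feeds the classification hierarchy. The bias-gene selection rule is the
explicit exception: |log2FC| > 1 **and raw p < 0.05**, because that rule
is stated on raw p.

**Fold changes** are computed from normalized group mean CPM with a
0.5-CPM pseudo-abundance, group2 over group1.

## 2. Expression-mode classification

Performed on vegetative samples only: under sexual development the
fertile-vs-sterile difference between heterokaryons and homokaryons
confounds any nuclear-organization signal. Heterokaryon ratio groups are
labelled by inoculum (het90/het50/het10), but the additive expectation for
each sample uses that sample's **measured DNA ratio** — a missing measured
ratio is an error, never silently replaced by the inoculum label.

Decision tree, each level BH-corrected within the genes reaching it:

1. across all five compositions, analysis-of-deviance LRT; non-significant
   → **conserved**;
2. homoA vs homoa contrast; non-significant → **other_difference**;
3. per heterokaryon ratio group, observed counts vs the additive
   expectation E_gj = (d_j·q_A + (1−d_j)·q_a)·s_j used as the NB offset
   (one-df LRT on a common scale factor); no group deviating →
   **additive**. Additivity is tested per ratio group and combined as the
   union of deviations (pooling the groups would hide a deviation confined
   to extreme ratios);
4. for deviating genes the three ratio groups are pooled (dominance
   predicts one common mean at every ratio, so pooling maximizes power):
   indistinguishable from one homokaryon and distinguishable from the
   other → **dominant_A** / **dominant_a**;
5. significantly above / below both homokaryons → **over_dominant** /
   **under_dominant** (transgressive);
6. remainder → **intermediate** (deviates from additivity but fits no
   template).

The summary table reports nested counts with percentages relative to the
group one level higher.

## 3. Allele-ratio regression and co-regulation

Per gene, unweighted OLS of R on D (R = fraction of allele-assignable
reads from mat A; D = measured DNA ratio for heterokaryons, 0/1 for
homokaryons), with two-sided 95% t-based confidence intervals. Pairs with
fewer than 10 assignable reads are treated as missing; genes with < 3
informative points or constant D are flagged unestimable rather than
raising. Binomial-variance weighting exists behind a flag but is off by
default to match the plain-lm construction.

Filter order: (1) mismap filter — per gene, the fraction of homokaryon
reads assigned to the absent nucleus, maximized over homokaryon samples
with ≥ 10 assignable reads, must be ≤ 0.05; genes with no qualifying
homokaryon sample are dropped (no uniquely mappable reads); (2) homokaryon
slope filter — the homokaryon-based regression CI must contain 1;
remaining slope deviations there can only be mapping artefacts. With deep
libraries the slope filter is the stricter of the two (its CI tightens
with depth while the 5% threshold is fixed); this is expected behaviour,
not a defect. Heterokaryon regressions then use heterokaryon samples only
(homokaryon anchor points available behind a flag, off by default).

**Flags.** slope_ne_1 / intercept_ne_0 when the 95% CI excludes 1 / 0,
with direction. **Stage Z-scores** follow the verbatim construction:
z_slope(g) = (slope_sexual(g) − mean slope_sexual) / SD(slope_vegetative),
likewise for intercepts, |z| > 2 significant. This centers on the
*sexual* mean but scales by the *vegetative* SD; the arguably more natural
gene-wise vegetative centering is available via `center=
"vegetative_gene"` but is not the default, because the default reproduces
the stated construction. **Distribution comparison**: Mann-Whitney U,
exact when both samples have ≤ 20 values without ties, normal
approximation with tie correction otherwise.

## 4. Normalization

TMM with the canonical trims (30% of each M tail, 5% of each A tail),
inverse-asymptotic-variance weights, upper-quartile reference selection,
factors rescaled to geometric mean 1. The implementation was checked once
against the reference implementation on a frozen matrix (agreement ~1e-13)
and is continuously checked against a brute-force oracle in the tests.
Note TMM is only *asymptotically* invariant to depth-scaling a library:
the variance weights change with depth, moving factors by a few percent on
small matrices.

Cross-strain normalization: factors are computed on a joint matrix
restricted to orthologue clusters shared by all strains, but with each
library's **full-matrix** column sum as its library size — so a genuine
expression shift on the shared orthologues is corrected rather than
absorbed as depth — and the factors are attached back to each strain's
full count matrix.

Low-expression filter default: CPM ≥ 1 in ≥ 3 samples (the replicate
count); both configurable, since no threshold is canonical.

## 5. Clustering and PCA

The variance-stabilizing transform is a prior-count log-CPM
(prior 4, rescaled per library), a documented substitute for a
shrinkage-GLM regularized log: the clustering conclusions this package
supports are topological (which samples group), not numeric. Hierarchical
clustering uses Euclidean distances over genes and average linkage
(complete linkage behind a flag); node support is the percentage of gene
bootstrap replicates (resampling genes with replacement) in which the
node's exact leaf set recurs. PCA is centered-gene PCA via SVD; scores,
loadings and variance fractions are returned.

## 6. The synthetic generator: what it emulates, what it does not

Defaults encode the study design: 3 lineages × 2 stages × 5 nuclear
compositions (homoA, homoa, het at 90/50/10% initial mat A) × 3
replicates. Per gene: baseline log2-CPM ~ N(5, 2²); NB dispersion
lognormal(ln 0.05, 0.5²); library sizes lognormal around 5e6 (tests use
1e6 for speed, stated where done). 20% of genes carry a 4-fold homokaryon
mat difference, 30% a 4-fold stage difference; the heterokaryon mode mix
defaults to 1% dominant per direction and 0.5% transgressive per
direction, the remainder additive/conserved. Allele-ratio programs:
vegetative (β1, β0) = (1, 0) exactly; sexual β1 ~ N(0.6, 0.1²),
β0 ~ N(0.2, 0.05²), emulating sexual-stage dosage compensation.
Mismap rates ~ Beta(1, 30) (mean ≈ 0.032, a tail above the 5% filter);
assignable fraction 0.8; nuclear-ratio drift logit-normal with sd 0.3 and
no bias (free parameters — realized ratio distributions are not reported
anywhere); measured DNA ratio adds logit noise sd 0.02 emulating qPCR.

Generative chain per sample: realized r drawn on the logit scale around
the inoculum (homokaryons are fixed points); expected expression
E = r·μ_A + (1−r)·μ_a with dominant genes forced to the dominant
homokaryon's mean and transgressive genes to 2^±1 beyond the more extreme
homokaryon; totals NB at libsize-scaled means; allele-assignable reads =
round(0.8 × total), split binomially with mat A probability
clip(β0 + β1·r, 0, 1) contaminated by symmetric mismapping
p_obs = p(1−m) + (1−p)m. Truth tables record the *unclipped* line; the
default ratios 0.1–0.9 keep the linear regime for |β1| ≤ 1.25,
β0 ∈ [−0.1, 0.35].

Not emulated: read-level artefacts (FASTQ, positional bias), reference
bias beyond symmetric mismapping, correlated gene programs, batch
effects, GC/length effects. A green test on this generator therefore
establishes the statistical machinery under the assumed NB/binomial
world, not robustness to mapping pathology.

## 7. Degenerate inputs and tie-breaks

All-zero libraries abort normalization; genes with zero totals get mean
exactly 0 in the NB fitter (log-kernel terms vanish); the additivity
offset is floored at 1e-8 counts; dispersions floored at 1e-6; Newton
steps clipped to ±5 on the log scale. A 2×2 overlap table with a zero
margin (including the all-zero table from disjoint bias sets) reports a
missing test rather than raising. Zero vegetative SD makes stage Z-scores
undefined and is an error, as is asking for Z-scores from < 3 genes.

## 8. Known limitations

- The NB LRT with plug-in shrunken dispersions is mildly liberal at n = 3
  per group; calibration is verified globally, not per gene.
- The homokaryon slope filter's stringency grows with sequencing depth
  (see section 3); at very high depth it dominates gene loss.
- Bootstrap support for clusters is over genes only; no sample-level
  uncertainty is propagated.
- The Yates-corrected chi-squared is conservative relative to the exact
  conditional (permutation) null — by design; the uncorrected variant is
  available behind a flag.
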