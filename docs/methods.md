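# Methods

## The fine-mapping problem

Expression QTL mapping in Diversity Outbred (DO) mice localizes an
association to a marker whose eight founder-haplotype allelic effects are
estimated by the QTL scan, but linkage disequilibrium leaves tens of
candidate regulatory variants within a megabase of the marker.
`dofinemap` scores each candidate SNP residing in a founder-strain
ATAC-seq peak (a "local-ATAC-MV": a SNP whose genotype associates with the
local accessibility signal) by how well its founder-strain genotype effect
explains the DO allelic-effect pattern, integrating footprint disruption,
genomic distance, and cross-modality correlations as an empirical-Bayes
prior.

## Model

For association `g` with `p_g` candidate SNPs, a Bernoulli(γ) indicator
`V_g` says whether any candidate is causal and a one-hot
`Z_g ~ Multinomial(1, Θ_g)` picks the causal SNP, with
`Θ_g ~ Dirichlet(Π_g)`.

**Trinarization.** The 8-strain DO allelic-effect vector `Y_g` and the
founder expression vector `B_g` are min-max scaled to [0, 1], centered on
the reference strain B6, and coded +1 / −1 / 0 at a ±0.2 cutoff (strict
inequalities). A SNP's genotype-effect pattern codes the strains carrying
the alternative allele as sign(effect) when the marginal regression of
founder expression on genotype is significant at 0.05, else 0.

**Edit-distance likelihood.** Per-strain absolute differences between
trinarized patterns take values in {0, 1, 2} and are tallied separately
over the five classical strains (129, AJ, B6, NOD, NZO; Multinomial(5, a))
and the three wild-derived strains (CAST, PWK, WSB; Multinomial(3, b)).
Under `V_g = 1` the observed pattern is compared with the causal
candidate's genotype-effect pattern (parameters `a1, b1`); under
`V_g = 0` with the founder-expression pattern (`a0, b0`).

**Prior.** `Π_{g,k} = F + D + |cor(A,E)| + |cor(A,B)| + 1`, where `F` is
the footprint-impact flag, `D ∈ (0, 0.5]` the distance score,
`cor(A,E)` the Pearson correlation (8 strains) between the harboring
peak's ATAC signal and the SNP's genotype-effect vector, and `cor(A,B)`
that between the ATAC signal and founder expression. The distance score
is flat at 0.5 up to 0.25 Mb and decays as `(5/12)/(10x − 5/3)` beyond,
so distance acts as a tie-breaker rather than dominating. By default the
distance is SNP-to-gene-promoter; a switch selects SNP-to-marker instead
(the two conventions both appear in the field; the promoter convention
matches the feature definition used here).

## Fitting

Soft EM. The E-step computes posterior responsibilities over `(V_g, Z_g)`
in log space with max-subtraction; a hard (argmax-imputation) variant is
available behind `em_mode="hard"`. The M-step plugs responsibilities into
pseudocounted multinomial MLEs — pseudocounts `λ_i p_g` with
`λ = (0.1, 0.01, 0)` are added per gene to each of the four weighted count
sums, tilting all triples toward low edit distances — the conjugate MAP
update for `Θ_g` (Dirichlet(Π + soft counts) mode, denominator floored at
1e-12, which only binds under a flat prior), and the mean responsibility
for γ (clipped away from {0, 1} by 1e-6). The monitored objective is the
penalized observed-data log likelihood: mixture likelihood + Dirichlet
prior density of `Θ_g` + the λ regularizer terms. Because every M-step
update maximizes the corresponding term, the objective is monotone
non-decreasing; convergence is declared at relative change < 1e-8
(default), with 10 seeded restarts (initialization: causal triples
jittered around (0.7, 0.2, 0.1), null triples around uniform, γ = 0.5,
`Θ ∝ Π`) and ties between restarts resolved toward the lowest index.

Note the pseudocount scale: with the observed median of ~36 candidates
per association, `λ_0 p_g ≈ 3.6` pseudo-trials accompany the at most 5
(classical) and 3 (wild) data trials per gene, so the fitted triples are
strongly regularized toward the ratio (0.909, 0.091, 0). This is a
deliberate property of the estimator (it enforces consistency between DO
and founder patterns); fitted triples should be read as penalized, not
raw, frequencies.

## Posterior summaries

Gene-level calls use direct posterior probability FDR control: sort by
`v̂_g`, select the largest prefix whose mean `1 − v̂` is at most the
target rate (ties at the cut included or excluded together). SNP-level
posteriors condition on causality (`w_{g,k}/v̂_g`); credible sets are the
smallest posterior-descending prefix reaching cumulative 0.80 and are
flagged informative when strictly smaller than half the candidates.
Selection strategies (most likely, least likely, random, closest to
marker, closest to gene) break ties toward the lower genomic coordinate.
Contributor attribution ranks each prior component ascending across a
gene's candidates (average ranks on ties) and normalizes the causal
SNP's rank by `p_g`.

## Footprint features

Footprint depth of a motif site is `FPD = (flank − site)/flank` where
`flank` averages the pooled 1–25 bp and 26–50 bp windows on both sides
(the upstream literature names the quantity but not the formula; this
fixed form is this package's convention). Allele-group contrasts pool
depth-normalized cut profiles within carriers and non-carriers;
`ΔFPD = FPD_SNP − FPD_REF`. Significance uses motif-specific empirical
nulls built from in-silico-insignificant records, one-sided in the
direction of the gain/loss class (gain: match significant only with the
alternative allele and ΔFPD > 0; loss: mirrored), with the add-one
convention and a minimum null size of 20. Per SNP the minimum p across
motifs is BH-corrected across SNPs at FDR 0.05 to set the flag `F`.
Local-ATAC-MV identification uses a per-peak max-statistic permutation
test (squared Pearson correlation between 0/1 genotype and strain-level
signal; permuting strain labels; add-one p), retaining the best SNP(s)
including exact ties, then BH across peaks. With eight strains the
permutation p of even a perfect association is floored by
genotype-pattern multiplicity (≈ 2·4!·4!/8! for a balanced SNP), which
matters when interpreting single-peak results.

## Synthetic data and what it does (not) show

The generator emulates the *structure* of founder multi-omics summaries:

- candidate counts `p_g ~ 1 + NegBin(shape 2.5, mean 40)`, matching the
  right-skewed observed distribution (median 36, sd ≈ 27);
- LD via per-locus haplotype prototypes (4 by default) copied with 3%
  per-strain mutation — candidates fall into a few correlated genotype
  clusters, as founder LD blocks produce;
- alternative alleles enriched in wild-derived strains (0.7 vs 0.4);
  essentially every variant involves a wild strain, as observed;
- ATAC signal = baseline + genotype effect + noise per SNP; founder
  expression is polygenic and graded: signed contributions from every
  haplotype prototype (sd 1.2, with at least one opposing sign) plus
  strain-level noise (sd 0.25), so most candidates carry significant
  marginal regressions — as in the real founder data, where roughly three
  quarters of candidate variants associate with cis expression — while
  expression patterns remain two-signed and are not exactly reproducible
  by any single genotype vector.

Plate sampling draws `V ~ Bern(γ)`, `Θ ~ Dirichlet(Π)` under the chosen
informativeness (NI: `Π ≡ 1`; MI: computed from the fixture's features;
HI: footprint component set to 10 on one random SNP, 0 elsewhere),
`Z ~ Mult(1, Θ)`, then edit-distance counts from the causal or null
multinomials. Counts are materialized into a trinarized pattern by
assigning drawn distances to strains uniformly at random subject to
feasibility (distance 2 needs a signed base entry; distance 1 from 0
draws its sign uniformly; infeasible draws are rejected and the counts
redrawn), with one deliberate constraint: the reference entry never
moves, because trinarized patterns are defined relative to B6 and a
nonzero reference entry is unrepresentable as a raw effect vector.
The materialized pattern's recomputed counts equal the drawn counts
exactly, and a raw allelic-effect vector mapping codes to {0, 0.5, 1}
round-trips through standardization.

Default generating parameters are γ = 0.5 and concentrated triples
(`a1 = (0.90, 0.08, 0.02)`, `b1 = (0.87, 0.10, 0.03)`,
`a0 = (0.86, 0.11, 0.03)`, `b0 = (0.87, 0.10, 0.03)`): causal pairs
nearly match, null concordance is slightly weaker. Two considerations fix
this regime. First, realized fits are pseudocount-penalized (above), so
parameters far from the tilt region cannot be recovered by the
estimator's own formula; plausible fitted values live near it. Second,
hypothesis separation in this model is structural — a causal gene's
pattern tracks a single-signed genotype-effect vector while a null gene's
tracks the two-signed expression pattern — rather than driven by kernel
contrast, which matches the model's premise that pseudocounts, not the
likelihood alone, enforce consistency.

What passing simulations do *not* show: real DO allelic effects are
estimated with error from finite mouse cohorts, founder expression is
normalized rather than generated, candidate features carry measurement
noise and shared peaks, and the model's count-kernel likelihood is an
approximation whose posteriors on fully realistic data can be
overconfident (the count kernel ignores the combinatorial multiplicity of
patterns mapping to the same counts). Headline real-data figures are
therefore not reproduced here; the simulations validate internal
consistency, estimator behavior, and directional claims.

## Evaluation harness

Power and realized FDR are computed against simulated truth at the 0.05
direct-posterior FDR level; the oracle evaluator hands the generating
parameters to a single E-step with `Θ` integrated out
(`E[Θ_k] = Π_k / ΣΠ`). Fine-mapping is summarized by the credible
proportion — the rank of the true causal SNP in a strategy's ordering
divided by `p_g` — averaged over causal genes and compared across the
five selection strategies and the three informativeness settings.

## Problem sizes used by the test suite

Parameter recovery is checked at G = 5000 (HI, 10 restarts); FDR
calibration over 50 replicates at G = 2000 with oracle-parameter
posteriors; fine-mapping orderings over 20 replicates per setting at
G = 300 with 2 restarts. These sizes give stable Monte-Carlo estimates
for the directional and tolerance checks involved while keeping the suite
desk-runnable.

## Known limitations

- At most one causal SNP per gene-marker association; trans-eQTLs are out
  of scope.
- The count-kernel likelihood reuses the same observed pattern under both
  hypotheses; posteriors are exact under the model but approximate under
  any fully generative reading (see above).
- Pearson correlations over eight strains are noisy; the prior treats
  them as fixed weights, not estimates.
- The FPD formula and the sidedness of the empirical ΔFPD test are this
  package's conventions where the upstream definitions are not printed.
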