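# Methods

This note documents the statistical models, the observation model behind the
synthetic data, the numerical choices, and the limits of what the test suite
demonstrates.

## Genotype substrate and per-locus statistics

All analyses run on a samples × loci matrix of ALT-allele dosages
(0/1/2/missing) with optional per-call depth, genotype quality and allele
depths, read from VCF 4.x. Coordinates are VCF-style (1-based). `p` always
denotes the ALT frequency; every MAF-symmetric statistic is unaffected by
this orientation choice.

Per locus we report allele frequency, MAF, call rate, observed and expected
heterozygosity (*He* = 1 − *p*² − *q*² per locus; the multilocus value is
1 − (1/m) Σ (*p*² + *q*²)), *F*<sub>IT</sub> = 1 − *Ho*/*He* (undefined at
monomorphic loci), and an exact Hardy–Weinberg test conditioned on the
allele counts: all heterozygote counts compatible with the observed allele
counts are enumerated with their conditional probabilities
∝ 2^h n! / (h! n<sub>AA</sub>! n<sub>aa</sub>!), giving a two-sided p-value
(mass of outcomes no more probable than the observed one) and a one-sided
heterozygote-excess tail. The excess tail is the one that matters here:
loci collapsed from paralogous genome regions show systematic heterozygote
excess.

## Filter cascade

Stages, in order: (1) indels and SNPs within ±5 bp (inclusive, same
chromosome) of an indel; (2) non-biallelic records; (3) per-genotype
masking at quality < 20 and depth < 8× (strict less-than; stages are
skipped with a warning when the VCF lacks the field); an optional
allele-balance stage masking heterozygotes whose allele depths fail a
two-sided exact binomial(depth, ½) test (off by default — it has almost no
effect once the locus-level screens run); (4) MAF ≥ 0.01; (5) call rate
≥ 0.60; (6) heterozygote fraction ≤ 0.70 (denominator: non-missing calls);
(7) removal of loci with *F*<sub>IT</sub> < 0 **and** heterozygote-excess
p < α = 0.05 — both conditions required, no multiple-testing correction
(the test is used per locus as a screen, not as inference). The cascade is
idempotent, every stage is recorded with before/after counts, and the stage
order is configurable but regression-tested in the order above. The
discovery-stage MAF (0.01) and the relatedness-stage MAF (0.10) are
deliberately separate knobs: rare alleles carry almost no pairwise
information but would otherwise dominate the locus set.

Replicate QC treats the dosage distance |d₁ − d₂| at co-called loci as the
number of mismatching alleles (het vs homozygote = 1 of 2; opposite
homozygotes = 2), giving an allele error rate out of 2 × co-called loci, an
allelic-dropout rate (opposite homozygotes / co-called loci) and the
shared-locus proportion (intersection over union of called loci).

## Relatedness estimators

**Allele-frequency reference.** Frequencies come from designated reference
samples. Pairs with preliminary moment relatedness ≥ 0.15 are broken by
removing the more-connected member (ties: lower coverage, then id); samples
covering < 80% of loci are dropped; frequencies are recomputed on the
survivors and fixed loci removed. A reference containing relatives biases
every downstream estimate low, which is why the screen precedes estimation.

**Method of moments.** Per shared biallelic locus, with dosage fractions
*x* = g/2, *r*<sub>l</sub> = 2(*x*<sub>A</sub>*y*<sub>A</sub>/*p* +
*x*<sub>a</sub>*y*<sub>a</sub>/*q* − 1); the multilocus estimate is the
unweighted mean (each biallelic locus carries weight n<sub>alleles</sub>−1
= 1). The estimator is unbiased (the clone-dyad expectation equals 1 in
closed form; simulation recovers 0 / 0.5 / 0.5 for unrelated, parent–
offspring and full-sib dyads) but is not variance-minimal and degrades
under genotyping error. The per-locus sampling variance
*s*(1−*s*)/(*p*²*q*²) is reported per locus and as its mean; how the study
aggregated it across loci is not recoverable, so both forms are exposed.

**Maximum likelihood over Jacquard coefficients.** The dyad's four alleles
fall into one of nine condensed identity-by-descent configurations
Δ₁…Δ₉ (Δ₇/Δ₈/Δ₉ the familiar k₂/k₁/k₀; Δ₁–Δ₆ involve inbreeding).
P(true genotype pair | state) is built by enumerating allele-type
assignments to the state's IBD classes, each class drawn independently from
the reference frequencies. Observation folds in an allele-level error
model: each true allele is read correctly with probability 1 − *e*,
otherwise replaced by a draw from the reference frequencies, so
P(read A | true A) = 1 − *e* + *e p*. This is one concrete choice among
several defensible GBS error models; it is documented here, injectable in
code, and its key property is that a 5% mistyping rate no longer drags
first-degree estimates below theory. The likelihood
Σ<sub>l</sub> log Σ<sub>s</sub> Δ<sub>s</sub> P<sub>l</sub>(obs | s) is
maximised on the simplex by EM (E-step: per-locus state posteriors;
M-step: Δ = mean posterior). It is concave in Δ, so the EM optimum is
global; the default start is uniform, the batched estimator warm-starts
from the moment estimate mapped to (k₂,k₁,k₀) = (r², 2r(1−r), (1−r)²)
— a speed device only — and seeded Dirichlet restarts remain available.
Convergence is |ΔlogL| < 10⁻⁶ with a 2000-iteration cap; non-convergence
returns best-so-far with a flag. A three-state variant (Δ₁–Δ₆ ≡ 0) is
provided; the nine-state model is the default because selfed offspring and
megagametophytes require the inbred states to reach r ≈ 1. Loci with
reference p ∈ {0,1} are excluded throughout (the moment estimator
diverges there).

With 2000 error-free SNPs the ML mean over parent–offspring dyads sits
~0.015 above 0.5: the simplex constraint truncates the lower tail of the
sampling distribution. The same upward nudge appears in the real-data
estimates this workflow targets.

**Genotype correlation** is the Pearson correlation of dosage vectors over
shared loci — scale-free, cheap, and used as the third vote in consensus.

**Individual inbreeding** is a two-component mixture per locus (IBD:
homozygote with probability p or q; non-IBD: HWE), the same error model,
solved by EM for F ∈ [0,1].

**Subsampling scans.** For precision-versus-MAF and precision-versus-SNP-
count curves, shared loci above a MAF floor are subsampled without
replacement (1000 draws of 1000 loci; 75% of available loci when fewer than
1000 remain) and the 2.5/97.5 percentiles of the per-draw estimates give a
95% interval. Pairs sharing fewer than 1000 informative SNPs are flagged
low-confidence everywhere; below that the class separation visibly
collapses.

## Parentage

Candidates sharing < 1000 SNPs with the offspring are ineligible. Three
rankings (moment, ML, correlation) are computed; slot 1 is filled when all
three agree on the top candidate, or — the generic case for an offspring
with both parents in the orchard, whose two true parents are statistically
exchangeable at r ≈ 0.5 — when all three top-two *sets* coincide and both
members clear the acceptance threshold t<sub>po</sub> = 0.4 (the slot takes
the ML-preferred member). Slot 2 repeats the rule with slot 1's parent
removed. Selfing is called at ML r ≥ t<sub>self</sub> = 0.75 toward a
single candidate together with offspring F̂ ≥ 0.25 (a selfed offspring of a
non-inbred parent expects F = 0.5). The thresholds sit in the wide empirical
gap between the unrelated/half-sib mass and the parent–offspring mass and
are configurable. Assignment is deterministic given the dyad table; ties in
rankings break toward more shared SNPs, then id, and are recorded.
Kinship classes for arbitrary dyads take the nearest theoretical r in
{0, 0.25, 0.5, 1}, with the k-pattern separating parent–offspring
(k₁ ≈ 1) from full sibs (≈ (¼, ½, ¼)) at r ≈ 0.5.

Externally sired offspring are single-linkage clustered at ML r ≥ 0.15
(half-sib-level sharing through the unobserved father); each cluster counts
as one donor. Parent-2 search is greedy and dyadic rather than a joint trio
likelihood — deliberate, matching the dyadic workflow; trio Mendelian
inconsistency is a diagnostic only.

## Mating structure

Per-parent IP (internal gamete slots: a both-internal offspring contributes
one to each parent, a selfed offspring two to its single parent) and EP
(sole-internal-parent seedlings) counts, with ramet-proportional
expectations E(IP)<sub>i</sub> = (ramets<sub>i</sub>/Σramets) ΣIP. The
effective number of parents uses the bias-corrected Simpson form
N<sub>ep</sub> = (n−1)²/[Σp<sub>i</sub>²(n+1)(n−2) + 3 − n]. **Convention
that matters:** n is the number of contribution *events* (gamete slots,
n = ΣIP = 2 × both-internal offspring), not seedlings; with the shipped
census (ΣIP = 392) this yields 16.2, whereas counting seedlings does not.
The with-external variant appends one contributor per external-donor
cluster and per sole-internal slot; because the donor clustering of the
original study is not recoverable, that variant is reported but not treated
as a reference value. Expected selfing is E(f<sub>s</sub>) =
(1 − PC) Σ P<sub>i</sub>², with genotype frequencies P defaulting to ramet
proportions.

## G-matrices

Additive: A = ZZ′/(2Σp<sub>j</sub>q<sub>j</sub>), Z = dosage − 2p.
Dominance: the orthogonal coding w = (−2p², 2pq, −2q²) for dosages
(0, 1, 2), normalised by Σ(2p<sub>j</sub>q<sub>j</sub>)² — zero-mean under
HWE, so full sibs expect 0.25 and parent–offspring 0. The prefilter drops
samples > 90% missing, then re-screens loci at call rate ≥ 0.7 and MAF
≥ 0.1. Remaining gaps are imputed naively: a seeded draw from the HWE
genotype probabilities (default, matching the frequencies-and-their-
probability description) or the expectation 2p. Naive imputation is known
to dilute pairwise signal roughly by the square of the complete fraction —
the simulation regression test pins this down: with 40% missingness the
parent–offspring additive mean drops from ≈ 0.5 to ≈ 0.18. This is a
faithful property of the method, not a defect of the implementation.

## The simulator

`simulate_crop` draws parents as outbred HWE genotypes on an allele-
frequency spectrum (default: density ∝ 1/x on [0.01, 0.5], folded, which
puts ln 5/ln 50 ≈ 41% of loci at MAF 0.01–0.05 — the rare-allele-dominated
shape of range-wide conifer samples); mothers and internal fathers are
sampled proportionally to ramet counts (default: the shipped 28-parent
census), the father is external with probability 0.336 (fresh unique donor
per event by default, or a finite donor pool), and same-genotype mating
yields selfed offspring naturally (expected rate (1 − PC) Σ P<sub>i</sub>²
≈ 3%; a forced selfing rate and a no-selfing switch exist). Loci segregate
independently — consistent with the estimators, which assume unlinked
markers. Megagametophytes are haploid gametes scored as homozygous
diploids.

`gbs_observe` models: negative-binomial depth (mean 45, dispersion 3 — the
study reports only medians ≈ 41–44, so dispersion is a free, documented
knob), missing below 8×; allele mistyping at rate e = 0.05 by
frequency-weighted replacement; binomial(depth, ½) read splits for true
heterozygotes with collapse to a homozygote when one allele draws zero
reads (allelic dropout); a 3% fraction of paralog loci whose homozygotes
flip to heterozygotes half the time (feeding stage 7 of the cascade);
per-library whole-locus dropout at rates (0.01, 0.03, 0.05, 0.30), chosen
so replicate shared-locus proportions span roughly 0.55–0.99 with a median
near 0.89. Replicates are independent re-observations of the same truth in
a different library.

Two error-rate conventions coexist and are easy to conflate. The
observation model's e is a per-observation mistyping probability; between
two replicates each erring independently with frequency-weighted redraws,
the *pairwise mismatch* rate is noticeably below e. The operational
replicate error rate — the proportion of alleles inconsistent between
replicates — is what `replicate_qc` measures; `simulate_replicate_pairs`
generates pairs under exactly that definition (one member taken as the
reference call set, the other's alleles flipped at the nominal rate), and
recovery tests use it.

What passing tests do **not** show about real data: the simulator has no
linkage, no population structure, no batch-correlated depth, no strand
bias, no null alleles from restriction-site polymorphism, and its paralogs
are a caricature (uniform flip rate). Estimator behaviour under those
violations is outside the demonstrated envelope.

## Problem sizes and numerics

The test suite exercises the full pipeline on a 5000-locus, 60-offspring,
80-reference orchard at the study's rate parameters (the simulator default
remains 298 offspring); simulation recoveries use 200 dyads × 2000 loci;
the acceptance script mirrors those sizes. Degenerate inputs are explicit
errors, not silent answers: empty cascade stages name the stage, dyads with
no shared informative loci return flagged undefined estimates, constant
dosage vectors make the correlation undefined, N<sub>ep</sub> requires at
least three contribution events, and fixed loci are rejected by the
frequency reference. EM tolerances: |ΔlogL| < 10⁻⁶ (dyads), 10⁻⁸
(inbreeding), 2000-iteration caps, likelihoods floored at 10⁻³⁰⁰ before
logs.

## Design choices made where the design was open

- Quality/depth masking applies to genotype-level fields (GQ/DP); site QUAL
  is not consulted, since the deposited data carry per-genotype fields.
- The 70%-heterozygote stage precedes the F<sub>IT</sub>/HWE stage; both
  orders are supported, the shipped order is the regression-tested default.
- The nine-state ML model is the default (the inbred states are required
  for selfed/megagametophyte dyads); the three-state model exists for
  outbred-only work.
- Acceptance thresholds t<sub>po</sub> = 0.4, t<sub>self</sub> = 0.75,
  F̂ ≥ 0.25 are read off the empirical class separation and configurable.
- The external-N<sub>ep</sub> donor grouping treats each relatedness
  cluster as one donor; singleton externals are singleton donors.
- Per-estimator subsampling intervals use percentiles rather than normal
  approximations; the same seed reproduces the same intervals exactly.
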