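# orchardkin

Kinship, parentage and mating-structure analysis for seed-orchard crops
genotyped by reduced-representation sequencing (GBS/RAD).

## The problem

Conifer seed orchards produce the genetically improved seed used in
operational forestry. Whether the crop delivers the expected gain depends on
its mating structure: which of the clonal parents actually contributed,
how unequal their contributions were, how much seed was sired by pollen
blowing in from surrounding unimproved stands (*pollen contamination*), and
how much came from self-fertilisation. With GBS genotypes for the candidate
parents and a sample of seedlings, all of this can be reconstructed — but
GBS data carry allelic dropout, ~5% allele mistyping, stochastic missingness
between library preparations, and paralog-collapsed loci that masquerade as
heterozygote-rich SNPs. `orchardkin` implements a filtering and estimation
workflow built for exactly these data, for tree breeders and evolutionary
geneticists who need pedigree reconstruction from noisy dominant-species
genotyping.

## What it computes

**Filtering.** A post-variant-calling cascade: indels and SNPs within ±5 bp
of an indel, non-biallelic records, genotypes with quality < 20 or depth
< 8×, loci with MAF < 0.01 or call rate < 60%, loci with > 70% heterozygous
calls, and loci with both negative *F*<sub>IT</sub> = 1 − *H*<sub>O</sub>/*H*<sub>E</sub>
and a significant exact-test heterozygote excess (the paralog signature).
Replicate samples yield shared-locus proportions, allele error rates and
allelic-dropout rates.

**Pairwise relatedness**, three estimators over the loci shared by a dyad,
against an allele-frequency reference built from screened unrelated samples:

- a method-of-moments estimator, per locus
  *r*<sub>l</sub> = 2(*x*<sub>A</sub>*y*<sub>A</sub>/*p* + *x*<sub>a</sub>*y*<sub>a</sub>/*q* − 1),
  averaged over loci, with per-locus sampling variance *s*(1−*s*)/(*p*²*q*²);
- a maximum-likelihood estimator over the nine condensed Jacquard
  identity-by-descent coefficients Δ₁…Δ₉, maximised on the simplex by EM,
  with an allele-level genotyping-error model
  (P(read A | true A) = 1 − *e* + *e p*); relatedness is
  *r* = 2Δ₁ + Δ₃ + Δ₅ + Δ₇ + ½Δ₈ and (*k*₀,*k*₁,*k*₂) = (Δ₉,Δ₈,Δ₇);
- the Pearson correlation of genotype scores (0/1/2).

On this 2θ scale, parent–offspring and full sibs sit at 0.5, half sibs at
0.25, clones and selfed-offspring-vs-parent at 1. A per-individual ML
inbreeding coefficient *F̂* comes from the same error model.

**Parentage.** A candidate parent is accepted only when the three estimators
agree on the top candidate (or on the top pair, for offspring with both
parents in the orchard) and the ML estimate clears a threshold; unassigned
slots are attributed to external pollen, and externally sired seedlings are
clustered on mutual relatedness to count distinct external donors. Selfed
seedlings combine a clone-level ML estimate with elevated *F̂*.

**Mating structure.** Per-parent contribution counts with ramet-proportional
expectations; the bias-corrected effective number of parents

&nbsp;&nbsp;&nbsp;&nbsp;*N*<sub>ep</sub> = (*n* − 1)² / [Σ *p*<sub>i</sub>² (*n* + 1)(*n* − 2) + 3 − *n*],

the expected selfing fraction E(*f*<sub>s</sub>) = (1 − PC) Σ *P*<sub>i</sub>²,
and per-group diversity (*H*<sub>O</sub>, *H*<sub>E</sub>, MAF). The census of
the Västerhus Scots pine orchard (28 parents: ramet counts and per-parent
internally/externally pollinated seedling counts) ships as
`orchardkin.vasterhus` and drives the worked examples.

**G-matrices.** VanRaden additive and orthogonal-coding dominance genomic
relationship matrices with a stricter prefilter and naive HWE imputation.

**Simulator.** `orchardkin.synthetic_data` generates complete orchards with
known truth — L-shaped allele-frequency spectrum, ramet-weighted mating,
external pollen, selfing, megagametophytes, replicate pairs — and a GBS
observation model (negative-binomial depth with an 8× call floor, allelic
dropout, allele mistyping, paralog loci, per-library locus dropout), so the
entire pipeline is testable without any sequence data.

## Worked example

```python
import numpy as np
from orchardkin.relatedness import (
    AlleleFrequencyReference, milligan_ml_pair, ritland_pair, genotype_correlation,
)
from orchardkin.synthetic_data import simulate_kinship_dyads

dosage, pairs, p = simulate_kinship_dyads("parent_offspring", 1, 2000, seed=42)
ref = AlleleFrequencyReference([f"l{i}" for i in range(2000)], p, ["truth"])
parent, child = dosage[0], dosage[1]

r_mom, _, n = ritland_pair(parent, child, ref)
jac, loglik, converged = milligan_ml_pair(parent, child, ref, e=0.0)
print(f"shared SNPs:          {n}")
print(f"moment estimate r:    {r_mom:.3f}")
print(f"ML estimate r:        {jac.r:.3f}  (k0={jac.k0:.3f}, k1={jac.k1:.3f}, k2={jac.k2:.3f})")
print(f"genotype correlation: {genotype_correlation(parent, child):.3f}")

from orchardkin import vasterhus
from orchardkin.mating_stats import effective_parents, expected_selfing
census = vasterhus.orchard_table()
nep = effective_parents(census["ip"])
shares = census["ramets"] / census["ramets"].sum()
print(f"effective parents (internal): {nep:.1f}")
print(f"expected selfing:             {100*expected_selfing(shares, 0.336):.2f}%")
```

prints

```
shared SNPs:          2000
moment estimate r:    0.480
ML estimate r:        0.509  (k0=0.000, k1=0.982, k2=0.000)
genotype correlation: 0.684
effective parents (internal): 16.2
expected selfing:             3.36%
```

The dyad is a simulated parent–offspring pair: both point estimates land
near the theoretical 0.5, and the ML *k*-pattern (*k*₁ ≈ 1, *k*₀ ≈ *k*₂ ≈ 0)
identifies the pair as parent–offspring rather than full sibs. The census
numbers say the 392 internal gamete contributions behave like ~16 equally
contributing parents of the 28 deployed, and that the orchard's genotype
frequencies plus one-third external pollen predict ~3.4% selfed seed.

A full run — filter → reference → relatedness → parentage → mating
statistics → G-matrix — goes through the CLI:

```sh
orchardkin simulate --seed 1 --out-prefix demo/run
orchardkin run --config pipeline.yaml      # paths + thresholds in YAML
```

or stage by stage (`orchardkin filter / relate / parentage / matingstats /
gmatrix / replicate-qc`); every stage writes TSV plus a JSON run manifest,
and reruns with the same config and seed are byte-identical.

## Layout

```
src/orchardkin/
  genotype_io.py     VCF input, dosage matrix, per-locus statistics, exact HWE
  qc_filtering.py    filter cascade, allele-balance filter, replicate QC
  relatedness.py     moment / ML-Jacquard / correlation estimators, inbreeding,
                     frequency reference, MAF & SNP-count subsampling scans
  parentage.py       consensus assignment, kinship classes, donor clustering
  mating_stats.py    contribution tables, N_ep, expected selfing, diversity
  gmatrix.py         VanRaden additive + dominance matrices, naive imputation
  synthetic_data.py  orchard and GBS observation simulator, fixtures
  vasterhus.py       the 28-parent orchard census table
  pipeline.py, cli.py
```

See `docs/methods.md` for the models, assumptions, parameter defaults and
known limitations.
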