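"""Post-calling SNP filter cascade and replicate-based quality control.

The cascade reproduces a GBS filtering recipe tuned for kinship work:
indel-adjacent and multi-allelic records go first, then per-call depth and
quality masking, then locus-level MAF, call-rate and two heterozygote-excess
screens (a hard 70% heterozygote ceiling and a combined negative-F_IT /
HWE-departure test) that target SNPs collapsed from paralogous fragments —
the dominant source of spurious heterozygosity in conifer GBS data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .genotype_io import MISSING, GenotypeMatrix, locus_stats

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ReplicateQC",
    "mask_genotypes",
    "het_allele_balance_filter",
    "filter_cascade",
    "replicate_qc",
]


@dataclass
class FilterConfig:
    """Thresholds for the locus/genotype filter cascade.

    Defaults are the discovery-stage settings: genotype quality and depth
    minima of 20 and 8x, discovery MAF 0.01, call rate 0.60, a 70%
    heterozygote ceiling, and alpha = 0.05 for the combined significant
    negative F_IT + heterozygote-excess HWE removal. The relatedness stage
    re-filters at MAF 0.1 (`maf_relatedness`), a deliberately separate knob.
    """

    min_quality: float = 20.0
    min_depth: int = 8
    maf_min: float = 0.01
    call_rate_min: float = 0.60
    het_max: float = 0.70
    fit_alpha: float = 0.05
    maf_relatedness: float = 0.10
    het_balance_alpha: float | None = None  # None disables the binomial AD stage

    def __post_init__(self):
        if self.min_quality < 0 or self.min_depth < 0:
            raise ValueError("quality/depth thresholds must be non-negative")


@dataclass
class FilterReport:
    """Ordered record of cascade stages with locus/genotype counts."""

    stages: list = field(default_factory=list)

    def add(self, name: str, before: int, after: int, masked_calls: int = 0, **thresholds):
        if self.stages and after > before:
            raise ValueError("locus counts must be non-increasing")
        self.stages.append(
            {
                "stage": name,
                "loci_before": before,
                "loci_after": after,
                "loci_removed": before - after,
                "calls_masked": masked_calls,
                **thresholds,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReplicateQC:
    """Concordance of one replicate pair.

    shared_locus_proportion
        co-called loci / loci called in either member.
    allele_error_rate
        mismatching alleles / (2 x co-called loci); the dosage distance
        |d1 - d2| counts mismatching alleles, so a het-vs-homozygote
        disagreement is 1 mismatch of 2 and opposite homozygotes are 2.
    allelic_dropout_rate
        opposite-homozygote loci / co-called loci.
    """

    pair: tuple
    n_union: int
    n_shared: int
    shared_locus_proportion: float
    allele_error_rate: float
    allelic_dropout_rate: float
    defined: bool = True


def mask_genotypes(
    G: GenotypeMatrix, min_quality: float = 20.0, min_depth: int = 8
) -> tuple[GenotypeMatrix, int]:
    """Set calls with quality < `min_quality` or depth < `min_depth` missing.

    Thresholds are strict "less-than" exclusions: depth 8 / quality 20 calls
    survive. A matrix without the relevant field skips that dimension with a
    warning. Returns the masked copy and the number of newly masked calls.
    """
    if min_quality < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    out = G.copy()
    bad = np.zeros(out.dosage.shape, dtype=bool)
    if G.depth is not None:
        bad |= (G.depth >= 0) & (G.depth < min_depth)
    else:
        warnings.warn("no depth field; depth masking skipped", stacklevel=2)
    if G.quality is not None:
        with np.errstate(invalid="ignore"):
            bad |= np.isfinite(G.quality) & (G.quality < min_quality)
    else:
        warnings.warn("no quality field; quality masking skipped", stacklevel=2)
    bad &= out.called
    out.dosage[bad] = MISSING
    return out, int(bad.sum())


def het_allele_balance_filter(
    G: GenotypeMatrix, alpha: float
) -> tuple[GenotypeMatrix, int]:
    """Mask heterozygous calls whose allele depths depart from binomial(DP, 1/2).

    A two-sided exact binomial test is applied to (ref_reads, alt_reads) of
    every heterozygote; calls with p < alpha are set missing. Homozygous
    calls are untouched. Optional stage, off by default (it has almost no
    effect once the locus-level heterozygosity screens run).
    """
    if G.allele_depths is None:
        raise ValueError("het_allele_balance_filter requires the AD field")
    out = G.copy()
    ad = G.allele_depths
    hets = (out.dosage == 1) & (ad[..., 0] >= 0) & (ad[..., 1] >= 0)
    idx = np.argwhere(hets)
    masked = 0
    cache: dict[tuple[int, int], float] = {}
    for i, j in idx:
        r, a = int(ad[i, j, 0]), int(ad[i, j, 1])
        tot = r + a
        if tot == 0:
            continue
        key = (min(r, a), tot)
        pval = cache.get(key)
        if pval is None:
            pval = binomtest(key[0], tot, 0.5).pvalue
            cache[key] = pval
        if pval < alpha:
            out.dosage[i, j] = MISSING
            masked += 1
    return out, masked


def filter_cascade(
    G: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the locus/genotype filter cascade in its documented order.

    Stages: (1) drop indels and indel-adjacent SNPs; (2) drop non-biallelic
    records; (3) mask low-quality/low-depth genotypes (and, if configured,
    allele-balance-failing heterozygotes); (4) MAF >= maf_min; (5) call rate
    >= call_rate_min; (6) drop loci with heterozygote fraction > het_max;
    (7) drop loci with F_IT < 0 *and* heterozygote-excess p < alpha (both
    conditions required). The report records every stage in execution order.
    Running the cascade twice is a no-op the second time (idempotence).
    """
    config = config or FilterConfig()
    report = FilterReport()

    def _check(g: GenotypeMatrix, stage: str):
        if g.n_loci == 0:
            raise ValueError(f"0 loci remain after {stage}")

    n0 = G.n_loci
    keep = ~(G.is_indel | G.indel_adjacent)
    G = G.take_loci(keep)
    report.add("indel_and_adjacent", n0, G.n_loci)
    _check(G, "indel_and_adjacent")

    n0 = G.n_loci
    G = G.take_loci(~G.multiallelic)
    report.add("biallelic", n0, G.n_loci)
    _check(G, "biallelic")

    n0 = G.n_loci
    if G.depth is not None or G.quality is not None:
        G, masked = mask_genotypes(G, config.min_quality, config.min_depth)
    else:
        masked = 0
    report.add(
        "mask_genotypes",
        n0,
        G.n_loci,
        masked_calls=masked,
        min_quality=config.min_quality,
        min_depth=config.min_depth,
    )
    if config.het_balance_alpha is not None:
        n0 = G.n_loci
        G, masked = het_allele_balance_filter(G, config.het_balance_alpha)
        report.add("het_allele_balance", n0, G.n_loci, masked_calls=masked,
                   alpha=config.het_balance_alpha)

    stats = locus_stats(G)
    n0 = G.n_loci
    keep = (stats["maf"] >= config.maf_min).fillna(False).to_numpy()
    G = G.take_loci(keep)
    stats = stats.loc[keep]
    report.add("maf", n0, G.n_loci, maf_min=config.maf_min)
    _check(G, "maf")

    n0 = G.n_loci
    keep = (stats["call_rate"] >= config.call_rate_min).to_numpy()
    G = G.take_loci(keep)
    stats = stats.loc[keep]
    report.add("call_rate", n0, G.n_loci, call_rate_min=config.call_rate_min)
    _check(G, "call_rate")

    n0 = G.n_loci
    keep = ~(stats["ho"] > config.het_max).to_numpy()
    G = G.take_loci(keep)
    stats = stats.loc[keep]
    report.add("het_fraction", n0, G.n_loci, het_max=config.het_max)
    _check(G, "het_fraction")

    n0 = G.n_loci
    drop = ((stats["f_it"] < 0) & (stats["het_excess_p"] < config.fit_alpha)).fillna(
        False
    ).to_numpy()
    G = G.take_loci(~drop)
    report.add("fit_hwe", n0, G.n_loci, alpha=config.fit_alpha)
    _check(G, "fit_hwe")

    return G, report


def replicate_qc(G: GenotypeMatrix, metadata: pd.DataFrame) -> list[ReplicateQC]:
    """Concordance statistics for every replicate pair in the metadata.

    Pairs are taken from the ``replicate_of`` column; statistics are
    symmetric in the two members. Pairs with no co-called loci are returned
    flagged undefined rather than dropped.
    """
    pairs = []
    for sid, rep_of in metadata["replicate_of"].dropna().items():
        if sid in G.sample_ids and rep_of in G.sample_ids:
            pairs.append((rep_of, sid))
    if not pairs:
        raise ValueError("no replicate pairs present in both metadata and genotypes")

    out = []
    for a, b in pairs:
        da = G.dosage[G.sample_index(a)]
        db = G.dosage[G.sample_index(b)]
        ca, cb = da != MISSING, db != MISSING
        union = int((ca | cb).sum())
        both = ca & cb
        n_shared = int(both.sum())
        if n_shared == 0:
            out.append(ReplicateQC((a, b), union, 0, np.nan, np.nan, np.nan, defined=False))
            continue
        diff = np.abs(da[both].astype(int) - db[both].astype(int))
        out.append(
            ReplicateQC(
                pair=(a, b),
                n_union=union,
                n_shared=n_shared,
                shared_locus_proportion=n_shared / union if union else np.nan,
                allele_error_rate=float(diff.sum()) / (2 * n_shared),
                allelic_dropout_rate=float((diff == 2).sum()) / n_shared,
            )
        )
    return out


def replicate_qc_frame(results: list[ReplicateQC]) -> pd.DataFrame:
    rows = [
        {
            "sample_a": r.pair[0],
            "sample_b": r.pair[1],
            "n_union": r.n_union,
            "n_shared": r.n_shared,
            "shared_locus_proportion": r.shared_locus_proportion,
            "allele_error_rate": r.allele_error_rate,
            "allelic_dropout_rate": r.allelic_dropout_rate,
            "defined": r.defined,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
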