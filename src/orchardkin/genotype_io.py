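"""Genotype containers, VCF input and per-locus statistics.

The central object is :class:`GenotypeMatrix`, a samples x loci matrix of
alternate-allele dosages (0, 1, 2, or missing) with optional per-call read
depth, genotype quality and allele depths. Every downstream stage —
filtering, relatedness estimation, parentage, G-matrices — operates on this
container. Coordinates follow VCF conventions (1-based, inclusive); dosage
counts the ALT allele, and the frequency ``p`` reported in locus statistics
is the ALT-allele frequency (MAF-symmetric quantities are unaffected by
this orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "locus_stats",
    "mean_he",
    "hwe_exact",
]

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING = -1

INDEL_WINDOW = 5  # bp on either side of an indel POS, inclusive


@dataclass
class GenotypeMatrix:
    """Samples x loci ALT-allele dosage matrix with per-call annotations.

    Attributes
    ----------
    sample_ids : list of str
        Row labels; unique.
    locus_ids : list of str
        Column labels, ``chrom:pos:ref:alt``; unique.
    dosage : ndarray of int8, shape (n_samples, n_loci)
        ALT-allele count per call in {0, 1, 2} or :data:`MISSING`.
    chrom, pos, ref, alt : ndarray
        Per-locus VCF coordinates and alleles.
    depth : ndarray of int32 or None
        Per-call read depth (DP); negative where absent.
    quality : ndarray of float32 or None
        Per-call genotype quality (GQ); NaN where absent.
    allele_depths : ndarray of int32, shape (n_samples, n_loci, 2), or None
        Per-call (ref_reads, alt_reads); negative where absent.
    is_indel, indel_adjacent, multiallelic : ndarray of bool
        Per-locus flags set at read time; flagged records are kept in the
        matrix and removed by the filter cascade, never silently dropped.
    """

    sample_ids: list
    locus_ids: list
    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    depth: np.ndarray | None = None
    quality: np.ndarray | None = None
    allele_depths: np.ndarray | None = None
    is_indel: np.ndarray = field(default=None)  # type: ignore[assignment]
    indel_adjacent: np.ndarray = field(default=None)  # type: ignore[assignment]
    multiallelic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise ValueError("dosage shape does not match sample/locus ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        for name in ("is_indel", "indel_adjacent", "multiallelic"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(m, dtype=bool))
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
            quality=None if self.quality is None else self.quality[idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[idx],
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            locus_ids=[self.locus_ids[i] for i in idx],
            dosage=self.dosage[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            depth=None if self.depth is None else self.depth[:, idx],
            quality=None if self.quality is None else self.quality[:, idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, idx],
            is_indel=self.is_indel[idx],
            indel_adjacent=self.indel_adjacent[idx],
            multiallelic=self.multiallelic[idx],
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([lookup[s] for s in sample_ids])

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            quality=None if self.quality is None else self.quality.copy(),
            allele_depths=None if self.allele_depths is None else self.allele_depths.copy(),
            is_indel=self.is_indel.copy(),
            indel_adjacent=self.indel_adjacent.copy(),
            multiallelic=self.multiallelic.copy(),
        )

    # -- TSV round-trip -------------------------------------------------

    def to_tsv(self, path) -> None:
        """Dump the dosage matrix as loci-by-samples TSV ('.' = missing)."""
        df = pd.DataFrame(
            self.dosage.T.astype(object), index=self.locus_ids, columns=self.sample_ids
        )
        df = df.where(df != MISSING, ".")
        df.index.name = "locus"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        dosage = df.replace(".", str(MISSING)).astype(np.int8).to_numpy().T
        locus_ids = list(df.index)
        chrom, pos, ref, alt = _split_locus_ids(locus_ids)
        return cls(
            sample_ids=list(df.columns),
            locus_ids=locus_ids,
            dosage=dosage,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
        )


def _split_locus_ids(locus_ids):
    parts = [lid.split(":") for lid in locus_ids]
    chrom = np.array([p[0] for p in parts], dtype=object)
    pos = np.array([int(p[1]) if len(p) > 1 else 0 for p in parts], dtype=np.int64)
    ref = np.array([p[2] if len(p) > 2 else "N" for p in parts], dtype=object)
    alt = np.array([p[3] if len(p) > 3 else "N" for p in parts], dtype=object)
    return chrom, pos, ref, alt


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------


def read_vcf(path, require_fields: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    GT is required; DP, GQ and AD are carried along when present. Indel
    records, SNPs within ±5 bp (inclusive, same chromosome) of any indel
    record, and multi-allelic records are *flagged*, not dropped — the
    filter cascade removes them explicitly so that the removal is counted.

    Parameters
    ----------
    path : str or Path
        VCF file (plain or bgzipped).
    require_fields : bool
        If True, raise when DP/GQ/AD are absent instead of returning None
        arrays.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)

    locus_ids, chroms, poss, refs, alts = [], [], [], [], []
    dosages, depths, quals, ads = [], [], [], []
    indel_flags, multi_flags = [], []
    has_dp = has_gq = has_ad = False
    indel_pos: dict[str, list[int]] = {}
    seen = set()

    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        lid = f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
        if lid in seen:
            raise ValueError(f"duplicate locus id {lid}")
        seen.add(lid)
        locus_ids.append(lid)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(alt)
        indel_flags.append(bool(v.is_indel))
        if v.is_indel:
            indel_pos.setdefault(v.CHROM, []).append(v.POS)
        multi_flags.append(len(v.ALT) > 1)

        # gts012: 0 homref, 1 het, 2 homalt, 3 unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        d = np.where(gt == 3, MISSING, gt)
        dosages.append(d)

        dp = v.format("DP")
        if dp is not None:
            has_dp = True
            dp = dp.reshape(n).astype(np.int32)
        depths.append(dp)
        gq = v.format("GQ")
        if gq is not None:
            has_gq = True
            gq = gq.reshape(n).astype(np.float32)
        quals.append(gq)
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            has_ad = True
            ad = ad[:, :2].astype(np.int32)
        else:
            ad = None
        ads.append(ad)

    if not locus_ids:
        raise ValueError(f"no records in {path}")
    m = len(locus_ids)
    dosage = np.stack(dosages, axis=1)

    def _stack(cols, fill, shape_tail=()):
        out = np.full((n, m) + shape_tail, fill)
        for j, c in enumerate(cols):
            if c is not None:
                out[:, j] = c
        return out

    depth = _stack(depths, -1).astype(np.int32) if has_dp else None
    quality = _stack(quals, np.nan).astype(np.float32) if has_gq else None
    allele_depths = _stack(ads, -1, (2,)).astype(np.int32) if has_ad else None
    if require_fields and (depth is None or quality is None or allele_depths is None):
        raise ValueError("VCF lacks DP/GQ/AD but require_fields=True")

    pos_arr = np.array(poss, dtype=np.int64)
    chrom_arr = np.array(chroms, dtype=object)
    adjacent = np.zeros(m, dtype=bool)
    for c, positions in indel_pos.items():
        parr = np.array(positions, dtype=np.int64)
        on_chrom = chrom_arr == c
        dist = np.abs(pos_arr[on_chrom, None] - parr[None, :]).min(axis=1)
        sub = adjacent[on_chrom]
        sub |= dist <= INDEL_WINDOW
        adjacent[on_chrom] = sub
    adjacent &= ~np.array(indel_flags)  # indels themselves carry is_indel

    return GenotypeMatrix(
        sample_ids=samples,
        locus_ids=locus_ids,
        dosage=dosage,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        depth=depth,
        quality=quality,
        allele_depths=allele_depths,
        is_indel=np.array(indel_flags),
        indel_adjacent=adjacent,
        multiallelic=np.array(multi_flags),
    )


def write_vcf(G: GenotypeMatrix, path, extra_header_lines=()) -> None:
    """Write a minimal VCF 4.2 with GT, and DP/GQ/AD where available."""
    fmt_keys = ["GT"]
    if G.depth is not None:
        fmt_keys.append("DP")
    if G.quality is not None:
        fmt_keys.append("GQ")
    if G.allele_depths is not None:
        fmt_keys.append("AD")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(str(c) for c in G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "DP" in fmt_keys:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if "GQ" in fmt_keys:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if "AD" in fmt_keys:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for j in range(G.n_loci):
            fields = [
                str(G.chrom[j]),
                str(int(G.pos[j])),
                ".",
                str(G.ref[j]),
                str(G.alt[j]),
                ".",
                "PASS",
                ".",
                ":".join(fmt_keys),
            ]
            calls = []
            for i in range(G.n_samples):
                parts = [gt_str[int(G.dosage[i, j])]]
                if "DP" in fmt_keys:
                    dp = int(G.depth[i, j])
                    parts.append(str(dp) if dp >= 0 else ".")
                if "GQ" in fmt_keys:
                    q = G.quality[i, j]
                    parts.append(str(int(q)) if np.isfinite(q) else ".")
                if "AD" in fmt_keys:
                    ad = G.allele_depths[i, j]
                    parts.append(f"{int(ad[0])},{int(ad[1])}" if ad[0] >= 0 else ".,.")
                calls.append(":".join(parts))
            fh.write("\t".join(fields) + "\t" + "\t".join(calls) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Required column: ``sample_id``. Recognised optional columns: ``role``
    (parent / offspring / reference / other), ``replicate_of``,
    ``megagametophyte_of``, ``ramet_count``, ``library_id``. Referential
    integrity of replicate/megagametophyte links is checked.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must contain a sample_id column")
    for col in ("role", "replicate_of", "megagametophyte_of", "library_id"):
        if col not in meta.columns:
            meta[col] = pd.NA
    if "ramet_count" in meta.columns:
        meta["ramet_count"] = pd.to_numeric(meta["ramet_count"], errors="coerce")
        if (meta["ramet_count"].dropna() <= 0).any():
            raise ValueError("ramet_count must be positive")
    else:
        meta["ramet_count"] = np.nan
    ids = set(meta["sample_id"])
    for col in ("replicate_of", "megagametophyte_of"):
        refs = meta[col].dropna()
        missing = set(refs) - ids
        if missing:
            raise ValueError(f"{col} refers to unknown samples: {sorted(missing)}")
    return meta.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Per-locus statistics
# ---------------------------------------------------------------------------


def hwe_exact(n_het: int, n_hom_ref: int, n_hom_alt: int) -> tuple[float, float]:
    """Exact Hardy–Weinberg test conditioned on allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts in ``n`` diploids and sums the hypergeometric-type probabilities.

    Returns
    -------
    (hwe_p, het_excess_p)
        Two-sided p-value (sum of outcome probabilities not exceeding the
        observed one) and the one-sided heterozygote-excess tail
        P(het count >= observed).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return np.nan, np.nan
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0, 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h) up to a constant: conditional distribution of het count given
    # allele counts under random union of gametes
    from scipy.special import gammaln

    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    i = np.searchsorted(hets, obs)
    if i >= len(hets) or hets[i] != obs:
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = p[i]
    two_sided = min(1.0, float(p[p <= p_obs * (1 + 1e-12)].sum()))
    excess = min(1.0, float(p[hets >= obs].sum()))
    return two_sided, excess


def locus_stats(G: GenotypeMatrix, samples=None) -> pd.DataFrame:
    """Per-locus allele frequency, diversity and HWE statistics.

    Parameters
    ----------
    G : GenotypeMatrix
    samples : sequence of sample ids, optional
        Subset over which frequencies are computed (default: all samples).

    Returns
    -------
    DataFrame indexed by locus id with columns ``p`` (ALT frequency), ``maf``,
    ``call_rate``, ``ho``, ``he``, ``f_it`` (1 - Ho/He; NaN where He = 0),
    ``hwe_p``, ``het_excess_p``, ``n_called``. Loci with no calls have all
    statistics NaN (flagged undefined). Invariant to sample order.
    """
    sub = G if samples is None else G.subset_samples(samples)
    d = sub.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    n_het = ((d == 1) & called).sum(axis=0)
    n_hom_alt = (d == 2).sum(axis=0)
    n_hom_ref = (d == 0).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (n_het + 2 * n_hom_alt) / (2 * n_called), np.nan)
        q = 1.0 - p
        maf = np.minimum(p, q)
        call_rate = n_called / sub.n_samples
        ho = np.where(n_called > 0, n_het / n_called, np.nan)
        he = 1.0 - p**2 - q**2
        f_it = np.where(he > 0, 1.0 - ho / he, np.nan)

    hwe_p = np.full(sub.n_loci, np.nan)
    het_excess_p = np.full(sub.n_loci, np.nan)
    for j in range(sub.n_loci):
        if n_called[j] > 0:
            hwe_p[j], het_excess_p[j] = hwe_exact(
                int(n_het[j]), int(n_hom_ref[j]), int(n_hom_alt[j])
            )

    stats = pd.DataFrame(
        {
            "p": p,
            "maf": maf,
            "call_rate": call_rate,
            "ho": ho,
            "he": he,
            "f_it": f_it,
            "hwe_p": hwe_p,
            "het_excess_p": het_excess_p,
            "n_called": n_called,
        },
        index=pd.Index(sub.locus_ids, name="locus"),
    )
    stats.loc[n_called == 0, ["p", "maf", "call_rate", "ho", "he", "f_it"]] = np.nan
    stats.loc[n_called == 0, "call_rate"] = 0.0
    return stats


def mean_he(stats: pd.DataFrame) -> float:
    """Multilocus expected heterozygosity, ``1 - (1/m) sum_l (p_l^2 + q_l^2)``.

    Loci with undefined ``p`` are excluded; raises if none remain.
    """
    p = stats["p"].dropna().to_numpy()
    if p.size == 0:
        raise ValueError("mean_he requires at least one locus with defined p")
    return float(np.mean(1.0 - p**2 - (1.0 - p) ** 2))
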