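"""Synthetic seed-orchard crops with GBS-like observation noise.

The generator produces the study conditions end to end with known truth:
28 clonal parents deployed with the Västerhus ramet numbers, open-pollinated
offspring with external pollen contamination and natural same-genotype
mating (selfing), an L-shaped allele-frequency spectrum dominated by rare
alleles, and a read-level observation model with overdispersed depth, a
depth floor, allelic dropout of heterozygotes, allele mistyping, paralog
loci that inject excess heterozygosity, and per-library locus dropout that
spreads the shared-locus proportion between replicates.

Everything is reproducible from ``(config, seed)``; the seed is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_vcf
from . import vasterhus

__all__ = [
    "SimulationConfig",
    "TruePedigree",
    "draw_frequencies",
    "hwe_genotypes",
    "mendelian_offspring",
    "simulate_crop",
    "gbs_observe",
    "simulate_replicate_pairs",
    "make_fixture",
    "make_qc_fixture",
]

EXTERNAL = "EXTERNAL"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic orchard and its GBS observation model.

    Defaults reproduce the study conditions: 28 parents with the Västerhus
    ramet counts as fecundity weights, 298 sampled seedlings, 33.6% external
    pollen, natural same-genotype mating (expected selfing ~3%), an L-shaped
    frequency spectrum from MAF 0.01, ~5% per-allele mistyping, mean depth 45
    with an 8x call floor, a small fraction of paralog-collapsed loci, and
    four libraries with unequal locus dropout.
    """

    # genome / spectrum
    n_loci: int = 5000
    spectrum: str | tuple = "l_shaped"  # "l_shaped", "uniform", or explicit tuple
    maf_min: float = 0.01

    # orchard
    n_parents: int = 28
    ramet_counts: tuple | None = None  # default: Västerhus census
    pollen_contamination: float = 0.336
    n_offspring: int = 298
    n_external_donors: int | None = None  # None: fresh donor per event
    forced_selfing_rate: float | None = None  # None: natural same-genotype mating
    allow_same_genotype_mating: bool = True

    # extra sample groups
    n_reference: int = 100
    n_replicate_pairs: int = 8
    megagametophyte_parents: int = 2
    megagametophytes_each: int = 8

    # observation model
    mean_depth: float = 45.0
    depth_dispersion: float = 3.0
    allele_error: float = 0.05
    paralog_fraction: float = 0.03
    paralog_het_rate: float = 0.5
    min_depth: int = 8
    n_libraries: int = 4
    library_locus_dropout: tuple = (0.01, 0.03, 0.05, 0.30)

    seed: int = None  # type: ignore[assignment]  # mandatory

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is mandatory")
        for name in ("pollen_contamination", "paralog_fraction", "paralog_het_rate",
                     "allele_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ramet_counts is None:
            counts = vasterhus.RAMET_COUNTS[: self.n_parents]
            if self.n_parents > len(counts):
                raise ValueError("no default ramet counts beyond 28 parents")
            self.ramet_counts = tuple(int(c) for c in counts)
        if any(c <= 0 for c in self.ramet_counts):
            raise ValueError("ramet counts must be positive")
        if len(self.ramet_counts) != self.n_parents:
            raise ValueError("ramet_counts length must equal n_parents")


@dataclass
class TruePedigree:
    """Ground truth emitted by :func:`simulate_crop`."""

    offspring: pd.DataFrame  # offspring_id, mother, father, selfed, external
    parent_ids: list
    p: np.ndarray  # true ALT frequencies
    donor_genotypes: dict = field(default_factory=dict)


def draw_frequencies(n_loci: int, spectrum="l_shaped", seed: int = 0,
                     maf_min: float = 0.01) -> np.ndarray:
    """Draw per-locus ALT frequencies.

    ``l_shaped`` uses density proportional to 1/x on [maf_min, 0.5] — the
    rare-allele-dominated spectrum typical of range-wide conifer samples,
    in which roughly ln(5)/ln(0.5/maf_min) of loci fall in
    [maf_min, 5 maf_min] — folded to MAF <= 0.5 with random allele
    orientation. ``uniform`` draws MAF uniformly on [maf_min, 0.5]. A tuple
    or array is returned verbatim.
    """
    if not np.isscalar(spectrum):
        return np.asarray(spectrum, dtype=float)
    rng = np.random.default_rng(seed)
    if maf_min <= 0:
        raise ValueError("maf_min must be positive")
    if spectrum == "l_shaped":
        u = rng.random(n_loci)
        maf = maf_min * (0.5 / maf_min) ** u  # inverse CDF of 1/x density
    elif spectrum == "uniform":
        maf = rng.uniform(maf_min, 0.5, n_loci)
    else:
        raise ValueError(f"unknown spectrum {spectrum!r}")
    flip = rng.random(n_loci) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def hwe_genotypes(p: np.ndarray, n: int, rng) -> np.ndarray:
    """Draw n outbred diploid genotypes at HWE, one row per individual."""
    shape = (n, p.size)
    return ((rng.random(shape) < p) .astype(np.int8)
            + (rng.random(shape) < p).astype(np.int8))


def _gamete(g: np.ndarray, rng) -> np.ndarray:
    """One haploid gamete per locus from a diploid dosage vector."""
    het = g == 1
    out = (g // 2).astype(np.int8)
    out[het] = rng.integers(0, 2, het.sum(), dtype=np.int8)
    return out


def mendelian_offspring(g_mother: np.ndarray, g_father: np.ndarray, rng) -> np.ndarray:
    """Mendelian segregation at independent loci."""
    return _gamete(g_mother, rng) + _gamete(g_father, rng)


def simulate_crop(config: SimulationConfig):
    """Simulate parents and an open-pollinated seed crop.

    Parents are outbred HWE draws from the spectrum. Each offspring samples
    its mother proportionally to ramet counts; with probability
    ``pollen_contamination`` the father is an external donor (a fresh HWE
    genotype, or one of a finite donor pool), otherwise an internal parent
    drawn proportionally to ramet counts — same-genotype mating yields a
    selfed offspring. With ``forced_selfing_rate`` set, that fraction of
    internal matings is forced to the mother's genotype instead.

    Returns ``(TruePedigree, true_genotypes: DataFrame samples x loci)``
    where rows cover parents then offspring (plus megagametophytes when
    configured, emitted as haploid-as-homozygous genotypes).
    """
    rng = np.random.default_rng(config.seed)
    p = draw_frequencies(config.n_loci, config.spectrum, rng.integers(2**31), config.maf_min)
    parents = hwe_genotypes(p, config.n_parents, rng)
    parent_ids = [f"P{i+1:02d}" for i in range(config.n_parents)]
    weights = np.asarray(config.ramet_counts, dtype=float)
    weights = weights / weights.sum()

    rows = {pid: parents[i] for i, pid in enumerate(parent_ids)}
    ped_rows = []
    donor_genotypes: dict[str, np.ndarray] = {}
    n_ext = 0
    for k in range(config.n_offspring):
        oid = f"O{k+1:03d}"
        mi = rng.choice(config.n_parents, p=weights)
        mother = parent_ids[mi]
        if rng.random() < config.pollen_contamination:
            if config.n_external_donors is None:
                n_ext += 1
                father = f"{EXTERNAL}:{n_ext}"
                donor_genotypes.setdefault(father, hwe_genotypes(p, 1, rng)[0])
            else:
                d = rng.integers(config.n_external_donors)
                father = f"{EXTERNAL}:{d+1}"
                if father not in donor_genotypes:
                    donor_genotypes[father] = hwe_genotypes(p, 1, rng)[0]
            g_f = donor_genotypes[father]
            external = True
        else:
            if (config.forced_selfing_rate is not None
                    and rng.random() < config.forced_selfing_rate):
                fi = mi
            else:
                fi = rng.choice(config.n_parents, p=weights)
                while not config.allow_same_genotype_mating and fi == mi:
                    fi = rng.choice(config.n_parents, p=weights)
            father = parent_ids[fi]
            g_f = parents[fi]
            external = False
        g_o = mendelian_offspring(parents[mi], g_f, rng)
        rows[oid] = g_o
        ped_rows.append(
            {
                "offspring_id": oid,
                "mother": mother,
                "father": father,
                "selfed": (not external) and father == mother,
                "external": external,
            }
        )

    for i in range(config.megagametophyte_parents):
        pid = parent_ids[i]
        for m in range(config.megagametophytes_each):
            mid = f"M{pid}_{m+1}"
            rows[mid] = 2 * _gamete(parents[i], rng)  # haploid scored as homozygous
            ped_rows.append(
                {
                    "offspring_id": mid,
                    "mother": pid,
                    "father": pid,
                    "selfed": False,
                    "external": False,
                }
            )

    true_genotypes = pd.DataFrame(
        np.vstack(list(rows.values())),
        index=list(rows.keys()),
        columns=[f"chr1:{1000 + 10 * j}:A:G" for j in range(config.n_loci)],
    )
    pedigree = TruePedigree(
        offspring=pd.DataFrame(ped_rows),
        parent_ids=parent_ids,
        p=p,
        donor_genotypes=donor_genotypes,
    )
    return pedigree, true_genotypes


def gbs_observe(
    true_genotypes: pd.DataFrame,
    config: SimulationConfig,
    p: np.ndarray,
    rng=None,
    library_of: np.ndarray | None = None,
    replicate_of: dict | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Pass true genotypes through the GBS observation model.

    Per call: read depth is negative-binomial with the configured mean and
    dispersion; calls below the depth floor are missing; each true allele is
    mis-scored with probability ``allele_error`` (replaced by a draw from
    the population frequencies); true heterozygotes receive
    binomial(depth, 1/2) allele reads and collapse to a homozygote when one
    allele draws zero reads (allelic dropout); a designated fraction of loci
    behave as collapsed paralogs, flipping homozygote calls to heterozygotes
    at ``paralog_het_rate``; and each library drops whole loci at its own
    rate. Samples listed in `replicate_of` are appended as independent
    re-observations of the same true genotype, placed round-robin in other
    libraries.

    Returns the observed :class:`GenotypeMatrix` and a metadata frame with
    library assignments and replicate links.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ids = list(true_genotypes.index)
    truth = true_genotypes.to_numpy(dtype=np.int8)
    replicate_of = replicate_of or {}
    base_n = len(ids)
    if library_of is None:
        library_of = np.arange(base_n) % config.n_libraries
    lib = list(library_of)
    rep_links = {}
    for rep_id, src in replicate_of.items():
        i = ids.index(src)
        truth = np.vstack([truth, truth[i]])
        ids = ids + [rep_id]
        lib.append((lib[i] + 1) % config.n_libraries)
        rep_links[rep_id] = src
    lib = np.asarray(lib)
    n, L = truth.shape

    # library-level locus dropout (same loci dropped for every member)
    drops = np.asarray(config.library_locus_dropout, dtype=float)
    if drops.size < config.n_libraries:
        drops = np.resize(drops, config.n_libraries)
    lib_mask = rng.random((config.n_libraries, L)) < drops[:, None]
    dropped = lib_mask[lib]

    depth = rng.negative_binomial(
        config.depth_dispersion,
        config.depth_dispersion / (config.depth_dispersion + config.mean_depth),
        size=(n, L),
    ).astype(np.int32)
    missing = dropped | (depth < config.min_depth)

    # allele-level mistyping
    a1 = (truth >= 1).astype(np.int8)
    a2 = (truth == 2).astype(np.int8)
    e = config.allele_error
    if e > 0:
        for a in (a1, a2):
            err = rng.random((n, L)) < e
            redraw = (rng.random((n, L)) < p[None, :]).astype(np.int8)
            a[err] = redraw[err]
    obs = (a1 + a2).astype(np.int8)

    # heterozygote allelic dropout from finite read sampling
    het = obs == 1
    alt_reads = np.zeros((n, L), dtype=np.int32)
    alt_reads[het] = rng.binomial(depth[het], 0.5)
    obs = np.where(het & (alt_reads == 0), 0, obs)
    obs = np.where(het & (alt_reads == depth), 2, obs)
    alt_reads = np.where(obs == 2, depth, np.where(obs == 0, 0, alt_reads))
    ref_reads = depth - alt_reads

    # paralog-collapsed loci: homozygotes flip to spurious heterozygotes
    n_paralog = int(round(config.paralog_fraction * L))
    paralog = np.zeros(L, dtype=bool)
    if n_paralog:
        paralog[rng.choice(L, n_paralog, replace=False)] = True
        flip = paralog[None, :] & (obs != 1) & (rng.random((n, L)) < config.paralog_het_rate)
        obs = np.where(flip, 1, obs)
        alt_reads = np.where(flip, depth // 2, alt_reads)
        ref_reads = depth - alt_reads

    quality = np.minimum(99, 3 * depth).astype(np.float32)
    obs = np.where(missing, MISSING, obs).astype(np.int8)

    cols = list(true_genotypes.columns)
    parts = [c.split(":") for c in cols]
    G = GenotypeMatrix(
        sample_ids=ids,
        locus_ids=cols,
        dosage=obs,
        chrom=np.array([pt[0] for pt in parts], dtype=object),
        pos=np.array([int(pt[1]) for pt in parts], dtype=np.int64),
        ref=np.array([pt[2] for pt in parts], dtype=object),
        alt=np.array([pt[3] for pt in parts], dtype=object),
        depth=depth,
        quality=quality,
        allele_depths=np.stack([ref_reads, alt_reads], axis=-1),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "library_id": [f"lib{int(l)+1}" for l in lib],
            "replicate_of": [rep_links.get(s, pd.NA) for s in ids],
        }
    ).set_index("sample_id", drop=False)
    return G, meta


def simulate_kinship_dyads(
    kind: str,
    n_dyads: int,
    n_loci: int,
    seed: int,
    maf_range: tuple = (0.1, 0.5),
):
    """Error-free dyads of a known kinship class on a shared locus panel.

    `kind` is ``parent_offspring``, ``full_sib``, ``half_sib`` (shared
    father, unrelated mothers), ``selfed`` (selfed offspring vs its parent)
    or ``unrelated``. MAF is uniform on `maf_range` with random allele
    orientation. Returns ``(dosage (2 n_dyads, L), pairs, p)`` where row
    2k / 2k+1 hold dyad k and ``p`` are the true ALT frequencies.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], n_loci)
    flip = rng.random(n_loci) < 0.5
    p = np.where(flip, 1 - maf, maf)
    rows = []
    for _ in range(n_dyads):
        if kind == "parent_offspring":
            gm, gf = hwe_genotypes(p, 2, rng)
            a, b = gm, mendelian_offspring(gm, gf, rng)
        elif kind == "full_sib":
            gm, gf = hwe_genotypes(p, 2, rng)
            a = mendelian_offspring(gm, gf, rng)
            b = mendelian_offspring(gm, gf, rng)
        elif kind == "half_sib":
            gf, m1, m2 = hwe_genotypes(p, 3, rng)
            a = mendelian_offspring(m1, gf, rng)
            b = mendelian_offspring(m2, gf, rng)
        elif kind == "selfed":
            gm = hwe_genotypes(p, 1, rng)[0]
            a, b = gm, mendelian_offspring(gm, gm, rng)
        elif kind == "unrelated":
            a, b = hwe_genotypes(p, 2, rng)
        else:
            raise ValueError(f"unknown kinship kind {kind!r}")
        rows += [a, b]
    pairs = [(2 * k, 2 * k + 1) for k in range(n_dyads)]
    return np.asarray(rows, dtype=np.int8), pairs, p


def simulate_replicate_pairs(
    n_pairs: int,
    n_loci: int,
    error: float,
    seed: int,
    p: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replicate pairs where one member's alleles are mis-scored at `error`.

    Matches the operational definition of the replicate error rate: one
    member is the reference call set and each allele of the other is
    flipped with probability `error`, so the expected proportion of
    mismatching alleles between the pair equals `error` exactly. No other
    noise is applied; all loci are co-called.
    """
    rng = np.random.default_rng(seed)
    if p is None:
        p = draw_frequencies(n_loci, "uniform", rng.integers(2**31), 0.05)
    truth = hwe_genotypes(p, n_pairs, rng)
    a1 = (truth >= 1).astype(np.int8)
    a2 = (truth == 2).astype(np.int8)
    f1 = rng.random(truth.shape) < error
    f2 = rng.random(truth.shape) < error
    rep = (np.where(f1, 1 - a1, a1) + np.where(f2, 1 - a2, a2)).astype(np.int8)

    ids = [f"S{i+1:03d}" for i in range(n_pairs)] + [f"S{i+1:03d}_rep" for i in range(n_pairs)]
    dosage = np.vstack([truth, rep])
    G = GenotypeMatrix(
        sample_ids=ids,
        locus_ids=[f"chr1:{1000+10*j}:A:G" for j in range(n_loci)],
        dosage=dosage,
        chrom=np.array(["chr1"] * n_loci, dtype=object),
        pos=np.array([1000 + 10 * j for j in range(n_loci)], dtype=np.int64),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["G"] * n_loci, dtype=object),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "replicate_of": [pd.NA] * n_pairs + [f"S{i+1:03d}" for i in range(n_pairs)],
        }
    ).set_index("sample_id", drop=False)
    return G, meta


def make_fixture(config: SimulationConfig, out_prefix) -> dict:
    """Write a complete reproducible fixture: VCF, metadata and truth tables.

    Emits ``<prefix>.vcf`` (GT/DP/GQ/AD), ``<prefix>.meta.tsv`` (roles,
    replicate and megagametophyte links, ramet counts, libraries),
    ``<prefix>.pedigree.tsv``, ``<prefix>.true_genotypes.tsv`` and
    ``<prefix>.frequencies.tsv``. Byte-identical for identical
    (config, seed).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ped, truth = simulate_crop(config)

    # reference panel of unrelated individuals observed alongside
    ref_ids = [f"R{i+1:03d}" for i in range(config.n_reference)]
    ref_g = hwe_genotypes(ped.p, config.n_reference, rng)
    ext_ids = list(ped.donor_genotypes)
    all_truth = pd.concat(
        [
            truth,
            pd.DataFrame(ref_g, index=ref_ids, columns=truth.columns),
        ]
    )

    rep_sources = rng.choice(
        [s for s in all_truth.index if not s.startswith("M")],
        size=min(config.n_replicate_pairs, len(all_truth)),
        replace=False,
    )
    replicate_of = {f"{s}_rep": s for s in rep_sources}
    G, obs_meta = gbs_observe(
        all_truth, config, ped.p, rng=rng, replicate_of=replicate_of
    )

    def _role(s):
        if s.startswith("P"):
            return "parent"
        if s.startswith("O"):
            return "offspring"
        if s.startswith("R"):
            return "reference"
        return "other"

    meta = obs_meta.copy()
    meta["role"] = [_role(replicate_of.get(s, s)) for s in meta["sample_id"]]
    mega = {
        r.offspring_id: r.mother
        for r in ped.offspring.itertuples()
        if r.offspring_id.startswith("M")
    }
    meta["megagametophyte_of"] = [mega.get(s, pd.NA) for s in meta["sample_id"]]
    ramets = dict(zip(ped.parent_ids, config.ramet_counts))
    meta["ramet_count"] = [ramets.get(s, pd.NA) for s in meta["sample_id"]]

    paths = {
        "vcf": f"{out_prefix}.vcf",
        "meta": f"{out_prefix}.meta.tsv",
        "pedigree": f"{out_prefix}.pedigree.tsv",
        "true_genotypes": f"{out_prefix}.true_genotypes.tsv",
        "frequencies": f"{out_prefix}.frequencies.tsv",
    }
    write_vcf(G, paths["vcf"])
    meta.to_csv(paths["meta"], sep="\t", index=False)
    ped.offspring.to_csv(paths["pedigree"], sep="\t", index=False)
    all_truth.to_csv(paths["true_genotypes"], sep="\t")
    pd.DataFrame({"locus": truth.columns, "p": ped.p}).to_csv(
        paths["frequencies"], sep="\t", index=False
    )
    return paths


def make_qc_fixture() -> tuple[GenotypeMatrix, dict]:
    """Deterministic 12-locus matrix engineering one failure per cascade stage.

    125 samples; exactly one locus each is indel-adjacent, multi-allelic,
    below the 0.01 MAF floor (one heterozygote: MAF = 1/250 = 0.004), below
    60% call rate, above 70% heterozygotes, and a significant-heterozygote-
    excess locus (negative F_IT and small exact-test p); the remaining six
    are clean and survive. Returns the matrix and a dict naming which locus
    id trips which stage.
    """
    n = 125
    loci = {}

    def balanced(n_ref, n_het, n_alt, n_missing=0):
        v = np.array(
            [0] * n_ref + [1] * n_het + [2] * n_alt + [MISSING] * n_missing,
            dtype=np.int8,
        )
        assert v.size == n
        return v

    clean = balanced(31, 63, 31)
    loci["chr1:100:A:G"] = ("indel_and_adjacent", clean.copy())
    loci["chr1:200:A:G"] = ("biallelic", clean.copy())
    loci["chr1:300:A:G"] = ("maf", balanced(124, 1, 0))
    loci["chr1:400:A:G"] = ("call_rate", balanced(30, 22, 10, 63))
    loci["chr1:500:A:G"] = ("het_fraction", balanced(31, 94, 0))
    loci["chr1:600:A:G"] = ("fit_hwe", balanced(20, 80, 25))
    for j in range(6):
        rolled = np.roll(clean, 7 * (j + 1))
        loci[f"chr1:{700 + 100 * j}:A:G"] = ("kept", rolled)

    ids = list(loci)
    dosage = np.stack([loci[k][1] for k in ids], axis=1)
    m = len(ids)
    G = GenotypeMatrix(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        locus_ids=ids,
        dosage=dosage,
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=np.array([int(k.split(":")[1]) for k in ids], dtype=np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        indel_adjacent=np.array([k == "chr1:100:A:G" for k in ids]),
        multiallelic=np.array([k == "chr1:200:A:G" for k in ids]),
    )
    expected = {k: v[0] for k, v in loci.items()}
    return G, expected


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if not np.isscalar(d["spectrum"]):
        d["spectrum"] = list(np.asarray(d["spectrum"], dtype=float))
    d["ramet_counts"] = list(d["ramet_counts"])
    return d
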