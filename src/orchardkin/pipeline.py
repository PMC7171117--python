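"""End-to-end orchestration: filter -> reference -> relatedness -> parentage
-> mating statistics -> G-matrix, with a machine-readable run manifest.

Every stage writes a TSV into the output directory and logs locus/sample
counts; all randomness is drawn from named substreams of a single root seed,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeMatrix, locus_stats, read_vcf, read_metadata, write_vcf
from .qc_filtering import FilterConfig, filter_cascade, replicate_qc, replicate_qc_frame
from .relatedness import (
    AlleleFrequencyReference,
    DyadEstimate,
    align_to_reference,
    build_reference,
    genotype_correlation,
    inbreeding_ml,
    milligan_ml_batch,
    ritland_pair,
    JacquardCoefficients,
    MIN_SHARED_SNPS,
)
from .parentage import (
    assign_parents,
    assignments_frame,
    cluster_external_donors,
)
from .mating_stats import (
    diversity_summary,
    expected_selfing,
    mating_table,
    nep_with_external,
    effective_parents,
)
from .gmatrix import gmatrix_prefilter, naive_impute, vanraden_matrices

log = logging.getLogger("orchardkin")

__all__ = ["PipelineConfig", "run_pipeline", "compute_dyads", "dyads_frame"]


@dataclass
class PipelineConfig:
    """Structured configuration of the full pipeline (YAML round-trippable)."""

    vcf: str = ""
    metadata: str = ""
    outdir: str = "orchardkin_out"
    seed: int = 1

    filter: FilterConfig = field(default_factory=FilterConfig)

    # relatedness stage
    error_rate: float = 0.05
    ml_model: str = "nine_state"
    min_shared_snps: int = MIN_SHARED_SNPS
    ref_r_threshold: float = 0.15
    ref_min_coverage: float = 0.80

    # parentage stage
    t_po: float = 0.4
    t_self: float = 0.75
    f_self: float = 0.25
    r_link: float = 0.15

    # gmatrix stage
    gmatrix_max_sample_missing: float = 0.90
    gmatrix_call_rate: float = 0.70
    gmatrix_maf: float = 0.10
    impute_mode: str = "draw"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fc = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=fc, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def compute_dyads(
    G: GenotypeMatrix,
    ref: AlleleFrequencyReference,
    pairs,
    error_rate: float = 0.05,
    model: str = "nine_state",
    seed: int = 0,
    maf_min: float = 0.10,
) -> dict:
    """All three estimators for every (id_a, id_b) pair, at MAF >= maf_min.

    Returns a dict keyed by the id pair; ML estimation is batched across
    dyads for speed and is identical to the single-pair routine.
    """
    maf = np.minimum(ref.p, 1 - ref.p)
    keep = maf >= maf_min
    sub_ref = AlleleFrequencyReference(
        [lid for lid, k in zip(ref.locus_ids, keep) if k],
        ref.p[keep],
        ref.source_samples,
        ref.excluded,
    )
    gidx, _ = align_to_reference(G, sub_ref)
    dosage = G.dosage[:, gidx]
    row = {s: i for i, s in enumerate(G.sample_ids)}
    idx_pairs = [(row[a], row[b]) for a, b in pairs]

    delta, ll, conv, n_shared = milligan_ml_batch(
        dosage, idx_pairs, sub_ref, e=error_rate, model=model, seed=seed
    )

    dyads = {}
    maf_sub = np.minimum(sub_ref.p, 1 - sub_ref.p)
    for k, (a, b) in enumerate(pairs):
        i, j = idx_pairs[k]
        r_mom, r_l, n = ritland_pair(dosage[i], dosage[j], sub_ref)
        est = DyadEstimate(id_x=a, id_y=b, n_shared_snps=n, r_ritland=r_mom)
        if n > 1:
            est.var_ritland = float(np.var(r_l))
            shared = (dosage[i] != -1) & (dosage[j] != -1)
            est.mean_maf = float(maf_sub[shared].mean())
            try:
                est.genotype_correlation = genotype_correlation(dosage[i], dosage[j])
            except ValueError:
                pass
        if n_shared[k] > 0 and np.isfinite(ll[k]):
            jac = JacquardCoefficients(delta[k])
            est.jacquard = jac
            est.r_ml = jac.r
            est.loglik = float(ll[k])
            est.ml_converged = bool(conv[k])
        dyads[(a, b)] = est
    return dyads


def dyads_frame(dyads: dict) -> pd.DataFrame:
    rows = []
    for (a, b), est in dyads.items():
        row = {
            "id_x": a,
            "id_y": b,
            "n_shared_snps": est.n_shared_snps,
            "r_ritland": est.r_ritland,
            "var_ritland": est.var_ritland,
            "r_ml": est.r_ml,
            "loglik": est.loglik,
            "ml_converged": est.ml_converged,
            "genotype_correlation": est.genotype_correlation,
            "mean_maf": est.mean_maf,
            "low_confidence": est.low_confidence,
        }
        if est.jacquard is not None:
            for i in range(9):
                row[f"delta{i+1}"] = est.jacquard.delta[i]
            row.update(k0=est.jacquard.k0, k1=est.jacquard.k1, k2=est.jacquard.k2)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write results plus a run manifest.

    Stage failures abort with the stage name; outputs written so far are
    listed as partial in the manifest on disk if the run aborts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "orchardkin",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "complete": False,
    }
    cfg_json = json.dumps(manifest["config"], sort_keys=True, default=str)
    manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()

    def _save_manifest():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "read_inputs"
    try:
        G = read_vcf(config.vcf)
        meta = read_metadata(config.metadata)
        manifest["stages"][stage] = {"n_samples": G.n_samples, "n_loci": G.n_loci}
        log.info("read %d samples x %d loci", G.n_samples, G.n_loci)

        stage = "filter"
        Gf, report = filter_cascade(G, config.filter)
        report.to_tsv(outdir / "filter_report.tsv")
        write_vcf(
            Gf,
            outdir / "filtered.vcf",
            extra_header_lines=[f"##orchardkin_version={__version__}"],
        )
        manifest["stages"][stage] = {"n_loci": Gf.n_loci}

        stage = "replicate_qc"
        try:
            qc = replicate_qc(Gf, meta)
            replicate_qc_frame(qc).to_csv(outdir / "replicate_qc.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"n_pairs": len(qc)}
        except ValueError as err:
            manifest["stages"][stage] = {"skipped": str(err)}

        stage = "reference"
        ref_candidates = list(meta.loc[meta["role"] == "reference", "sample_id"])
        ref_candidates = [s for s in ref_candidates if s in Gf.sample_ids]
        ref = build_reference(
            Gf, ref_candidates, config.ref_r_threshold, config.ref_min_coverage
        )
        pd.DataFrame({"locus": ref.locus_ids, "p": ref.p}).to_csv(
            outdir / "reference_frequencies.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "n_samples": len(ref.source_samples),
            "excluded": ref.excluded,
            "n_loci": len(ref.locus_ids),
        }

        stage = "relatedness"
        # technical replicates serve QC only; analysis roles exclude them
        primary = meta[meta["replicate_of"].isna()]
        parents = [s for s in primary.loc[primary["role"] == "parent", "sample_id"] if s in Gf.sample_ids]
        offspring = [
            s for s in primary.loc[primary["role"] == "offspring", "sample_id"] if s in Gf.sample_ids
        ]
        pairs = [(o, p) for o in offspring for p in parents]
        dyads = compute_dyads(
            Gf,
            ref,
            pairs,
            error_rate=config.error_rate,
            model=config.ml_model,
            seed=_stage_seed(config.seed, "relatedness"),
            maf_min=config.filter.maf_relatedness,
        )
        dyads_frame(dyads).to_csv(outdir / "dyads.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_dyads": len(dyads)}

        stage = "parentage"
        maf = np.minimum(ref.p, 1 - ref.p)
        keep = maf >= config.filter.maf_relatedness
        sub_ref = AlleleFrequencyReference(
            [lid for lid, k in zip(ref.locus_ids, keep) if k],
            ref.p[keep],
            ref.source_samples,
        )
        gidx, _ = align_to_reference(Gf, sub_ref)
        inbreeding = {
            o: inbreeding_ml(
                Gf.dosage[Gf.sample_index(o)][gidx], sub_ref, e=config.error_rate
            )
            for o in offspring
        }
        assignments = [
            assign_parents(
                o,
                parents,
                dyads,
                inbreeding=inbreeding[o],
                t_po=config.t_po,
                t_self=config.t_self,
                f_self=config.f_self,
                min_shared=config.min_shared_snps,
            )
            for o in offspring
        ]
        ped = assignments_frame(assignments)
        ped.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)

        external_ids = [
            a.offspring_id for a in assignments if a.classification in ("external", "single_internal")
        ]
        ext_pairs = [
            (external_ids[i], external_ids[j])
            for i in range(len(external_ids))
            for j in range(i + 1, len(external_ids))
        ]
        ext_dyads = (
            compute_dyads(
                Gf,
                ref,
                ext_pairs,
                error_rate=config.error_rate,
                model=config.ml_model,
                seed=_stage_seed(config.seed, "external"),
                maf_min=config.filter.maf_relatedness,
            )
            if ext_pairs
            else {}
        )
        clusters = cluster_external_donors(assignments, ext_dyads, config.r_link)
        manifest["stages"][stage] = {
            "n_assigned_both": int((ped["classification"].isin(["both_internal", "selfed"])).sum()),
            "n_single": int((ped["classification"] == "single_internal").sum()),
            "n_external_only": int((ped["classification"] == "external").sum()),
            "n_external_donor_clusters": len(clusters),
        }

        stage = "mating_stats"
        ramets = {
            r.sample_id: int(r.ramet_count)
            for r in meta.itertuples()
            if pd.notna(r.ramet_count)
        }
        summary = mating_table(assignments, ramet_counts=ramets or None)
        summary.nep_internal = (
            effective_parents(summary.per_parent["ip"])
            if summary.per_parent["ip"].sum() >= 3
            else np.nan
        )
        if clusters:
            summary.nep_with_external = nep_with_external(summary, clusters)
        if ramets:
            shares = np.array(list(ramets.values()), dtype=float)
            summary.expected_selfing = expected_selfing(
                shares / shares.sum(), summary.pollen_contamination
            )
        summary.per_parent.to_csv(outdir / "mating_table.tsv", sep="\t", index=False)
        summary.scalar_frame().to_csv(outdir / "mating_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "pollen_contamination": summary.pollen_contamination,
            "selfing_rate": summary.selfing_rate,
            "nep_internal": summary.nep_internal,
        }

        stage = "diversity"
        groups = {
            role: list(meta.loc[meta["role"] == role, "sample_id"])
            for role in meta["role"].dropna().unique()
        }
        diversity_summary(Gf, groups).to_csv(outdir / "diversity.tsv", sep="\t", index=False)

        stage = "gmatrix"
        Gg = gmatrix_prefilter(
            Gf,
            config.gmatrix_max_sample_missing,
            config.gmatrix_call_rate,
            config.gmatrix_maf,
        )
        gstats = locus_stats(Gg)
        p = gstats["p"].to_numpy()
        ok = np.isfinite(p) & (p > 0) & (p < 1)
        Gg = Gg.take_loci(ok)
        gref = AlleleFrequencyReference(list(Gg.locus_ids), p[ok], Gg.sample_ids)
        X, frac = naive_impute(
            Gg, gref, seed=_stage_seed(config.seed, "impute"), mode=config.impute_mode
        )
        gres = vanraden_matrices(X, gref, Gg.sample_ids, imputed_fraction=frac)
        gres.to_frame("additive").to_csv(outdir / "G_additive.tsv", sep="\t")
        gres.to_frame("dominance").to_csv(outdir / "G_dominance.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_loci": gres.n_loci,
            "imputed_fraction": gres.imputed_fraction,
        }

        manifest["complete"] = True
        _save_manifest()
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return outdir
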