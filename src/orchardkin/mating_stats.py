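"""Orchard mating-structure and diversity summaries.

Per-parent bookkeeping of internally (IP) and externally (EP) pollinated
seedlings with ramet-proportional expectations, the bias-corrected
effective number of parents

    N_ep = (n - 1)^2 / [ sum_i p_i^2 (n + 1)(n - 2) + 3 - n ],

the expected selfing proportion E(f_s) = (1 - PC) sum_i P_i^2 given the
orchard genotype frequencies and the pollen-contamination level PC, and
per-group diversity (Ho, He, mean MAF).

Note on Eq.-style bookkeeping: ``n`` in N_ep is the total number of
contribution events (gamete slots), not seedlings — each both-internal
offspring contributes two IP events, one per parental slot, and a selfed
offspring contributes both to the same parent. With the Västerhus census
(392 IP events from 196 both-internal seedlings) this convention reproduces
the published effective-parent number; counting seedlings does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, locus_stats, mean_he
from .parentage import EXTERNAL

__all__ = [
    "MatingSummary",
    "mating_table",
    "effective_parents",
    "expected_selfing",
    "diversity_summary",
]


@dataclass
class MatingSummary:
    """Per-parent contribution counts, expectations and scalar summaries."""

    per_parent: pd.DataFrame  # parent_id, ip, ep, e_ip, e_ep
    n_offspring: int
    n_both_internal: int
    n_single_internal: int
    n_external_only: int
    n_selfed: int
    pollen_contamination: float
    selfing_rate: float
    nep_internal: float = np.nan
    nep_with_external: float = np.nan
    expected_selfing: float = np.nan
    notes: list = field(default_factory=list)

    def scalar_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "n_offspring",
                    "n_both_internal",
                    "n_single_internal",
                    "n_external_only",
                    "n_selfed",
                    "pollen_contamination",
                    "selfing_rate",
                    "nep_internal",
                    "nep_with_external",
                    "expected_selfing",
                ],
                "value": [
                    self.n_offspring,
                    self.n_both_internal,
                    self.n_single_internal,
                    self.n_external_only,
                    self.n_selfed,
                    self.pollen_contamination,
                    self.selfing_rate,
                    self.nep_internal,
                    self.nep_with_external,
                    self.expected_selfing,
                ],
            }
        )


def mating_table(assignments, ramet_counts: dict | None = None) -> MatingSummary:
    """Per-parent IP/EP counts and ramet-proportional expectations.

    IP counts every parental gamete slot of a both-internal offspring (a
    selfed offspring contributes 2 to its single parent), EP counts
    single-internal offspring by their internal parent. Expectations follow
    relative ramet abundance: E(IP)_i = (ramets_i / sum ramets) * sum IP,
    likewise for EP. Pollen contamination is the fraction of offspring with
    at least one EXTERNAL slot; the selfing rate is the fraction called
    selfed. Totals reconcile exactly with the assignment classes:
    sum IP = 2 x both-internal and sum EP = single-internal.
    """
    ip: dict[str, int] = {}
    ep: dict[str, int] = {}
    n_both = n_single = n_extonly = n_selfed = 0
    for a in assignments:
        p1, p2 = a.parent1, a.parent2
        if a.classification == "selfed":
            n_selfed += 1
            n_both += 1
            ip[p1] = ip.get(p1, 0) + 2
        elif a.classification == "both_internal":
            n_both += 1
            ip[p1] = ip.get(p1, 0) + 1
            ip[p2] = ip.get(p2, 0) + 1
        elif a.classification == "single_internal":
            n_single += 1
            internal = p1 if p1 != EXTERNAL else p2
            ep[internal] = ep.get(internal, 0) + 1
        else:
            n_extonly += 1

    n = len(list(assignments))
    parents = sorted(set(ip) | set(ep) | set(ramet_counts or {}))
    table = pd.DataFrame(
        {
            "parent_id": parents,
            "ip": [ip.get(pid, 0) for pid in parents],
            "ep": [ep.get(pid, 0) for pid in parents],
        }
    ).set_index("parent_id", drop=False)

    notes = []
    if ramet_counts:
        missing = [pid for pid in parents if pid not in ramet_counts]
        if missing:
            notes.append(f"expectations omitted: no ramet counts for {missing}")
            table["e_ip"] = np.nan
            table["e_ep"] = np.nan
        else:
            ramets = np.array([ramet_counts[pid] for pid in parents], dtype=float)
            share = ramets / ramets.sum()
            table["ramets"] = ramets.astype(int)
            table["e_ip"] = share * table["ip"].sum()
            table["e_ep"] = share * table["ep"].sum()
    else:
        notes.append("expectations omitted: no ramet counts supplied")

    n_external_pollinated = n_single + n_extonly
    return MatingSummary(
        per_parent=table,
        n_offspring=n,
        n_both_internal=n_both,
        n_single_internal=n_single,
        n_external_only=n_extonly,
        n_selfed=n_selfed,
        pollen_contamination=n_external_pollinated / n if n else np.nan,
        selfing_rate=n_selfed / n if n else np.nan,
        notes=notes,
    )


def effective_parents(contribution_counts) -> float:
    """Bias-corrected effective number of parents from contribution counts.

    ``N_ep = (n-1)^2 / [sum p_i^2 (n+1)(n-2) + 3 - n]`` with
    ``p_i = count_i / n`` and ``n = sum(counts)``, the total number of
    contribution events. Equals the Simpson-type equivalent number
    ``1 / sum p_i^2`` in the large-n limit and is maximal for equal
    contributions. Undefined (raises) for n < 3.
    """
    counts = np.asarray(list(contribution_counts), dtype=float)
    if np.any(counts < 0):
        raise ValueError("contribution counts must be non-negative")
    n = counts.sum()
    if n < 3:
        raise ValueError("effective_parents requires at least 3 contribution events")
    p = counts / n
    denom = (p**2).sum() * (n + 1) * (n - 2) + 3 - n
    return float((n - 1) ** 2 / denom)


def nep_with_external(summary_or_counts, donor_clusters) -> float:
    """Effective parents including external donors.

    Appends, to the internal IP contribution counts, one contributor per
    external-donor cluster (with its member count as the contribution) and
    one event per sole-internal-parent slot of single-internal offspring.
    """
    if isinstance(summary_or_counts, MatingSummary):
        counts = list(summary_or_counts.per_parent["ip"] + summary_or_counts.per_parent["ep"])
    else:
        counts = list(summary_or_counts)
    counts += [c.size for c in donor_clusters]
    return effective_parents([c for c in counts if c > 0])


def expected_selfing(genotype_freqs, pollen_contamination: float) -> float:
    """Expected proportion of selfed seedlings, ``(1 - PC) sum_i P_i^2``.

    `genotype_freqs` are the orchard genotype (ramet) frequencies and must
    sum to one; PC is the pollen-contamination proportion. Decreasing in PC
    and invariant under relabeling.
    """
    P = np.asarray(list(genotype_freqs), dtype=float)
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must sum to 1")
    if not 0 <= pollen_contamination <= 1:
        raise ValueError("PC must lie in [0, 1]")
    return float((1.0 - pollen_contamination) * (P**2).sum())


def diversity_summary(G: GenotypeMatrix, groups: dict) -> pd.DataFrame:
    """Per-group Ho, He, mean MAF, mean depth and SNP counts.

    `groups` maps group label to a list of sample ids; group frequencies are
    recomputed within each group. Empty groups (or groups with no called
    loci) are skipped with a note column.
    """
    rows = []
    for label, sample_ids in groups.items():
        sample_ids = [s for s in sample_ids if s in G.sample_ids]
        if not sample_ids:
            rows.append({"group": label, "n_samples": 0, "note": "skipped: empty group"})
            continue
        stats = locus_stats(G, samples=sample_ids)
        defined = stats["p"].notna()
        if not defined.any():
            rows.append(
                {"group": label, "n_samples": len(sample_ids), "note": "skipped: no called loci"}
            )
            continue
        sub = G.subset_samples(sample_ids)
        depth = np.nan
        if sub.depth is not None:
            d = sub.depth[sub.depth >= 0]
            depth = float(d.mean()) if d.size else np.nan
        rows.append(
            {
                "group": label,
                "n_samples": len(sample_ids),
                "n_snps": int(defined.sum()),
                "ho": float(stats.loc[defined, "ho"].mean()),
                "he": mean_he(stats),
                "maf": float(stats.loc[defined, "maf"].mean()),
                "mean_depth": depth,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
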