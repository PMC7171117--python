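"""Consensus parentage assignment and kinship-class calling.

A candidate parent is accepted for an offspring only when three independent
estimators — method-of-moments relatedness, maximum-likelihood relatedness
and genotype-score correlation — all rank the same candidate first and the
ML estimate clears an acceptance threshold. Slots that fail consensus are
recorded as EXTERNAL (sired by pollen from outside the orchard), never
guessed. Selfed offspring are recognised by a clone-level ML estimate
toward a single candidate together with an elevated individual inbreeding
coefficient. Offspring with an EXTERNAL slot are then clustered on their
mutual relatedness to count distinct external pollen donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relatedness import DyadEstimate, MIN_SHARED_SNPS

__all__ = [
    "EXTERNAL",
    "PedigreeAssignment",
    "ExternalDonorCluster",
    "rank_candidates",
    "assign_parents",
    "classify_dyad",
    "cluster_external_donors",
    "assignments_frame",
]

EXTERNAL = "EXTERNAL"

KINSHIP_R = {
    "unrelated": 0.0,
    "half_sib": 0.25,
    "parent_offspring": 0.5,
    "full_sib": 0.5,
    "clone_or_selfed": 1.0,
}


@dataclass
class PedigreeAssignment:
    offspring_id: str
    parent1: str = EXTERNAL
    parent2: str = EXTERNAL
    classification: str = "external"  # both_internal / single_internal / external / selfed
    consensus: dict = field(default_factory=dict)
    supporting: dict = field(default_factory=dict)
    inbreeding: float = np.nan

    def __post_init__(self):
        if self.classification == "selfed" and self.parent1 != self.parent2:
            raise ValueError("selfed assignment requires parent1 == parent2")


@dataclass
class ExternalDonorCluster:
    cluster_id: int
    members: list

    @property
    def size(self) -> int:
        return len(self.members)


def rank_candidates(
    offspring_id: str,
    candidate_ids,
    dyads: dict,
    min_shared: int = MIN_SHARED_SNPS,
) -> dict:
    """Per-estimator descending candidate rankings for one offspring.

    `dyads` maps (offspring_id, candidate_id) to :class:`DyadEstimate`.
    Candidates sharing fewer than `min_shared` SNPs are excluded. Ties are
    broken toward the larger shared-SNP count, then lexicographic id, and
    flagged in the returned structure.

    Returns ``{"ritland": [...], "ml": [...], "correlation": [...],
    "ties": {...}}``.
    """
    eligible = []
    for cid in candidate_ids:
        est = dyads.get((offspring_id, cid)) or dyads.get((cid, offspring_id))
        if est is None or est.n_shared_snps < min_shared:
            continue
        eligible.append((cid, est))

    rankings: dict = {"ties": {}}
    for key, attr in (
        ("ritland", "r_ritland"),
        ("ml", "r_ml"),
        ("correlation", "genotype_correlation"),
    ):
        scored = [
            (cid, getattr(est, attr), est.n_shared_snps)
            for cid, est in eligible
            if np.isfinite(getattr(est, attr))
        ]
        scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
        rankings[key] = [cid for cid, _, _ in scored]
        if len(scored) >= 2 and scored[0][1] == scored[1][1]:
            rankings["ties"][key] = (scored[0][0], scored[1][0])
    return rankings


def assign_parents(
    offspring_id: str,
    candidate_ids,
    dyads: dict,
    inbreeding: float = np.nan,
    t_po: float = 0.4,
    t_self: float = 0.75,
    f_self: float = 0.25,
    min_shared: int = MIN_SHARED_SNPS,
) -> PedigreeAssignment:
    """Consensus assignment of up to two internal parents for one offspring.

    parent1 comes from estimator consensus: either all three rankings agree
    on the same top candidate, or — the usual case for an offspring with
    both parents in the orchard, whose two true parents sit at
    indistinguishable relatedness — all three top-two *sets* coincide, in
    which case the member with the higher ML relatedness fills slot 1.
    Either way the slot is EXTERNAL unless the ML relatedness reaches
    `t_po`. parent2 is assigned by the same rule after removing parent1
    from candidacy. When the top candidate's ML relatedness reaches
    `t_self` (clone-level) and the offspring's inbreeding coefficient
    reaches `f_self`, the offspring is called selfed and parent2 = parent1.
    Deterministic given the dyad estimates.
    """

    def _consensus(cands):
        ranks = rank_candidates(offspring_id, cands, dyads, min_shared)
        tops = {k: (ranks[k][0] if ranks[k] else None) for k in ("ritland", "ml", "correlation")}
        if tops["ritland"] is not None and len(set(tops.values())) == 1:
            return ranks, tops, tops["ritland"]
        # set-level agreement on the top pair (mother/father order is noise);
        # only meaningful when both members look like parents themselves
        pair_sets = [frozenset(ranks[k][:2]) for k in ("ritland", "ml", "correlation")]

        def _r_ml(c):
            est = dyads.get((offspring_id, c)) or dyads.get((c, offspring_id))
            return est.r_ml if est is not None and np.isfinite(est.r_ml) else -np.inf

        if (
            len(pair_sets[0]) == 2
            and all(s == pair_sets[0] for s in pair_sets)
            and all(_r_ml(c) >= t_po for c in pair_sets[0])
        ):
            best = max(pair_sets[0], key=lambda c: (_r_ml(c), c))
            return ranks, tops, best
        return ranks, tops, None

    ranks1, tops1, top1 = _consensus(candidate_ids)
    assignment = PedigreeAssignment(offspring_id=offspring_id, inbreeding=inbreeding)
    assignment.consensus = {"slot1": tops1}

    if top1 is None:
        return assignment
    est1 = dyads.get((offspring_id, top1)) or dyads.get((top1, offspring_id))
    if not np.isfinite(est1.r_ml) or est1.r_ml < t_po:
        return assignment

    # selfed: clone-level relatedness to a single parent + elevated inbreeding
    if est1.r_ml >= t_self and np.isfinite(inbreeding) and inbreeding >= f_self:
        assignment.parent1 = top1
        assignment.parent2 = top1
        assignment.classification = "selfed"
        assignment.supporting = {"parent1": est1, "parent2": est1}
        return assignment

    assignment.parent1 = top1
    assignment.classification = "single_internal"
    assignment.supporting["parent1"] = est1

    remaining = [c for c in candidate_ids if c != top1]
    ranks2, tops2, top2 = _consensus(remaining)
    assignment.consensus["slot2"] = tops2
    if top2 is not None:
        est2 = dyads.get((offspring_id, top2)) or dyads.get((top2, offspring_id))
        if np.isfinite(est2.r_ml) and est2.r_ml >= t_po:
            assignment.parent2 = top2
            assignment.classification = "both_internal"
            assignment.supporting["parent2"] = est2
    return assignment


def classify_dyad(estimate: DyadEstimate) -> tuple[str, bool]:
    """Kinship class of a dyad from its ML relatedness and k-coefficients.

    The class is the nearest theoretical relatedness among 0 (unrelated),
    0.25 (half-sib), 0.5, and 1 (clone / selfed-vs-parent); at 0.5 the
    IBD-sharing pattern disambiguates parent-offspring (k1 ~ 1) from
    full sibs (k ~ (0.25, 0.5, 0.25)). Returns ``(class, low_confidence)``;
    the flag is set when fewer than 1000 SNPs supported the estimate.
    """
    if estimate.jacquard is None or not np.isfinite(estimate.r_ml):
        raise ValueError("classification requires an ML estimate")
    r = estimate.r_ml
    targets = {"unrelated": 0.0, "half_sib": 0.25, "degree_one": 0.5, "clone_or_selfed": 1.0}
    cls = min(targets, key=lambda k: abs(r - targets[k]))
    if cls == "degree_one":
        j = estimate.jacquard
        po_dist = abs(j.k1 - 1.0) + abs(j.k0) + abs(j.k2)
        fs_dist = abs(j.k0 - 0.25) + abs(j.k1 - 0.5) + abs(j.k2 - 0.25)
        cls = "parent_offspring" if po_dist <= fs_dist else "full_sib"
    return cls, estimate.low_confidence


def cluster_external_donors(
    assignments,
    dyads: dict,
    r_link: float = 0.15,
) -> list:
    """Group externally sired offspring into putative shared-donor clusters.

    Offspring with at least one EXTERNAL slot are single-linkage clustered:
    two belong to the same cluster when their mutual ML relatedness is
    >= `r_link` (half-sib-level sharing through the unobserved father).
    Each cluster counts as one distinct external donor; unlinked offspring
    are singleton donors. The clusters partition the external offspring.
    """
    external = [
        a.offspring_id
        for a in assignments
        if EXTERNAL in (a.parent1, a.parent2)
    ]
    if not external:
        return []
    index = {o: i for i, o in enumerate(external)}
    parent = list(range(len(external)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, a in enumerate(external):
        for b in external[i + 1 :]:
            est = dyads.get((a, b)) or dyads.get((b, a))
            if est is not None and np.isfinite(est.r_ml) and est.r_ml >= r_link:
                union(index[a], index[b])

    groups: dict[int, list] = {}
    for o in external:
        groups.setdefault(find(index[o]), []).append(o)
    return [
        ExternalDonorCluster(cluster_id=k, members=sorted(members))
        for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0]))
    ]


def assignments_frame(assignments) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "offspring_id": a.offspring_id,
                "parent1": a.parent1,
                "parent2": a.parent2,
                "classification": a.classification,
                "inbreeding": a.inbreeding,
            }
        )
    return pd.DataFrame(rows)
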