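"""Consensus parentage, kinship classes and external-donor clustering."""

import numpy as np
import pytest

from orchardkin.parentage import (
    EXTERNAL,
    PedigreeAssignment,
    assign_parents,
    classify_dyad,
    cluster_external_donors,
    rank_candidates,
)
from orchardkin.relatedness import (
    DyadEstimate,
    JacquardCoefficients,
    milligan_ml_batch,
)
from orchardkin.synthetic_data import simulate_kinship_dyads, hwe_genotypes, mendelian_offspring

from conftest import make_ref


def _dyad(o, c, r=0.0, n=2000, corr=None, jac=None):
    est = DyadEstimate(
        id_x=o, id_y=c, n_shared_snps=n, r_ritland=r, r_ml=r,
        genotype_correlation=corr if corr is not None else r,
    )
    if jac is not None:
        est.jacquard = JacquardCoefficients(np.asarray(jac, dtype=float))
        est.r_ml = est.jacquard.r
    return est


class TestRankCandidates:
    def test_low_shared_snp_candidates_excluded(self):
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.5, n=900),
            ("o", "b"): _dyad("o", "b", 0.3, n=2000),
        }
        ranks = rank_candidates("o", ["a", "b"], dyads)
        assert ranks["ritland"] == ["b"]
        assert ranks["ml"] == ["b"]

    def test_tie_broken_by_shared_snps_and_recorded(self):
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.5, n=1500),
            ("o", "b"): _dyad("o", "b", 0.5, n=2500),
        }
        ranks = rank_candidates("o", ["a", "b"], dyads)
        assert ranks["ritland"][0] == "b"
        assert "ritland" in ranks["ties"]

    def test_true_parent_tops_all_rankings_on_simulated_trio(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.5, 2000)
        ref = make_ref(p)
        parents = hwe_genotypes(p, 10, rng)
        child = mendelian_offspring(parents[3], parents[7], rng)
        dosage = np.vstack([parents, child])
        pairs = [(10, i) for i in range(10)]
        delta, ll, conv, n = milligan_ml_batch(dosage, pairs, ref, e=0.0, seed=0)
        dyads = {}
        for k, (_, i) in enumerate(pairs):
            jac = JacquardCoefficients(delta[k])
            from orchardkin.relatedness import ritland_pair, genotype_correlation

            r, _, ns = ritland_pair(dosage[10], dosage[i], ref)
            dyads[("child", f"p{i}")] = DyadEstimate(
                id_x="child", id_y=f"p{i}", n_shared_snps=ns, r_ritland=r,
                r_ml=jac.r, jacquard=jac,
                genotype_correlation=genotype_correlation(dosage[10], dosage[i]),
            )
        ranks = rank_candidates("child", [f"p{i}" for i in range(10)], dyads)
        assert {ranks["ritland"][0], ranks["ml"][0], ranks["correlation"][0]} <= {"p3", "p7"}
        assert set(ranks["ritland"][:2]) == {"p3", "p7"}


class TestAssignParents:
    def test_consensus_disagreement_leaves_external(self):
        # correlation prefers b, the other two prefer a, and b does not look
        # like a parent itself: no assignment is made
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.5, corr=0.3),
            ("o", "b"): _dyad("o", "b", 0.1, corr=0.6),
        }
        a = assign_parents("o", ["a", "b"], dyads)
        assert a.parent1 == EXTERNAL
        assert a.classification == "external"

    def test_order_flip_between_estimators_resolved_by_pair_set(self):
        # both candidates are parent-level; correlation flips the order —
        # the agreed top pair is accepted with the ML-preferred member first
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.52, corr=0.70),
            ("o", "b"): _dyad("o", "b", 0.49, corr=0.72),
            ("o", "c"): _dyad("o", "c", 0.03, corr=0.40),
        }
        a = assign_parents("o", ["a", "b", "c"], dyads)
        assert a.classification == "both_internal"
        assert {a.parent1, a.parent2} == {"a", "b"}
        assert a.parent1 == "a"

    def test_agreeing_candidate_accepted_above_threshold(self):
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.52),
            ("o", "b"): _dyad("o", "b", 0.05),
        }
        a = assign_parents("o", ["a", "b"], dyads)
        assert a.parent1 == "a"
        assert a.parent2 == EXTERNAL
        assert a.classification == "single_internal"

    def test_below_threshold_rejected(self):
        dyads = {("o", "a"): _dyad("o", "a", 0.35)}
        a = assign_parents("o", ["a"], dyads)
        assert a.parent1 == EXTERNAL

    def test_both_parents_assigned(self):
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.55),
            ("o", "b"): _dyad("o", "b", 0.48),
            ("o", "c"): _dyad("o", "c", 0.02),
        }
        a = assign_parents("o", ["a", "b", "c"], dyads)
        assert (a.parent1, a.parent2) == ("a", "b")
        assert a.classification == "both_internal"

    def test_selfed_called_with_high_r_and_inbreeding(self):
        dyads = {
            ("o", "a"): _dyad("o", "a", 0.93),
            ("o", "b"): _dyad("o", "b", 0.4),
        }
        a = assign_parents("o", ["a", "b"], dyads, inbreeding=0.45)
        assert a.classification == "selfed"
        assert a.parent1 == a.parent2 == "a"
        # without elevated inbreeding the same dyad is a plain assignment
        b = assign_parents("o", ["a", "b"], dyads, inbreeding=0.05)
        assert b.classification == "both_internal"

    def test_deterministic(self):
        dyads = {("o", "a"): _dyad("o", "a", 0.52)}
        runs = [assign_parents("o", ["a"], dyads) for _ in range(3)]
        assert len({(r.parent1, r.parent2, r.classification) for r in runs}) == 1


class TestClassifyDyad:
    def test_k_pattern_disambiguation(self):
        po = _dyad("a", "b", jac=[0, 0, 0, 0, 0, 0, 0, 1, 0])
        assert classify_dyad(po)[0] == "parent_offspring"
        fs = _dyad("a", "b", jac=[0, 0, 0, 0, 0, 0, 0.25, 0.5, 0.25])
        assert classify_dyad(fs)[0] == "full_sib"

    def test_nearest_r_classes(self):
        hs = _dyad("a", "b", jac=[0, 0, 0, 0, 0, 0, 0, 0.55, 0.45])
        assert classify_dyad(hs)[0] == "half_sib"  # r = 0.275
        un = _dyad("a", "b", jac=[0, 0, 0, 0, 0, 0, 0, 0.1, 0.9])
        assert classify_dyad(un)[0] == "unrelated"
        cl = _dyad("a", "b", jac=[0, 0, 0, 0, 0, 0, 0.9, 0.1, 0.0])
        assert classify_dyad(cl)[0] == "clone_or_selfed"

    def test_low_confidence_flag(self):
        est = _dyad("a", "b", n=500, jac=[0, 0, 0, 0, 0, 0, 0, 1, 0])
        assert classify_dyad(est)[1] is True

    def test_simulated_half_sibs_classified(self):
        dosage, pairs, p = simulate_kinship_dyads("half_sib", 40, 4000, seed=21)
        ref = make_ref(p)
        delta, ll, conv, n = milligan_ml_batch(dosage, pairs, ref, e=0.05, seed=0)
        classes = []
        for k in range(len(pairs)):
            est = DyadEstimate(
                id_x="a", id_y="b", n_shared_snps=int(n[k]),
                r_ml=JacquardCoefficients(delta[k]).r,
                jacquard=JacquardCoefficients(delta[k]),
            )
            classes.append(classify_dyad(est)[0])
        frac = np.mean([c == "half_sib" for c in classes])
        assert frac >= 0.95


class TestClusterExternalDonors:
    def _assign(self, oid, external=True):
        return PedigreeAssignment(
            offspring_id=oid,
            parent1="P1",
            parent2=EXTERNAL if external else "P2",
            classification="single_internal" if external else "both_internal",
        )

    def test_no_external_offspring(self):
        assignments = [self._assign("o1", external=False)]
        assert cluster_external_donors(assignments, {}) == []

    def test_shared_external_father_forms_cluster(self):
        assignments = [self._assign(o) for o in ("o1", "o2", "o3")]
        dyads = {("o1", "o2"): _dyad("o1", "o2", 0.28), ("o1", "o3"): _dyad("o1", "o3", 0.01),
                 ("o2", "o3"): _dyad("o2", "o3", 0.02)}
        clusters = cluster_external_donors(assignments, dyads)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 2]
        big = next(c for c in clusters if c.size == 2)
        assert big.members == ["o1", "o2"]

    def test_unrelated_externals_are_singletons(self):
        assignments = [self._assign(o) for o in ("o1", "o2", "o3")]
        clusters = cluster_external_donors(assignments, {})
        assert [c.size for c in clusters] == [1, 1, 1]
        members = sorted(m for c in clusters for m in c.members)
        assert members == ["o1", "o2", "o3"]

    def test_simulated_shared_donor_pair(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 3000)
        ref = make_ref(p)
        donor = hwe_genotypes(p, 1, rng)[0]
        o1 = mendelian_offspring(hwe_genotypes(p, 1, rng)[0], donor, rng)
        o2 = mendelian_offspring(hwe_genotypes(p, 1, rng)[0], donor, rng)
        o3 = mendelian_offspring(*hwe_genotypes(p, 2, rng), rng)
        dosage = np.vstack([o1, o2, o3])
        pairs = [(0, 1), (0, 2), (1, 2)]
        delta, ll, conv, n = milligan_ml_batch(dosage, pairs, ref, seed=0)
        names = ["o1", "o2", "o3"]
        dyads = {}
        for k, (i, j) in enumerate(pairs):
            jac = JacquardCoefficients(delta[k])
            dyads[(names[i], names[j])] = DyadEstimate(
                id_x=names[i], id_y=names[j], n_shared_snps=int(n[k]),
                r_ml=jac.r, jacquard=jac,
            )
        assignments = [self._assign(o) for o in names]
        clusters = cluster_external_donors(assignments, dyads)
        assert sorted(c.size for c in clusters) == [1, 2]
        assert next(c for c in clusters if c.size == 2).members == ["o1", "o2"]
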