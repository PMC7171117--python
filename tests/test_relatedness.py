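"""Relatedness estimators: moment, maximum likelihood, correlation."""

import itertools

import numpy as np
import pytest

from orchardkin.genotype_io import MISSING
from orchardkin.relatedness import (
    STATE_PARTITIONS,
    AlleleFrequencyReference,
    JacquardCoefficients,
    build_reference,
    genotype_correlation,
    inbreeding_ml,
    jacquard_genotype_prob,
    maf_threshold_scan,
    milligan_ml_pair,
    observed_state_table,
    ritland_pair,
    ritland_variance,
)
from orchardkin.synthetic_data import (
    hwe_genotypes,
    mendelian_offspring,
    simulate_kinship_dyads,
)

from conftest import make_ref


class TestRitland:
    def test_single_locus_hand_values(self):
        ref = make_ref([0.5])
        r, _, n = ritland_pair(np.array([1]), np.array([1]), ref)
        assert r == pytest.approx(0.0)
        r, _, _ = ritland_pair(np.array([2]), np.array([2]), ref)
        assert r == pytest.approx(2.0)  # single-locus values may exceed 1

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7])
    def test_clone_expectation_is_one(self, p):
        # closed-form expectation over HWE genotype pairs of a clone dyad
        ref = make_ref([p])
        weights = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        expectation = sum(
            w * ritland_pair(np.array([g]), np.array([g]), ref)[0]
            for g, w in weights.items()
        )
        assert expectation == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kind,expected",
        [("unrelated", 0.0), ("parent_offspring", 0.5), ("full_sib", 0.5)],
    )
    def test_unbiased_for_known_kinship(self, kind, expected):
        dosage, pairs, p = simulate_kinship_dyads(kind, 150, 800, seed=5)
        ref = make_ref(p)
        rs = [ritland_pair(dosage[i], dosage[j], ref)[0] for i, j in pairs]
        assert np.mean(rs) == pytest.approx(expected, abs=0.02)

    def test_symmetry_and_missing_handling(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.5, 100)
        ref = make_ref(p)
        a = hwe_genotypes(p, 1, rng)[0]
        b = hwe_genotypes(p, 1, rng)[0]
        a[:10] = MISSING
        r_ab, _, n_ab = ritland_pair(a, b, ref)
        r_ba, _, n_ba = ritland_pair(b, a, ref)
        assert r_ab == pytest.approx(r_ba)
        assert n_ab == n_ba == 90

    def test_no_shared_loci_undefined(self):
        ref = make_ref([0.5, 0.5])
        r, _, n = ritland_pair(
            np.array([1, MISSING]), np.array([MISSING, 1]), ref
        )
        assert np.isnan(r) and n == 0


class TestRitlandVariance:
    def test_hand_values(self):
        assert ritland_variance(0.0, 0.3) == 0.0
        assert ritland_variance(0.5, 0.5) == pytest.approx(4.0)
        assert ritland_variance(0.2, 0.1) == pytest.approx(19.753086, abs=1e-5)

    def test_fixed_locus_rejected(self):
        with pytest.raises(ValueError):
            ritland_variance(0.5, 0.0)


class TestGenotypeCorrelation:
    def test_hand_values(self):
        x = np.array([0, 1, 2, 1])
        assert genotype_correlation(x, x) == pytest.approx(1.0)
        assert genotype_correlation(x, 2 - x) == pytest.approx(-1.0)
        y = np.array([0, 1, 2, 2])
        assert genotype_correlation(x, y) == pytest.approx(0.8528, abs=1e-4)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            genotype_correlation(np.array([1, 1, 1]), np.array([0, 1, 2]))


def mc_state_probability(state_idx, gx, gy, p, e, n=400_000, seed=0):
    """Monte-Carlo oracle: sample allele types per IBD class, apply the
    allele-level error model, and count observed genotype pairs."""
    rng = np.random.default_rng(seed)
    partition = STATE_PARTITIONS[state_idx]
    hits = 0
    for _ in range(n):
        allele = {}
        for cls in partition:
            a = 1 if rng.random() < p else 0
            for pos in cls:
                allele[pos] = a
        obs = {}
        for pos in range(4):
            a = allele[pos]
            if rng.random() < e:
                a = 1 if rng.random() < p else 0
            obs[pos] = a
        if obs[0] + obs[1] == gx and obs[2] + obs[3] == gy:
            hits += 1
    return hits / n


class TestJacquardProbabilities:
    def test_hand_examples(self):
        p = 0.3
        assert jacquard_genotype_prob(9, 2, 2, p) == pytest.approx(p**4)
        assert jacquard_genotype_prob(7, 1, 2, p) == 0.0
        assert jacquard_genotype_prob(8, 2, 1, p) == pytest.approx(p * p * (1 - p))

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            jacquard_genotype_prob(0, 0, 0, 0.5)

    def test_probabilities_sum_to_one_on_grid(self):
        for p in (0.05, 0.2, 0.5, 0.8):
            for e in (0.0, 0.05, 0.2):
                table = observed_state_table(np.array([p]), e)
                sums = table.sum(axis=(1, 2)).ravel()
                np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "state,gx,gy", [(1, 1, 1), (2, 0, 2), (3, 2, 1), (5, 1, 2), (8, 1, 1)]
    )
    def test_against_monte_carlo_with_error(self, state, gx, gy):
        p, e = 0.35, 0.1
        exact = jacquard_genotype_prob(state, gx, gy, p, e)
        mc = mc_state_probability(state - 1, gx, gy, p, e, seed=state)
        assert exact == pytest.approx(mc, abs=4e-3)


def grid_search_three_state(g_x, g_y, ref, e, step=0.02):
    """Brute-force oracle: best log-likelihood over the (D7, D8, D9) simplex."""
    table = observed_state_table(ref.p, e)
    shared = (g_x != MISSING) & (g_y != MISSING)
    idx = np.flatnonzero(shared)
    L = table[6:9][:, g_x[idx], g_y[idx], idx].T
    best = -np.inf
    steps = int(round(1 / step))
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            d7, d8 = i * step, j * step
            d9 = 1 - d7 - d8
            lik = L @ np.array([d7, d8, d9])
            ll = np.log(np.maximum(lik, 1e-300)).sum()
            best = max(best, ll)
    return best


FIXTURE_10 = {
    # deterministic 10-locus dyad used by the optimiser oracle tests
    "g_x": np.array([2, 1, 1, 0, 2, 1, 0, 1, 2, 1], dtype=np.int8),
    "g_y": np.array([2, 1, 0, 0, 1, 1, 0, 2, 2, 0], dtype=np.int8),
    "p": np.array([0.5, 0.3, 0.2, 0.4, 0.45, 0.25, 0.15, 0.35, 0.5, 0.3]),
}


class TestMilliganML:
    def test_em_matches_grid_search_oracle(self):
        ref = make_ref(FIXTURE_10["p"])
        jac, ll, conv = milligan_ml_pair(
            FIXTURE_10["g_x"], FIXTURE_10["g_y"], ref, e=0.05, model="three_state"
        )
        grid_ll = grid_search_three_state(FIXTURE_10["g_x"], FIXTURE_10["g_y"], ref, e=0.05)
        assert conv
        assert ll >= grid_ll - 1e-9  # EM optimum can only beat the grid
        assert ll == pytest.approx(grid_ll, abs=1e-3)

    def test_nine_state_matches_scipy_optimiser(self):
        from scipy.optimize import minimize

        ref = make_ref(FIXTURE_10["p"])
        jac, ll, _ = milligan_ml_pair(
            FIXTURE_10["g_x"], FIXTURE_10["g_y"], ref, e=0.05, model="nine_state",
            n_restarts=2,
        )
        table = observed_state_table(ref.p, 0.05)
        L = table[:, FIXTURE_10["g_x"], FIXTURE_10["g_y"], np.arange(10)].T

        def negll(x):
            d = x**2 / (x**2).sum()
            return -np.log(np.maximum(L @ d, 1e-300)).sum()

        best = np.inf
        for s in range(5):
            rng = np.random.default_rng(s)
            res = minimize(negll, rng.random(9) + 0.1, method="Nelder-Mead",
                           options={"maxiter": 5000, "fatol": 1e-10})
            best = min(best, res.fun)
        assert ll == pytest.approx(-best, abs=1e-3)

    def test_loglik_monotone_in_iteration_budget(self):
        ref = make_ref(FIXTURE_10["p"])
        lls = []
        for it in (1, 3, 10, 30, 100, 2000):
            _, ll, _ = milligan_ml_pair(
                FIXTURE_10["g_x"], FIXTURE_10["g_y"], ref, e=0.05, max_iter=it
            )
            lls.append(ll)
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))

    def test_self_dyad_is_clone(self):
        dosage, pairs, p = simulate_kinship_dyads("unrelated", 1, 2000, seed=3)
        ref = make_ref(p)
        jac, _, conv = milligan_ml_pair(dosage[0], dosage[0], ref, model="three_state")
        assert conv
        assert jac.k2 == pytest.approx(1.0, abs=1e-6)
        assert jac.r == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_dyads_mass_on_no_ibd(self):
        dosage, pairs, p = simulate_kinship_dyads("unrelated", 30, 1500, seed=9)
        ref = make_ref(p)
        rs, k0s = [], []
        for i, j in pairs:
            jac, _, _ = milligan_ml_pair(dosage[i], dosage[j], ref)
            rs.append(jac.r)
            k0s.append(jac.k0)
        assert np.mean(rs) == pytest.approx(0.0, abs=0.03)
        assert np.mean(k0s) > 0.9

    def test_estimator_symmetry(self):
        dosage, pairs, p = simulate_kinship_dyads("parent_offspring", 1, 800, seed=4)
        ref = make_ref(p)
        jac_ab, ll_ab, _ = milligan_ml_pair(dosage[0], dosage[1], ref, e=0.02)
        jac_ba, ll_ba, _ = milligan_ml_pair(dosage[1], dosage[0], ref, e=0.02)
        assert ll_ab == pytest.approx(ll_ba, abs=1e-6)
        assert jac_ab.r == pytest.approx(jac_ba.r, abs=1e-4)

    def test_unknown_model_rejected(self):
        ref = make_ref([0.5])
        with pytest.raises(ValueError):
            milligan_ml_pair(np.array([1]), np.array([1]), ref, model="bogus")


class TestInbreedingML:
    def test_fully_homozygous_sample(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.5, 500)
        ref = make_ref(p)
        g = 2 * (rng.random(500) < p).astype(np.int8)  # haploid-as-homozygous
        assert inbreeding_ml(g, ref) == pytest.approx(1.0, abs=1e-3)

    def test_hwe_sample_near_zero(self):
        rng = np.random.default_rng(1)
        p = np.full(2000, 0.5)
        ref = make_ref(p)
        g = np.array([0] * 500 + [1] * 1000 + [2] * 500, dtype=np.int8)
        assert inbreeding_ml(g, ref) == pytest.approx(0.0, abs=0.02)

    def test_selfed_offspring_near_half(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.5, 2000)
        ref = make_ref(p)
        fs = []
        for _ in range(20):
            parent = hwe_genotypes(p, 1, rng)[0]
            child = mendelian_offspring(parent, parent, rng)
            fs.append(inbreeding_ml(child, ref))
        assert np.mean(fs) == pytest.approx(0.5, abs=0.05)


class TestBuildReference:
    def _matrix(self, rows, ids):
        from orchardkin.genotype_io import GenotypeMatrix

        dosage = np.asarray(rows, dtype=np.int8)
        m = dosage.shape[1]
        return GenotypeMatrix(
            sample_ids=ids,
            locus_ids=[f"chr1:{100+j}:A:G" for j in range(m)],
            dosage=dosage,
            chrom=np.array(["chr1"] * m, dtype=object),
            pos=np.arange(m) + 100,
            ref=np.array(["A"] * m, dtype=object),
            alt=np.array(["G"] * m, dtype=object),
        )

    def test_one_of_two_clones_removed(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.5, 400)
        others = hwe_genotypes(p, 6, rng)
        clone = hwe_genotypes(p, 1, rng)[0]
        G = self._matrix(
            np.vstack([others, clone, clone]),
            [f"u{i}" for i in range(6)] + ["c1", "c2"],
        )
        ref = build_reference(G, G.sample_ids)
        assert len([s for s in ("c1", "c2") if s in ref.source_samples]) == 1
        assert set(ref.excluded.values()) == {"elevated relatedness"}

    def test_low_coverage_sample_removed(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.5, 400)
        rows = hwe_genotypes(p, 6, rng)
        rows[0, : int(400 * 0.6)] = MISSING
        G = self._matrix(rows, [f"u{i}" for i in range(6)])
        ref = build_reference(G, G.sample_ids, min_coverage=0.8)
        assert ref.excluded.get("u0") == "low coverage"

    def test_unrelated_panel_untouched(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.5, 800)
        G = self._matrix(hwe_genotypes(p, 12, rng), [f"u{i:02d}" for i in range(12)])
        ref = build_reference(G, G.sample_ids)
        assert ref.excluded == {}
        assert len(ref.source_samples) == 12
        assert np.all((ref.p > 0) & (ref.p < 1))

    def test_too_few_survivors_raise(self):
        G = self._matrix(np.array([[1, 1], [1, 1]], dtype=np.int8), ["a", "b"])
        with pytest.raises(ValueError):
            build_reference(G, ["a"])


class TestMafThresholdScan:
    def _dyad_matrix(self, seed=0, L=3000):
        rng = np.random.default_rng(seed)
        # L-shaped-ish mix so thresholds bite
        maf = np.concatenate(
            [rng.uniform(0.01, 0.05, L // 2), rng.uniform(0.05, 0.5, L - L // 2)]
        )
        p = np.where(rng.random(L) < 0.5, maf, 1 - maf)
        ref = make_ref(p)
        gm = hwe_genotypes(p, 1, rng)[0]
        gf = hwe_genotypes(p, 1, rng)[0]
        child = mendelian_offspring(gm, gf, rng)
        from orchardkin.genotype_io import GenotypeMatrix

        G = GenotypeMatrix(
            sample_ids=["par", "kid"],
            locus_ids=ref.locus_ids,
            dosage=np.vstack([gm, child]),
            chrom=np.array(["chr1"] * L, dtype=object),
            pos=np.arange(L) + 1000,
            ref=np.array(["A"] * L, dtype=object),
            alt=np.array(["G"] * L, dtype=object),
        )
        return G, ref

    def test_threshold_above_max_maf_skipped(self):
        G, ref = self._dyad_matrix()
        out = maf_threshold_scan(
            G, [("par", "kid")], ref, thresholds=(0.01, 0.49999), n_replicates=50
        )
        assert (out.loc[out.sweep == 0.49999, "note"].str.contains("skipped")).all()

    def test_deterministic_under_seed(self):
        G, ref = self._dyad_matrix()
        a = maf_threshold_scan(G, [("par", "kid")], ref, thresholds=(0.05,), seed=3,
                               n_replicates=100)
        b = maf_threshold_scan(G, [("par", "kid")], ref, thresholds=(0.05,), seed=3,
                               n_replicates=100)
        assert a.equals(b)

    def test_by_count_mode_precision_improves_with_snps(self):
        G, ref = self._dyad_matrix(seed=6, L=6000)
        out = maf_threshold_scan(
            G, [("par", "kid")], ref, mode="by_count", counts=(100, 1000),
            n_replicates=300, seed=2
        ).set_index("sweep")
        width = out["ritland_hi"] - out["ritland_lo"]
        assert width.loc[1000] < width.loc[100]
        assert (out["n_subsampled"] == [100, 1000]).all()

    def test_estimate_dyad_collects_all_three_estimators(self):
        from orchardkin.genotype_io import GenotypeMatrix
        from orchardkin.relatedness import estimate_dyad

        G, ref = self._dyad_matrix(seed=8, L=1500)
        est = estimate_dyad(G, "par", "kid", ref, e=0.0)
        assert est.n_shared_snps == 1500
        # half the panel is rare-allele loci, so a single moment estimate is
        # noisy; the ML estimate is tighter
        assert est.r_ritland == pytest.approx(0.5, abs=0.2)
        assert est.r_ml == pytest.approx(0.5, abs=0.1)
        assert np.isfinite(est.genotype_correlation)
        assert est.jacquard is not None and est.ml_converged
        assert not est.low_confidence

    def test_precision_improves_with_maf(self):
        G, ref = self._dyad_matrix(seed=5, L=6000)
        out = maf_threshold_scan(
            G, [("par", "kid")], ref, thresholds=(0.01, 0.3), n_snps=1000,
            n_replicates=300, seed=1
        ).set_index("sweep")
        width = out["ritland_hi"] - out["ritland_lo"]
        assert width.loc[0.3] < width.loc[0.01]
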