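"""Pairwise relatedness estimation from biallelic SNP dosages.

Three estimators are provided, all operating on the loci shared between the
two members of a dyad and an external allele-frequency reference:

* **Method of moments** (Ritland-style): an unbiased per-locus estimator
  averaged over loci; cheap, but sensitive to genotyping error and to
  related individuals in the frequency reference.
* **Maximum likelihood over condensed Jacquard coefficients** (Milligan-
  style): the dyad's four alleles fall into one of nine identity-by-descent
  configurations Delta_1..Delta_9; the likelihood of the observed genotype
  pair is a mixture over configurations and is maximised on the simplex by
  EM. Genotyping error is folded in at the allele level, which keeps the
  estimator consistent under the ~5% mistyping typical of GBS calls, and
  the simplex constraint keeps estimates in the biologically meaningful
  range.
* **Genotype-score correlation**: the Pearson correlation of dosage vectors,
  a scale-free sanity check used for consensus with the other two.

Relatedness ``r`` is reported on the 2*theta scale: parent-offspring and
full sibs 0.5, half sibs 0.25, clones or selfed-offspring-vs-parent 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, locus_stats

__all__ = [
    "AlleleFrequencyReference",
    "JacquardCoefficients",
    "DyadEstimate",
    "build_reference",
    "ritland_pair",
    "ritland_variance",
    "genotype_correlation",
    "jacquard_genotype_prob",
    "observed_state_table",
    "milligan_ml_pair",
    "milligan_ml_batch",
    "inbreeding_ml",
    "estimate_dyad",
    "maf_threshold_scan",
    "MIN_SHARED_SNPS",
]

#: Dyads sharing fewer informative SNPs than this are flagged low-confidence.
MIN_SHARED_SNPS = 1000

# Condensed Jacquard states as partitions of the dyad's four alleles
# (x1, x2, y1, y2) into IBD classes. State order is Delta_1 .. Delta_9.
STATE_PARTITIONS = (
    ((0, 1, 2, 3),),                      # D1: all four IBD
    ((0, 1), (2, 3)),                     # D2: each individual inbred, no cross
    ((0, 1, 2), (3,)),                    # D3: x inbred, IBD with one of y
    ((0, 1), (2,), (3,)),                 # D4: x inbred only
    ((2, 3, 0), (1,)),                    # D5: y inbred, IBD with one of x
    ((2, 3), (0,), (1,)),                 # D6: y inbred only
    ((0, 2), (1, 3)),                     # D7: two cross pairs IBD (k2)
    ((0, 2), (1,), (3,)),                 # D8: one cross pair IBD (k1)
    ((0,), (1,), (2,), (3,)),             # D9: no IBD (k0)
)

THREE_STATE = (6, 7, 8)  # D7, D8, D9 — inbred configurations fixed at zero


@dataclass
class AlleleFrequencyReference:
    """Reference allele frequencies estimated from assumed-unrelated samples."""

    locus_ids: list
    p: np.ndarray
    source_samples: list
    excluded: dict = field(default_factory=dict)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("reference frequencies must be strictly inside (0, 1)")


@dataclass
class JacquardCoefficients:
    """The nine condensed IBD-configuration probabilities of a dyad."""

    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (9,):
            raise ValueError("expected nine coefficients")
        if np.any(self.delta < -1e-9) or abs(self.delta.sum() - 1) > 1e-6:
            raise ValueError("coefficients must lie on the simplex")

    @property
    def k0(self) -> float:
        return float(self.delta[8])

    @property
    def k1(self) -> float:
        return float(self.delta[7])

    @property
    def k2(self) -> float:
        return float(self.delta[6])

    @property
    def r(self) -> float:
        d = self.delta
        return float(2 * d[0] + d[2] + d[4] + d[6] + 0.5 * d[7])

    @property
    def f_x(self) -> float:
        return float(self.delta[:4].sum())

    @property
    def f_y(self) -> float:
        d = self.delta
        return float(d[0] + d[1] + d[4] + d[5])


@dataclass
class DyadEstimate:
    """All pairwise estimates for one dyad."""

    id_x: str
    id_y: str
    n_shared_snps: int
    r_ritland: float = np.nan
    var_ritland: float = np.nan
    r_ml: float = np.nan
    jacquard: JacquardCoefficients | None = None
    loglik: float = np.nan
    ml_converged: bool = True
    genotype_correlation: float = np.nan
    mean_maf: float = np.nan

    @property
    def low_confidence(self) -> bool:
        return self.n_shared_snps < MIN_SHARED_SNPS


# ---------------------------------------------------------------------------
# Allele-frequency reference
# ---------------------------------------------------------------------------


def build_reference(
    G: GenotypeMatrix,
    candidates: list,
    r_threshold: float = 0.15,
    min_coverage: float = 0.80,
) -> AlleleFrequencyReference:
    """Build the allele-frequency reference from candidate unrelated samples.

    Candidates forming pairs with preliminary method-of-moments relatedness
    >= `r_threshold` are removed one at a time (the member involved in most
    such pairs first; ties broken toward lower locus coverage, then id), so
    the surviving set can be treated as unrelated. Samples covering fewer
    than `min_coverage` of the loci are removed as well. Frequencies are
    then recomputed on the survivors and loci fixed at p in {0, 1} (or
    uncalled) are dropped.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate reference samples")
    sub = G.subset_samples(candidates)
    coverage = sub.called.mean(axis=1)
    cov = dict(zip(candidates, coverage))
    excluded: dict[str, str] = {}

    # preliminary frequencies from all candidates
    prelim = locus_stats(sub)
    p = prelim["p"].to_numpy()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    ref0 = AlleleFrequencyReference(
        [lid for lid, k in zip(sub.locus_ids, ok) if k], p[ok], candidates
    )
    sub_ok = sub.take_loci(ok)

    active = list(candidates)
    rmat = {}
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            r, _, n = ritland_pair(
                sub_ok.dosage[sub_ok.sample_index(a)],
                sub_ok.dosage[sub_ok.sample_index(b)],
                ref0,
            )
            if n > 0 and np.isfinite(r):
                rmat[(a, b)] = r

    def _offenders(members):
        counts = {s: 0 for s in members}
        for (a, b), r in rmat.items():
            if r >= r_threshold and a in counts and b in counts:
                counts[a] += 1
                counts[b] += 1
        return counts

    while True:
        counts = _offenders(active)
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        tied = [s for s, c in counts.items() if c == worst]
        # lower coverage loses; among equal coverage remove the later id
        victim = sorted(tied, key=lambda s: (cov[s], s))[0]
        active.remove(victim)
        excluded[victim] = "elevated relatedness"

    for s in list(active):
        if cov[s] < min_coverage:
            active.remove(s)
            excluded[s] = "low coverage"

    if len(active) < 2:
        raise ValueError("fewer than two reference samples survive the screens")

    final = locus_stats(G.subset_samples(active))
    p = final["p"].to_numpy()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    return AlleleFrequencyReference(
        locus_ids=[lid for lid, k in zip(G.locus_ids, ok) if k],
        p=p[ok],
        source_samples=active,
        excluded=excluded,
    )


def align_to_reference(G: GenotypeMatrix, ref: AlleleFrequencyReference):
    """Column indices of G matching the reference loci (order preserved)."""
    lookup = {lid: j for j, lid in enumerate(G.locus_ids)}
    idx = [lookup[lid] for lid in ref.locus_ids if lid in lookup]
    kept = [i for i, lid in enumerate(ref.locus_ids) if lid in lookup]
    return np.asarray(idx, dtype=int), np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# Method of moments
# ---------------------------------------------------------------------------


def ritland_pair(g_x, g_y, ref: AlleleFrequencyReference):
    """Method-of-moments relatedness for one dyad.

    Per biallelic locus, with allele-dosage fractions ``x = g_x/2`` etc. and
    reference ALT frequency p: ``r_l = 2 (x_alt y_alt / p + x_ref y_ref / q - 1)``.
    The multilocus estimate is the unweighted mean over shared informative
    loci (for biallelic loci every locus carries weight n_alleles - 1 = 1).
    Single-locus values can fall outside [0, 1]; only the average is
    interpretable.

    Returns ``(r, per_locus_values, n_shared)``; r is NaN when no locus is
    shared.
    """
    g_x = np.asarray(g_x)
    g_y = np.asarray(g_y)
    p = ref.p
    shared = (g_x != MISSING) & (g_y != MISSING)
    n = int(shared.sum())
    if n == 0:
        return np.nan, np.array([]), 0
    xa = g_x[shared] / 2.0
    ya = g_y[shared] / 2.0
    ps = p[shared]
    qs = 1.0 - ps
    r_l = 2.0 * (xa * ya / ps + (1 - xa) * (1 - ya) / qs - 1.0)
    return float(r_l.mean()), r_l, n


def ritland_variance(s, p, q=None):
    """Sampling variance of the per-locus moment estimator, ``s(1-s)/(p^2 q^2)``.

    ``s`` is the expected similarity of the compared individuals at a locus
    with allele frequencies p and q = 1 - p. Undefined at fixed loci.
    """
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    q = 1.0 - p if q is None else np.asarray(q, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("variance undefined for p in {0, 1}")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("similarity s must lie in [0, 1]")
    return s * (1.0 - s) / (p**2 * q**2)


def genotype_correlation(g_x, g_y):
    """Pearson correlation of the two dosage vectors over shared loci."""
    g_x = np.asarray(g_x)
    g_y = np.asarray(g_y)
    shared = (g_x != MISSING) & (g_y != MISSING)
    if shared.sum() < 2:
        raise ValueError("genotype correlation needs at least two shared loci")
    x = g_x[shared].astype(float)
    y = g_y[shared].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("genotype correlation undefined for a constant dosage vector")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Maximum likelihood over Jacquard coefficients
# ---------------------------------------------------------------------------


def _true_state_table(p: np.ndarray) -> np.ndarray:
    """P(true genotype pair | state) for each locus.

    Enumerates, for each condensed state, the allele-type assignment to its
    IBD classes (each class drawn independently from the reference
    frequencies) and accumulates the implied unordered genotype pair.

    Returns array of shape (9, 3, 3, L) indexed by
    (state, dosage_x, dosage_y, locus).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    L = p.size
    q = 1.0 - p
    T = np.zeros((9, 3, 3, L))
    for s, partition in enumerate(STATE_PARTITIONS):
        k = len(partition)
        for combo in range(2**k):
            alleles = [(combo >> c) & 1 for c in range(k)]
            prob = np.ones(L)
            allele_of = {}
            for cls, a in zip(partition, alleles):
                prob = prob * (p if a == 1 else q)
                for pos in cls:
                    allele_of[pos] = a
            gx = allele_of[0] + allele_of[1]
            gy = allele_of[2] + allele_of[3]
            T[s, gx, gy] += prob
    return T


def _error_matrix(p: np.ndarray, e: float) -> np.ndarray:
    """P(observed dosage | true dosage) per locus under allele-level mistyping.

    Each true allele is read correctly with probability 1 - e, otherwise
    replaced by a draw from the reference frequencies, so
    P(read ALT | true ALT) = 1 - e + e p and P(read ALT | true REF) = e p.
    Shape (L, 3, 3), rows true, columns observed.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if not 0 <= e < 1:
        raise ValueError("error rate must lie in [0, 1)")
    a = 1.0 - e + e * p  # obs ALT | true ALT
    b = e * p            # obs ALT | true REF
    E = np.empty((p.size, 3, 3))
    E[:, 0, 0] = (1 - b) ** 2
    E[:, 0, 1] = 2 * b * (1 - b)
    E[:, 0, 2] = b**2
    E[:, 1, 0] = (1 - a) * (1 - b)
    E[:, 1, 1] = a * (1 - b) + b * (1 - a)
    E[:, 1, 2] = a * b
    E[:, 2, 0] = (1 - a) ** 2
    E[:, 2, 1] = 2 * a * (1 - a)
    E[:, 2, 2] = a**2
    return E


def observed_state_table(p: np.ndarray, e: float) -> np.ndarray:
    """P(observed genotype pair | state, p_l, e), shape (9, 3, 3, L).

    The workhorse table: computed once per (reference, error rate) and
    indexed by every dyad sharing those loci.
    """
    T = _true_state_table(p)
    E = _error_matrix(p, e)
    return np.einsum("lig,ljh,sijl->sghl", E, E, T, optimize=True)


def jacquard_genotype_prob(state: int, g_x: int, g_y: int, p: float, e: float = 0.0) -> float:
    """P(observed dosage pair | condensed state) at a single locus.

    ``state`` is 1-based (1..9 for Delta_1..Delta_9).
    """
    if not 1 <= state <= 9:
        raise ValueError("state must be in 1..9")
    O = observed_state_table(np.array([p]), e)
    return float(O[state - 1, g_x, g_y, 0])


def _em_batch(Lmats, n_real, max_iter, tol, n_restarts, seed, init_delta=None):
    """EM on the Jacquard simplex, vectorised over a batch of dyads.

    Lmats: (C, Lmax, S) per-locus state likelihoods, padded with ones past
    each dyad's real loci (a padded row's posterior equals the current Delta
    and is subtracted analytically in the M-step). `init_delta` (C, S) gives
    a per-dyad warm start (the objective is concave in Delta, so the start
    affects speed, never the optimum). Returns (delta (C, S), loglik (C,),
    converged (C,)).
    """
    C, Lmax, S = Lmats.shape
    rng = np.random.default_rng(seed)
    inits = [np.full(S, 1.0 / S) if init_delta is None else init_delta]
    inits += [rng.dirichlet(np.ones(S)) for _ in range(n_restarts)]

    best_delta = np.zeros((C, S))
    best_ll = np.full(C, -np.inf)
    best_conv = np.zeros(C, dtype=bool)
    n_pad = Lmax - n_real

    for init in inits:
        delta_full = np.tile(init, (C, 1)) if init.ndim == 1 else init.copy()
        ll_full = np.full(C, -np.inf)
        conv_full = np.zeros(C, dtype=bool)

        active = np.arange(C)
        Lact = Lmats
        LactT = np.ascontiguousarray(Lmats.transpose(0, 2, 1))
        delta = delta_full.copy()
        n_pad_a, n_real_a = n_pad.astype(float), n_real.astype(float)
        prev_ll = np.full(C, -np.inf)
        it = 0
        while it < max_iter and active.size:
            # a burst of iterations, then retire converged dyads
            for _ in range(min(32, max_iter - it)):
                lik = np.matmul(Lact, delta[:, :, None])[:, :, 0]
                np.maximum(lik, 1e-300, out=lik)
                ll = np.log(lik).sum(axis=1)
                # E-step column sums as batched mat-vec; padded rows
                # contribute delta exactly and are subtracted analytically
                inv = 1.0 / lik
                w = np.matmul(LactT, inv[:, :, None])[:, :, 0] * delta
                new_delta = (w - n_pad_a[:, None] * delta) / n_real_a[:, None]
                np.clip(new_delta, 0, None, out=new_delta)
                new_delta /= new_delta.sum(axis=1, keepdims=True)
                done = np.abs(ll - prev_ll) < tol
                prev_ll = ll
                delta = np.where(done[:, None], delta, new_delta)
                it += 1
                if done.all():
                    break
            finished = np.abs(ll - prev_ll) < tol if it >= max_iter else done
            if finished.any() or it >= max_iter:
                stop = finished | (it >= max_iter)
                idx = active[stop]
                delta_full[idx] = delta[stop]
                ll_full[idx] = prev_ll[stop]
                conv_full[idx] = finished[stop]
                keep = ~stop
                active = active[keep]
                Lact = np.ascontiguousarray(Lact[keep])
                LactT = np.ascontiguousarray(LactT[keep])
                delta = delta[keep]
                prev_ll = prev_ll[keep]
                n_pad_a = n_pad_a[keep]
                n_real_a = n_real_a[keep]
        if active.size:  # max_iter exhausted
            delta_full[active] = delta
            ll_full[active] = prev_ll

        better = ll_full > best_ll + 1e-12
        best_delta[better] = delta_full[better]
        best_ll[better] = ll_full[better]
        best_conv[better] = conv_full[better]
        first = ~np.isfinite(best_ll)
        best_delta[first] = delta_full[first]
        best_ll[first] = ll_full[first]
        best_conv[first] = conv_full[first]
    return best_delta, best_ll, best_conv


def _pair_state_likelihoods(g_x, g_y, table_s):
    """Per-locus likelihood rows for one dyad; table_s is (S, 3, 3, L)."""
    shared = (g_x != MISSING) & (g_y != MISSING)
    idx = np.flatnonzero(shared)
    L = table_s[:, g_x[idx], g_y[idx], idx].T  # (n_shared, S)
    return L, idx


def milligan_ml_pair(
    g_x,
    g_y,
    ref: AlleleFrequencyReference,
    e: float = 0.0,
    model: str = "nine_state",
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 0,
    seed: int = 0,
    table: np.ndarray | None = None,
):
    """Maximum-likelihood Jacquard coefficients for one dyad by EM.

    Maximises ``sum_l log sum_s Delta_s P_l(obs | s, p_l, e)`` over the
    Delta simplex. The E-step computes per-locus state posteriors; the
    M-step sets Delta to their mean — the log-likelihood is non-decreasing
    at every iteration. `model` is ``nine_state`` (full simplex) or
    ``three_state`` (inbred configurations Delta_1..Delta_6 fixed at zero).
    Uniform initialisation plus `n_restarts` seeded Dirichlet restarts guard
    against boundary attraction.

    Returns ``(JacquardCoefficients, loglik, converged)``.
    """
    if model not in ("nine_state", "three_state"):
        raise ValueError(f"unknown model {model!r}")
    g_x = np.asarray(g_x)
    g_y = np.asarray(g_y)
    if table is None:
        table = observed_state_table(ref.p, e)
    states = list(range(9)) if model == "nine_state" else list(THREE_STATE)
    Lmat, idx = _pair_state_likelihoods(g_x, g_y, np.ascontiguousarray(table[states]))
    if Lmat.shape[0] == 0:
        raise ValueError("no shared informative loci for this dyad")
    delta_s, ll, conv = _em_batch(
        Lmat[None, :, :],
        np.array([Lmat.shape[0]]),
        max_iter,
        tol,
        n_restarts,
        seed,
    )
    full = np.zeros(9)
    full[states] = delta_s[0]
    return JacquardCoefficients(full), float(ll[0]), bool(conv[0])


def milligan_ml_batch(
    dosage: np.ndarray,
    pairs,
    ref: AlleleFrequencyReference,
    e: float = 0.0,
    model: str = "nine_state",
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 0,
    seed: int = 0,
    chunk: int = 256,
):
    """Vectorised :func:`milligan_ml_pair` over many (row_i, row_j) pairs.

    `dosage` columns must align with ``ref.p``. Yields the same estimates as
    the single-pair routine; dyads are processed in chunks padded to a
    common locus count. Returns (delta (N, 9), loglik (N,), converged (N,),
    n_shared (N,)).
    """
    states = list(range(9)) if model == "nine_state" else list(THREE_STATE)
    table_s = np.ascontiguousarray(observed_state_table(ref.p, e)[states])
    N = len(pairs)
    S = len(states)
    delta_out = np.zeros((N, 9))
    ll_out = np.full(N, np.nan)
    conv_out = np.zeros(N, dtype=bool)
    n_out = np.zeros(N, dtype=int)

    for start in range(0, N, chunk):
        batch = pairs[start : start + chunk]
        mats, ns, warm = [], [], []
        for i, j in batch:
            Lmat, _ = _pair_state_likelihoods(dosage[i], dosage[j], table_s)
            mats.append(Lmat)
            ns.append(Lmat.shape[0])
            r, _, _ = ritland_pair(dosage[i], dosage[j], ref)
            warm.append(min(max(r, 0.0), 0.98) if np.isfinite(r) else 0.0)
        Lmax = max(ns) if ns else 0
        if Lmax == 0:
            continue
        stack = np.ones((len(batch), Lmax, S))
        for c, m in enumerate(mats):
            stack[c, : m.shape[0]] = m
        n_real = np.array(ns)
        empty = n_real == 0
        n_real_safe = np.where(empty, 1, n_real)
        # warm start near the moment estimate (speed only; objective concave)
        r0 = np.asarray(warm)
        init = np.full((len(batch), S), 0.02 / S)
        k_idx = {s: c for c, s in enumerate(states)}
        init[:, k_idx[6]] += 0.98 * r0**2
        init[:, k_idx[7]] += 0.98 * 2 * r0 * (1 - r0)
        init[:, k_idx[8]] += 0.98 * (1 - r0) ** 2
        d, ll, conv = _em_batch(
            stack, n_real_safe, max_iter, tol, n_restarts, seed, init_delta=init
        )
        sl = slice(start, start + len(batch))
        tmp = np.zeros((len(batch), 9))
        tmp[:, states] = d
        delta_out[sl] = tmp
        ll_out[sl] = np.where(empty, np.nan, ll)
        conv_out[sl] = conv & ~empty
        n_out[sl] = n_real
    return delta_out, ll_out, conv_out, n_out


def inbreeding_ml(g_x, ref: AlleleFrequencyReference, e: float = 0.0,
                  max_iter: int = 2000, tol: float = 1e-8) -> float:
    """Maximum-likelihood individual inbreeding coefficient by EM.

    The genotype at each locus is a mixture: with probability F the two
    alleles are IBD (homozygous ALT with probability p, REF with q, never
    het), with probability 1 - F they are an HWE draw. Observation passes
    through the same allele-level error model as the dyadic estimator.
    """
    g_x = np.asarray(g_x)
    called = g_x != MISSING
    if not called.any():
        raise ValueError("no called loci")
    p = ref.p[called]
    q = 1.0 - p
    E = _error_matrix(p, e)
    true_ibd = np.stack([q, np.zeros_like(p), p], axis=1)
    true_hwe = np.stack([q**2, 2 * p * q, p**2], axis=1)
    obs = g_x[called]
    rows = np.arange(p.size)
    p_ibd = np.einsum("li,lig->lg", true_ibd, E)[rows, obs]
    p_hwe = np.einsum("li,lig->lg", true_hwe, E)[rows, obs]

    F = 0.5
    prev = -np.inf
    for _ in range(max_iter):
        num = F * p_ibd
        den = num + (1 - F) * p_hwe
        ll = np.log(np.maximum(den, 1e-300)).sum()
        z = num / np.maximum(den, 1e-300)
        F = float(z.mean())
        if abs(ll - prev) < tol:
            break
        prev = ll
    return F


# ---------------------------------------------------------------------------
# Dyad convenience and the MAF / SNP-count subsampling scan
# ---------------------------------------------------------------------------


def estimate_dyad(
    G: GenotypeMatrix,
    id_x: str,
    id_y: str,
    ref: AlleleFrequencyReference,
    e: float = 0.0,
    model: str = "nine_state",
    table: np.ndarray | None = None,
    seed: int = 0,
) -> DyadEstimate:
    """Compute all three estimators for one sample pair."""
    gidx, _ = align_to_reference(G, ref)
    g_x = G.dosage[G.sample_index(id_x)][gidx]
    g_y = G.dosage[G.sample_index(id_y)][gidx]
    r_mom, r_l, n = ritland_pair(g_x, g_y, ref)
    est = DyadEstimate(id_x=id_x, id_y=id_y, n_shared_snps=n, r_ritland=r_mom)
    if n == 0:
        return est
    shared = (g_x != MISSING) & (g_y != MISSING)
    maf = np.minimum(ref.p, 1 - ref.p)
    est.mean_maf = float(maf[shared].mean())
    est.var_ritland = float(np.var(r_l)) if n > 1 else np.nan
    try:
        est.genotype_correlation = genotype_correlation(g_x, g_y)
    except ValueError:
        pass
    jac, ll, conv = milligan_ml_pair(
        g_x, g_y, ref, e=e, model=model, table=table, seed=seed
    )
    est.jacquard = jac
    est.r_ml = jac.r
    est.loglik = ll
    est.ml_converged = conv
    return est


DEFAULT_MAF_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4)
DEFAULT_SNP_COUNTS = (100, 250, 500, 1000, 2000, 4000)


def maf_threshold_scan(
    G: GenotypeMatrix,
    dyads,
    ref: AlleleFrequencyReference,
    thresholds=DEFAULT_MAF_THRESHOLDS,
    mode: str = "by_maf",
    n_snps: int = 1000,
    n_replicates: int = 1000,
    seed: int = 0,
    counts=DEFAULT_SNP_COUNTS,
) -> pd.DataFrame:
    """Precision of the estimators versus MAF threshold or SNP count.

    For each dyad and each MAF threshold, shared loci with MAF >= threshold
    are repeatedly subsampled without replacement (`n_replicates` draws of
    `n_snps` loci, or 75% of the available loci when fewer than `n_snps`
    remain) and the method-of-moments estimate and genotype correlation are
    recomputed per draw; the 2.5/97.5 percentiles give a 95% CI. In
    ``by_count`` mode the MAF floor is fixed at 0.1 and the subsample size
    sweeps `counts` instead. Thresholds with no available loci are skipped
    with a note row.
    """
    rng = np.random.default_rng(seed)
    gidx, _ = align_to_reference(G, ref)
    maf = np.minimum(ref.p, 1 - ref.p)
    rows = []
    sweep = thresholds if mode == "by_maf" else counts
    if mode not in ("by_maf", "by_count"):
        raise ValueError("mode must be by_maf or by_count")

    for id_x, id_y in dyads:
        g_x = G.dosage[G.sample_index(id_x)][gidx]
        g_y = G.dosage[G.sample_index(id_y)][gidx]
        shared = (g_x != MISSING) & (g_y != MISSING)
        for value in sweep:
            if mode == "by_maf":
                use = shared & (maf >= value)
                target = n_snps
            else:
                use = shared & (maf >= 0.1)
                target = value
            idx = np.flatnonzero(use)
            L = idx.size
            if L == 0 or (mode == "by_count" and L < target):
                rows.append(
                    {
                        "id_x": id_x,
                        "id_y": id_y,
                        "sweep": value,
                        "n_available": L,
                        "note": "skipped: no loci available",
                    }
                )
                continue
            n_draw = target if L >= target else max(1, int(0.75 * L))
            draws = np.stack(
                [rng.choice(idx, size=n_draw, replace=False) for _ in range(n_replicates)]
            )
            xa = g_x[draws] / 2.0
            ya = g_y[draws] / 2.0
            ps = ref.p[draws]
            qs = 1 - ps
            r_l = 2.0 * (xa * ya / ps + (1 - xa) * (1 - ya) / qs - 1.0)
            r_rep = r_l.mean(axis=1)
            x = g_x[draws].astype(float)
            y = g_y[draws].astype(float)
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr_rep = (xc * yc).sum(axis=1) / denom
            rows.append(
                {
                    "id_x": id_x,
                    "id_y": id_y,
                    "sweep": value,
                    "n_available": L,
                    "n_subsampled": n_draw,
                    "mean_maf": float(maf[idx].mean()),
                    "ritland_mean": float(r_rep.mean()),
                    "ritland_lo": float(np.percentile(r_rep, 2.5)),
                    "ritland_hi": float(np.percentile(r_rep, 97.5)),
                    "correlation_mean": float(np.nanmean(corr_rep)),
                    "correlation_lo": float(np.nanpercentile(corr_rep, 2.5)),
                    "correlation_hi": float(np.nanpercentile(corr_rep, 97.5)),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
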