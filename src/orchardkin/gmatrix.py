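"""Realized genomic relationship matrices (additive and dominance).

The additive matrix follows VanRaden's first method,
``A_R = Z Z' / (2 sum_j p_j q_j)`` with ``Z`` the dosage matrix centred at
``2p``. The dominance matrix uses the orthogonal (Vitezica-style) genotype
coding ``w = -2p^2, 2pq, -2q^2`` for dosages 0, 1, 2 (p = ALT frequency;
the coding has zero mean under HWE), normalised by
``sum_j (2 p_j q_j)^2``. Both require a complete matrix, so a
stricter prefilter and a naive HWE imputation of the remaining gaps are
provided; naive imputation is known to dilute pairwise signal, which is the
behaviour the regression tests pin down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, locus_stats
from .relatedness import AlleleFrequencyReference, align_to_reference

__all__ = ["GMatrixResult", "gmatrix_prefilter", "naive_impute", "vanraden_matrices"]


@dataclass
class GMatrixResult:
    sample_ids: list
    additive: np.ndarray
    dominance: np.ndarray
    n_loci: int
    imputed_fraction: float

    def __post_init__(self):
        for m in (self.additive, self.dominance):
            if m.shape != (len(self.sample_ids),) * 2:
                raise ValueError("matrix shape does not match sample count")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError("relationship matrix must be symmetric")

    def to_frame(self, which: str = "additive") -> pd.DataFrame:
        m = self.additive if which == "additive" else self.dominance
        return pd.DataFrame(m, index=self.sample_ids, columns=self.sample_ids)


def gmatrix_prefilter(
    G: GenotypeMatrix,
    max_sample_missing: float = 0.90,
    call_rate_min: float = 0.70,
    maf_min: float = 0.10,
) -> GenotypeMatrix:
    """Stricter prefilter ahead of G-matrix construction.

    Samples missing more than `max_sample_missing` of the loci are dropped
    first; loci are then re-screened at call rate >= `call_rate_min` and
    MAF >= `maf_min`.
    """
    missing_frac = 1.0 - G.called.mean(axis=1)
    keep_samples = missing_frac <= max_sample_missing
    if not keep_samples.any():
        raise ValueError("no samples survive the missingness screen")
    G = G.take_samples(keep_samples)
    stats = locus_stats(G)
    keep = (
        (stats["call_rate"] >= call_rate_min) & (stats["maf"] >= maf_min)
    ).fillna(False).to_numpy()
    if not keep.any():
        raise ValueError("no loci survive the call-rate/MAF screen")
    return G.take_loci(keep)


def naive_impute(
    G: GenotypeMatrix,
    ref: AlleleFrequencyReference,
    seed: int | None = 0,
    mode: str = "draw",
) -> tuple[np.ndarray, float]:
    """Fill missing dosages from population allele frequencies.

    ``draw`` mode (default) replaces each missing call with a seeded draw
    from the HWE genotype probabilities (q^2, 2pq, p^2); ``expectation``
    mode fills the mean dosage 2p instead. Returns the dense float matrix
    and the imputed fraction.
    """
    gidx, _ = align_to_reference(G, ref)
    if len(gidx) != G.n_loci:
        raise ValueError("reference does not cover all loci (fixed loci upstream?)")
    p = ref.p
    X = G.dosage.astype(float).copy()
    miss = G.dosage == MISSING
    frac = float(miss.mean())
    if mode == "expectation":
        fill = np.broadcast_to(2 * p, X.shape)
        X[miss] = fill[miss]
    elif mode == "draw":
        rng = np.random.default_rng(seed)
        draws = (
            (rng.random(X.shape) < p).astype(np.int8)
            + (rng.random(X.shape) < p).astype(np.int8)
        ).astype(float)
        X[miss] = draws[miss]
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    return X, frac


def vanraden_matrices(
    X: np.ndarray,
    ref: AlleleFrequencyReference,
    sample_ids: list,
    imputed_fraction: float = 0.0,
) -> GMatrixResult:
    """Additive and dominance relationship matrices from a complete matrix.

    `X` is samples x loci dosage with no missing values, columns aligned to
    ``ref.p``.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("complete matrix required; impute first")
    p = ref.p
    q = 1.0 - p
    two_pq = 2.0 * p * q
    denom_a = two_pq.sum()
    if denom_a <= 0:
        raise ValueError("sum of 2pq is zero; no segregating loci")
    Z = X - 2.0 * p
    A = (Z @ Z.T) / denom_a

    W = np.empty_like(X)
    W[:] = np.broadcast_to(-2.0 * p**2, X.shape)  # dosage 0 (REF homozygote)
    W[X == 1] = np.broadcast_to(two_pq, X.shape)[X == 1]
    W[X == 2] = np.broadcast_to(-2.0 * q**2, X.shape)[X == 2]
    denom_d = (two_pq**2).sum()
    D = (W @ W.T) / denom_d

    return GMatrixResult(
        sample_ids=list(sample_ids),
        additive=A,
        dominance=D,
        n_loci=X.shape[1],
        imputed_fraction=imputed_fraction,
    )
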