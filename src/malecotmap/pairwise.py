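"""Two-locus LD from unphased genotypes.

Haplotype frequencies for each marker pair are estimated by EM on the
3x3 genotype count table (only the double heterozygote has ambiguous
phase), then summarised as signed D and D'.  Each pair also carries an
information weight used by the map-fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .exceptions import EmptyTableError, UndefinedLDError

__all__ = ["PairLD", "em_haplotype_freqs", "d_prime", "pairwise_ld_table"]

_EPS = 1e-12


@dataclass(frozen=True)
class PairLD:
    """LD summary for one marker pair (i < j)."""

    i: int
    j: int
    d_kb: float
    haplotype_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    D: float
    D_prime: float
    K_weight: float
    n_used: int
    converged: bool


def _count_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 genotype cross-counts over pairwise-complete individuals."""
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a = g1[ok].astype(int)
    b = g2[ok].astype(int)
    n = np.zeros((3, 3))
    np.add.at(n, (a, b), 1)
    return n


def _em_tables(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over a stack of 3x3 count tables.

    Parameters
    ----------
    counts
        ``(P, 3, 3)`` array; ``counts[p, a, b]`` is the number of
        individuals with dosages ``a`` at locus 1 and ``b`` at locus 2.

    Returns
    -------
    freqs : (P, 4) haplotype frequencies (AB, Ab, aB, ab), where A/B are
        the counted alleles.
    loglik : (P,) final multinomial log-likelihood.
    converged : (P,) bool.
    n_iter : (P,) iterations used.
    """
    counts = np.asarray(counts, float)
    if counts.ndim == 2:
        counts = counts[None]
    P = counts.shape[0]
    n2 = 2.0 * counts.sum(axis=(1, 2))

    N = counts
    # fixed haplotype count contributions (everything but the double het)
    fixed_AB = 2 * N[:, 2, 2] + N[:, 2, 1] + N[:, 1, 2]
    fixed_Ab = 2 * N[:, 2, 0] + N[:, 2, 1] + N[:, 1, 0]
    fixed_aB = 2 * N[:, 0, 2] + N[:, 1, 2] + N[:, 0, 1]
    fixed_ab = 2 * N[:, 0, 0] + N[:, 1, 0] + N[:, 0, 1]
    dh = N[:, 1, 1]

    pA = (fixed_AB + fixed_Ab + dh) / n2
    pB = (fixed_AB + fixed_aB + dh) / n2

    def loglik(f: np.ndarray) -> np.ndarray:
        fAB, fAb, faB, fab = f.T
        cell = np.empty_like(N)
        cell[:, 0, 0] = fab**2
        cell[:, 0, 1] = 2 * faB * fab
        cell[:, 0, 2] = faB**2
        cell[:, 1, 0] = 2 * fAb * fab
        cell[:, 1, 1] = 2 * fAB * fab + 2 * fAb * faB
        cell[:, 1, 2] = 2 * fAB * faB
        cell[:, 2, 0] = fAb**2
        cell[:, 2, 1] = 2 * fAB * fAb
        cell[:, 2, 2] = fAB**2
        return np.sum(N * np.log(np.maximum(cell, _EPS)), axis=(1, 2))

    def run(f0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        f = f0.copy()
        ll = loglik(f)
        done = np.zeros(P, bool)
        iters = np.zeros(P, int)
        for it in range(max_iter):
            fAB, fAb, faB, fab = f.T
            num = fAB * fab
            den = num + fAb * faB
            pi = np.where(den > _EPS, num / np.maximum(den, _EPS), 0.5)
            cAB = fixed_AB + pi * dh
            cAb = fixed_Ab + (1 - pi) * dh
            caB = fixed_aB + (1 - pi) * dh
            cab = fixed_ab + pi * dh
            f = np.stack([cAB, cAb, caB, cab], axis=1) / n2[:, None]
            ll_new = loglik(f)
            # EM guarantees monotone log-likelihood; tolerate rounding only
            if np.any(ll_new < ll - 1e-7):
                raise AssertionError("EM log-likelihood decreased")
            newly_done = (ll_new - ll) < tol
            iters[~done] = it + 1
            done = done | newly_done
            ll = ll_new
            if done.all():
                break
        return f, ll, done, iters

    # start at linkage equilibrium
    f0 = np.stack([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)], axis=1)
    f1, ll1, conv1, it1 = run(np.maximum(f0, _EPS))
    # perturbed restart toward maximal positive association; the two-locus
    # likelihood can be bimodal so keep whichever mode scores higher
    shift = 0.5 * (np.minimum(pA, pB) - pA * pB)
    fp = f0 + np.stack([shift, -shift, -shift, shift], axis=1)
    fp = np.clip(fp, _EPS, 1.0)
    fp /= fp.sum(axis=1, keepdims=True)
    f2, ll2, conv2, it2 = run(fp)
    better = ll2 > ll1 + 1e-9
    f = np.where(better[:, None], f2, f1)
    ll = np.where(better, ll2, ll1)
    conv = np.where(better, conv2, conv1)
    iters = np.where(better, it2, it1)
    return f, ll, conv, iters


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float, bool]:
    """EM haplotype frequencies (AB, Ab, aB, ab) for one unphased pair.

    Returns ``(freqs, loglik, converged)``.  Raises
    :class:`UndefinedLDError` if either column is monomorphic among
    pairwise-complete individuals.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    counts = _count_table(g1, g2)
    n = counts.sum()
    if n < 10:
        raise UndefinedLDError("fewer than 10 pairwise-complete individuals")
    pA = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise UndefinedLDError("monomorphic locus: LD undefined")
    f, ll, conv, _ = _em_tables(counts[None], tol=tol, max_iter=max_iter)
    return f[0], float(ll[0]), bool(conv[0])


def d_prime(freqs: np.ndarray) -> tuple[float, float]:
    """Signed D and D' from four haplotype frequencies (AB, Ab, aB, ab).

    D = p_AB - p_A p_B; D' divides by the sign-appropriate maximum
    attainable |D| given the allele frequencies.
    """
    f = np.asarray(freqs, float)
    if f.shape != (4,) or np.any(f < -1e-9) or abs(f.sum() - 1) > 1e-6:
        raise UndefinedLDError("invalid haplotype frequency vector")
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    if min(pA, 1 - pA, pB, 1 - pB) <= _EPS:
        raise UndefinedLDError("monomorphic locus: LD undefined")
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return float(D), float(D / dmax) if dmax > _EPS else 0.0


def _d_prime_vec(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pA = f[:, 0] + f[:, 1]
    pB = f[:, 0] + f[:, 2]
    D = f[:, 0] - pA * pB
    dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
    dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    dp = np.where(dmax > _EPS, D / np.maximum(dmax, _EPS), 0.0)
    return D, np.clip(dp, -1.0, 1.0)


def pairwise_ld_table(
    genotypes: GenotypeMatrix,
    max_pair_kb: float = 500.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """EM-based LD for every marker pair within ``max_pair_kb``.

    Monomorphic SNPs are excluded up front.  The information weight for
    pair (i, j) is ``n_ij * p_i(1-p_i) * p_j(1-p_j)`` rescaled to mean 1,
    with ``n_ij`` the pairwise-complete count: pairs of common, well-typed
    markers say more about the decline curve than rare or patchy ones.

    Returns a DataFrame with one row per pair, ordered by (i, j), columns
    ``snp_i, snp_j, i, j, d_kb, D, D_prime, K_weight, n_used, converged``.
    """
    g = genotypes.genotypes
    pos = genotypes.positions_kb
    p = genotypes.allele_freqs
    poly = np.flatnonzero((p > 0) & (p < 1))
    if poly.size < 2:
        raise EmptyTableError("fewer than 2 polymorphic SNPs")

    ii, jj = np.triu_indices(poly.size, k=1)
    gi = poly[ii]
    gj = poly[jj]
    d = pos[gj] - pos[gi]
    keep = d <= max_pair_kb
    gi, gj, d = gi[keep], gj[keep], d[keep]
    if gi.size == 0:
        raise EmptyTableError("no marker pairs within the distance cap")

    # 3x3 count tables for all pairs at once via indicator cross-products
    if np.isnan(g).any():
        counts = np.empty((gi.size, 3, 3))
        for k, (a, b) in enumerate(zip(gi, gj)):
            counts[k] = _count_table(g[:, a], g[:, b])
    else:
        ind = np.stack([(g == v).astype(float) for v in (0.0, 1.0, 2.0)])  # (3,n,m)
        cross = np.einsum("ank,bnl->klab", ind, ind)  # (m,m,3,3)
        counts = cross[gi, gj]

    f, ll, conv, _ = _em_tables(counts, tol=tol, max_iter=max_iter)
    D, dp = _d_prime_vec(f)
    n_used = counts.sum(axis=(1, 2))
    pi = f[:, 0] + f[:, 1]
    pj = f[:, 0] + f[:, 2]
    K = n_used * pi * (1 - pi) * pj * (1 - pj)
    K = K / K.mean()
    table = pd.DataFrame(
        {
            "snp_i": [genotypes.snp_ids[a] for a in gi],
            "snp_j": [genotypes.snp_ids[b] for b in gj],
            "i": gi,
            "j": gj,
            "d_kb": d,
            "D": D,
            "D_prime": dp,
            "K_weight": K,
            "n_used": n_used.astype(int),
            "converged": conv,
        }
    )
    table = table.sort_values(["i", "j"], kind="stable").reset_index(drop=True)
    table.attrs["max_pair_kb"] = max_pair_kb
    return table
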