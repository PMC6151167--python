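"""Block-jackknife standard errors and permutation Mantel tests.

Genome-wide means of window statistics are autocorrelated along the
chromosome, so naive standard errors are anti-conservative. The block
jackknife deletes 1-Mb blocks (much longer than linkage disequilibrium)
and uses the spread of the delete-one-block estimates. Because terminal
blocks hold unequal window counts, the weighted delete-m form of Busing,
Meijer & van der Leeden (1999) is used; with equal blocks it reduces to
the classic delete-one jackknife.

The Mantel test correlates the off-diagonal entries of two symmetric
pairwise matrices and assesses significance by jointly permuting the
row/column labels of the second matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class JackknifeEstimate:
    mean: float
    se: float
    ci95_low: float
    ci95_high: float
    n_blocks: int
    block_span: float


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    alternative: str
    seed: int | None = None


def block_jackknife(values, chromosomes=None, positions=None,
                    block_span: float = 1e6) -> JackknifeEstimate:
    """Weighted delete-one-block jackknife of a per-window statistic.

    ``values`` are per-window statistics; ``chromosomes``/``positions``
    give each window's location (blocks are ``block_span`` tiles per
    chromosome). If positions are omitted, windows are treated as a
    consecutive series at unit spacing, so ``block_span`` is then the
    number of windows per block. NaN windows are dropped before
    blocking.
    """
    v = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(v.size, dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)
    if chromosomes is None:
        chromosomes = np.zeros(v.size)
    chromosomes = np.asarray(chromosomes)
    ok = np.isfinite(v)
    v, positions, chromosomes = v[ok], positions[ok], chromosomes[ok]
    if v.size == 0:
        raise ValueError("no finite window values")

    block_ids = pd.factorize(np.asarray(
        [f"{c}:{int(p // block_span)}" for c, p in zip(chromosomes, positions)]
    ))[0]
    g = int(block_ids.max()) + 1
    if g < 2:
        raise ValueError(
            "need at least 2 non-empty blocks; reduce block_span "
            f"(got {g} block for span {block_span:g})"
        )
    n = v.size
    total = v.sum()
    theta = total / n
    m = np.bincount(block_ids, minlength=g).astype(float)
    block_sums = np.bincount(block_ids, weights=v, minlength=g)
    theta_minus = (total - block_sums) / (n - m)   # delete-one-block estimates
    h = n / m
    theta_dot = g * theta - float(((1.0 - m / n) * theta_minus).sum())
    var = float((1.0 / g) * (((h * theta - (h - 1.0) * theta_minus - theta_dot) ** 2
                              / (h - 1.0)).sum()))
    se = math.sqrt(max(var, 0.0))
    return JackknifeEstimate(
        mean=float(theta), se=se,
        ci95_low=float(theta) - 1.96 * se, ci95_high=float(theta) + 1.96 * se,
        n_blocks=g, block_span=block_span,
    )


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(a, b, n_permutations: int = 999,
                seed: int | np.random.Generator | None = None,
                alternative: str = "greater",
                method: str = "sampled") -> MantelResult:
    """Permutation Mantel test of two symmetric pairwise matrices.

    ``a`` and ``b`` may be DataFrames (labels aligned by index) or
    square arrays. Labels whose row contains NaN in either matrix are
    dropped from both. ``alternative`` is ``"greater"`` (one-sided,
    positive association; the default, matching the directional
    hypotheses tested here) or ``"two-sided"``. With
    ``method="sampled"`` the p-value is
    ``(1 + #{permutation statistic >= observed}) / (1 + n_permutations)``;
    with ``method="exact"`` all n! label permutations are enumerated
    (identity included) and the p-value is the exact exceedance
    fraction — only sensible for small matrices.
    """
    if isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame):
        if list(a.index) != list(b.index):
            common = [l for l in a.index if l in b.index]
            if len(common) < len(a.index) or len(common) < len(b.index):
                raise ValueError("matrix labels do not match")
            b = b.loc[common, common]
        a = a.to_numpy(dtype=float)
        b = b.to_numpy(dtype=float)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T, equal_nan=True)
            and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")

    # complete-case labels: drop any row/column containing an off-diagonal NaN
    off_a = a.copy(); np.fill_diagonal(off_a, 0.0)
    off_b = b.copy(); np.fill_diagonal(off_b, 0.0)
    keep = ~(np.isnan(off_a).any(axis=1) | np.isnan(off_b).any(axis=1))
    a = a[np.ix_(keep, keep)]
    b = b[np.ix_(keep, keep)]
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels for a permutation Mantel test")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    va = _upper(a)
    va = (va - va.mean())
    sa = math.sqrt((va ** 2).sum())
    if sa == 0:
        raise ValueError("matrix A is constant off-diagonal")

    def corr(mat_b: np.ndarray) -> float:
        vb = _upper(mat_b)
        vb = vb - vb.mean()
        sb = math.sqrt((vb ** 2).sum())
        if sb == 0:
            return 0.0
        return float((va * vb).sum() / (sa * sb))

    r_obs = corr(b)
    stat_obs = abs(r_obs) if alternative == "two-sided" else r_obs

    def stat_of(perm) -> float:
        r_perm = corr(b[np.ix_(perm, perm)])
        return abs(r_perm) if alternative == "two-sided" else r_perm

    eps = 1e-12  # ties at the observed statistic count as exceedances
    if method == "exact":
        import itertools

        perms = list(itertools.permutations(range(n)))
        count = sum(stat_of(np.asarray(p)) >= stat_obs - eps for p in perms)
        p = count / len(perms)
        n_perm_used = len(perms)
    elif method == "sampled":
        count = 0
        for _ in range(n_permutations):
            if stat_of(rng.permutation(n)) >= stat_obs - eps:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        n_perm_used = n_permutations
    else:
        raise ValueError("method must be 'sampled' or 'exact'")
    return MantelResult(
        r=r_obs, r_squared=r_obs ** 2, p_value=p,
        n_permutations=n_perm_used, alternative=alternative,
        seed=seed if isinstance(seed, int) else None,
    )
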