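"""Windowed population-genomic diversity and divergence statistics.

All statistics are pairwise-difference based and expressed per site:

* ``pi`` — nucleotide diversity within a population: the mean, over all
  haplotype pairs, of the per-pair fraction of jointly callable sites at
  which the two haplotypes differ.
* ``pi_S`` — sample-size-weighted average of the two within-population
  diversities, used as a proxy for ancestral diversity.
* ``pi_T`` — diversity of the pooled sample (all C(n1+n2, 2) pairs).
* ``F_ST`` (Hudson) — (pi_T - pi_S) / pi_T.
* ``d_XY`` — mean per-pair difference fraction over the n1*n2
  between-population pairs (absolute divergence).
* ``d_a`` — d_XY - pi_S ("net" divergence since the split; may be
  negative and is reported unclamped).
* Tajima's ``D`` — standardized difference of the pairwise and
  segregating-sites estimators of theta.

Missing data are handled with per-pair denominators: each pair of
haplotypes is normalized by its own count of jointly callable sites.
Allele matrices are ``(haplotypes, sites)`` integer arrays over {0, 1}
with ``-1`` marking a missing call.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class StatConfig:
    """Window-level configuration for the statistics pipeline."""

    window_span: int = 50_000
    min_fraction_genotyped: float = 0.10
    min_fraction_individuals: float = 0.75
    pi_s_weight_rule: str = "sample_size"  # or "equal"
    thin_distance: int = 500
    tajima_min_call_frac: float = 0.75

    def __post_init__(self) -> None:
        for name in ("min_fraction_genotyped", "min_fraction_individuals"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.pi_s_weight_rule not in ("sample_size", "equal"):
            raise ValueError(f"unknown pi_s_weight_rule {self.pi_s_weight_rule!r}")


# ---------------------------------------------------------------------------
# pairwise-difference machinery
# ---------------------------------------------------------------------------

def _all_pairs(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def mean_pairwise_diff(
    alleles: np.ndarray,
    pairs: Iterable[tuple[int, int]] | None = None,
    *,
    invariant_base: float = 0.0,
    scale_to_span: float | None = None,
) -> float:
    """Mean per-pair difference fraction over ``pairs``.

    Each pair is normalized by its own jointly callable site count plus
    ``invariant_base`` (positions known callable and invariant but not
    represented as matrix columns). With variants-only input the
    callability of absent positions is unobservable, so
    ``scale_to_span`` instead extrapolates each pair's callable
    fraction at the matrix sites to the full span: the denominator
    becomes ``callable * span / n_matrix_sites``, which is unbiased
    when masking is independent of allele state. Pairs with an empty
    denominator are skipped; if no pair has a positive denominator the
    result is NaN.
    """
    a = np.asarray(alleles)
    if a.ndim != 2:
        raise ValueError("alleles must be a (haplotypes, sites) matrix")
    if pairs is None:
        pairs = _all_pairs(a.shape[0])
    n_sites = a.shape[1]
    if scale_to_span is not None and n_sites == 0:
        return 0.0  # no variant site in a fully callable span
    vals = []
    for i, j in pairs:
        ok = (a[i] >= 0) & (a[j] >= 0)
        callable_ = np.count_nonzero(ok)
        if scale_to_span is not None:
            denom = callable_ * scale_to_span / n_sites
        else:
            denom = invariant_base + callable_
        if denom <= 0:
            continue
        diff = np.count_nonzero(a[i][ok] != a[j][ok])
        vals.append(diff / denom)
    if not vals:
        return math.nan
    return float(np.mean(vals))


def pi_within(alleles: np.ndarray, *, invariant_base: float = 0.0,
              scale_to_span: float | None = None) -> float:
    """Nucleotide diversity of one population (all within pairs)."""
    n = np.asarray(alleles).shape[0]
    if n < 2:
        return math.nan
    return mean_pairwise_diff(alleles, invariant_base=invariant_base,
                              scale_to_span=scale_to_span)


def pi_total(
    alleles1: np.ndarray, alleles2: np.ndarray, *, invariant_base: float = 0.0,
    scale_to_span: float | None = None,
) -> float:
    """Pooled diversity over all C(n1+n2, 2) pairs."""
    pooled = np.vstack([alleles1, alleles2])
    if pooled.shape[0] < 2:
        raise ValueError("pooled haplotype count must be >= 2")
    return mean_pairwise_diff(pooled, invariant_base=invariant_base,
                              scale_to_span=scale_to_span)


def pi_s_weighted(
    pi1: float, pi2: float, n1: int, n2: int, rule: str = "sample_size"
) -> float:
    """Weighted within-population diversity; w = n1/(n1+n2) by default."""
    if rule == "sample_size":
        w = n1 / (n1 + n2)
    elif rule == "equal":
        w = 0.5
    else:
        raise ValueError(f"unknown weight rule {rule!r}")
    return w * pi1 + (1.0 - w) * pi2


def fst_hudson(pi_t: float, pi_s: float) -> float:
    """Hudson's F_ST = (pi_T - pi_S) / pi_T; NaN when pi_T == 0."""
    if not (math.isfinite(pi_t) and math.isfinite(pi_s)) or pi_t == 0.0:
        return math.nan
    return (pi_t - pi_s) / pi_t


def dxy(
    alleles1: np.ndarray, alleles2: np.ndarray, *, invariant_base: float = 0.0,
    scale_to_span: float | None = None,
) -> float:
    """Absolute divergence: mean over the n1*n2 between-population pairs."""
    a1 = np.asarray(alleles1)
    a2 = np.asarray(alleles2)
    n1, n2 = a1.shape[0], a2.shape[0]
    if n1 < 1 or n2 < 1:
        raise ValueError("each population needs >= 1 haplotype")
    pooled = np.vstack([a1, a2])
    pairs = [(i, n1 + j) for i in range(n1) for j in range(n2)]
    return mean_pairwise_diff(pooled, pairs, invariant_base=invariant_base,
                              scale_to_span=scale_to_span)


def d_a(dxy_value: float, pi_s: float) -> float:
    """Net divergence d_a = d_XY - pi_S (negative values preserved)."""
    return dxy_value - pi_s


# ---------------------------------------------------------------------------
# fast paths for complete (no-missing) 0/1 matrices from the simulator
# ---------------------------------------------------------------------------

def pi_from_matrix(matrix: np.ndarray, n_sites: float) -> float:
    """pi per site for a complete 0/1 haplotype matrix over ``n_sites``."""
    m = np.asarray(matrix)
    n = m.shape[0]
    if n < 2:
        return math.nan
    c = m.sum(axis=0, dtype=np.int64)
    return float((2.0 * c * (n - c)).sum() / (n * (n - 1)) / n_sites)


def dxy_from_matrices(m1: np.ndarray, m2: np.ndarray, n_sites: float) -> float:
    """d_XY per site for complete 0/1 matrices over ``n_sites``."""
    a, b = np.asarray(m1), np.asarray(m2)
    n1, n2 = a.shape[0], b.shape[0]
    c1 = a.sum(axis=0, dtype=np.int64)
    c2 = b.sum(axis=0, dtype=np.int64)
    return float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum() / (n1 * n2) / n_sites)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989) plus a1 via closure; returns (a1, e1, e2)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(alleles: np.ndarray, min_call_frac: float = 0.75) -> float:
    """Tajima's D from a haplotype matrix, tolerating missing calls.

    Only sites callable in at least ``min_call_frac`` of the haplotype
    rows enter the computation (this stabilizes the frequency-spectrum
    constants under genotype-level missingness). The pairwise estimate
    uses per-site callable counts; the sample size entering the
    constants is the rounded mean callable count over retained sites.
    Returns NaN for fewer than 4 usable haplotypes or S == 0.
    """
    a = np.asarray(alleles)
    if a.ndim != 2 or a.shape[0] < 4:
        return math.nan
    h = a.shape[0]
    valid = a >= 0
    ncall = valid.sum(axis=0)
    keep = (ncall >= max(2, math.ceil(min_call_frac * h))) & (ncall >= 2)
    if not keep.any():
        return math.nan
    c = ((a == 1) & valid)[:, keep].sum(axis=0).astype(np.int64)
    n_s = ncall[keep].astype(np.int64)
    poly = (c > 0) & (c < n_s)
    s = int(poly.sum())
    if s == 0:
        return math.nan
    n = h if bool(valid.all()) else int(round(float(n_s.mean())))
    if n < 4:
        return math.nan
    pi_hat = float((2.0 * c * (n_s - c) / (n_s * (n_s - 1.0))).sum())
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_hat - s / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# per-window statistics
# ---------------------------------------------------------------------------

@dataclass
class WindowStats:
    chromosome: str
    start: int
    end: int
    pop1: str
    pop2: str
    n_callable_sites: float = math.nan
    pi1: float = math.nan
    pi2: float = math.nan
    pi_s: float = math.nan
    pi_t: float = math.nan
    fst: float = math.nan
    dxy: float = math.nan
    da: float = math.nan
    tajima_d1: float = math.nan
    tajima_d2: float = math.nan
    n1: int = 0
    n2: int = 0
    passed_filter: bool = False


def _pop_rows(window, meta_by_sample: dict, pop: str) -> list[int]:
    return [
        k
        for k, sid in enumerate(window.haplotype_owner)
        if meta_by_sample[sid].population == pop
    ]


def _pop_individuals(window, meta_by_sample: dict, pop: str) -> list[str]:
    seen = []
    for sid in window.haplotype_owner:
        if meta_by_sample[sid].population == pop and sid not in seen:
            seen.append(sid)
    return seen


def _passes_coverage(window, rows_by_sample: dict[str, list[int]],
                     samples: Sequence[str], cfg: StatConfig) -> bool:
    """The window-inclusion rule: at least ``min_fraction_genotyped`` of
    the window's positions genotyped in at least
    ``min_fraction_individuals`` of the population's individuals."""
    span = window.end - window.start
    a = window.alleles
    n_ind = len(samples)
    if n_ind == 0:
        return False
    need = math.ceil(cfg.min_fraction_individuals * n_ind)
    if a.shape[1] == 0:
        called_sites = 0
    else:
        per_ind = np.zeros((n_ind, a.shape[1]), dtype=bool)
        for k, sid in enumerate(samples):
            rows = rows_by_sample[sid]
            per_ind[k] = np.all(a[rows] >= 0, axis=0)
        called_sites = int((per_ind.sum(axis=0) >= need).sum())
    if getattr(window, "assume_callable", False):
        # positions without a matrix column are invariant and callable
        called_sites += span - a.shape[1]
    return called_sites / span >= cfg.min_fraction_genotyped


def window_stats(window, pops: tuple[str, str], meta, cfg: StatConfig | None = None) -> WindowStats:
    """Compute the full per-window statistics record for one population pair.

    ``meta`` is a sequence of SampleMeta-like objects (``sample_id``,
    ``population`` attributes). Windows failing the coverage filter in
    either population return an all-NaN record with
    ``passed_filter=False``.
    """
    cfg = cfg or StatConfig()
    meta_by_sample = {m.sample_id: m for m in meta}
    rows_by_sample: dict[str, list[int]] = {}
    for k, sid in enumerate(window.haplotype_owner):
        rows_by_sample.setdefault(sid, []).append(k)

    rows1 = _pop_rows(window, meta_by_sample, pops[0])
    rows2 = _pop_rows(window, meta_by_sample, pops[1])
    out = WindowStats(window.chromosome, window.start, window.end, pops[0], pops[1],
                      n1=len(rows1), n2=len(rows2))
    ok = all(
        _passes_coverage(window, rows_by_sample,
                         _pop_individuals(window, meta_by_sample, p), cfg)
        for p in pops
    )
    if not ok or len(rows1) < 2 or len(rows2) < 2:
        return out
    out.passed_filter = True

    a = window.alleles
    span = window.end - window.start
    assume = bool(getattr(window, "assume_callable", False))
    scale = float(span) if assume else None
    a1 = a[rows1]
    a2 = a[rows2]
    out.n_callable_sites = float(span) if assume else float(a.shape[1])
    out.pi1 = pi_within(a1, scale_to_span=scale)
    out.pi2 = pi_within(a2, scale_to_span=scale)
    out.pi_s = pi_s_weighted(out.pi1, out.pi2, len(rows1), len(rows2),
                             cfg.pi_s_weight_rule)
    out.pi_t = pi_total(a1, a2, scale_to_span=scale)
    out.fst = fst_hudson(out.pi_t, out.pi_s)
    out.dxy = dxy(a1, a2, scale_to_span=scale)
    out.da = d_a(out.dxy, out.pi_s)
    out.tajima_d1 = tajimas_d(a1, cfg.tajima_min_call_frac)
    out.tajima_d2 = tajimas_d(a2, cfg.tajima_min_call_frac)
    return out


def stats_to_dataframe(records: Iterable[WindowStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# site thinning and individual-level dXY
# ---------------------------------------------------------------------------

@dataclass
class ThinnedSites:
    """Genome subsample of well-spaced sites for individual-level dXY.

    With all-sites input the thinned set samples callable positions
    directly and per-site differences are already per bp. With
    variants-only input (``assume_callable``) the thinned set holds
    variants only, so per-site values are rescaled by the genome-wide
    variant density ``total_sites / total_span`` to a per-bp scale.
    """

    chromosomes: np.ndarray      # per-site chromosome label
    positions: np.ndarray        # per-site position
    alleles: np.ndarray          # (haplotypes, sites), -1 missing
    haplotype_owner: list        # sample_id per row
    total_span: float = math.nan    # bp scanned across input windows
    total_sites: int = 0            # matrix sites scanned (pre-thinning)
    assume_callable: bool = False

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def per_bp_scale(self) -> float:
        if not self.assume_callable:
            return 1.0
        if not self.total_span or not math.isfinite(self.total_span):
            return 1.0
        return self.total_sites / self.total_span


def thin_sites(windows: Iterable, meta, min_gap: int = 500) -> ThinnedSites:
    """Greedy left-to-right 500-bp site thinning.

    A site is kept iff it lies at least ``min_gap`` bp beyond the last
    kept site on the same chromosome and at least one individual per
    population has a called genotype there. Windows must arrive in
    genomic order and share a haplotype-row layout.
    """
    meta_by_sample = {m.sample_id: m for m in meta}
    pops = sorted({m.population for m in meta})
    kept_cols: list[np.ndarray] = []
    kept_pos: list[int] = []
    kept_chrom: list[str] = []
    owner: list | None = None
    last_kept: dict[str, float] = {}
    total_span = 0.0
    total_sites = 0
    assume = False
    for w in windows:
        total_span += w.end - w.start
        total_sites += w.alleles.shape[1]
        assume = assume or bool(getattr(w, "assume_callable", False))
        if owner is None:
            owner = list(w.haplotype_owner)
            pop_rows = {
                p: [k for k, sid in enumerate(owner)
                    if meta_by_sample[sid].population == p]
                for p in pops
            }
        elif list(w.haplotype_owner) != owner:
            raise ValueError("inconsistent haplotype layout across windows")
        a = w.alleles
        for s, pos in enumerate(np.asarray(w.site_positions)):
            last = last_kept.get(w.chromosome)
            if last is not None and pos < last + min_gap:
                continue
            col = a[:, s]
            if all(np.any(col[pop_rows[p]] >= 0) for p in pops):
                kept_cols.append(col)
                kept_pos.append(int(pos))
                kept_chrom.append(w.chromosome)
                last_kept[w.chromosome] = pos
    if owner is None:
        owner = []
    if kept_cols:
        mat = np.stack(kept_cols, axis=1)
    else:
        mat = np.zeros((len(owner), 0), dtype=np.int8)
    return ThinnedSites(np.asarray(kept_chrom), np.asarray(kept_pos), mat, owner,
                        total_span=total_span, total_sites=total_sites,
                        assume_callable=assume)


def pairwise_individual_dxy(thinned: ThinnedSites) -> pd.DataFrame:
    """Symmetric matrix of individual-level dXY over the thinned sites.

    Entry (i, j) treats each individual's haplotypes as a mini-population;
    the diagonal is within-individual heterozygosity. Pairs with no
    jointly callable site get NaN with a warning.
    """
    samples: list[str] = []
    for sid in thinned.haplotype_owner:
        if sid not in samples:
            samples.append(sid)
    rows = {
        sid: [k for k, o in enumerate(thinned.haplotype_owner) if o == sid]
        for sid in samples
    }
    n = len(samples)
    out = np.full((n, n), math.nan)
    a = thinned.alleles
    scale = thinned.per_bp_scale
    for i in range(n):
        ri = rows[samples[i]]
        if len(ri) >= 2:
            out[i, i] = pi_within(a[ri]) * scale
        else:
            out[i, i] = 0.0
        for j in range(i + 1, n):
            rj = rows[samples[j]]
            val = dxy(a[ri], a[rj]) * scale
            if math.isnan(val):
                warnings.warn(
                    f"no jointly callable thinned site for pair "
                    f"({samples[i]}, {samples[j]})"
                )
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=samples, columns=samples)
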