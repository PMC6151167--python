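"""Structured coalescent with recombination and infinite-sites mutation.

The simulator generates ancestries of a 50-kb (configurable) locus under
two demographic scenarios used throughout the analysis:

* a single population that underwent one instantaneous size change of
  magnitude ``x`` at time ``t`` generations ago (``x > 1`` means the
  population is ``x``-fold larger at present than before the change);
* two populations of equal size that split ``T`` generations ago and
  have since exchanged migrants at a per-generation rate ``m``.

The Z chromosome is simulated as a separate run with every population
size multiplied by ``z_scale`` (3/4 under an even sex ratio) and, in the
two-population scenario, migration reduced by a factor ``d``
(``m_Z = (1 - d) * m``). Time is expressed in generations throughout, so
the Z and autosomal runs share the same time and migration units.

Implementation: an exact Hudson ancestral-recombination-graph walk.
Each lineage carries a sorted list of ancestral-material intervals
``(left, right, birth_time, leaves)``, where ``leaves`` is the set of
sampled haplotypes descending from the interval (stored as an integer
bitmask for speed). Coalescence of two
lineages emits, for every overlapping stretch, the two branch records
that the stretch contributes to the marginal genealogies; stretches
whose merged leaf set reaches the full sample size have found their
local MRCA and are retired. Recombination splits a lineage at a uniform
point inside its ancestral-material span (trapped gaps included, as in
the exact ARG). The resulting branch records are a flat representation
of the marginal tree sequence and are all that mutation dropping and
summary statistics require: an infinite-sites mutation on a branch
derives exactly the leaves stored with the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .popgen_stats import dxy_from_matrices, pi_from_matrix, tajimas_d

__all__ = [
    "DemographicModel",
    "single_size_change",
    "two_population_split",
    "TreeSequenceLite",
    "SegregatingSiteMatrix",
    "simulate_genealogies",
    "drop_mutations",
    "simulate_matrix",
    "run_size_change_grid",
    "run_two_pop_grid",
    "za_ratio_table",
]

_MAX_EVENTS = 2_000_000


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant demography in units of generations.

    ``deme_sizes`` are present-day diploid sizes. A size change of
    magnitude ``x`` at time ``t`` means each deme's size before ``t``
    (backwards) was ``deme_sizes[d] / x``. ``migration`` is the
    per-generation probability that a lineage's ancestor was a migrant
    (backwards rate per lineage); a full matrix may be supplied for
    more than two demes. ``rho_site`` is the population recombination
    rate 4*N_ref*r per bp, with ``N_ref`` (``rho_ref_size``) the
    baseline autosomal size the scenario is quoted at, so the physical
    per-bp rate r is shared by autosomal and Z runs and across epochs.
    """

    sample_sizes: tuple[int, ...] = (10,)
    deme_sizes: tuple[float, ...] = (3e6,)
    size_change_time: float | None = None
    size_change_magnitude: float = 1.0
    split_time: float | None = None
    ancestral_size: float | None = None
    migration: float = 0.0
    migration_matrix: tuple[tuple[float, ...], ...] | None = None
    mu: float = 2e-9
    rho_site: float = 0.01
    rho_ref_size: float | None = None
    locus_length: float = 50_000.0

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != len(self.deme_sizes):
            raise ValueError("sample_sizes and deme_sizes length mismatch")
        if any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme sizes must be positive")
        if self.size_change_magnitude <= 0:
            raise ValueError("size change magnitude must be positive")
        if self.migration < 0 or self.mu < 0 or self.rho_site < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_haplotypes(self) -> int:
        return int(sum(self.sample_sizes))

    @property
    def r_per_bp(self) -> float:
        ref = self.rho_ref_size if self.rho_ref_size is not None else self.deme_sizes[0]
        return self.rho_site / (4.0 * ref)

    def size_at(self, deme: int, time: float, merged: bool) -> float:
        if merged:
            base = (self.ancestral_size if self.ancestral_size is not None
                    else self.deme_sizes[0])
            return base
        base = self.deme_sizes[deme]
        if self.size_change_time is not None and time >= self.size_change_time:
            base = base / self.size_change_magnitude
        return base

    def mig_matrix(self) -> np.ndarray:
        d = len(self.deme_sizes)
        if self.migration_matrix is not None:
            m = np.asarray(self.migration_matrix, dtype=float)
            if m.shape != (d, d):
                raise ValueError("migration matrix shape mismatch")
            return m
        m = np.full((d, d), self.migration, dtype=float)
        np.fill_diagonal(m, 0.0)
        return m

    def for_chrom_class(self, chrom_class: str, z_scale: float = 0.75,
                        z_migration_reduction: float = 0.0) -> "DemographicModel":
        """Return the model for ``"autosome"`` or ``"Z"`` runs.

        Z: every population size (all epochs) scaled by ``z_scale`` and
        migration reduced by the factor ``d``; times, mutation and the
        physical recombination rate are untouched.
        """
        if chrom_class == "autosome":
            return replace(self, rho_ref_size=self.r_ref())
        if chrom_class != "Z":
            raise ValueError(f"unknown chromosome class {chrom_class!r}")
        if not 0.0 < z_scale <= 1.0:
            raise ValueError("z_scale must be in (0, 1]")
        if not 0.0 <= z_migration_reduction <= 1.0:
            raise ValueError("z_migration_reduction must be in [0, 1]")
        keep = 1.0 - z_migration_reduction
        mig_mat = self.migration_matrix
        if mig_mat is not None:
            mig_mat = tuple(tuple(v * keep for v in row) for row in mig_mat)
        return replace(
            self,
            deme_sizes=tuple(s * z_scale for s in self.deme_sizes),
            ancestral_size=(None if self.ancestral_size is None
                            else self.ancestral_size * z_scale),
            migration=self.migration * keep,
            migration_matrix=mig_mat,
            rho_ref_size=self.r_ref(),
        )

    def r_ref(self) -> float:
        return self.rho_ref_size if self.rho_ref_size is not None else self.deme_sizes[0]


def single_size_change(ne: float = 3e6, x: float = 1.0,
                       t: float | None = None, *, n_haplotypes: int = 10,
                       **kwargs) -> DemographicModel:
    """One population; pre-change size ``ne``, present size ``x * ne``.

    ``x = 1`` (or ``t is None``) is the constant-size model.
    """
    if t is None or x == 1.0:
        return DemographicModel(sample_sizes=(n_haplotypes,), deme_sizes=(ne,),
                                rho_ref_size=ne, **kwargs)
    return DemographicModel(
        sample_sizes=(n_haplotypes,),
        deme_sizes=(ne * x,),
        size_change_time=float(t),
        size_change_magnitude=float(x),
        rho_ref_size=ne,
        **kwargs,
    )


def two_population_split(ne: float = 2e6, split_time: float = 1e6,
                         migration: float = 0.0, *,
                         n_haplotypes_per_pop: int = 10,
                         ancestral_size: float | None = None,
                         **kwargs) -> DemographicModel:
    """Two demes of size ``ne`` splitting ``split_time`` generations ago."""
    return DemographicModel(
        sample_sizes=(n_haplotypes_per_pop, n_haplotypes_per_pop),
        deme_sizes=(ne, ne),
        split_time=float(split_time),
        ancestral_size=ne if ancestral_size is None else ancestral_size,
        migration=migration,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# ancestry simulation
# ---------------------------------------------------------------------------

@dataclass
class TreeSequenceLite:
    """Flat branch-record representation of a marginal tree sequence.

    Each branch is ``(left, right, child_time, parent_time, leaves)``:
    over the genomic interval [left, right) the lineage subtending
    ``leaves`` (a bitmask over haplotypes) existed from ``child_time``
    to ``parent_time``, at which point it coalesced. The union of
    branch records over any position x is the marginal genealogy at x.
    """

    branches: list
    locus_length: float
    n_haplotypes: int

    def breakpoints(self) -> np.ndarray:
        pts = {0.0, self.locus_length}
        for left, right, *_ in self.branches:
            pts.add(left)
            pts.add(right)
        return np.asarray(sorted(pts))

    def _covering(self, x: float):
        return [b for b in self.branches if b[0] <= x < b[1]]

    def tmrca(self, x: float) -> float:
        return max(b[3] for b in self._covering(x))

    def total_branch_length(self, x: float) -> float:
        return float(sum(b[3] - b[2] for b in self._covering(x)))


@dataclass
class SegregatingSiteMatrix:
    """Haplotype-by-site 0/1 matrix from infinite-sites mutation."""

    positions: np.ndarray
    matrix: np.ndarray
    locus_length: float
    sample_sizes: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def by_population(self) -> list[np.ndarray]:
        out = []
        offset = 0
        for n in self.sample_sizes:
            out.append(self.matrix[offset:offset + n])
            offset += n
        return out


def _merge_intervals(iv_a: list, iv_b: list, t: float, full_mask: int,
                     branches: list) -> list:
    """Merge two lineages' ancestral material at coalescence time ``t``.

    Emits branch records for overlapping stretches and drops stretches
    whose merged leaf set is the complete sample (local MRCA found).
    """
    out: list = []
    i = j = 0
    a = iv_a[i] if iv_a else None
    b = iv_b[j] if iv_b else None
    while a is not None or b is not None:
        if b is None or (a is not None and a[1] <= b[0]):
            out.append(a)
            i += 1
            a = iv_a[i] if i < len(iv_a) else None
            continue
        if a is None or b[1] <= a[0]:
            out.append(b)
            j += 1
            b = iv_b[j] if j < len(iv_b) else None
            continue
        lo = max(a[0], b[0])
        hi = min(a[1], b[1])
        if a[0] < lo:
            out.append((a[0], lo, a[2], a[3]))
        elif b[0] < lo:
            out.append((b[0], lo, b[2], b[3]))
        branches.append((lo, hi, a[2], t, a[3]))
        branches.append((lo, hi, b[2], t, b[3]))
        union = a[3] | b[3]
        if union != full_mask:
            out.append((lo, hi, t, union))
        if a[1] > hi:
            a = (hi, a[1], a[2], a[3])
        else:
            i += 1
            a = iv_a[i] if i < len(iv_a) else None
        if b[1] > hi:
            b = (hi, b[1], b[2], b[3])
        else:
            j += 1
            b = iv_b[j] if j < len(iv_b) else None
    # compact: merge adjacent pieces with identical birth time and leaves
    compact: list = []
    for piece in out:
        if (compact and compact[-1][1] == piece[0]
                and compact[-1][2] == piece[2] and compact[-1][3] == piece[3]):
            prev = compact.pop()
            piece = (prev[0], piece[1], piece[2], piece[3])
        compact.append(piece)
    return compact


def _split_intervals(iv: list, pos: float) -> tuple[list, list]:
    left: list = []
    right: list = []
    for piece in iv:
        if piece[1] <= pos:
            left.append(piece)
        elif piece[0] >= pos:
            right.append(piece)
        else:
            left.append((piece[0], pos, piece[2], piece[3]))
            right.append((pos, piece[1], piece[2], piece[3]))
    return left, right


def simulate_genealogies(model: DemographicModel,
                         rng: np.random.Generator) -> TreeSequenceLite:
    """Sample one ancestral recombination graph under ``model``."""
    n_total = model.n_haplotypes
    length = float(model.locus_length)
    r_bp = model.r_per_bp
    mig = model.mig_matrix()
    mig_out = mig.sum(axis=1)

    # lineages: [deme, intervals]
    lineages: list = []
    hap = 0
    for deme, n in enumerate(model.sample_sizes):
        for _ in range(n):
            lineages.append([deme, [(0.0, length, 0.0, 1 << hap)]])
            hap += 1
    full_mask = (1 << n_total) - 1

    if (len(model.deme_sizes) > 1 and model.split_time is None
            and float(mig.max(initial=0.0)) == 0.0):
        raise ValueError("demes never merge: no split time and no migration")

    branches: list = []
    t = 0.0
    merged = False  # becomes True once the split (backwards merge) is passed
    boundaries = sorted(
        b for b in (model.size_change_time, model.split_time)
        if b is not None and b > 0.0
    )
    n_demes = len(model.deme_sizes)
    events = 0

    while lineages:
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError(
                "event cap exceeded; runaway lineage count "
                f"(k={len(lineages)}, t={t:.3g})"
            )
        # per-deme counts
        counts = [0] * n_demes
        for lin in lineages:
            counts[lin[0]] += 1
        coal_rates = [
            counts[d] * (counts[d] - 1) / 2.0 / (2.0 * model.size_at(d, t, merged))
            for d in range(n_demes)
        ]
        coal_total = sum(coal_rates)
        mig_total = 0.0
        if not merged and n_demes > 1:
            mig_total = sum(mig_out[lin[0]] for lin in lineages)
        rec_rate = 0.0
        spans = None
        if r_bp > 0.0:
            spans = [lin[1][-1][1] - lin[1][0][0] for lin in lineages]
            rec_rate = r_bp * sum(spans)
        total = coal_total + mig_total + rec_rate
        next_boundary = boundaries[0] if boundaries else None
        if total <= 0.0:
            if next_boundary is None:
                raise RuntimeError("zero total event rate with lineages remaining")
            t = next_boundary
        else:
            t_next = t + rng.exponential(1.0 / total)
            if next_boundary is not None and t_next >= next_boundary:
                t = next_boundary
            else:
                t = t_next
        if next_boundary is not None and t == next_boundary:
            boundaries.pop(0)
            if model.split_time is not None and t == model.split_time:
                merged = True
                for lin in lineages:
                    lin[0] = 0
            continue

        u = rng.uniform(0.0, total)
        if u < coal_total:
            # coalescence: pick deme, then an unordered lineage pair in it
            for d in range(n_demes):
                if u < coal_rates[d]:
                    break
                u -= coal_rates[d]
            idx = [k for k, lin in enumerate(lineages) if lin[0] == d]
            i1 = int(rng.integers(len(idx)))
            i2 = int(rng.integers(len(idx) - 1))
            if i2 >= i1:
                i2 += 1
            ka, kb = idx[i1], idx[i2]
            merged_iv = _merge_intervals(lineages[ka][1], lineages[kb][1],
                                         t, full_mask, branches)
            for k in sorted((ka, kb), reverse=True):
                del lineages[k]
            if merged_iv:
                lineages.append([d, merged_iv])
            continue
        u -= coal_total
        if u < mig_total:
            # migration: pick lineage weighted by out-rate, then destination
            for lin in lineages:
                rate = mig_out[lin[0]]
                if u < rate:
                    row = mig[lin[0]]
                    v = rng.uniform(0.0, rate)
                    for dest in range(n_demes):
                        if dest == lin[0]:
                            continue
                        if v < row[dest]:
                            lin[0] = dest
                            break
                        v -= row[dest]
                    break
                u -= rate
            continue
        u -= mig_total
        # recombination: pick lineage weighted by span, uniform breakpoint
        for k, lin in enumerate(lineages):
            w = r_bp * spans[k]
            if u < w:
                lo = lin[1][0][0]
                hi = lin[1][-1][1]
                pos = rng.uniform(lo, hi)
                left, right = _split_intervals(lin[1], pos)
                if left and right:
                    lineages[k] = [lin[0], left]
                    lineages.append([lin[0], right])
                break
            u -= w

    return TreeSequenceLite(branches, length, n_total)


def drop_mutations(ts: TreeSequenceLite, mu: float,
                   rng: np.random.Generator,
                   sample_sizes: tuple[int, ...] | None = None) -> SegregatingSiteMatrix:
    """Poisson infinite-sites mutations on the branch records.

    Each branch receives Poisson(mu * interval span * branch length)
    mutations at positions uniform over its genomic interval; the
    leaves recorded with the branch carry the derived allele 1. Every
    site is polymorphic by construction.
    """
    if sample_sizes is None:
        sample_sizes = (ts.n_haplotypes,)
    if mu < 0:
        raise ValueError("mu must be non-negative")
    sites: list[tuple[float, frozenset]] = []
    if mu > 0 and ts.branches:
        lams = np.fromiter(
            ((b[1] - b[0]) * (b[3] - b[2]) for b in ts.branches),
            dtype=float, count=len(ts.branches),
        ) * mu
        counts = rng.poisson(lams)
        for k in np.nonzero(counts)[0]:
            left, right, _, _, leaves = ts.branches[k]
            for pos in rng.uniform(left, right, size=int(counts[k])):
                sites.append((float(pos), leaves))
    sites.sort(key=lambda s: s[0])
    matrix = np.zeros((ts.n_haplotypes, len(sites)), dtype=np.int8)
    for s, (_, leaves) in enumerate(sites):
        rows = [h for h in range(ts.n_haplotypes) if leaves >> h & 1]
        matrix[rows, s] = 1
    positions = np.asarray([p for p, _ in sites])
    return SegregatingSiteMatrix(positions, matrix, ts.locus_length,
                                 tuple(sample_sizes))


def simulate_matrix(model: DemographicModel,
                    rng: np.random.Generator) -> SegregatingSiteMatrix:
    """Ancestry plus mutations in one call."""
    ts = simulate_genealogies(model, rng)
    return drop_mutations(ts, model.mu, rng, model.sample_sizes)


# ---------------------------------------------------------------------------
# replicate machinery and the two simulation grids
# ---------------------------------------------------------------------------

def replicate_seeds(seed: int, n_replicates: int) -> list[np.random.SeedSequence]:
    """Spawn one child seed sequence per replicate from a master seed.

    Grid runners reuse the same replicate streams in every cell (common
    random numbers), which sharpens paired contrasts between cells
    without biasing any single cell's mean.
    """
    return np.random.SeedSequence(seed).spawn(n_replicates)


def _replicate_means(model: DemographicModel, seeds,
                     want_tajima: bool = False) -> dict:
    pis = np.empty(len(seeds))
    tds = np.full(len(seeds), np.nan)
    for k, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        m = simulate_matrix(model, rng)
        pis[k] = pi_from_matrix(m.matrix, m.locus_length)
        if want_tajima:
            tds[k] = tajimas_d(m.matrix)
    out = {"mean_pi": float(pis.mean()), "n_replicates": len(seeds)}
    if want_tajima:
        out["mean_tajima_d"] = float(np.nanmean(tds))
    return out


def run_size_change_grid(x_grid: Sequence[float], t_grid: Sequence[float],
                         ne: float = 3e6, *, z_scale: float = 0.75,
                         n_haplotypes: int = 10, n_replicates: int = 300,
                         heavy_tail_factor: int = 10,
                         locus_length: float = 50_000.0, mu: float = 2e-9,
                         rho_site: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Single-population size-change response surface.

    For every (x, t) cell, simulate replicate windows for the autosomal
    model (pre-change size ``ne``) and the Z model (all sizes scaled by
    ``z_scale``) and record mean nucleotide diversity and mean Tajima's
    D per partition, plus the ratio of mean pi_Z to mean pi_A.

    Contraction cells (x < 1) receive ``heavy_tail_factor`` times the
    base replicate count: their per-window diversity is a heavy-tailed
    mixture (a window either escapes into the large pre-change
    population or coalesces in the small present one), so equalizing
    Monte Carlo error across the surface requires more replicates
    exactly where each replicate is cheapest.
    """
    seeds = replicate_seeds(seed, n_replicates * max(1, heavy_tail_factor))
    rows = []
    for x in x_grid:
        reps = n_replicates * (heavy_tail_factor if x < 1 else 1)
        for t in t_grid:
            base = single_size_change(ne, float(x), float(t),
                                      n_haplotypes=n_haplotypes, mu=mu,
                                      rho_site=rho_site,
                                      locus_length=locus_length)
            cell = {"x": float(x), "t": float(t)}
            for cls in ("autosome", "Z"):
                model = base.for_chrom_class(cls, z_scale=z_scale)
                res = _replicate_means(model, seeds[:reps], want_tajima=True)
                suffix = "A" if cls == "autosome" else "Z"
                cell[f"mean_pi_{suffix}"] = res["mean_pi"]
                cell[f"mean_tajima_d_{suffix}"] = res["mean_tajima_d"]
            cell["pi_ratio_ZA"] = cell["mean_pi_Z"] / cell["mean_pi_A"]
            cell["n_replicates"] = reps
            rows.append(cell)
    return pd.DataFrame(rows)


def _two_pop_replicates(model: DemographicModel, seeds) -> dict:
    vals = {k: np.empty(len(seeds)) for k in ("pi1", "pi2", "pi_t", "dxy")}
    for k, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        m = simulate_matrix(model, rng)
        m1, m2 = m.by_population()
        vals["pi1"][k] = pi_from_matrix(m1, m.locus_length)
        vals["pi2"][k] = pi_from_matrix(m2, m.locus_length)
        vals["pi_t"][k] = pi_from_matrix(m.matrix, m.locus_length)
        vals["dxy"][k] = dxy_from_matrices(m1, m2, m.locus_length)
    mean = {k: float(v.mean()) for k, v in vals.items()}
    mean["pi_s"] = 0.5 * (mean["pi1"] + mean["pi2"])
    mean["fst"] = (mean["pi_t"] - mean["pi_s"]) / mean["pi_t"]
    mean["da"] = mean["dxy"] - mean["pi_s"]
    return mean


def run_two_pop_grid(split_times: Sequence[float], m_grid: Sequence[float],
                     d_grid: Sequence[float], ne: float = 2e6, *,
                     z_scale: float = 0.75, n_haplotypes_per_pop: int = 10,
                     n_replicates: int = 300, locus_length: float = 50_000.0,
                     mu: float = 2e-9, rho_site: float = 0.01,
                     seed: int = 0) -> pd.DataFrame:
    """Two-population split/migration response surface.

    For every (T, m, d) cell, simulate autosomal (deme size ``ne``,
    migration ``m``) and Z (sizes scaled by ``z_scale``, migration
    ``(1-d)*m``) replicate windows and record the replicate-mean
    statistics and the dXY(Z)/dXY(A) ratio of means.
    """
    seeds = replicate_seeds(seed, n_replicates)
    rows = []
    for T in split_times:
        for m in m_grid:
            base = two_population_split(
                ne, float(T), float(m),
                n_haplotypes_per_pop=n_haplotypes_per_pop,
                mu=mu, rho_site=rho_site, locus_length=locus_length,
            )
            auto = _two_pop_replicates(base.for_chrom_class("autosome"), seeds)
            for d in d_grid:
                zmod = base.for_chrom_class("Z", z_scale=z_scale,
                                            z_migration_reduction=float(d))
                zres = _two_pop_replicates(zmod, seeds)
                rows.append({
                    "split_time": float(T), "m": float(m), "d": float(d),
                    "mean_dxy_A": auto["dxy"], "mean_dxy_Z": zres["dxy"],
                    "dxy_ratio_ZA": zres["dxy"] / auto["dxy"],
                    "mean_fst_A": auto["fst"], "mean_fst_Z": zres["fst"],
                    "mean_da_A": auto["da"], "mean_da_Z": zres["da"],
                    "mean_pi_s_A": auto["pi_s"], "mean_pi_s_Z": zres["pi_s"],
                    "n_replicates": n_replicates,
                })
    return pd.DataFrame(rows)


def za_ratio_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot a size-change grid into the (x, t) ratio surface."""
    return grid.pivot(index="x", columns="t", values="pi_ratio_ZA")
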