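"""Genotype, metadata and chromosome-class input with quality filtering.

Reads multi-sample VCFs (plain or bgzipped, via cyvcf2) together with a
population map (``sample  population  sex  lat  lon`` TSV) and a
chromosome-class table (``chrom  class`` TSV, class in {autosome, Z}),
and yields fixed non-overlapping windows of a ploidy-aware haplotype
matrix.

Filtering follows the genotype-call thresholds used for the resequencing
data: calls with depth outside [10, 100] are set to missing, and variant
calls additionally require genotype quality >= 30. Both variant and
invariant VCF records are retained so that callable-site denominators
are correct with an all-sites VCF; a ``assume_callable`` flag supports
variants-only input (synthetic data) by treating absent positions as
callable and invariant.

Lepidopteran females are ZW and therefore hemizygous for the Z: on
Z-class windows each female contributes a single haplotype row, and
residual heterozygous female Z calls (W-mapping or genotyping artifacts)
are set to missing. Sex can be declared in the population map or
inferred from Z heterozygosity.

Coordinates are 0-based half-open internally; VCF's 1-based positions
are converted at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str
    sex: str = "unknown"          # {male, female, unknown}
    latitude: float = math.nan
    longitude: float = math.nan

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r} for {self.sample_id}")
        if not math.isnan(self.latitude) and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude out of range for {self.sample_id}")
        if not math.isnan(self.longitude) and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude out of range for {self.sample_id}")


@dataclass(frozen=True)
class QualityFilters:
    """Per-genotype quality thresholds."""

    min_depth: int = 10
    max_depth: int = 100
    min_gq: int = 30              # applied to variant calls only


@dataclass
class GenotypeWindow:
    """Haplotype-by-site allele matrix for one fixed window.

    ``alleles`` holds {0, 1, MISSING}; ``ploidy`` maps each sample to
    the number of haplotype rows it contributes (2 on autosomes, 1 for
    females on Z). ``assume_callable`` marks variants-only input whose
    absent positions are treated as callable invariant sites.
    """

    chromosome: str
    start: int                     # 0-based inclusive
    end: int                       # exclusive
    chrom_class: str               # {autosome, Z}
    alleles: np.ndarray            # (haplotypes, sites) int8
    site_positions: np.ndarray     # 0-based, ascending, within [start, end)
    is_variant: np.ndarray         # per-site bool
    haplotype_owner: list[str]     # sample_id per row
    ploidy: dict[str, int]
    assume_callable: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions)
        if pos.size and (pos.min() < self.start or pos.max() >= self.end):
            raise ValueError("site positions outside window bounds")


def read_sample_map(path) -> list[SampleMeta]:
    """Population map TSV with header ``sample population sex lat lon``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    required = {"sample", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map needs columns {sorted(required)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(SampleMeta(
            sample_id=row["sample"],
            population=row["population"],
            sex=str(row.get("sex", "unknown")) if pd.notna(row.get("sex")) else "unknown",
            latitude=float(row["lat"]) if "lat" in df.columns and pd.notna(row["lat"]) else math.nan,
            longitude=float(row["lon"]) if "lon" in df.columns and pd.notna(row["lon"]) else math.nan,
        ))
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in population map")
    return metas


def read_chrom_classes(path) -> dict[str, str]:
    """Chromosome-class TSV ``chrom class`` with class in {autosome, Z}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"chrom", "class"}.issubset(df.columns):
        raise ValueError("chromosome-class table needs columns: chrom, class")
    out = {}
    for _, row in df.iterrows():
        cls = row["class"]
        if cls not in ("autosome", "Z"):
            raise ValueError(f"unknown chromosome class {cls!r}")
        if row["chrom"] in out:
            raise ValueError(f"duplicate chromosome {row['chrom']!r}")
        out[row["chrom"]] = cls
    return out


def _window_from_buffer(chrom, cls, wstart, span, cols, positions, variant_flags,
                        samples, assume_callable) -> GenotypeWindow:
    n_hap = 2 * len(samples)
    if cols:
        mat = np.stack(cols, axis=1).astype(np.int8)
        pos = np.asarray(positions)
        var = np.asarray(variant_flags, dtype=bool)
    else:
        mat = np.zeros((n_hap, 0), dtype=np.int8)
        pos = np.asarray([], dtype=int)
        var = np.asarray([], dtype=bool)
    owner = [s for s in samples for _ in range(2)]
    return GenotypeWindow(
        chromosome=chrom, start=wstart, end=wstart + span, chrom_class=cls,
        alleles=mat, site_positions=pos, is_variant=var,
        haplotype_owner=owner, ploidy={s: 2 for s in samples},
        assume_callable=assume_callable,
    )


def load_genotypes(vcf_path, meta: Sequence[SampleMeta],
                   classes: dict[str, str],
                   filters: QualityFilters | None = None,
                   window_span: int = 50_000,
                   assume_callable: bool = False) -> Iterator[GenotypeWindow]:
    """Stream fixed windows of quality-filtered diploid genotypes.

    Windows are emitted in genomic order, diploid for every sample
    (female Z hemizygosity is applied downstream by
    :func:`haploidize_female_z` once sexes are known). Genotypes
    failing DP in [min_depth, max_depth], or variant genotypes with
    GQ < min_gq, are set to missing. Multi-allelic sites are reduced to
    their two most frequent alleles; calls carrying other alleles are
    set to missing.
    """
    from cyvcf2 import VCF

    filters = filters or QualityFilters()
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    wanted = [m.sample_id for m in meta]
    missing_samples = [s for s in wanted if s not in vcf_samples]
    if missing_samples:
        raise ValueError(
            f"samples in population map absent from VCF: {missing_samples}"
        )
    sample_idx = [vcf_samples.index(s) for s in wanted]

    state = None  # (chrom, cls, wstart, cols, positions, variant_flags)

    def flush():
        nonlocal state
        if state is not None:
            chrom, cls, wstart, cols, positions, var = state
            yield _window_from_buffer(chrom, cls, wstart, window_span, cols,
                                      positions, var, wanted, assume_callable)
            state = None

    for rec in vcf:
        chrom = rec.CHROM
        if chrom not in classes:
            raise ValueError(f"chromosome {chrom!r} has no chromosome-class entry")
        pos0 = rec.POS - 1
        wstart = (pos0 // window_span) * window_span
        if state is None or state[0] != chrom or state[2] != wstart:
            yield from flush()
            state = (chrom, classes[chrom], wstart, [], [], [])

        alts = [a for a in rec.ALT if a not in (".", "<NON_REF>", "*")]
        is_variant = len(alts) > 0

        gts = rec.genotypes
        if gts is None:
            continue
        dp = rec.format("DP")
        gq = rec.format("GQ") if is_variant else None

        col = np.full(2 * len(wanted), MISSING, dtype=np.int8)
        # map alleles to the two most frequent (0-based VCF allele indices)
        allele_map = _biallelic_map(rec, gts, sample_idx)
        for k, si in enumerate(sample_idx):
            g = gts[si]
            a0 = int(g[0])
            a1 = int(g[1]) if len(g) > 2 else a0   # haploid record: reuse
            d = int(dp[si][0]) if dp is not None else None
            if d is not None and d >= 0 and not (
                    filters.min_depth <= d <= filters.max_depth):
                continue
            if is_variant and gq is not None:
                q = float(gq[si][0])
                if not math.isnan(q) and q >= 0 and q < filters.min_gq:
                    continue
            for h, a in enumerate((a0, a1)):
                if a < 0:
                    continue
                col[2 * k + h] = allele_map.get(a, MISSING)
        state[3].append(col)
        state[4].append(pos0)
        state[5].append(is_variant)

    yield from flush()


def _biallelic_map(rec, gts, sample_idx) -> dict[int, int]:
    """Map VCF allele indices to {0, 1}, keeping the two most frequent."""
    n_alleles = 1 + len(rec.ALT)
    if n_alleles <= 2:
        return {0: 0, 1: 1}
    counts = np.zeros(n_alleles, dtype=int)
    for si in sample_idx:
        g = gts[si]
        for a in (int(g[0]), int(g[1])):
            if 0 <= a < n_alleles:
                counts[a] += 1
    order = np.argsort(-counts, kind="stable")[:2]
    first, second = int(order[0]), int(order[1])
    # preserve reference-vs-alternate orientation where possible
    if second < first:
        first, second = second, first
    return {first: 0, second: 1}


# ---------------------------------------------------------------------------
# sex inference and female-Z haploidization
# ---------------------------------------------------------------------------

def z_heterozygosity(z_windows: Iterable[GenotypeWindow]) -> pd.DataFrame:
    """Per-sample heterozygous fraction and call count over Z variant sites."""
    het: dict[str, int] = {}
    tot: dict[str, int] = {}
    for w in z_windows:
        if w.chrom_class != "Z":
            raise ValueError("z_heterozygosity expects Z-class windows")
        if not w.site_positions.size:
            continue
        var = w.is_variant
        a = w.alleles[:, var]
        samples = list(dict.fromkeys(w.haplotype_owner))
        for k, s in enumerate(samples):
            a0 = a[2 * k]
            a1 = a[2 * k + 1]
            ok = (a0 >= 0) & (a1 >= 0)
            het[s] = het.get(s, 0) + int(np.count_nonzero(a0[ok] != a1[ok]))
            tot[s] = tot.get(s, 0) + int(np.count_nonzero(ok))
    rows = [
        {"sample": s, "n_sites": tot.get(s, 0),
         "het_fraction": het.get(s, 0) / tot[s] if tot.get(s, 0) else math.nan}
        for s in tot
    ]
    return pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame(
        columns=["n_sites", "het_fraction"])


def infer_sex(z_windows: Iterable[GenotypeWindow], meta: Sequence[SampleMeta],
              min_sites: int = 100,
              rel_threshold: float = 0.1) -> dict[str, str]:
    """Infer sample sexes from Z heterozygosity.

    ZW females are hemizygous on Z, so their apparent Z heterozygosity
    collapses toward zero while ZZ males show ordinary diploid levels.
    A sample is called female when its heterozygous fraction over its
    genotyped Z variant sites falls below ``rel_threshold`` times the
    cohort reference level (the median over samples, which is male-level
    provided females are a minority; declared sexes refine the
    reference). Declared sexes other than "unknown" always override the
    inference. Samples with fewer than ``min_sites`` genotyped Z variant
    sites come back "unknown" with a warning and should be excluded from
    Z-class statistics.
    """
    table = z_heterozygosity(z_windows)
    declared = {m.sample_id: m.sex for m in meta}
    known_males = [s for s, sex in declared.items() if sex == "male"]
    ref_pool = pd.Series(dtype=float)
    if known_males and len(table):
        ref_pool = table.loc[[s for s in known_males if s in table.index],
                             "het_fraction"].dropna()
    if (not len(ref_pool) or ref_pool.median() <= 0) and len(table):
        # no usable declared males: cohort median is male-level as long
        # as hemizygous females are a minority
        ref_pool = table["het_fraction"].dropna()
    reference = float(ref_pool.median()) if len(ref_pool) else math.nan

    out: dict[str, str] = {}
    for m in meta:
        if declared[m.sample_id] != "unknown":
            out[m.sample_id] = declared[m.sample_id]
            continue
        if (m.sample_id not in table.index
                or table.loc[m.sample_id, "n_sites"] < min_sites
                or not math.isfinite(reference) or reference <= 0):
            warnings.warn(
                f"sex of {m.sample_id} undetermined "
                "(too few genotyped Z variant sites); excluded from Z statistics"
            )
            out[m.sample_id] = "unknown"
            continue
        frac = table.loc[m.sample_id, "het_fraction"]
        out[m.sample_id] = ("female" if frac < rel_threshold * reference
                            else "male")
    return out


def haploidize_female_z(window: GenotypeWindow,
                        sexes: dict[str, str]) -> GenotypeWindow:
    """Enforce female hemizygosity on a Z-class window.

    Each female keeps a single haplotype row; residual heterozygous
    female Z genotypes are impossible on a hemizygous chromosome and
    are set to missing. Samples of unknown sex are dropped from the
    window. Autosomal windows are returned unchanged.
    """
    if window.chrom_class != "Z":
        return window
    samples = list(dict.fromkeys(window.haplotype_owner))
    rows_by_sample: dict[str, list[int]] = {}
    for k, s in enumerate(window.haplotype_owner):
        rows_by_sample.setdefault(s, []).append(k)

    new_rows = []
    owner = []
    ploidy = {}
    for s in samples:
        sex = sexes.get(s, "unknown")
        rows = rows_by_sample[s]
        if sex == "male":
            for r in rows:
                new_rows.append(window.alleles[r].copy())
                owner.append(s)
            ploidy[s] = len(rows)
        elif sex == "female":
            if len(rows) == 1:
                hap = window.alleles[rows[0]].copy()
            else:
                a0 = window.alleles[rows[0]]
                a1 = window.alleles[rows[1]]
                hap = a0.copy()
                both = (a0 >= 0) & (a1 >= 0)
                hap[both & (a0 != a1)] = MISSING     # impossible het call
                only1 = (a0 < 0) & (a1 >= 0)
                hap[only1] = a1[only1]
            new_rows.append(hap)
            owner.append(s)
            ploidy[s] = 1
        # unknown sex: excluded
    alleles = (np.stack(new_rows, axis=0) if new_rows
               else np.zeros((0, window.alleles.shape[1]), dtype=np.int8))
    return replace(window, alleles=alleles, haplotype_owner=owner,
                   ploidy=ploidy)
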