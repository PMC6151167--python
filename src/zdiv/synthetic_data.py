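"""Synthetic study inputs generated from known demographic truth.

Emulates the sampling design of a multi-population resequencing study
of a ZW butterfly clade: several populations along a 1-D geographic
transect, a few diploid individuals each, autosomal contigs plus a Z
contig, genotype-level missingness and depth/quality noise straddling
the filter thresholds, and hemizygous females whose Z genotypes are
emitted as homozygous diploid calls — exactly how real callers emit
them — so the haploidization path is exercised end to end.

Demography: all populations split from a common ancestor at a single
time and exchange migrants at a rate decaying geometrically with
transect distance (an isolation-by-distance emulation); the Z contig is
simulated at three-quarters of the autosomal population size with
migration reduced by a factor ``d``. All parameters and the derived
expectations are recorded in ``truth.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .coalsim import DemographicModel, simulate_matrix
from .genomic_io import MISSING, GenotypeWindow

KM_PER_DEGREE = 111.19493  # equatorial, spherical Earth R = 6371 km


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Study design and demographic truth for the generator.

    Defaults are a desk-scale version of a Heliconius-like design:
    diploid effective sizes in the millions, mutation rate 2e-9 per bp
    per generation, per-generation migration within the simulated
    0–1e-6 range, and a 60% Z-specific migration reduction.
    """

    n_populations: int = 3
    samples_per_population: int = 4
    female_fraction: float = 0.25
    ne: float = 2e6
    split_time: float = 4e5
    migration: float = 5e-7          # nearest-neighbour per-generation rate
    migration_decay: float = 0.25    # geometric decay per transect step
    z_scale: float = 0.75
    z_migration_reduction: float = 0.6
    mu: float = 2e-9
    rho_site: float = 0.01
    n_autosomes: int = 2
    windows_per_chromosome: int = 6
    window_span: int = 20_000
    transect_spacing_km: float = 300.0
    origin_lat: float = 0.0
    origin_lon: float = -75.0
    missing_rate: float = 0.02
    dp_fail_rate: float = 0.05
    gq_fail_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")


def _migration_matrix(spec: SyntheticStudySpec) -> tuple[tuple[float, ...], ...]:
    k = spec.n_populations
    rows = []
    for i in range(k):
        row = []
        for j in range(k):
            if i == j:
                row.append(0.0)
            else:
                row.append(spec.migration * spec.migration_decay ** (abs(i - j) - 1))
        rows.append(tuple(row))
    return tuple(rows)


def _model(spec: SyntheticStudySpec, chrom_class: str) -> DemographicModel:
    k = spec.n_populations
    base = DemographicModel(
        sample_sizes=(2 * spec.samples_per_population,) * k,
        deme_sizes=(spec.ne,) * k,
        split_time=spec.split_time,
        ancestral_size=spec.ne,
        migration_matrix=_migration_matrix(spec),
        mu=spec.mu,
        rho_site=spec.rho_site,
        rho_ref_size=spec.ne,
        locus_length=float(spec.window_span),
    )
    return base.for_chrom_class(chrom_class, z_scale=spec.z_scale,
                                z_migration_reduction=spec.z_migration_reduction)


def _sample_table(spec: SyntheticStudySpec) -> list[dict]:
    rows = []
    n_f = round(spec.female_fraction * spec.samples_per_population)
    for p in range(spec.n_populations):
        for i in range(spec.samples_per_population):
            sex = "female" if i < n_f else "male"
            rows.append({
                "sample": f"P{p + 1}_{i + 1}",
                "population": f"pop{p + 1}",
                "true_sex": sex,
                # one sample per population left for the inference path
                "declared_sex": "unknown" if i == spec.samples_per_population - 1 else sex,
                "lat": spec.origin_lat,
                "lon": spec.origin_lon + p * spec.transect_spacing_km / KM_PER_DEGREE,
            })
    return rows


def inject_missingness(window: GenotypeWindow, rate: float,
                       rng: np.random.Generator) -> GenotypeWindow:
    """Mask genotype calls (sample x site) independently at ``rate``.

    Both haplotype rows of a diploid call are masked together, so the
    ploidy structure of the window is preserved.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0 or window.alleles.size == 0:
        return window
    alleles = window.alleles.copy()
    samples = list(dict.fromkeys(window.haplotype_owner))
    rows_by_sample: dict[str, list[int]] = {}
    for k, s in enumerate(window.haplotype_owner):
        rows_by_sample.setdefault(s, []).append(k)
    mask = rng.random((len(samples), alleles.shape[1])) < rate
    for k, s in enumerate(samples):
        alleles[np.ix_(rows_by_sample[s], np.nonzero(mask[k])[0])] = MISSING
    return replace(window, alleles=alleles)


def _format_genotype(a0: int, a1: int | None, dp: int, gq: int) -> str:
    if a0 == MISSING:
        gt = "./."
    elif a1 is None:
        gt = f"{a0}/{a0}"          # hemizygous female emitted as homozygous
    else:
        gt = f"{a0}/{a1}"
    return f"{gt}:{dp}:{gq}"


def _draw_dp(rng: np.random.Generator, fail_rate: float) -> int:
    u = rng.random()
    if u < fail_rate / 2:
        return int(rng.integers(2, 10))       # below the minimum-depth filter
    if u < fail_rate:
        return int(rng.integers(101, 160))    # above the maximum-depth filter
    return int(np.clip(rng.normal(35, 10), 10, 100))


def _draw_gq(rng: np.random.Generator, fail_rate: float) -> int:
    if rng.random() < fail_rate:
        return int(rng.integers(2, 30))
    return int(rng.integers(30, 100))


def generate_study(spec: SyntheticStudySpec, out_dir, seed: int) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces ``study.vcf`` (variants-only, so pipelines should run with
    ``assume_callable``), ``samples.tsv``, ``chrom_classes.tsv`` and
    ``truth.json``; returns a dict of paths plus the truth record.
    Identical spec and seed give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = _sample_table(spec)
    sample_ids = [s["sample"] for s in samples]
    chrom_len = spec.windows_per_chromosome * spec.window_span
    chroms = [(f"chr{i + 1}", "autosome") for i in range(spec.n_autosomes)]
    chroms.append(("chrZ", "Z"))

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    lines += [f"##contig=<ID={c},length={chrom_len}>" for c, _ in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))

    for chrom, cls in chroms:
        model = _model(spec, cls)
        for w in range(spec.windows_per_chromosome):
            mat = simulate_matrix(model, rng)
            offset = w * spec.window_span
            used = set()
            for s_idx in np.argsort(mat.positions):
                pos1 = offset + int(mat.positions[s_idx]) + 1
                if pos1 in used:
                    continue
                used.add(pos1)
                col = mat.matrix[:, s_idx]
                fields = [chrom, str(pos1), ".", "A", "T", ".", "PASS", ".",
                          "GT:DP:GQ"]
                for k, srec in enumerate(samples):
                    a0, a1 = int(col[2 * k]), int(col[2 * k + 1])
                    if rng.random() < spec.missing_rate:
                        a0 = a1 = MISSING
                    dp = _draw_dp(rng, spec.dp_fail_rate)
                    gq = _draw_gq(rng, spec.gq_fail_rate)
                    if cls == "Z" and srec["true_sex"] == "female":
                        fields.append(_format_genotype(a0, None, dp, gq))
                    else:
                        fields.append(_format_genotype(
                            a0, a1 if a0 != MISSING else MISSING, dp, gq))
                lines.append("\t".join(fields))

    vcf_path = out / "study.vcf"
    vcf_path.write_text("\n".join(lines) + "\n")

    map_path = out / "samples.tsv"
    with open(map_path, "w") as fh:
        fh.write("sample\tpopulation\tsex\tlat\tlon\n")
        for s in samples:
            fh.write(f"{s['sample']}\t{s['population']}\t{s['declared_sex']}\t"
                     f"{s['lat']:.6f}\t{s['lon']:.6f}\n")

    class_path = out / "chrom_classes.tsv"
    with open(class_path, "w") as fh:
        fh.write("chrom\tclass\n")
        for c, cls in chroms:
            fh.write(f"{c}\t{cls}\n")

    theta_a = 4 * spec.ne * spec.mu
    truth = {
        "spec": asdict(spec),
        "seed": seed,
        "true_sexes": {s["sample"]: s["true_sex"] for s in samples},
        "expected": {
            # migration and the recent split push within-population
            # diversity slightly above the single-deme value, so the
            # tolerances are intentionally loose smoke-test bands
            "pi_A": {"value": theta_a, "rtol": 0.35},
            "pi_ratio_ZA": {"value": spec.z_scale, "atol": 0.2},
            "dxy_increases_with_distance": True,
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return {"vcf": vcf_path, "samples": map_path, "chrom_classes": class_path,
            "truth": truth_path, "truth_record": truth}
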