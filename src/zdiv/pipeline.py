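"""Stage orchestration shared by the command-line interface and drivers.

Each stage is a plain function over files: ``run_stats`` computes
windowed statistics and individual-level dXY matrices from a VCF plus
metadata, ``run_ratios`` builds the Z/A ratio layer and Mantel tests
from those matrices, ``run_synth`` writes a synthetic study, and
``run_all`` chains them on a synthetic study and verifies the recovered
values against the recorded truth. Every output directory receives a
run manifest with the configuration snapshot and seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genomic_io import (QualityFilters, haploidize_female_z, infer_sex,
                         load_genotypes, read_chrom_classes, read_sample_map)
from .popgen_stats import (StatConfig, pairwise_individual_dxy,
                           stats_to_dataframe, thin_sites, window_stats)
from .resampling import block_jackknife, mantel_test
from .synthetic_data import SyntheticStudySpec, generate_study
from .za_analysis import (bin_series, geographic_distance_matrix,
                          population_coordinates, ratio_series,
                          ratio_vs_proxy_test, za_ratio_matrix)

DEFAULT_CONFIG: dict = {
    "window_span": 50_000,
    "min_depth": 10,
    "max_depth": 100,
    "min_gq": 30,
    "min_fraction_genotyped": 0.10,
    "min_fraction_individuals": 0.75,
    "pi_s_weight_rule": "sample_size",
    "thin_distance": 500,
    "assume_callable": False,
    "sex_min_sites": 100,
    "sex_rel_threshold": 0.1,
    "jackknife_block_span": 1_000_000,
    "mantel_permutations": 999,
    "bin_km": 500.0,
    "bin_dxy": 1.25e-3,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML config and overrides onto the defaults.

    Unknown keys raise with the list of valid keys.
    """
    import yaml

    cfg = dict(DEFAULT_CONFIG)
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if key not in DEFAULT_CONFIG and key != "synth":
                raise KeyError(
                    f"unknown config key {key!r}; valid keys: "
                    f"{sorted(DEFAULT_CONFIG) + ['synth']}"
                )
            cfg[key] = value
    return cfg


def write_manifest(out_dir, subcommand: str, cfg: dict, seed, inputs: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "subcommand": subcommand,
        "config": {k: v for k, v in cfg.items() if k != "synth"},
        "seed": seed,
        "input_checksums": checksums,
        "tool_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _stat_config(cfg: dict) -> StatConfig:
    return StatConfig(
        window_span=cfg["window_span"],
        min_fraction_genotyped=cfg["min_fraction_genotyped"],
        min_fraction_individuals=cfg["min_fraction_individuals"],
        pi_s_weight_rule=cfg["pi_s_weight_rule"],
        thin_distance=cfg["thin_distance"],
    )


def run_stats(vcf, samples, chrom_classes, out_dir, cfg: dict,
              seed: int | None = None) -> dict:
    """Windowed statistics plus thinned individual-level dXY matrices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = read_sample_map(samples)
    classes = read_chrom_classes(chrom_classes)
    filters = QualityFilters(cfg["min_depth"], cfg["max_depth"], cfg["min_gq"])
    scfg = _stat_config(cfg)

    windows = list(load_genotypes(vcf, meta, classes, filters,
                                  window_span=cfg["window_span"],
                                  assume_callable=cfg["assume_callable"]))
    z_windows = [w for w in windows if w.chrom_class == "Z"]
    sexes = infer_sex(z_windows, meta, min_sites=cfg["sex_min_sites"],
                      rel_threshold=cfg["sex_rel_threshold"])
    windows = [haploidize_female_z(w, sexes) if w.chrom_class == "Z" else w
               for w in windows]

    pops = sorted({m.population for m in meta})
    records = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            for w in windows:
                records.append(window_stats(w, (pops[i], pops[j]), meta, scfg))
    stats_df = stats_to_dataframe(records)
    stats_df.insert(0, "chrom_class",
                    [classes[c] for c in stats_df["chromosome"]])
    stats_df.to_csv(out / "window_stats.tsv", sep="\t", index=False)

    # genome-wide jackknife summaries per pair and chromosome class
    jk_rows = []
    for (p1, p2, cls), grp in stats_df.groupby(["pop1", "pop2", "chrom_class"]):
        ok = grp[grp.passed_filter]
        for stat in ("pi1", "pi2", "pi_s", "pi_t", "fst", "dxy", "da",
                     "tajima_d1", "tajima_d2"):
            vals = ok[stat].to_numpy()
            if np.isfinite(vals).sum() < 2:
                continue
            try:
                est = block_jackknife(vals, ok["chromosome"].to_numpy(),
                                      ok["start"].to_numpy(),
                                      block_span=cfg["jackknife_block_span"])
            except ValueError:
                continue
            jk_rows.append({"pop1": p1, "pop2": p2, "chrom_class": cls,
                            "statistic": stat, "mean": est.mean, "se": est.se,
                            "ci95_low": est.ci95_low, "ci95_high": est.ci95_high,
                            "n_blocks": est.n_blocks})
    pd.DataFrame(jk_rows).to_csv(out / "jackknife.tsv", sep="\t", index=False)

    # thinned-site individual dXY per chromosome class
    dxy_paths = {}
    for cls in ("autosome", "Z"):
        sel = [w for w in windows if w.chrom_class == cls]
        if not sel:
            continue
        thinned = thin_sites(sel, meta, min_gap=cfg["thin_distance"])
        mat = pairwise_individual_dxy(thinned)
        path = out / f"dxy_{cls}.tsv"
        mat.to_csv(path, sep="\t")
        dxy_paths[cls] = path

    with open(out / "sexes.tsv", "w") as fh:
        fh.write("sample\tsex\n")
        for s, sex in sexes.items():
            fh.write(f"{s}\t{sex}\n")
    return {"window_stats": out / "window_stats.tsv",
            "jackknife": out / "jackknife.tsv",
            "sexes": sexes, "dxy": dxy_paths, "stats_df": stats_df}


def run_ratios(dxy_auto, dxy_z, samples, out_dir, cfg: dict,
               seed: int = 0) -> dict:
    """Z/A ratio series, binned summaries and Mantel tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a = pd.read_csv(dxy_auto, sep="\t", index_col=0)
    z = pd.read_csv(dxy_z, sep="\t", index_col=0)
    common = [s for s in a.index if s in z.index]
    a = a.loc[common, common]
    z = z.loc[common, common]
    meta = read_sample_map(samples)
    meta_by_id = {m.sample_id: m for m in meta}
    coords = pd.DataFrame(
        {"latitude": [meta_by_id[s].latitude for s in common],
         "longitude": [meta_by_id[s].longitude for s in common]},
        index=common)
    dist = geographic_distance_matrix(coords)
    series = ratio_series(a, z, dist)
    series["dxy_A"] = series["dxy_A"]
    series.to_csv(out / "ratio_series.tsv", sep="\t", index=False)
    bin_series(series, "geographic_km", cfg["bin_km"]).to_csv(
        out / "ratio_bins_km.tsv", sep="\t", index=False)
    bin_series(series, "dxy_A", cfg["bin_dxy"]).to_csv(
        out / "ratio_bins_dxy.tsv", sep="\t", index=False)

    ratio = za_ratio_matrix(a, z)
    results = []
    tests = {}
    for proxy_name, proxy_mat in (("distance", dist), ("dxy_A", a)):
        try:
            res = ratio_vs_proxy_test(ratio, proxy_mat, proxy=proxy_name,
                                      n_permutations=cfg["mantel_permutations"],
                                      seed=seed)
        except ValueError as exc:
            results.append({"proxy": proxy_name, "error": str(exc)})
            continue
        tests[proxy_name] = res
        results.append({"proxy": proxy_name, "r": res.r, "r_squared": res.r_squared,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations, "seed": seed})
    pd.DataFrame(results).to_csv(out / "mantel.tsv", sep="\t", index=False)
    return {"series": series, "mantel": tests, "out": out}


def run_synth(spec: SyntheticStudySpec, out_dir, seed: int) -> dict:
    return generate_study(spec, out_dir, seed)


class TruthViolation(RuntimeError):
    pass


def run_all(out_dir, cfg: dict, spec: SyntheticStudySpec | None = None,
            seed: int = 0) -> dict:
    """synth -> stats -> ratios on a synthetic study, checked against truth."""
    out = Path(out_dir)
    spec = spec or SyntheticStudySpec()
    synth = run_synth(spec, out / "synth", seed)
    stats = run_stats(synth["vcf"], synth["samples"], synth["chrom_classes"],
                      out / "stats", cfg, seed)
    ratios = run_ratios(stats["dxy"]["autosome"], stats["dxy"]["Z"],
                        synth["samples"], out / "ratios", cfg, seed)
    truth = synth["truth_record"]

    df = stats["stats_df"]
    ok = df[df.passed_filter]
    pi_a = float(pd.concat([ok[ok.chrom_class == "autosome"].pi1,
                            ok[ok.chrom_class == "autosome"].pi2]).mean())
    pi_z = float(pd.concat([ok[ok.chrom_class == "Z"].pi1,
                            ok[ok.chrom_class == "Z"].pi2]).mean())
    checks = {}
    exp = truth["expected"]
    checks["pi_A"] = {
        "observed": pi_a, "expected": exp["pi_A"]["value"],
        "ok": bool(abs(pi_a - exp["pi_A"]["value"])
                   <= exp["pi_A"]["rtol"] * exp["pi_A"]["value"]),
    }
    ratio = pi_z / pi_a if pi_a > 0 else math.nan
    checks["pi_ratio_ZA"] = {
        "observed": ratio, "expected": exp["pi_ratio_ZA"]["value"],
        "ok": bool(abs(ratio - exp["pi_ratio_ZA"]["value"])
                   <= exp["pi_ratio_ZA"]["atol"]),
    }
    inferred = stats["sexes"]
    mism = [s for s, true_sex in truth["true_sexes"].items()
            if inferred.get(s) not in ("unknown", true_sex)]
    checks["sex_inference"] = {"mismatches": mism, "ok": not mism}

    (out / "truth_checks.json").write_text(
        json.dumps(checks, indent=2, default=str) + "\n")
    failed = [k for k, v in checks.items() if not v["ok"]]
    if failed:
        raise TruthViolation(f"truth checks failed: {failed}; see {out}")
    return {"checks": checks, "stats": stats, "ratios": ratios}
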