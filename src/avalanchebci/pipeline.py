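"""End-to-end orchestration: simulate -> avalanches -> stats -> decode -> report.

Each stage reads the previous stage's artifact from the output directory and
is idempotent; ``run_all`` chains them. Every stage writes a manifest with
seeds and input hashes next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .avalanches import binarize, branching_ratio, extract_trial_atms, segment_avalanches
from .cohort import CohortSpec, make_cohort, make_ground_truth
from .config import PipelineConfig, RunManifest
from .decoding import compare_pipelines, evaluate_pipelines
from .io import (
    avalanche_catalog,
    load_area_map,
    load_cohort,
    load_trial_atms,
    save_cohort,
    save_trial_atms,
)
from .permutation import (
    aggregate_hit_miss,
    bci_correlation,
    group_reliability,
    hit_miss_contrast,
    node_concordance,
    subject_edge_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "run_simulate",
    "run_avalanches",
    "run_stats",
    "run_decode",
    "run_report",
    "run_all",
]


def _out_dir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _manifest(config: PipelineConfig, stage: str, out: Path, *inputs: Path) -> None:
    man = RunManifest(stage=stage, seed=config.seed, config=asdict(config))
    for p in inputs:
        man.add_input(p)
    man.write(out / f"manifest_{stage}.json")


def _cohort_spec(config: PipelineConfig) -> CohortSpec:
    spec = CohortSpec(**config.cohort_spec_kwargs())
    if config.profile == "small":
        spec = spec.small()
    return spec


def run_simulate(config: PipelineConfig) -> Path:
    out = _out_dir(config)
    config.dump(out / "config_resolved.yaml")
    spec = _cohort_spec(config)
    gt = make_ground_truth(
        n_regions=spec.n_regions,
        effect_size=config.effect_size,
        miss_attenuation=config.miss_attenuation,
        seed=config.seed,
    )
    cohort = make_cohort(spec, gt)
    path = out / "cohort.h5"
    save_cohort(path, cohort)
    _manifest(config, "simulate", out)
    logger.info("wrote %s (%d subjects)", path, spec.n_subjects)
    return path


def run_avalanches(config: PipelineConfig) -> Path:
    out = _out_dir(config)
    cohort_path = Path(config.cohort_path or out / "cohort.h5")
    if not cohort_path.exists():
        raise FileNotFoundError(f"avalanches stage: cohort file {cohort_path} missing; run simulate first")
    cohort = load_cohort(cohort_path)
    atm_sets, catalog_frames, sigma_rows = [], [], []
    for rec in cohort.subjects:
        atms = extract_trial_atms(
            rec.data, threshold_z=config.threshold_z, bin_length_samples=config.bin_length
        )
        atm_sets.append(atms)
        raster = binarize(rec.data, config.threshold_z, config.bin_length)
        avalanches = segment_avalanches(raster)
        cat = avalanche_catalog(avalanches)
        cat.insert(0, "subject_id", rec.data.subject_id)
        catalog_frames.append(cat)
        est = branching_ratio(avalanches)
        sigma_rows.append(
            {
                "subject_id": rec.data.subject_id,
                "sigma": est.sigma,
                "n_avalanches": est.n_avalanches_used,
                "n_single_bin": est.n_single_bin_excluded,
            }
        )
    path = out / "atms.h5"
    save_trial_atms(path, atm_sets)
    pd.concat(catalog_frames, ignore_index=True).to_csv(out / "avalanche_catalog.csv", index=False)
    pd.DataFrame(sigma_rows).to_csv(out / "branching_ratio.csv", index=False)
    _manifest(config, "avalanches", out, cohort_path)
    return path


def run_stats(config: PipelineConfig) -> Path:
    out = _out_dir(config)
    atms_path = out / "atms.h5"
    cohort_path = Path(config.cohort_path or out / "cohort.h5")
    for p, stage in ((atms_path, "avalanches"), (cohort_path, "simulate")):
        if not p.exists():
            raise FileNotFoundError(f"stats stage: {p} missing; run the {stage} stage first")
    atm_sets = load_trial_atms(atms_path)
    cohort = load_cohort(cohort_path)

    area_df = load_area_map(config.area_map)
    n_regions = atm_sets[0].n_regions
    if len(area_df) != n_regions:
        raise ValueError(
            f"stats stage: area map has {len(area_df)} regions but data has "
            f"{n_regions}; pass a matching --area-map"
        )

    rng = np.random.default_rng(config.seed)
    edge_results = [
        subject_edge_test(
            atms,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            rng_seed=int(rng.integers(2**31)),
        )
        for atms in atm_sets
    ]
    reliability = group_reliability(
        edge_results,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        rng_seed=int(rng.integers(2**31)),
    )
    nodes = node_concordance(
        reliability.reliable,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        rng_seed=int(rng.integers(2**31)),
    )
    hm = [
        hit_miss_contrast(
            atms,
            edge_mask=reliability.reliable if reliability.reliable.any() else None,
            n_permutations=config.n_permutations,
            rng_seed=int(rng.integers(2**31)),
        )
        for atms in atm_sets
    ]
    hm_summary = aggregate_hit_miss(hm)
    diffs = np.stack([r.observed_diff for r in edge_results])
    corr = bci_correlation(
        diffs,
        cohort.bci_scores,
        area_df["area"].to_numpy(),
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        rng_seed=int(rng.integers(2**31)),
    )

    edges_i, edges_j = np.nonzero(reliability.reliable)
    pd.DataFrame(
        {
            "source": edges_i,
            "target": edges_j,
            "n_subjects_significant": reliability.concordance_counts[edges_i, edges_j],
            "p": reliability.p_values[edges_i, edges_j],
        }
    ).to_csv(out / "reliable_edges.csv", index=False)
    pd.DataFrame(
        {
            "region": area_df["region"],
            "area": area_df["area"],
            "degree": nodes.degree,
            "p": nodes.p_values,
            "significant": nodes.significant,
        }
    ).to_csv(out / "node_significance.csv", index=False)
    summary = {
        "n_reliable_edges": int(reliability.reliable.sum()),
        "n_significant_regions": int(nodes.significant.sum()),
        "significant_regions": area_df["region"][nodes.significant].tolist(),
        "hit_miss": {
            "mean_statistic": hm_summary["mean_statistic"],
            "fraction_positive": hm_summary["fraction_positive"],
            "per_subject_p": hm_summary["per_subject_p"].tolist(),
        },
        "area_names": corr.area_names,
        "block_means": corr.block_means.tolist(),
        "block_p": corr.block_p.tolist(),
        "significant_blocks": [
            [corr.area_names[i], corr.area_names[j]]
            for i, j in zip(*np.nonzero(corr.significant))
        ],
        "per_subject_significant_edges": [int(r.significant.sum()) for r in edge_results],
    }
    path = out / "stats_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    _manifest(config, "stats", out, atms_path, cohort_path)
    return path


def run_decode(config: PipelineConfig) -> Path:
    out = _out_dir(config)
    cohort_path = Path(config.cohort_path or out / "cohort.h5")
    if not cohort_path.exists():
        raise FileNotFoundError(f"decode stage: cohort file {cohort_path} missing; run simulate first")
    cohort = load_cohort(cohort_path)
    results = []
    rows = []
    rng = np.random.default_rng(config.seed)
    for rec in cohort.subjects:
        res = evaluate_pipelines(
            rec.data,
            n_splits=config.n_splits,
            test_fraction=config.test_fraction,
            rng_seed=int(rng.integers(2**31)),
            bin_length_samples=config.bin_length,
        )
        results.append(res)
        for split in range(res.n_splits):
            for pipe in ("atm", "csp"):
                rows.append(
                    {
                        "subject_id": res.subject_id,
                        "split": split,
                        "pipeline": pipe,
                        "accuracy": res.accuracies[pipe][split],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "decoding_accuracies.csv", index=False)
    comparison = compare_pipelines(results, alpha=config.alpha)
    path = out / "decoding_comparison.csv"
    comparison.to_csv(path, index=False)
    _manifest(config, "decode", out, cohort_path)
    return path


def run_report(config: PipelineConfig) -> Path:
    """Collect the headline tables into one human-readable report."""
    out = _out_dir(config)
    parts = ["# Pipeline report", ""]
    stats_path = out / "stats_summary.json"
    if stats_path.exists():
        s = json.loads(stats_path.read_text())
        parts += [
            "## Encoding (permutation statistics)",
            f"- reliable edges: {s['n_reliable_edges']}",
            f"- regions with above-chance clustering: {s['significant_regions']}",
            f"- hit/miss contrast: mean statistic {s['hit_miss']['mean_statistic']:.4f}, "
            f"positive in {100 * s['hit_miss']['fraction_positive']:.0f}% of subjects",
            f"- significant correlation blocks: {s['significant_blocks']}",
            "",
        ]
    sigma_path = out / "branching_ratio.csv"
    if sigma_path.exists():
        sig = pd.read_csv(sigma_path)
        parts += [
            "## Criticality",
            f"- branching ratio, cohort geometric mean: "
            f"{float(np.exp(np.log(sig['sigma']).mean())):.3f}",
            "",
        ]
    comp_path = out / "decoding_comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        counts = comp["decision"].value_counts().to_dict()
        parts += [
            "## Decoding (ATM+SVM vs CSP+SVM)",
            f"- mean accuracy ATM {comp['atm_mean'].mean():.3f}, CSP {comp['csp_mean'].mean():.3f}",
            f"- per-subject decisions after FDR: {counts}",
            "",
            comp.to_string(index=False),
            "",
        ]
    path = out / "report.md"
    path.write_text("\n".join(parts))
    _manifest(config, "report", out)
    return path


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Full pipeline; stages resume from existing intermediates."""
    out = _out_dir(config)
    artifacts = {}
    if config.cohort_path is None and not (out / "cohort.h5").exists():
        artifacts["cohort"] = run_simulate(config)
    artifacts["atms"] = run_avalanches(config)
    artifacts["stats"] = run_stats(config)
    artifacts["decoding"] = run_decode(config)
    artifacts["report"] = run_report(config)
    return artifacts
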