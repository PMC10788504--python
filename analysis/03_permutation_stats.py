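"""Multi-level permutation statistics on the avalanche transition matrices.

Four stages: (1) per subject, edges whose MI-vs-Rest transition probability
difference beats a trial-label permutation null (BH across edges); (2) edges
significant in more subjects than a significant-edge randomization predicts
("reliable" edges); (3) regions where reliable edges cluster beyond chance;
(4) the hit/miss contrast on reliable edges and the functional-area-level
Spearman correlation between edge differences and BCI scores.

Run:  python analysis/03_permutation_stats.py --out results --n-perm 10000 --seed 0
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import avalanchebci as ab
from avalanchebci.io import load_area_map, load_cohort, load_trial_atms


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    atm_sets = load_trial_atms(args.out / "atms.h5")
    cohort = load_cohort(args.out / "cohort.h5")
    area_df = load_area_map(
        args.out / "areas.csv" if (args.out / "areas.csv").exists() else None
    )
    rng = np.random.default_rng(args.seed)

    edge_results = [
        ab.subject_edge_test(a, n_permutations=args.n_perm, alpha=args.alpha,
                             rng_seed=int(rng.integers(2**31)))
        for a in atm_sets
    ]
    per_subject = [int(r.significant.sum()) for r in edge_results]
    print(f"per-subject significant edges: median {int(np.median(per_subject))}, "
          f"range [{min(per_subject)}, {max(per_subject)}]")

    rel = ab.group_reliability(edge_results, n_permutations=args.n_perm,
                               alpha=args.alpha, rng_seed=int(rng.integers(2**31)))
    print(f"reliable edges: {int(rel.reliable.sum())}")

    nodes = ab.node_concordance(rel.reliable, n_permutations=args.n_perm,
                                alpha=args.alpha, rng_seed=int(rng.integers(2**31)))
    flagged = area_df["region"][nodes.significant].tolist()
    print(f"regions with above-chance clustering: {flagged}")

    hm = [
        ab.hit_miss_contrast(a, edge_mask=rel.reliable if rel.reliable.any() else None,
                             n_permutations=args.n_perm, rng_seed=int(rng.integers(2**31)))
        for a in atm_sets
    ]
    agg = ab.aggregate_hit_miss(hm)
    print(f"hit/miss contrast: mean statistic {agg['mean_statistic']:.4f}, "
          f"positive in {100 * agg['fraction_positive']:.0f}% of subjects")

    corr = ab.bci_correlation(
        np.stack([r.observed_diff for r in edge_results]),
        cohort.bci_scores,
        area_df["area"].to_numpy(),
        n_permutations=args.n_perm,
        alpha=args.alpha,
        rng_seed=int(rng.integers(2**31)),
    )
    sig_blocks = [
        (corr.area_names[i], corr.area_names[j], round(float(corr.block_means[i, j]), 3))
        for i, j in zip(*np.nonzero(corr.significant))
    ]
    print(f"significant correlation blocks (source, target, mean rho): {sig_blocks}")

    ii, jj = np.nonzero(rel.reliable)
    pd.DataFrame({
        "source": area_df["region"].iloc[ii].values,
        "target": area_df["region"].iloc[jj].values,
        "n_subjects": rel.concordance_counts[ii, jj],
        "p": rel.p_values[ii, jj],
    }).to_csv(args.out / "reliable_edges.csv", index=False)
    pd.DataFrame({
        "region": area_df["region"],
        "area": area_df["area"],
        "degree": nodes.degree,
        "p": nodes.p_values,
        "significant": nodes.significant,
    }).to_csv(args.out / "node_significance.csv", index=False)
    (args.out / "stats_summary.json").write_text(json.dumps({
        "per_subject_significant_edges": per_subject,
        "n_reliable_edges": int(rel.reliable.sum()),
        "significant_regions": flagged,
        "hit_miss_mean_statistic": agg["mean_statistic"],
        "hit_miss_fraction_positive": agg["fraction_positive"],
        "area_names": corr.area_names,
        "block_means": corr.block_means.tolist(),
        "block_p": corr.block_p.tolist(),
        "significant_blocks": sig_blocks,
    }, indent=2))
    print(f"wrote {args.out / 'stats_summary.json'}")


if __name__ == "__main__":
    main()
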