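"""Collect the headline tables of the analysis into one report.

Summarizes criticality (branching ratios by bin length), the encoding
results (reliable edges, clustered regions, hit/miss contrast, correlation
blocks) and the decoding benchmark into results/report.md.

Run:  python analysis/05_report.py --out results
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out
    parts = ["# Avalanche-transition-matrix analysis report", ""]

    sigma_path = out / "branching_ratio.csv"
    if sigma_path.exists():
        sigma = pd.read_csv(sigma_path)
        parts += ["## Criticality", ""]
        group_col = "bin_length" if "bin_length" in sigma.columns else None
        if group_col:
            for bl, grp in sigma.groupby(group_col):
                geo = float(np.exp(np.log(grp["sigma"]).mean()))
                parts.append(f"- bin length {bl}: branching ratio {geo:.3f}")
        else:
            geo = float(np.exp(np.log(sigma["sigma"]).mean()))
            parts.append(f"- branching ratio {geo:.3f}")
        parts.append("")

    stats_path = out / "stats_summary.json"
    if stats_path.exists():
        s = json.loads(stats_path.read_text())
        parts += [
            "## Encoding",
            "",
            f"- reliable edges: {s['n_reliable_edges']}",
            f"- regions with above-chance edge clustering: {s['significant_regions']}",
            f"- hit/miss contrast positive in "
            f"{100 * s['hit_miss_fraction_positive']:.0f}% of subjects "
            f"(mean statistic {s['hit_miss_mean_statistic']:.4f})",
            f"- significant BCI-correlation blocks: {s['significant_blocks']}",
            "",
        ]

    comp_path = out / "decoding_comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        parts += [
            "## Decoding (ATM+SVM vs CSP+SVM)",
            "",
            f"- accuracy: ATM {comp['atm_mean'].mean():.3f} "
            f"(inter-subject sd {comp['atm_mean'].std(ddof=1):.3f}), "
            f"CSP {comp['csp_mean'].mean():.3f} "
            f"(sd {comp['csp_mean'].std(ddof=1):.3f})",
            f"- intra-subject variability (median sd over splits): "
            f"ATM {comp['atm_sd'].median():.3f}, CSP {comp['csp_sd'].median():.3f}",
            f"- per-subject decisions after FDR: "
            f"{comp['decision'].value_counts().to_dict()}",
            "",
            comp.to_string(index=False),
            "",
        ]

    (out / "report.md").write_text("\n".join(parts))
    print(f"wrote {out / 'report.md'}")


if __name__ == "__main__":
    main()
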