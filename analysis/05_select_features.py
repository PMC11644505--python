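#!/usr/bin/env python
"""Screen the aggregated feature table: significance filter + decorrelation.

Uses the winning (window, statistic) from step 04, writes the kept-feature
ranking and the redundancy audit trail.
"""

import argparse
import json
from pathlib import Path

from tuberspec.feature_selection import screen
from tuberspec.temporal_selection import WindowSpec, aggregate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "select_window", ROOT / "analysis" / "04_select_window.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    tables, yields = mod.load_cached_features(args.seed)

    choice = json.loads((ROOT / "results" / "window_choice.json").read_text())
    window = WindowSpec(*choice["window"])
    aggregated = aggregate(tables, window, choice["statistic"])
    aggregated.to_parquet(
        ROOT / "scratch" / f"features_seed{args.seed}" / "aggregated.parquet")

    result = screen(aggregated, yields, alpha=0.05, threshold=0.7)

    outdir = ROOT / "results"
    result.kept.to_csv(outdir / "selected_features.csv", index=False)
    result.removed_redundant.to_csv(
        outdir / "removed_redundant.csv", index=False)
    summary = {
        "window": choice["window"], "statistic": choice["statistic"],
        "n_features": int(aggregated.shape[1]),
        "n_nonsignificant": int(len(result.removed_nonsignificant)),
        "n_redundant": int(len(result.removed_redundant)),
        "n_kept": int(len(result.kept)),
    }
    (outdir / "selection_summary.json").write_text(
        json.dumps(summary, indent=1))

    print(f"screened {summary['n_features']} features aggregated with "
          f"{choice['statistic']} over {window}")
    print(f"removed {summary['n_nonsignificant']} non-significant and "
          f"{summary['n_redundant']} redundant; kept {summary['n_kept']}")
    print("top of ranking:")
    print(result.kept.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
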