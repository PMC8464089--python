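"""Sequential-feature-addition evaluation under nested ten-fold CV.

Reads results/analysis/features.csv, and for each problem x classifier pair
evaluates nested-CV accuracy as top-ranked features are added one at a
time, reporting the optimal point (fewest features at maximal accuracy)
and the all-features (no selection) accuracy.  The curve is truncated at
--max-features (default 10) to keep a laptop-scale runtime; pass 30 for
the full curve.  Writes curves.csv and summary.csv.
"""
import argparse
import time
from pathlib import Path

import pandas as pd

from eegfractal import (
    default_classifiers,
    default_problems,
    relieff_rank,
    sequential_curve,
)
from eegfractal.features import feature_names


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=Path("results/analysis/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    parser.add_argument("--classifiers", default="svm_linear,svm_rbf",
                        help="comma-separated subset of {mlp, svm_linear, svm_rbf}")
    parser.add_argument("--problems", default="ABCD/E,AB/CD/E,A/D/E,A/E,D/E")
    parser.add_argument("--ranking", choices=("global", "foldwise"), default="global")
    parser.add_argument("--max-features", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table = pd.read_csv(args.features)
    feats = feature_names()
    specs = default_classifiers(args.classifiers.split(","))
    wanted = set(args.problems.split(","))
    problems = [p for p in default_problems() if p.name in wanted]

    curve_rows, summary_rows = [], []
    for problem in problems:
        keep = table["label"].isin(problem.label_map)
        y = problem.map_labels(table.loc[keep, "label"].to_numpy())
        ranking = relieff_rank(table.loc[keep, feats], y)
        for spec in specs:
            t0 = time.perf_counter()
            curve = sequential_curve(
                table[feats],
                table["label"],
                problem,
                spec,
                ranking=ranking if args.ranking == "global" else None,
                ranking_mode=args.ranking,
                max_features=args.max_features,
                seed=args.seed,
            )
            n_star, acc_star = curve.optimal_point
            summary_rows.append(
                {
                    "problem": problem.name,
                    "classifier": spec.kind,
                    "optimal_n": n_star,
                    "optimal_accuracy": acc_star,
                    "all_features_accuracy": curve.all_features_accuracy,
                }
            )
            for n, acc in enumerate(curve.accuracies, start=1):
                curve_rows.append(
                    {"problem": problem.name, "classifier": spec.kind,
                     "n_features": n, "accuracy": acc}
                )
            print(
                f"{problem.name:>8s} {spec.kind:<10s} best {acc_star:6.2f}% "
                f"with {n_star} features (all: {curve.all_features_accuracy:.2f}%) "
                f"[{time.perf_counter() - t0:.0f}s]"
            )

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(curve_rows).to_csv(args.out / "curves.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(args.out / "summary.csv", index=False)


if __name__ == "__main__":
    main()
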