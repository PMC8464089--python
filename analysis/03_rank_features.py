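"""ReliefF feature ranking per classification problem.

Reads results/analysis/features.csv (run 02_extract_features.py first),
ranks the 30 features with ReliefF separately for each of the five class
groupings, and writes one ranking CSV per problem plus a combined top-five
table (the layout of a published feature-selection table).
"""
import argparse
from pathlib import Path

import pandas as pd

from eegfractal import default_problems, relieff_rank, top_n
from eegfractal.features import feature_names


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=Path("results/analysis/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    table = pd.read_csv(args.features)
    feats = feature_names()
    args.out.mkdir(parents=True, exist_ok=True)

    top5_rows = []
    for problem in default_problems():
        keep = table["label"].isin(problem.label_map)
        y = problem.map_labels(table.loc[keep, "label"].to_numpy())
        ranking = relieff_rank(table.loc[keep, feats], y)
        safe = problem.name.replace("/", "-")
        ranking.to_frame().to_csv(args.out / f"ranking_{safe}.csv", index=False)
        top5 = top_n(ranking, 5)
        top5_rows.append({"problem": problem.name, **{f"rank{i+1}": f for i, f in enumerate(top5)}})
        print(f"{problem.name:>8s}: " + ", ".join(top5))

    pd.DataFrame(top5_rows).to_csv(args.out / "top5_features.csv", index=False)


if __name__ == "__main__":
    main()
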