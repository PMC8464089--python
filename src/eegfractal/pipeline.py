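"""End-to-end orchestration: ingest, decompose, extract, rank, evaluate, report.

Reads a Bonn-convention corpus from disk (one directory per class, one
plain-text file per segment, one numeric sample per line) or generates the
synthetic corpus, then runs rhythm decomposition, feature extraction,
ReliefF ranking and the nested-CV problem suite, persisting every
intermediate artifact (features.csv, ranking.csv, curves.csv, report.md)
so the pipeline can resume from a saved feature table.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluate import (
    ClassifierSpec,
    ProblemDefinition,
    default_classifiers,
    default_problems,
    problem_from_name,
    run_problem_suite,
)
from .features import FeatureConfigs, extract_features, feature_names
from .relieff import relieff_rank
from .rhythms import DEFAULT_BANDS, BandDefinition, decompose
from .segment import BONN_SAMPLING_RATE, EEGSegment
from .synthetic import SyntheticCorpusSpec, generate_bonn_mimic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_bonn", "build_feature_table", "run_pipeline"]

# both Bonn folder conventions map onto canonical tags A-E
_CLASS_ALIASES = {
    "A": "A", "Z": "A",
    "B": "B", "O": "B",
    "C": "C", "N": "C",
    "D": "D", "F": "D",
    "E": "E", "S": "E",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the standard study setup."""

    data: str = "synthetic"  # directory path or 'synthetic'
    corpus: SyntheticCorpusSpec = field(default_factory=SyntheticCorpusSpec)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    features: FeatureConfigs = field(default_factory=FeatureConfigs)
    zero_phase: bool = True
    problems: tuple[str, ...] = ("ABCD/E", "AB/CD/E", "A/D/E", "A/E", "D/E")
    classifiers: tuple[str, ...] = ("mlp", "svm_linear", "svm_rbf")
    ranking_mode: str = "global"
    relieff_k: int = 10
    max_features: int | None = None
    seed: int = 0
    out: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("problems", "classifiers"):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def echo(self) -> dict:
        return {
            "data": self.data,
            "bands": [(b.name, b.low_edge, b.high_edge) for b in self.bands],
            "p_max": list(self.features.higuchi.p_max),
            "hurst_min_block": self.features.hurst.min_block,
            "zero_phase": self.zero_phase,
            "problems": list(self.problems),
            "classifiers": list(self.classifiers),
            "ranking_mode": self.ranking_mode,
            "relieff_k": self.relieff_k,
            "max_features": self.max_features,
            "seed": self.seed,
        }


def load_bonn(
    directory: str | Path, sampling_rate: float = BONN_SAMPLING_RATE
) -> list[EEGSegment]:
    """Load a Bonn-convention corpus (class folders of one-number-per-line files).

    Folder names may use either lettering convention (A-E or Z/O/N/F/S).
    Files are read in lexicographic order for determinism.  Malformed lines
    raise an error naming the file and line number.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such corpus directory: {directory}")
    segments: list[EEGSegment] = []
    class_dirs = sorted(p for p in directory.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories in {directory}")
    for class_dir in class_dirs:
        tag = _CLASS_ALIASES.get(class_dir.name.upper(), class_dir.name)
        files = sorted(class_dir.glob("*.txt")) or sorted(
            p for p in class_dir.iterdir() if p.is_file()
        )
        if not files:
            raise ValueError(f"class folder {class_dir} contains no files")
        for path in files:
            values = []
            for lineno, line in enumerate(path.read_text().splitlines(), start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    values.append(float(line))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric value on line {lineno}: {line!r}"
                    ) from exc
            segments.append(
                EEGSegment(
                    samples=np.array(values),
                    sampling_rate=sampling_rate,
                    label=tag,
                    source_id=path.stem,
                )
            )
    return segments


def build_feature_table(
    segments: Sequence[EEGSegment],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    configs: FeatureConfigs = FeatureConfigs(),
    zero_phase: bool = True,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Decompose every segment and assemble the 30-feature table.

    Returns a DataFrame with the 30 feature columns plus ``source_id`` and
    ``label``.  Rows with any undefined feature are dropped (with a warning)
    unless ``drop_incomplete`` is False, in which case they keep NaNs.
    """
    rows = []
    for seg in segments:
        bank = decompose(seg, bands, zero_phase=zero_phase)
        vec = extract_features(bank, configs)
        row = dict(vec.values)
        row["source_id"] = seg.source_id
        row["label"] = seg.label
        if vec.missing:
            logger.warning(
                "segment %s has undefined features: %s", seg.source_id, vec.missing
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    front = feature_names(configs)
    table = table[front + ["source_id", "label"]]
    if drop_incomplete:
        complete = table[front].notna().all(axis=1)
        if not complete.all():
            logger.warning("dropping %d incomplete rows", int((~complete).sum()))
            table = table.loc[complete].reset_index(drop=True)
    return table


def _report_markdown(config: RunConfig, report: dict, elapsed: dict) -> str:
    lines = ["# Pipeline report", "", "## Configuration", ""]
    for key, val in config.echo().items():
        lines.append(f"- {key}: {val}")
    lines += ["", "## Stage timings (s)", ""]
    for stage, dt in elapsed.items():
        lines.append(f"- {stage}: {dt:.1f}")
    lines += ["", "## Top five features per problem", ""]
    for name, entry in report["problems"].items():
        lines.append(f"- **{name}**: " + ", ".join(entry["top5"]))
    lines += [
        "",
        "## Accuracy with and without feature selection",
        "",
        "| Problem | Classifier | With selection (n*) | Without selection |",
        "|---|---|---|---|",
    ]
    for row in report["curves"]:
        lines.append(
            f"| {row['problem']} | {row['classifier']} "
            f"| {row['optimal_accuracy']:.2f}% ({row['optimal_n']}) "
            f"| {row['all_features_accuracy']:.2f}% |"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and persist artifacts under ``config.out``.

    Stages: ingest -> rhythm decomposition + feature extraction -> ReliefF
    ranking -> nested-CV problem suite.  Artifacts: ``features.csv``,
    ``ranking.csv``, ``curves.csv``, ``report.md``.  Deterministic for a
    fixed config (including seed).
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    elapsed: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.data == "synthetic":
        spec = config.corpus
        if spec.seed != config.seed:
            spec = SyntheticCorpusSpec(
                n_classes=spec.n_classes,
                segments_per_class=spec.segments_per_class,
                n_samples=spec.n_samples,
                sampling_rate=spec.sampling_rate,
                seed=config.seed,
                class_profiles=spec.class_profiles,
            )
        segments = generate_bonn_mimic(spec)
    else:
        segments = load_bonn(config.data)
    elapsed["ingest"] = time.perf_counter() - t0
    logger.info("ingested %d segments in %.1fs", len(segments), elapsed["ingest"])

    t0 = time.perf_counter()
    table = build_feature_table(
        segments, config.bands, config.features, zero_phase=config.zero_phase
    )
    table.to_csv(out / "features.csv", index=False)
    elapsed["features"] = time.perf_counter() - t0
    logger.info("feature table %s in %.1fs", table.shape, elapsed["features"])

    t0 = time.perf_counter()
    feats = feature_names(config.features)
    global_ranking = relieff_rank(
        table[feats], table["label"], k_neighbors=config.relieff_k
    )
    global_ranking.to_frame().to_csv(out / "ranking.csv", index=False)
    elapsed["ranking"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    problems = [problem_from_name(p) for p in config.problems]
    specs = default_classifiers(config.classifiers)
    report = run_problem_suite(
        table[feats],
        table["label"],
        problems,
        specs,
        ranking_mode=config.ranking_mode,
        max_features=config.max_features,
        seed=config.seed,
        relieff_k=config.relieff_k,
    )
    elapsed["evaluation"] = time.perf_counter() - t0

    curve_rows = []
    for name, entry in report["problems"].items():
        for kind, curve in entry["curves"].items():
            for n, acc in enumerate(curve.accuracies, start=1):
                curve_rows.append(
                    {"problem": name, "classifier": kind, "n_features": n, "accuracy": acc}
                )
    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    (out / "report.md").write_text(_report_markdown(config, report, elapsed))

    report["features"] = table
    report["global_ranking"] = global_ranking
    report["config_echo"] = config.echo()
    report["elapsed"] = elapsed
    return report
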