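"""Nonlinear waveform measures and the 30-dimensional feature vector.

Four measure families are implemented:

* **Higuchi fractal dimension (HFD)** — slope of the log-log scaling of the
  mean normalized curve length A(p) of p-decimated sub-series against 1/p,
  evaluated up to a saturation scale ``p_max``.  Two saturation scales
  (30 and 45) are used, giving two features per signal.
* **Katz fractal dimension (KFD)** — treats the sampled waveform as a planar
  curve with unit abscissa spacing; K = log10(n) / (log10(b/U) + log10(n))
  where U is the total curve length, b the maximal distance from the first
  point and n = U/m with m the mean step length (so n = N-1).
* **Hurst exponent** — classical rescaled-range (R/S) analysis: block sizes
  halve from the full length down to ``min_block``; per block the range of
  the cumulative demeaned series is divided by the population SD, R/S is
  averaged over blocks, and H is the slope of log(R/S) against log(m).
* **Lempel-Ziv complexity (LZC)** — the signal is binarized against its mean
  or median (values strictly above the margin map to 1, ties to 0), parsed
  with the LZ76 exhaustive-history scheme, and the component count c is
  normalized as C = c / (m / log2 m).

Applying all six measures (HFD at two scales, KFD, Hurst, LZC with two
margins) to the original signal and its four rhythms yields 30 named
features per segment.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .rhythms import RhythmBank

__all__ = [
    "FeatureError",
    "HiguchiConfig",
    "HurstConfig",
    "LZConfig",
    "FeatureConfigs",
    "FeatureVector",
    "higuchi_fd",
    "katz_fd",
    "hurst_exponent",
    "lz_complexity",
    "extract_features",
    "feature_names",
    "SOURCE_NAMES",
    "MEASURE_NAMES",
]

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """A nonlinear measure is undefined for the given input."""


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class HiguchiConfig:
    """Saturation scales for the Higuchi length curve (two features)."""

    p_max: tuple[int, int] = (30, 45)

    def __post_init__(self) -> None:
        for p in self.p_max:
            if p < 2:
                raise ValueError(f"p_max must be >= 2, got {p}")


@dataclass(frozen=True)
class HurstConfig:
    """Halving schedule floor for rescaled-range analysis."""

    min_block: int = 16

    def __post_init__(self) -> None:
        if self.min_block < 8:
            raise ValueError(f"min_block must be >= 8, got {self.min_block}")


@dataclass(frozen=True)
class LZConfig:
    """Binarization margin for Lempel-Ziv complexity."""

    threshold_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("mean", "median"):
            raise ValueError(f"threshold_mode must be 'mean' or 'median', got {self.threshold_mode!r}")


@dataclass(frozen=True)
class FeatureConfigs:
    higuchi: HiguchiConfig = HiguchiConfig()
    hurst: HurstConfig = HurstConfig()


# ---------------------------------------------------------------------------
# Higuchi


def _higuchi_log_lengths(x: np.ndarray, p_max: int) -> np.ndarray:
    """log of the mean normalized curve length A(p) for p = 1..p_max."""
    y = x.size
    logs = np.empty(p_max)
    for p in range(1, p_max + 1):
        lengths = np.empty(p)
        for f in range(1, p + 1):
            sub = x[f - 1 :: p]  # T(f), T(f+p), ...
            j_max = sub.size - 1  # = floor((Y - f) / p)
            if j_max < 1:
                raise FeatureError(f"signal too short for p_max={p_max}")
            norm = (y - 1) / (j_max * p)
            lengths[f - 1] = np.abs(np.diff(sub)).sum() * norm / p
        a_p = lengths.mean()
        if a_p <= 0:
            raise FeatureError("curve length is zero (constant signal?)")
        logs[p - 1] = math.log(a_p)
    return logs


def higuchi_fd(signal: Iterable[float], config: HiguchiConfig | int = 30) -> float:
    """Higuchi fractal dimension at a single saturation scale.

    Fits an ordinary least-squares line to log A(p) versus log(1/p) over
    p = 1..p_max and returns its slope.  For a straight-line signal the
    result is 1; for white noise it approaches 2.

    Raises
    ------
    FeatureError
        If the signal is constant (zero curve length) or shorter than
        4 * p_max.
    """
    p_max = config.p_max[0] if isinstance(config, HiguchiConfig) else int(config)
    x = np.asarray(signal, dtype=float)
    if x.size <= 4 * p_max:
        raise FeatureError(f"need length > 4*p_max = {4 * p_max}, got {x.size}")
    log_a = _higuchi_log_lengths(x, p_max)
    log_inv_p = -np.log(np.arange(1, p_max + 1))
    slope = np.polyfit(log_inv_p, log_a, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Katz


def katz_fd(signal: Iterable[float]) -> float:
    """Katz fractal dimension of a waveform with unit sample spacing.

    The waveform is the planar curve (j, T(j)); U is the summed Euclidean
    distance between consecutive points, b the maximal distance from the
    first point, and n = U / (mean step) = N - 1.  Not amplitude-invariant
    by construction.
    """
    y = np.asarray(signal, dtype=float)
    if y.size < 3:
        raise FeatureError(f"need at least 3 samples, got {y.size}")
    dy = np.diff(y)
    u = float(np.sqrt(1.0 + dy**2).sum())
    j = np.arange(y.size, dtype=float)
    b = float(np.sqrt(j**2 + (y - y[0]) ** 2).max())
    n = y.size - 1  # U / (U / (N-1))
    log_n = math.log10(n)
    return log_n / (math.log10(b / u) + log_n)


# ---------------------------------------------------------------------------
# Hurst (rescaled range)


def _rs_average(x: np.ndarray, m: int) -> float | None:
    """Mean R/S over non-overlapping blocks of length m (remainder dropped)."""
    n_blocks = x.size // m
    blocks = x[: n_blocks * m].reshape(n_blocks, m)
    means = blocks.mean(axis=1, keepdims=True)
    w = blocks - means
    v = np.cumsum(w, axis=1)
    r = v.max(axis=1) - v.min(axis=1)
    s = np.sqrt((w**2).mean(axis=1))  # population SD
    valid = s > 0
    if not valid.any():
        return None
    return float((r[valid] / s[valid]).mean())


def hurst_exponent(signal: Iterable[float], config: HurstConfig = HurstConfig()) -> float:
    """Hurst exponent by rescaled-range (R/S) regression.

    Block lengths follow the halving schedule M, M/2, M/4, ... down to
    ``config.min_block``; blocks with zero standard deviation are excluded.
    Returns the slope of log(R/S_ave(m)) on log(m).  The estimate is not
    clipped here; values outside [0, 1] can occur from finite-sample bias.

    Raises
    ------
    FeatureError
        If fewer than 3 block lengths yield a valid R/S average (e.g. a
        constant signal).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4 * config.min_block:
        raise FeatureError(
            f"need length >= 4*min_block = {4 * config.min_block}, got {x.size}"
        )
    ms, rs = [], []
    m = x.size
    while m >= config.min_block:
        avg = _rs_average(x, m)
        if avg is not None and avg > 0:
            ms.append(m)
            rs.append(avg)
        m //= 2
    if len(ms) < 3:
        raise FeatureError("fewer than 3 valid block lengths for R/S regression")
    slope = np.polyfit(np.log(ms), np.log(rs), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Lempel-Ziv


def binarize(signal: np.ndarray, mode: str) -> np.ndarray:
    """Binary sequence u(j) = 1 where T(j) is strictly above the margin, else 0."""
    x = np.asarray(signal, dtype=float)
    margin = np.mean(x) if mode == "mean" else np.median(x)
    return (x > margin).astype(np.uint8)


def lz76_component_count(bits: np.ndarray) -> int:
    """Number of components in the LZ76 exhaustive-history parsing.

    Scans left to right; each component is the shortest prefix of the
    remaining sequence that does not occur in the history extended by the
    component minus its last symbol.  A final incomplete component counts
    as one.  Implemented over ``bytes`` so the substring searches run in C.
    """
    s = bits.tobytes()
    n = len(s)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        k = 1
        # grow the candidate component while it already occurred
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lz_complexity(signal: Iterable[float], config: LZConfig = LZConfig()) -> float:
    """Normalized Lempel-Ziv complexity C = c / (m / log2 m).

    The signal is binarized against its mean or median margin, parsed with
    the LZ76 exhaustive-history scheme, and the component count normalized
    by the asymptotic rate of a random binary sequence.  Values near 1
    indicate maximal (random-like) complexity.
    """
    x = np.asarray(signal, dtype=float)
    m = x.size
    if m < 2:
        raise FeatureError(f"need at least 2 samples, got {m}")
    bits = binarize(x, config.threshold_mode)
    c = lz76_component_count(bits)
    return c / (m / math.log2(m))


# ---------------------------------------------------------------------------
# feature vector assembly

SOURCE_NAMES: tuple[str, ...] = ("Original Signal", "Delta", "Theta", "Alpha", "Beta")
MEASURE_NAMES: tuple[str, ...] = (
    "HFD_kmax=30",
    "HFD_kmax=45",
    "KFD",
    "Hurst",
    "LZC_mean",
    "LZC_median",
)

_SOURCE_KEYS = {
    "Original Signal": "original",
    "Delta": "delta",
    "Theta": "theta",
    "Alpha": "alpha",
    "Beta": "beta",
}


def feature_names(configs: FeatureConfigs = FeatureConfigs()) -> list[str]:
    """The 30 feature names, measure-major, e.g. ``'KFD(Beta)'``."""
    p30, p45 = sorted(configs.higuchi.p_max)
    measures = (
        f"HFD_kmax={p30}",
        f"HFD_kmax={p45}",
        "KFD",
        "Hurst",
        "LZC_mean",
        "LZC_median",
    )
    return [f"{m}({s})" for m in measures for s in SOURCE_NAMES]


@dataclass
class FeatureVector:
    """The 30 nonlinear features of one segment, keyed ``MEASURE(SOURCE)``.

    Entries whose measure was undefined for the signal (e.g. the Hurst
    exponent of a constant segment) are NaN and listed in ``missing``.
    """

    values: dict[str, float]
    label: str = ""
    source_id: str = ""
    missing: list[str] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return not self.missing

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


def extract_features(
    bank: RhythmBank, configs: FeatureConfigs = FeatureConfigs()
) -> FeatureVector:
    """Compute all 30 features for a rhythm bank.

    The two Higuchi scales share one length-curve evaluation (the shorter
    scale's fit uses a prefix of the longer one's points).  Hurst estimates
    are clipped to [0, 1]; per-measure failures become NaN entries with a
    logged warning rather than aborting the whole vector.
    """
    p_small, p_large = sorted(configs.higuchi.p_max)
    values: dict[str, float] = {}
    missing: list[str] = []

    def _set(name: str, fn) -> None:
        try:
            values[name] = float(fn())
        except FeatureError as exc:
            logger.warning("feature %s undefined: %s", name, exc)
            values[name] = float("nan")
            missing.append(name)

    signals = bank.signals
    per_source: dict[str, dict[str, float]] = {}
    for source, key in _SOURCE_KEYS.items():
        x = signals[key]
        entry: dict[str, float] = {}
        try:
            log_a = _higuchi_log_lengths(x, p_large)
            log_inv_p = -np.log(np.arange(1, p_large + 1))
            entry[f"HFD_kmax={p_large}"] = float(np.polyfit(log_inv_p, log_a, 1)[0])
            entry[f"HFD_kmax={p_small}"] = float(
                np.polyfit(log_inv_p[:p_small], log_a[:p_small], 1)[0]
            )
        except FeatureError as exc:
            logger.warning("HFD undefined for %s: %s", source, exc)
        per_source[source] = entry

    measures = (
        f"HFD_kmax={p_small}",
        f"HFD_kmax={p_large}",
        "KFD",
        "Hurst",
        "LZC_mean",
        "LZC_median",
    )
    for measure in measures:
        for source in SOURCE_NAMES:
            x = signals[_SOURCE_KEYS[source]]
            name = f"{measure}({source})"
            if measure.startswith("HFD"):
                if measure in per_source[source]:
                    values[name] = per_source[source][measure]
                else:
                    values[name] = float("nan")
                    missing.append(name)
            elif measure == "KFD":
                _set(name, lambda x=x: katz_fd(x))
            elif measure == "Hurst":
                _set(name, lambda x=x: min(1.0, max(0.0, hurst_exponent(x, configs.hurst))))
            elif measure == "LZC_mean":
                _set(name, lambda x=x: lz_complexity(x, LZConfig("mean")))
            elif measure == "LZC_median":
                _set(name, lambda x=x: lz_complexity(x, LZConfig("median")))

    return FeatureVector(
        values=values,
        label=bank.original.label,
        source_id=bank.original.source_id,
        missing=missing,
    )
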