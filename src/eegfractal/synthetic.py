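"""Synthetic signals with known nonlinear properties, and a Bonn-style corpus.

Two kinds of generators live here:

* **Oracle signals** for validating the estimators — fractional Gaussian
  noise with an exact Hurst index (circulant-embedding synthesis, so the
  sample autocovariance matches the fGn autocovariance exactly in
  distribution), and Weierstrass-type cosine series with a prescribed
  fractal dimension.

* **A Bonn-mimic corpus**: five labelled collections of 100 single-channel
  segments each (nominally 4097 samples at 173.61 Hz), with class-dependent
  amplitude, spectral content and roughness so the feature pipeline has
  discriminative structure to find.  The seizure-like class E has a
  large-amplitude low-frequency oscillation with superimposed spikes and a
  smoother waveform (lower Katz dimension) than the alpha-dominated normal
  classes; this mirrors the qualitative morphology of ictal versus normal
  EEG without claiming clinical realism.

All generators are pure functions of their parameters and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .segment import BONN_N_SAMPLES, BONN_SAMPLING_RATE, EEGSegment

__all__ = [
    "ClassProfile",
    "SyntheticCorpusSpec",
    "DEFAULT_CLASS_PROFILES",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_weierstrass",
    "generate_bonn_mimic",
    "write_bonn_corpus",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise (estimator oracle)


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H) of unit fGn."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(hurst: float, n: int, seed: int) -> EEGSegment:
    """Fractional Gaussian noise with exact covariance (circulant embedding).

    The increments of fractional Brownian motion with Hurst index H.  The
    autocovariance of the circulant embedding matches the fGn autocovariance
    exactly, so the output is a genuine (not approximate) stationary Gaussian
    sample — suitable as an oracle for the rescaled-range estimator.
    H = 0.5 reduces to white noise.

    Parameters
    ----------
    hurst
        Target Hurst index, strictly inside (0, 1).
    n
        Number of samples (internally padded to a power-of-two circulant).
    seed
        Seed for the Gaussian draws; fixed seed gives identical output.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    g = 1 << max(1, int(np.ceil(np.log2(2 * n))))
    half = g // 2
    gamma = fgn_autocovariance(hurst, np.arange(half + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    # circulant embedding of fGn is nonneg-definite; clip fp noise only
    if lam.min() < -1e-8:
        raise RuntimeError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    u = rng.standard_normal(half + 1)
    v = rng.standard_normal(half + 1)
    w = np.empty(g, dtype=complex)
    w[0] = np.sqrt(lam[0] / g) * u[0]
    w[half] = np.sqrt(lam[half] / g) * u[half]
    w[1:half] = np.sqrt(lam[1:half] / (2 * g)) * (u[1:half] + 1j * v[1:half])
    w[half + 1 :] = np.conj(w[1:half][::-1])
    x = np.fft.fft(w).real[:n]
    return EEGSegment(
        samples=x,
        sampling_rate=BONN_SAMPLING_RATE,
        label="fgn",
        source_id=f"fgn(H={hurst},n={n},seed={seed})",
    )


# ---------------------------------------------------------------------------
# Weierstrass cosine series (fractal-dimension oracle)


def generate_weierstrass(
    dim: float, n: int, n_harmonics: int = 25, lam: float = 3.0
) -> EEGSegment:
    """Weierstrass-type cosine series with prescribed fractal dimension.

    W(t) = sum_k lam^{-kH} cos(2 pi lam^k t) with H = 2 - dim, sampled on
    [0, 1).  The graph's box-counting (and Higuchi) dimension equals
    ``dim`` in the infinite-series limit; harmonics above the Nyquist
    frequency of the sampling grid carry geometrically small amplitude.
    Deterministic — no randomness involved.
    """
    if not 1.0 < dim < 2.0:
        raise ValueError(f"dim must be in (1, 2), got {dim}")
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    h = 2.0 - dim
    t = np.arange(n) / n
    x = np.zeros(n)
    for k in range(n_harmonics):
        freq = lam**k
        if freq > n:  # beyond any representable oscillation
            break
        x += lam ** (-k * h) * np.cos(2.0 * np.pi * freq * t)
    return EEGSegment(
        samples=x,
        sampling_rate=BONN_SAMPLING_RATE,
        label="weierstrass",
        source_id=f"weierstrass(dim={dim},n={n})",
    )


# ---------------------------------------------------------------------------
# Bonn-mimic corpus


@dataclass(frozen=True)
class ClassProfile:
    """Spectral/amplitude recipe for one synthetic class.

    ``band_mix`` maps (low, high) frequency edges in Hz to relative noise
    amplitudes; ``white_level`` adds broadband roughness; ``spike_rate``
    (Hz) and ``spike_amp`` superimpose sharp transients (seizure-like
    classes); ``slow_amp``/``slow_freq`` add a large rhythmic oscillation.
    Amplitudes are in microvolts (SD for noise terms).
    """

    label: str
    band_mix: tuple[tuple[float, float, float], ...]  # (low, high, amplitude)
    white_level: float = 0.0
    spike_rate: float = 0.0
    spike_amp: float = 0.0
    spike_width: float = 0.04  # seconds, half-width of the transient
    slow_amp: float = 0.0
    slow_freq: float = 0.0


DEFAULT_CLASS_PROFILES: tuple[ClassProfile, ...] = (
    # normal, eyes open/closed: alpha-dominant band noise with broadband roughness
    ClassProfile("A", band_mix=((8.0, 14.0, 40.0),), white_level=18.0),
    ClassProfile("B", band_mix=((8.0, 14.0, 50.0),), white_level=15.0),
    # interictal: mixed theta/delta, intermediate roughness, larger amplitude
    ClassProfile(
        "C", band_mix=((0.5, 4.0, 30.0), (4.0, 8.0, 45.0)), white_level=14.0
    ),
    ClassProfile(
        "D", band_mix=((0.5, 4.0, 45.0), (4.0, 8.0, 55.0)), white_level=11.0
    ),
    # seizure-like: huge slow oscillation with broad spike-wave transients and
    # little broadband noise -> high amplitude but smooth waveform (low KFD)
    ClassProfile(
        "E",
        band_mix=((0.5, 2.0, 250.0),),
        white_level=4.0,
        spike_rate=1.5,
        spike_amp=180.0,
        spike_width=0.1,
        slow_amp=400.0,
        slow_freq=1.0,
    ),
)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Layout and class recipes for a synthetic five-collection corpus."""

    n_classes: int = 5
    segments_per_class: int = 100
    n_samples: int = BONN_N_SAMPLES
    sampling_rate: float = BONN_SAMPLING_RATE
    seed: int = 0
    class_profiles: tuple[ClassProfile, ...] = DEFAULT_CLASS_PROFILES

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError(f"n_samples must be >= 64, got {self.n_samples}")
        if self.segments_per_class < 1:
            raise ValueError("segments_per_class must be >= 1")
        if not 1 <= self.n_classes <= len(self.class_profiles):
            raise ValueError(
                f"n_classes must be in [1, {len(self.class_profiles)}], got {self.n_classes}"
            )
        if self.sampling_rate <= 2 * 30.0:
            raise ValueError("sampling_rate must exceed twice the highest band edge (30 Hz)")


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [low, high] Hz."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_train(
    rng: np.random.Generator, n: int, fs: float, rate: float, width_s: float
) -> np.ndarray:
    """Biphasic transients at Poisson times, unit peak amplitude."""
    width = max(3, int(width_s * fs))
    tt = np.arange(-2 * width, 2 * width + 1)
    kernel = tt / width * np.exp(0.5 - 0.5 * (tt / width) ** 2)  # unit-peak biphasic
    n_spikes = rng.poisson(rate * n / fs)
    times = rng.integers(0, n, size=n_spikes)
    impulses = np.zeros(n)
    amps = 0.7 + 0.6 * rng.random(n_spikes)
    np.add.at(impulses, times, amps)
    return np.convolve(impulses, kernel, mode="same")


def _render_segment(
    profile: ClassProfile, spec: SyntheticCorpusSpec, rng: np.random.Generator
) -> np.ndarray:
    n, fs = spec.n_samples, spec.sampling_rate
    x = np.zeros(n)
    for low, high, amp in profile.band_mix:
        x += amp * _band_noise(rng, n, fs, low, high)
    if profile.white_level > 0:
        x += profile.white_level * rng.standard_normal(n)
    if profile.slow_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        freq = profile.slow_freq * (0.9 + 0.2 * rng.random())
        t = np.arange(n) / fs
        x += profile.slow_amp * np.sin(2 * np.pi * freq * t + phase)
    if profile.spike_rate > 0:
        x += profile.spike_amp * _spike_train(
            rng, n, fs, profile.spike_rate, profile.spike_width
        )
    return x


def generate_bonn_mimic(spec: SyntheticCorpusSpec = SyntheticCorpusSpec()) -> list[EEGSegment]:
    """Generate the labelled synthetic corpus (n_classes x segments_per_class).

    Segment order is class-major (all of class 1, then class 2, ...);
    a fixed spec (including seed) reproduces the corpus exactly.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[EEGSegment] = []
    for profile in spec.class_profiles[: spec.n_classes]:
        for i in range(spec.segments_per_class):
            x = _render_segment(profile, spec, rng)
            segments.append(
                EEGSegment(
                    samples=x,
                    sampling_rate=spec.sampling_rate,
                    label=profile.label,
                    source_id=f"{profile.label}{i + 1:03d}",
                )
            )
    return segments


def write_bonn_corpus(segments: Sequence[EEGSegment], directory: str | Path) -> None:
    """Write segments in the Bonn on-disk convention.

    One subdirectory per class label, one plain-text file per segment with
    one integer (rounded sample, microvolts) per line — interchangeable
    with the real corpus for the rest of the pipeline.
    """
    directory = Path(directory)
    for seg in segments:
        class_dir = directory / seg.label
        class_dir.mkdir(parents=True, exist_ok=True)
        path = class_dir / f"{seg.source_id or seg.label}.txt"
        rounded = np.rint(seg.samples).astype(np.int64)
        path.write_text("\n".join(str(v) for v in rounded) + "\n")
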