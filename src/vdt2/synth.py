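"""Synthetic sustained-vowel data.

Two generators live here:

* :func:`synth_vowel` renders a pulse-train-excited periodic waveform with
  controllable fundamental frequency, jitter (cycle-to-cycle period
  perturbation), shimmer (cycle-to-cycle amplitude perturbation) and
  harmonic-to-noise ratio, returning the ground-truth period/amplitude
  sequences alongside the audio.  It serves as the independent oracle for
  the acoustic feature extractor.

* :func:`sample_cohort` draws per-recording feature tables for a two-group
  cohort (T2DM patients vs. non-diabetic controls, six vowels, two
  repetitions each) whose per-cell moments follow a packaged reference table
  of group/vowel means and standard deviations, with a tunable shared
  per-subject random effect and a simulated data-cleaning dropout.

Feature cells are sampled as truncated Gaussians: the reference table only
provides first and second moments, so a Gaussian clipped to the physical
bounds (F0 > 50 Hz, intensities >= 0 dB, perturbation measures >= 0) is the
minimal-assumption choice.  Cross-feature correlation is not modelled by
default; ``feature_cov`` offers a hook for a shared latent factor.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import ConfigError
from .features import (
    FEATURE_NAMES,
    GROUP_CONTROL,
    GROUP_T2DM,
    META_COLUMNS,
    VOWELS,
)

__all__ = [
    "VowelSynthSpec",
    "SynthResult",
    "GroupStats",
    "CohortConfig",
    "synth_vowel",
    "sample_cohort",
    "reference_group_stats",
    "vowel_preset",
    "write_wav",
    "generate_wav_dataset",
]

#: Lower physical bounds used to truncate sampled feature values.
_LOWER_BOUNDS = {
    "meanF0": 50.0,
    "stdevF0": 0.0,
    "meanInten": 0.0,
    "stdevInten": 0.0,
    "HNR": 0.0,
    "localShimmer": 0.0,
    "localdbShimmer": 0.0,
    "apq3Shimmer": 0.0,
    "apq5Shimmer": 0.0,
    "apq11Shimmer": 0.0,
    "localJitter": 0.0,
    "localabsJitter": 0.0,
    "rapJitter": 0.0,
    "ppq5Jitter": 0.0,
}


@dataclass
class VowelSynthSpec:
    """Synthesis parameters for one sustained vowel.

    Parameters
    ----------
    f0_hz : float
        Target fundamental frequency.
    jitter_frac : float
        Cycle-to-cycle period perturbation, as a fraction of the mean period.
    shimmer_frac : float
        Cycle-to-cycle amplitude perturbation, as a fraction of the mean
        cycle amplitude.
    hnr_db : float
        Target harmonic-to-noise power ratio in dB; ``inf`` means noiseless.
    duration_s, sample_rate_hz, seed
        Recording length, sampling rate, and RNG seed.
    """

    f0_hz: float = 155.30
    jitter_frac: float = 0.0
    shimmer_frac: float = 0.0
    hnr_db: float = np.inf
    duration_s: float = 4.0
    sample_rate_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ConfigError("f0_hz must be positive")
        if self.jitter_frac < 0 or self.shimmer_frac < 0:
            raise ConfigError("jitter_frac and shimmer_frac must be >= 0")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.sample_rate_hz < 8000:
            raise ConfigError("sample_rate_hz must be >= 8000")
        if self.sample_rate_hz < 8 * self.f0_hz:
            raise ConfigError(
                f"sample rate {self.sample_rate_hz} too low to represent "
                f"f0={self.f0_hz} Hz (needs >= 8 samples per period)"
            )


@dataclass
class SynthResult:
    """A rendered vowel plus its ground truth.

    ``boundaries``/``periods``/``amplitudes`` are the true cycle-start
    times (s), cycle periods (s) and cycle peak amplitudes (linear, on the
    same scale as ``samples``).
    """

    samples: np.ndarray
    rate: int
    boundaries: np.ndarray
    periods: np.ndarray
    amplitudes: np.ndarray


def synth_vowel(spec: VowelSynthSpec) -> SynthResult:
    """Render a jittered/shimmered pulse train with additive white noise.

    Each glottal cycle is a smooth decaying pulse; successive periods are
    ``meanT * (1 + jitter_frac * c * z_i)`` and cycle amplitudes
    ``1 + shimmer_frac * c * z'_i`` with standard-normal ``z`` clipped to
    +/- 3 and ``c = sqrt(pi)/2`` calibrating the requested fractions to
    the expected local jitter/shimmer of the sequences.  White noise is
    scaled so the harmonic:noise power ratio equals ``10**(hnr_db/10)``;
    the peak is normalized to 0.9 full scale.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    mean_t = 1.0 / spec.f0_hz
    n_samples = int(round(spec.duration_s * fs))

    # Perturbations are calibrated so that the EXPECTED local jitter /
    # local shimmer of the ground-truth sequences equals the requested
    # fraction: for i.i.d. standard-normal z, E|z_{i+1} - z_i| = 2/sqrt(pi),
    # so the draws are scaled by sqrt(pi)/2.
    calib = np.sqrt(np.pi) / 2.0

    # Draw periods until the pulse train covers the requested duration.
    n_cycles_max = int(np.ceil(spec.duration_s / mean_t)) + 8
    z = np.clip(rng.standard_normal(n_cycles_max), -3.0, 3.0)
    periods = mean_t * (1.0 + spec.jitter_frac * calib * z)
    periods = np.maximum(periods, 0.2 * mean_t)  # guard against collapse
    boundaries = np.concatenate(([0.0], np.cumsum(periods)))[:-1]
    keep = boundaries + periods <= spec.duration_s
    boundaries, periods = boundaries[keep], periods[keep]

    zp = np.clip(rng.standard_normal(len(periods)), -3.0, 3.0)
    amps = np.maximum(1.0 + spec.shimmer_frac * calib * zp, 0.05)

    # One smooth glottal-like pulse per cycle, u*exp(1-u) with attack time
    # mean period / 8: the rounded peak makes the sampled cycle amplitude
    # insensitive to the pulse's sub-sample position, and pulses are placed
    # at their exact fractional onset so no spurious jitter is injected.
    tau = mean_t / 8.0
    harmonic = np.zeros(n_samples)
    for t0, t_i, a in zip(boundaries, periods, amps):
        pos = t0 * fs
        s0 = int(np.ceil(pos))
        s1 = min(int(np.floor((t0 + t_i) * fs)) + 1, n_samples)
        if s1 <= s0:
            continue
        u = (np.arange(s0, s1) - pos) / (tau * fs)
        harmonic[s0:s1] += a * u * np.exp(1.0 - u)

    signal = harmonic
    if np.isfinite(spec.hnr_db):
        # scale noise against the AC (zero-mean) harmonic power: HNR is a
        # ratio of periodic to aperiodic energy and excludes the DC offset
        # a one-sided pulse train carries
        p_harm = float(np.var(harmonic))
        p_noise = p_harm / 10.0 ** (spec.hnr_db / 10.0)
        signal = harmonic + rng.standard_normal(n_samples) * np.sqrt(p_noise)

    scale = 0.9 / np.max(np.abs(signal))
    return SynthResult(
        samples=signal * scale,
        rate=fs,
        boundaries=boundaries,
        periods=periods,
        amplitudes=amps * scale,
    )


class GroupStats:
    """Per-(group, vowel, feature) means and standard deviations.

    Wraps a long-format table with columns ``group, vowel, feature, mean,
    sd`` and validates completeness: all 2 x 6 x 14 cells must be present
    with non-negative SDs.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"group", "vowel", "feature", "mean", "sd"}
        if not required.issubset(table.columns):
            raise ConfigError(f"GroupStats table needs columns {sorted(required)}")
        if (table["sd"] < 0).any():
            raise ConfigError("GroupStats SDs must be >= 0")
        self._table = table.set_index(["group", "vowel", "feature"]).sort_index()
        dup = self._table.index.duplicated()
        if dup.any():
            raise ConfigError(f"duplicate GroupStats cells: {self._table.index[dup].tolist()}")

    @property
    def table(self) -> pd.DataFrame:
        return self._table.reset_index()

    def get(self, group: str, vowel: str, feature: str) -> tuple[float, float]:
        """Return (mean, sd) for one cell; raises ConfigError naming the
        cell if absent."""
        try:
            row = self._table.loc[(group, vowel, feature)]
        except KeyError:
            raise ConfigError(
                f"missing GroupStats cell (group={group!r}, vowel={vowel!r}, "
                f"feature={feature!r})"
            ) from None
        return float(row["mean"]), float(row["sd"])

    def validate_complete(self, groups=None, vowels=None, features=None) -> None:
        for g in groups or (GROUP_T2DM, GROUP_CONTROL):
            for v in vowels or VOWELS:
                for f in features or FEATURE_NAMES:
                    self.get(g, v, f)

    def anomalies(self) -> list[str]:
        """Flag suspicious cells.

        Currently detects vowels whose control column is identical to the
        T2DM column for every feature — in the packaged reference table this
        happens for /i/, which carries no between-group signal.
        """
        flags = []
        for v in sorted({ix[1] for ix in self._table.index}):
            try:
                identical = all(
                    self.get(GROUP_T2DM, v, f) == self.get(GROUP_CONTROL, v, f)
                    for f in FEATURE_NAMES
                )
            except ConfigError:
                continue
            if identical:
                flags.append(
                    f"vowel /{v}/: control row identical to T2DM row for all "
                    "14 features (likely a transcription artefact; carries no "
                    "between-group signal)"
                )
        return flags

    @classmethod
    def from_csv(cls, path) -> "GroupStats":
        return cls(pd.read_csv(path))


def reference_group_stats() -> GroupStats:
    """The packaged reference moments for both groups and all six vowels."""
    ref = importlib.resources.files("vdt2").joinpath("data/group_stats.csv")
    with importlib.resources.as_file(ref) as path:
        return GroupStats.from_csv(path)


def vowel_preset(
    group: str, vowel: str, stats: GroupStats | None = None, **overrides
) -> VowelSynthSpec:
    """Synthesis spec whose f0/jitter/shimmer/HNR targets equal the
    reference cell means for the requested group and vowel."""
    stats = stats or reference_group_stats()
    spec = dict(
        f0_hz=stats.get(group, vowel, "meanF0")[0],
        jitter_frac=stats.get(group, vowel, "localJitter")[0],
        shimmer_frac=stats.get(group, vowel, "localShimmer")[0],
        hnr_db=stats.get(group, vowel, "HNR")[0],
    )
    spec.update(overrides)
    return VowelSynthSpec(**spec)


@dataclass
class CohortConfig:
    """Cohort composition and sampling controls.

    Defaults reproduce the study conditions: 32 T2DM and 15 control
    subjects, six vowels recorded twice each (564 raw recordings), with 22
    recordings removed by simulated data cleaning (542 retained).
    ``subject_effect_rho`` is the fraction of each feature's variance
    attributable to a shared per-subject offset.
    """

    n_t2dm: int = 32
    n_control: int = 15
    vowels: tuple[str, ...] = VOWELS
    repetitions: int = 2
    subject_effect_rho: float = 0.5
    dropout_n: int = 22
    seed: int = 0
    feature_cov: float = 0.0  # optional shared latent factor across features

    def __post_init__(self) -> None:
        if self.n_t2dm < 1 or self.n_control < 1:
            raise ConfigError("each group needs at least one subject")
        if not 0.0 <= self.subject_effect_rho < 1.0:
            raise ConfigError("subject_effect_rho must be in [0, 1)")
        n_rows = (self.n_t2dm + self.n_control) * len(self.vowels) * self.repetitions
        if not 0 <= self.dropout_n < n_rows:
            raise ConfigError(f"dropout_n must be in [0, {n_rows})")
        if not 0.0 <= self.feature_cov < 1.0:
            raise ConfigError("feature_cov must be in [0, 1)")


def sample_cohort(
    config: CohortConfig | None = None, stats: GroupStats | None = None
) -> pd.DataFrame:
    """Draw a per-recording feature cohort.

    Each recording's feature value is ``cell_mean + sd * (sqrt(rho) * z_sf +
    sqrt(1-rho) * eps)`` where ``z_sf`` is a per-(subject, feature) standard
    normal shared across that subject's recordings, then truncated to the
    feature's physical bounds.  Degenerate reference cells (mean = SD = 0,
    i.e. localabsJitter, printed as 0.000 +/- 0.000 after rounding) are
    reconstructed from the physical identity
    ``localabsJitter = localJitter / meanF0``.
    """
    config = config or CohortConfig()
    stats = stats or reference_group_stats()
    stats.validate_complete(vowels=config.vowels)

    rng = np.random.default_rng(config.seed)
    subjects = [(f"t2dm{i + 1:02d}", GROUP_T2DM) for i in range(config.n_t2dm)]
    subjects += [(f"ctrl{i + 1:02d}", GROUP_CONTROL) for i in range(config.n_control)]

    rho = config.subject_effect_rho
    lam = config.feature_cov
    rows = []
    for s_idx, (sid, group) in enumerate(subjects):
        sex = "M" if s_idx % 2 == 0 else "F"
        z_subj = rng.standard_normal(len(FEATURE_NAMES))
        if lam > 0:  # shared latent factor inducing cross-feature correlation
            shared = rng.standard_normal()
            z_subj = np.sqrt(1 - lam) * z_subj + np.sqrt(lam) * shared
        for vowel in config.vowels:
            for rep in range(1, config.repetitions + 1):
                eps = rng.standard_normal(len(FEATURE_NAMES))
                row = {
                    "subject": sid,
                    "sex": sex,
                    "group": group,
                    "vowel": vowel,
                    "repetition": rep,
                }
                deferred = []
                for f_idx, feat in enumerate(FEATURE_NAMES):
                    mu, sd = stats.get(group, vowel, feat)
                    if mu == 0.0 and sd == 0.0:
                        deferred.append(feat)
                        continue
                    val = mu + sd * (
                        np.sqrt(rho) * z_subj[f_idx] + np.sqrt(1 - rho) * eps[f_idx]
                    )
                    row[feat] = max(val, _LOWER_BOUNDS.get(feat, 0.0))
                for feat in deferred:
                    if feat == "localabsJitter":
                        row[feat] = row["localJitter"] / row["meanF0"]
                    else:
                        row[feat] = 0.0
                rows.append(row)

    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    if config.dropout_n > 0:
        drop = rng.choice(len(table), size=config.dropout_n, replace=False)
        table = table.drop(index=table.index[drop]).reset_index(drop=True)
    return table


def write_wav(path, samples: np.ndarray, rate: int) -> None:
    """Write mono 16-bit PCM."""
    clipped = np.clip(samples, -1.0, 1.0)
    wavfile.write(str(path), rate, np.round(clipped * 32767).astype(np.int16))


def generate_wav_dataset(
    outdir,
    config: CohortConfig | None = None,
    stats: GroupStats | None = None,
    duration_s: float = 4.0,
    sample_rate_hz: int = 44100,
) -> list[Path]:
    """Render one WAV per (subject, vowel, repetition), named
    ``<name>_<M|F>_<T|N>_<vowel>_<rep>.wav``.

    Per-subject f0 offsets follow the same shared-offset model as
    :func:`sample_cohort`.  Intended for small smoke datasets; rendering the
    full 564-recording cohort at 44.1 kHz takes a while.
    """
    config = config or CohortConfig()
    stats = stats or reference_group_stats()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    subjects = [(f"t2dm{i + 1:02d}", GROUP_T2DM, "T") for i in range(config.n_t2dm)]
    subjects += [(f"ctrl{i + 1:02d}", GROUP_CONTROL, "N") for i in range(config.n_control)]
    paths = []
    for s_idx, (sid, group, tag) in enumerate(subjects):
        sex = "M" if s_idx % 2 == 0 else "F"
        z_f0 = np.clip(rng.standard_normal(), -2.5, 2.5)
        for vowel in config.vowels:
            mu_f0, sd_f0 = stats.get(group, vowel, "meanF0")
            jit = max(stats.get(group, vowel, "localJitter")[0], 0.0)
            shim = max(stats.get(group, vowel, "localShimmer")[0], 0.0)
            hnr = stats.get(group, vowel, "HNR")[0]
            f0 = max(mu_f0 + np.sqrt(config.subject_effect_rho) * sd_f0 * z_f0, 60.0)
            for rep in range(1, config.repetitions + 1):
                spec = VowelSynthSpec(
                    f0_hz=f0,
                    jitter_frac=jit,
                    shimmer_frac=shim,
                    hnr_db=hnr,
                    duration_s=duration_s,
                    sample_rate_hz=sample_rate_hz,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                res = synth_vowel(spec)
                path = outdir / f"{sid}_{sex}_{tag}_{vowel}_{rep}.wav"
                write_wav(path, res.samples, res.rate)
                paths.append(path)
    return paths
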