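"""Praat-convention acoustic feature extraction for sustained vowels.

Implements the 14-measure sustained-vowel feature set: voiced-frame F0
statistics (normalized-autocorrelation pitch with parabolic lag
interpolation), frame-intensity statistics, the autocorrelation
harmonic-to-noise ratio, four cycle-level jitter measures and five
cycle-level shimmer measures, plus parsing of the
``name_M_T/N/sen_a_1.wav`` recording naming convention.

Jitter/shimmer definitions (T_i periods, A_i cycle peak amplitudes):

====================  =====================================================
localabsJitter        mean_i |T_{i+1} - T_i|               (seconds)
localJitter           localabsJitter / mean(T)
rapJitter             mean_i |T_i - mean(T_{i-1..i+1})| / mean(T)
ppq5Jitter            mean_i |T_i - mean(T_{i-2..i+2})| / mean(T)
localShimmer          mean_i |A_{i+1} - A_i| / mean(A)
localdbShimmer        mean_i |20 log10(A_{i+1}/A_i)|       (dB)
apqK Shimmer          mean_i |A_i - mean(A_{i-..i+})| / mean(A), K in 3,5,11
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import (
    InsufficientCyclesError,
    MetadataParseError,
    NoVoicedFramesError,
    VDT2Error,
)
from .features import FEATURE_NAMES, GROUP_CONTROL, GROUP_T2DM

__all__ = [
    "Waveform",
    "PeriodSequence",
    "PitchConfig",
    "RecordingMeta",
    "f0_contour",
    "mark_periods",
    "jitter_metrics",
    "shimmer_metrics",
    "hnr_metric",
    "intensity_metrics",
    "extract_features",
    "parse_filename",
    "extract_directory",
]

#: dB SPL reference pressure convention: full-scale amplitude 1.0 maps to
#: 1 Pa against the 20 micropascal reference, i.e. ~94 dB.
_DB_REF = 2e-5


@dataclass
class Waveform:
    """Mono audio in [-1, 1] at a fixed sampling rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise VDT2Error("sampling rate must be positive")
        if self.samples.ndim == 2:  # dual-channel input: average to mono
            self.samples = self.samples.mean(axis=1)
        if self.samples.ndim != 1:
            raise VDT2Error("samples must be a 1-D or 2-D (stereo) array")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @classmethod
    def from_wav(cls, path) -> "Waveform":
        """Read PCM WAV (8/16/24/32-bit int or float), scaled to [-1, 1]."""
        rate, data = wavfile.read(str(path))
        data = np.asarray(data)
        if np.issubdtype(data.dtype, np.integer):
            info = np.iinfo(data.dtype)
            if info.min < 0:
                data = data.astype(float) / max(abs(info.min), info.max)
            else:  # unsigned 8-bit
                data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
        else:
            data = data.astype(float)
        return cls(samples=data, rate=rate)


@dataclass
class PeriodSequence:
    """Glottal cycle boundaries (s), periods (s) and peak amplitudes."""

    boundaries: np.ndarray
    periods: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.periods) != len(self.amplitudes):
            raise VDT2Error("periods and amplitudes must have equal length")


@dataclass
class PitchConfig:
    """Pitch-analysis settings.

    The default search band (75-500 Hz) covers adult sustained-vowel F0
    with margin; the 40 ms window holds at least three periods at 75 Hz.
    """

    fmin_hz: float = 75.0
    fmax_hz: float = 500.0
    window_s: float = 0.04
    hop_s: float = 0.01
    voicing_threshold: float = 0.45
    octave_cost: float = 0.05  # per-octave penalty favouring shorter lags

    def __post_init__(self) -> None:
        if not 0 < self.fmin_hz < self.fmax_hz:
            raise VDT2Error("need 0 < fmin < fmax")
        if self.window_s < 2.0 / self.fmin_hz:
            raise VDT2Error("analysis window must cover >= 2 periods at fmin")


@dataclass
class RecordingMeta:
    subject: str
    sex: str
    group: str  # "T2DM" | "ND" | "sentence"
    vowel: str
    repetition: int


def _frames(x: np.ndarray, rate: int, window_s: float, hop_s: float):
    win = int(round(window_s * rate))
    hop = int(round(hop_s * rate))
    starts = np.arange(0, len(x) - win + 1, hop)
    times = (starts + win / 2) / rate
    return starts, win, times


def _autocorr(frame: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation via FFT with the unbiased lag correction.

    The raw FFT estimate at lag k sums only n-k products; without the
    n/(n-k) correction a perfectly periodic frame peaks well below 1 and
    the harmonic-to-noise ratio saturates far below its true value.
    """
    frame = frame - frame.mean()
    n = len(frame)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frame, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return np.zeros(n)
    lags = np.arange(n)
    return (ac / ac[0]) * (n / np.maximum(n - lags, 1))


def f0_contour(w: Waveform, config: PitchConfig | None = None) -> pd.DataFrame:
    """Frame-wise pitch track.

    Returns a DataFrame with ``time`` (s), ``f0`` (Hz, NaN when unvoiced)
    and ``strength`` (normalized autocorrelation peak).  A frame is voiced
    when its peak autocorrelation in the lag band exceeds the voicing
    threshold.  Raises :class:`NoVoicedFramesError` if nothing is voiced.
    """
    config = config or PitchConfig()
    x = w.samples
    starts, win, times = _frames(x, w.rate, config.window_s, config.hop_s)
    if len(starts) == 0:
        raise NoVoicedFramesError("signal shorter than one analysis window")

    lag_min = max(2, int(np.floor(w.rate / config.fmax_hz)))
    lag_max = int(np.ceil(w.rate / config.fmin_hz))
    if lag_max >= win:
        raise VDT2Error("window too short for fmin lag search")

    f0 = np.full(len(starts), np.nan)
    strength = np.zeros(len(starts))
    for i, s in enumerate(starts):
        ac = _autocorr(x[s : s + win])
        band = ac[lag_min : lag_max + 1]
        # candidate lags: local maxima of the autocorrelation in the band
        interior = (band[1:-1] >= band[:-2]) & (band[1:-1] >= band[2:])
        cand = np.flatnonzero(interior) + 1 + lag_min
        if cand.size == 0:
            cand = np.array([int(np.argmax(band)) + lag_min])
        # penalize longer lags (sub-octave candidates of a periodic signal
        # score as high as the true period without this cost)
        scores = ac[cand] - config.octave_cost * np.log2(cand / lag_min)
        k = int(cand[np.argmax(scores)])
        r = ac[k]
        # parabolic interpolation around the peak lag
        if lag_min < k < min(lag_max, win - 2):
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            k_interp = k + delta
            r = y1 - 0.25 * (y0 - y2) * delta
        else:
            k_interp = float(k)
        strength[i] = r
        if r >= config.voicing_threshold:
            f0[i] = w.rate / k_interp

    contour = pd.DataFrame({"time": times, "f0": f0, "strength": strength})
    if not np.isfinite(contour["f0"]).any():
        raise NoVoicedFramesError("no voiced frames found")
    return contour


def _local_period(contour: pd.DataFrame, t: float) -> float:
    """Pitch period near time t, interpolated over voiced frames."""
    voiced = contour.dropna(subset=["f0"])
    f0 = float(np.interp(t, voiced["time"], voiced["f0"]))
    return 1.0 / f0


def mark_periods(
    w: Waveform,
    contour: pd.DataFrame,
    max_period_dev: float = 0.25,
    min_cycles: int = 12,
) -> PeriodSequence:
    """Locate glottal cycle boundaries by contour-guided peak picking.

    Starting from the strongest peak in the voiced region, successive cycle
    marks are placed at the signal maximum inside a +/-25% window around one
    local pitch period ahead (and, walking backwards, behind).  Cycles whose
    period deviates more than ``max_period_dev`` from the local contour
    period are discarded.  Raises :class:`InsufficientCyclesError` when
    fewer than ``min_cycles`` cycles survive.
    """
    from scipy.ndimage import uniform_filter1d

    x = w.samples
    voiced = contour.dropna(subset=["f0"])
    if voiced.empty:
        raise NoVoicedFramesError("contour has no voiced frames")
    t_lo, t_hi = float(voiced["time"].iloc[0]), float(voiced["time"].iloc[-1])
    s_lo, s_hi = int(t_lo * w.rate), min(int(t_hi * w.rate) + 1, len(x))
    if s_hi <= s_lo:
        raise InsufficientCyclesError("voiced region is empty")

    # polarity: pick peaks on the dominant-sign side; peak-pick on a
    # lightly smoothed signal (~0.3 ms) so broadband noise cannot drag the
    # argmax off the pulse peak
    seg = x[s_lo:s_hi]
    sign = 1.0 if abs(seg.max()) >= abs(seg.min()) else -1.0
    smooth = max(3, int(round(0.0003 * w.rate)) | 1)
    ys = uniform_filter1d(sign * x, smooth)

    def refine(k: int) -> float:
        """Parabolic sub-sample refinement of a peak position."""
        if 1 <= k < len(ys) - 1:
            y0, y1, y2 = ys[k - 1], ys[k], ys[k + 1]
            den = y0 - 2 * y1 + y2
            if abs(den) > 1e-15:
                d = 0.5 * (y0 - y2) / den
                if -0.5 <= d <= 0.5:
                    return k + float(d)
        return float(k)

    anchor = refine(s_lo + int(np.argmax(ys[s_lo:s_hi])))

    def walk(start: float, direction: int) -> list[float]:
        marks = []
        pos = start
        while True:
            t = _local_period(contour, pos / w.rate) * w.rate
            centre = pos + direction * t
            lo = max(int(round(centre - max_period_dev * t)), s_lo)
            hi = min(int(round(centre + max_period_dev * t)), s_hi)
            if hi - lo < 2:
                break
            nxt = refine(lo + int(np.argmax(ys[lo:hi])))
            marks.append(nxt)
            pos = nxt
        return marks

    fwd = walk(anchor, +1)
    bwd = walk(anchor, -1)
    marks = np.array(sorted(bwd[::-1] + [anchor] + fwd))
    if len(marks) < 2:
        raise InsufficientCyclesError("could not place cycle marks")

    periods = np.diff(marks) / w.rate
    boundaries = marks[:-1] / w.rate
    # cycle amplitude: raw-signal peak in a window centred on each mark
    # (extending to the next mark would pick up the neighbouring pulse's
    # rising edge and flatten genuine shimmer)
    amplitudes = np.empty(len(periods))
    for i in range(len(periods)):
        left = 0.4 * (marks[i] - marks[i - 1]) if i > 0 else 0.4 * (marks[1] - marks[0])
        right = 0.4 * (marks[i + 1] - marks[i])
        a = max(int(round(marks[i] - left)), 0)
        b = min(int(round(marks[i] + right)) + 1, len(x))
        amplitudes[i] = np.max(np.abs(x[a:b]))

    # discard cycles deviating from the local contour period (octave guard)
    expected = np.array([_local_period(contour, t) for t in boundaries])
    ok = np.abs(periods - expected) <= max_period_dev * expected
    boundaries, periods, amplitudes = boundaries[ok], periods[ok], amplitudes[ok]

    if len(periods) < min_cycles:
        raise InsufficientCyclesError(
            f"only {len(periods)} usable cycles (need >= {min_cycles})"
        )
    return PeriodSequence(boundaries=boundaries, periods=periods, amplitudes=amplitudes)


def _window_quotient(v: np.ndarray, k: int) -> float:
    """mean_i |v_i - mean(v in k-point window centred at i)| over valid i."""
    half = k // 2
    n = len(v)
    devs = [
        abs(v[i] - v[i - half : i + half + 1].mean()) for i in range(half, n - half)
    ]
    return float(np.mean(devs))


def jitter_metrics(p: PeriodSequence) -> dict[str, float]:
    """The four period-perturbation measures."""
    t = p.periods
    if len(t) < 6:
        raise InsufficientCyclesError("jitter needs >= 6 periods")
    if (t <= 0).any():
        raise VDT2Error("periods must be positive")
    mean_t = t.mean()
    local_abs = float(np.mean(np.abs(np.diff(t))))
    return {
        "localJitter": local_abs / mean_t,
        "localabsJitter": local_abs,
        "rapJitter": _window_quotient(t, 3) / mean_t,
        "ppq5Jitter": _window_quotient(t, 5) / mean_t,
    }


def shimmer_metrics(p: PeriodSequence) -> dict[str, float]:
    """The five amplitude-perturbation measures."""
    a = p.amplitudes
    if len(a) < 12:
        raise InsufficientCyclesError("shimmer needs >= 12 amplitudes (apq11)")
    if (a <= 0).any():
        raise VDT2Error("amplitudes must be positive")
    mean_a = a.mean()
    return {
        "localShimmer": float(np.mean(np.abs(np.diff(a)))) / mean_a,
        "localdbShimmer": float(np.mean(np.abs(20.0 * np.log10(a[1:] / a[:-1])))),
        "apq3Shimmer": _window_quotient(a, 3) / mean_a,
        "apq5Shimmer": _window_quotient(a, 5) / mean_a,
        "apq11Shimmer": _window_quotient(a, 11) / mean_a,
    }


def frame_hnr_db(r: float) -> float:
    """Harmonicity of one frame from its normalized autocorrelation peak:
    ``10 log10(r / (1 - r))`` (r = 0.5 gives 0 dB)."""
    r = float(np.clip(r, 1e-6, 0.9999))
    return 10.0 * np.log10(r / (1.0 - r))


def hnr_metric(
    w: Waveform,
    contour: pd.DataFrame,
    window_s: float = 0.08,
    hop_s: float = 0.01,
    cap_db: tuple[float, float] = (0.0, 40.0),
) -> float:
    """Autocorrelation harmonic-to-noise ratio in dB.

    Per frame, the normalized autocorrelation peak ``r`` near the pitch
    lag estimates harmonic/(harmonic+noise) and the frame harmonicity is
    ``10 log10(r / (1 - r))``.  Frames use a longer window (default 80 ms)
    than pitch tracking: more periods per frame keep the edge bias of the
    autocorrelation estimate well below the noise term.  The mean over
    voiced frames is clipped to [0, 40] dB; a noiseless periodic signal
    hits the 40 dB cap.
    """
    voiced = contour.dropna(subset=["f0"])
    if voiced.empty:
        raise NoVoicedFramesError("no voiced frames for HNR")
    x = w.samples
    window_s = min(window_s, len(x) / w.rate)
    starts, win, times = _frames(x, w.rate, window_s, hop_s)
    t_lo, t_hi = float(voiced["time"].iloc[0]), float(voiced["time"].iloc[-1])
    vals = []
    for s, t in zip(starts, times):
        if not t_lo <= t <= t_hi:
            continue
        lag = _local_period(contour, t) * w.rate
        lo = max(2, int(np.floor(0.9 * lag)))
        hi = min(int(np.ceil(1.1 * lag)), win - 2)
        if hi <= lo:
            continue
        ac = _autocorr(x[s : s + win])
        k = lo + int(np.argmax(ac[lo : hi + 1]))
        r = ac[k]
        if lo < k < hi:  # parabolic refinement of the peak value
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            den = y0 - 2 * y1 + y2
            if abs(den) > 1e-15:
                d = float(np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5))
                r = y1 - 0.25 * (y0 - y2) * d
        vals.append(frame_hnr_db(r))
    if not vals:
        r_mean = float(np.clip(voiced["strength"].mean(), 1e-6, 0.9999))
        return float(np.clip(frame_hnr_db(r_mean), *cap_db))
    return float(np.clip(np.mean(vals), *cap_db))


def intensity_metrics(
    w: Waveform,
    window_s: float = 0.04,
    hop_s: float = 0.01,
    silence_range_db: float = 60.0,
) -> tuple[float, float]:
    """Frame-RMS intensity mean and SD in dB.

    Uses the convention that full-scale amplitude 1.0 corresponds to 1 Pa
    re 20 micropascal, so a full-scale sine reads ~90.97 dB.  Frames more
    than ``silence_range_db`` below the loudest frame are treated as
    silence and excluded.
    """
    x = w.samples
    if not np.any(x != 0):
        raise VDT2Error("all-zero signal has no intensity")
    starts, win, _ = _frames(x, w.rate, window_s, hop_s)
    if len(starts) == 0:
        raise VDT2Error("signal shorter than one intensity window")
    rms = np.sqrt(
        np.array([np.mean(x[s : s + win] ** 2) for s in starts])
    )
    rms = np.maximum(rms, 1e-12)
    db = 20.0 * np.log10(rms / _DB_REF)
    keep = db >= db.max() - silence_range_db
    db = db[keep]
    return float(db.mean()), float(db.std())


def extract_features(
    w: Waveform,
    pitch: PitchConfig | None = None,
    recording_id: str | None = None,
) -> dict[str, float]:
    """The full 14-measure feature vector for one recording.

    Composes pitch tracking, period marking, jitter/shimmer, HNR and
    intensity analysis; errors from sub-operations are re-raised tagged
    with ``recording_id``.
    """
    if w.duration_s < 0.5:
        raise VDT2Error(
            f"{recording_id or 'recording'}: need >= 0.5 s of audio, "
            f"got {w.duration_s:.3f} s"
        )
    try:
        contour = f0_contour(w, pitch)
        f0 = contour["f0"].dropna()
        periods = mark_periods(w, contour)
        jit = jitter_metrics(periods)
        shim = shimmer_metrics(periods)
        hnr = hnr_metric(w, contour)
        mean_int, sd_int = intensity_metrics(w)
    except VDT2Error as exc:
        if recording_id:
            raise type(exc)(f"{recording_id}: {exc}") from exc
        raise
    vec = {
        "meanF0": float(f0.mean()),
        "stdevF0": float(f0.std(ddof=0)),
        "meanInten": mean_int,
        "stdevInten": sd_int,
        "HNR": hnr,
        **shim,
        **jit,
    }
    return {name: vec[name] for name in FEATURE_NAMES}


_SEX_CODES = {"M", "F"}
_GROUP_CODES = {"T": GROUP_T2DM, "N": GROUP_CONTROL, "sen": "sentence"}
_VOWEL_CODES = {"a", "o", "e", "i", "u", "ü", "v"}  # "v" aliases /ü/


def parse_filename(name: str) -> RecordingMeta:
    """Parse the ``name_M_T/N/sen_a_1.wav`` naming convention.

    The subject name may itself contain underscores; the trailing four
    fields are sex, group code, vowel (or sentence marker) and repetition.
    """
    stem = name.rsplit("/", 1)[-1]
    if stem.lower().endswith(".wav"):
        stem = stem[:-4]
    parts = stem.split("_")
    if len(parts) < 5:
        raise MetadataParseError(f"{name!r}: expected 5 underscore-separated fields")
    subject = "_".join(parts[:-4])
    sex, group_code, vowel, rep = parts[-4:]
    if sex not in _SEX_CODES:
        raise MetadataParseError(f"{name!r}: bad sex field {sex!r} (expected M or F)")
    if group_code not in _GROUP_CODES:
        raise MetadataParseError(
            f"{name!r}: bad group field {group_code!r} (expected T, N or sen)"
        )
    group = _GROUP_CODES[group_code]
    if group == "sentence":
        vowel_out = vowel  # sentence marker, not constrained to vowel vocab
    elif vowel in _VOWEL_CODES:
        vowel_out = "ü" if vowel == "v" else vowel
    else:
        raise MetadataParseError(f"{name!r}: bad vowel field {vowel!r}")
    try:
        repetition = int(rep)
    except ValueError:
        raise MetadataParseError(f"{name!r}: bad repetition field {rep!r}") from None
    return RecordingMeta(
        subject=subject, sex=sex, group=group, vowel=vowel_out, repetition=repetition
    )


def extract_directory(
    wav_dir, pitch: PitchConfig | None = None, pattern: str = "*.wav"
) -> pd.DataFrame:
    """Extract features for every parseable WAV in a directory into a
    cohort table (metadata columns + 14 features)."""
    from pathlib import Path

    rows = []
    for path in sorted(Path(wav_dir).glob(pattern)):
        meta = parse_filename(path.name)
        w = Waveform.from_wav(path)
        vec = extract_features(w, pitch, recording_id=path.name)
        rows.append(
            {
                "subject": meta.subject,
                "sex": meta.sex,
                "group": meta.group,
                "vowel": meta.vowel,
                "repetition": meta.repetition,
                **vec,
            }
        )
    return pd.DataFrame(rows)
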