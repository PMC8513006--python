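"""Non-overlapping windowing and the 49 time/frequency-domain features.

For each window, eleven summary statistics are computed on four signals —
the vector magnitude (vm) and the three axes — giving 44 features; two
gravity-angle statistics (``mangle``, ``sdangle``) describe the orientation
of the device x-axis relative to the acceleration vector; and three spectral
features of the vm series (``p625``, ``df``, ``fpdf``) summarise periodicity
in the human-movement band.

Conventions (documented because the feature set's provenance leaves them
open): standard deviations use the sample (n−1) denominator; third/fourth
moments, skewness and kurtosis use population (n) central moments; kurtosis
is plain m4/m2² (not excess); quantiles use linear interpolation between
order statistics; the coefficient of variation divides by |mean| and is
zeroed when |mean| < 1e-6 g; the spectral features exclude the DC term and
break dominant-frequency ties toward the lowest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, WindowTooShortError
from .ingest import LabeledSegment
from .labels import ActivityLabel

SIGNALS = ("vm", "x", "y", "z")

#: the 49 feature column names, in canonical order
FEATURE_NAMES: tuple[str, ...] = (
    "mvm", "mean_x", "mean_y", "mean_z",
    "sdvm", "sd_x", "sd_y", "sd_z",
    "cv_vm", "cv_x", "cv_y", "cv_z",
    "min_vm", "min_x", "min_y", "min_z",
    "max_vm", "max_x", "max_y", "max_z",
    "lower_vm_25", "lower_x_25", "lower_y_25", "lower_z_25",
    "upper_vm_75", "upper_x_75", "upper_y_75", "upper_z_75",
    "third_vm", "third_x", "third_y", "third_z",
    "fourth_vm", "fourth_x", "fourth_y", "fourth_z",
    "skewness_vm", "skewness_x", "skewness_y", "skewness_z",
    "kurtosis_vm", "kurtosis_x", "kurtosis_y", "kurtosis_z",
    "mangle", "sdangle",
    "p625", "df", "fpdf",
)

METADATA_COLUMNS = ("participant_id", "activity", "category", "window_start_s")

CV_MEAN_GUARD = 1e-6     # |mean| below this → cv := 0
MOMENT_GUARD = 1e-12     # m2 below this → skewness = kurtosis := 0
SPECTRUM_GUARD = 1e-12   # all positive-frequency moduli below this → (0,0,0)
BAND = (0.6, 2.5)        # Hz, human-movement band for p625


@dataclass
class LabeledWindow:
    """A fixed-length block of consecutive samples from one activity."""

    participant_id: str
    activity: ActivityLabel
    window_start_s: float
    xyz: np.ndarray          # shape (window_length × rate, 3)
    sampling_rate: float


def segment_windows(segment: LabeledSegment, window_length: float,
                    sampling_rate: float) -> list[LabeledWindow]:
    """Split a segment into consecutive non-overlapping windows.

    The trailing partial window is discarded; a window longer than the
    segment yields zero windows (not an error).
    """
    w = round(window_length * sampling_rate)
    if w != window_length * sampling_rate or w <= 0:
        raise ValueError("window_length × sampling_rate must be a positive "
                         "integer sample count")
    n_win = len(segment) // w
    return [
        LabeledWindow(segment.participant_id, segment.activity,
                      float(segment.t[i * w]),
                      segment.xyz[i * w:(i + 1) * w], sampling_rate)
        for i in range(n_win)
    ]


def vector_magnitude(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, in g."""
    return np.sqrt(np.sum(np.asarray(xyz, dtype=float) ** 2, axis=-1))


def _signal_stats(v: np.ndarray) -> list[float]:
    n = len(v)
    mean = v.mean()
    sd = v.std(ddof=1)
    cv = 0.0 if abs(mean) < CV_MEAN_GUARD else 100.0 * sd / abs(mean)
    d = v - mean
    m2 = np.mean(d ** 2)
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    if m2 < MOMENT_GUARD:
        skew = kurt = 0.0
    else:
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    q25, q75 = np.quantile(v, [0.25, 0.75])
    return [float(mean), float(sd), float(cv), float(v.min()), float(v.max()),
            float(q25), float(q75), float(m3), float(m4),
            float(skew), float(kurt)]


def time_features(xyz: np.ndarray) -> dict[str, float]:
    """The 44 per-signal statistics plus mangle/sdangle for one window."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 2:
        raise WindowTooShortError("window must contain at least 2 samples")
    vm = vector_magnitude(xyz)
    stats = {s: _signal_stats(v) for s, v in
             zip(SIGNALS, (vm, xyz[:, 0], xyz[:, 1], xyz[:, 2]))}
    out: dict[str, float] = {}
    for i, stat in enumerate(("mean", "sd", "cv", "min", "max",
                              "q25", "q75", "third", "fourth",
                              "skewness", "kurtosis")):
        for j, s in enumerate(SIGNALS):
            out[FEATURE_NAMES[i * 4 + j]] = stats[s][i]
    # angle of the x-axis relative to the acceleration vector, degrees
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(vm > 0, xyz[:, 0] / np.where(vm > 0, vm, 1.0), 0.0)
    theta = np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))
    out["mangle"] = float(theta.mean())
    out["sdangle"] = float(theta.std(ddof=1))
    return out


def freq_features(vm: np.ndarray, sampling_rate: float
                  ) -> tuple[float, float, float]:
    """Spectral features (p625, df, fpdf) of the vm series.

    Moduli of the discrete Fourier transform at positive frequencies only;
    the DC term is excluded.  A constant signal returns (0, 0, 0).
    """
    vm = np.asarray(vm, dtype=float)
    if len(vm) < 2:
        raise WindowTooShortError("need at least 2 samples")
    moduli = np.abs(np.fft.rfft(vm))[1:]
    # bin k sits at k·rate/n; computed directly so band-edge bins (0.6 and
    # 2.5 Hz land exactly on a bin for many window lengths) classify exactly
    freqs = np.arange(1, len(moduli) + 1) * sampling_rate / len(vm)
    total = moduli.sum()
    if np.all(moduli < SPECTRUM_GUARD):
        return 0.0, 0.0, 0.0
    in_band = (freqs >= BAND[0]) & (freqs <= BAND[1])
    p625 = float(moduli[in_band].sum() / total)
    k = int(np.argmax(moduli))          # first max → lowest frequency on ties
    return p625, float(freqs[k]), float(moduli[k] / total)


def window_features(window: LabeledWindow) -> dict[str, float]:
    """All 49 features of one labeled window, in canonical order."""
    out = time_features(window.xyz)
    vm = vector_magnitude(window.xyz)
    out["p625"], out["df"], out["fpdf"] = freq_features(
        vm, window.sampling_rate)
    return {name: out[name] for name in FEATURE_NAMES}


def extract_features(segments: list[LabeledSegment], window_length: float,
                     sampling_rate: float) -> pd.DataFrame:
    """Window every segment and compute one 49-feature row per window.

    Returns a DataFrame with metadata columns (participant, activity,
    FT/NFT category, window start time) followed by the 49 features.
    """
    rows = []
    for seg in segments:
        for win in segment_windows(seg, window_length, sampling_rate):
            row = {
                "participant_id": win.participant_id,
                "activity": win.activity.name,
                "category": win.activity.category,
                "window_start_s": win.window_start_s,
            }
            row.update(window_features(win))
            rows.append(row)
    if not rows:
        raise EmptyMatrixError("no windows produced from the given segments")
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
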