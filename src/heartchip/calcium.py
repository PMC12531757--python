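"""Calcium-transient analysis for GCaMP recordings of beating cardiomyocytes.

The analysis chain mirrors the standard contractility workflow for
engineered myocardial tissue: extract a mean-intensity trace per region of
interest from a time-lapse movie, normalize it to ΔF/F0, detect individual
beats, and summarize each recording by beat frequency, transient amplitude,
time to peak, time to 80% decay, and the coefficients of variation (CV,
sd/mean) of frequency and amplitude.  The CVs serve as arrhythmia indices:
a healthy, regularly beating tissue has near-zero CV of its inter-beat
intervals, while calcium mishandling raises both CVs.

Longitudinal experiments (drug treatment over days) are expressed as fold
changes against each chip's own day-0 baseline via
:func:`normalize_to_day0`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FluorescenceTrace",
    "Beat",
    "TransientSummary",
    "ROISet",
    "extract_roi_traces",
    "compute_dff",
    "detect_beats",
    "summarize_transients",
    "analyze_trace",
    "normalize_to_day0",
]


class InvalidParameterError(ValueError):
    """Raised when a physically meaningless parameter combination is given."""


@dataclass
class FluorescenceTrace:
    """A uniformly sampled fluorescence intensity time series.

    Parameters
    ----------
    time : array of float
        Sample times in seconds; strictly increasing and uniform.
    intensity : array of float
        Fluorescence intensity (arbitrary units, or ΔF/F0 after
        :func:`compute_dff`).
    roi_id, chip_id, tissue_id : str
        Provenance labels.
    units : str
        Either ``"au"`` (raw intensity) or ``"dff"``.
    f0 : float, optional
        Baseline used for ΔF/F0 conversion, recorded by :func:`compute_dff`.
    """

    time: np.ndarray
    intensity: np.ndarray
    roi_id: str = ""
    chip_id: str = ""
    tissue_id: str = ""
    units: str = "au"
    f0: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise InvalidParameterError("trace needs >= 2 samples")
        if self.time.shape != self.intensity.shape:
            raise InvalidParameterError("time and intensity shapes differ")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise InvalidParameterError("timestamps must be uniform")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidParameterError("intensity contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class Beat:
    """Kinetic parameters of a single calcium transient.

    ``decay80_time`` is the time from the peak until the signal has lost
    80 % of this beat's amplitude; it is ``None`` when the trace ends (or
    the next beat starts) before the 80 % level is reached.
    """

    onset_time: float
    peak_time: float
    peak_dff: float
    amplitude: float
    time_to_peak: float
    decay80_time: float | None

    def __post_init__(self) -> None:
        if not self.onset_time < self.peak_time:
            raise InvalidParameterError("onset must precede peak")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive")
        if self.decay80_time is not None and self.decay80_time <= 0:
            raise InvalidParameterError("decay80_time must be positive")


@dataclass
class TransientSummary:
    """Per-recording aggregate of beat parameters.

    ``frequency`` is 1/mean(inter-beat interval); CVs use the sample
    (n−1) standard deviation over per-beat values and are ``None`` when
    fewer than three beats were detected.
    """

    frequency: float | None
    cv_frequency: float | None
    mean_amplitude: float | None
    cv_amplitude: float | None
    mean_time_to_peak: float | None
    mean_decay80: float | None
    n_beats: int
    duration: float

    def as_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "cv_frequency": self.cv_frequency,
            "mean_amplitude": self.mean_amplitude,
            "cv_amplitude": self.cv_amplitude,
            "mean_time_to_peak": self.mean_time_to_peak,
            "mean_decay80": self.mean_decay80,
            "n_beats": self.n_beats,
            "duration": self.duration,
        }


@dataclass
class ROISet:
    """Named rectangular regions of interest, ``(row0, col0, row1, col1)``.

    Covers both layouts used on-chip: 3 ROIs per off-chip tissue and
    2 regions × 5 ROIs = 10 ROIs per chip (see :meth:`grid`).
    """

    rois: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def add(self, name: str, row0: int, col0: int, row1: int, col1: int) -> None:
        if row1 <= row0 or col1 <= col0:
            raise InvalidParameterError(f"ROI {name!r} is empty")
        self.rois[name] = (row0, col0, row1, col1)

    @classmethod
    def grid(
        cls,
        image_shape: tuple[int, int],
        n_regions: int = 2,
        rois_per_region: int = 5,
    ) -> "ROISet":
        """Tile ``n_regions`` horizontal bands, each split into equal ROIs."""
        h, w = image_shape
        out = cls()
        band = h // n_regions
        step = w // rois_per_region
        for r in range(n_regions):
            for i in range(rois_per_region):
                out.add(
                    f"region{r + 1}_roi{i + 1}",
                    r * band,
                    i * step,
                    (r + 1) * band,
                    (i + 1) * step,
                )
        return out

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        for name, (r0, c0, r1, c1) in self.rois.items():
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise InvalidParameterError(f"ROI {name!r} outside image bounds")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_roi_traces(
    movie: np.ndarray,
    rois: ROISet,
    frame_interval: float,
    chip_id: str = "",
) -> list[FluorescenceTrace]:
    """Mean intensity per ROI per frame of a ``(T, H, W)`` movie."""
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise InvalidParameterError("movie must be (T, H, W) with >= 2 frames")
    if frame_interval is None or frame_interval <= 0:
        raise InvalidParameterError("frame_interval must be a positive number of seconds")
    rois.validate(movie.shape[1:])
    t = np.arange(movie.shape[0]) * float(frame_interval)
    traces = []
    for name, (r0, c0, r1, c1) in rois.rois.items():
        vals = movie[:, r0:r1, c0:c1].mean(axis=(1, 2))
        traces.append(
            FluorescenceTrace(time=t, intensity=vals, roi_id=name, chip_id=chip_id)
        )
    return traces


def compute_dff(
    trace: FluorescenceTrace,
    f0_method: str = "percentile",
    f0_param: float = 10.0,
) -> FluorescenceTrace:
    """Convert a raw trace to ΔF/F0 = (F − F0)/F0.

    ``f0_method`` is one of ``"percentile"`` (F0 = the ``f0_param``-th
    percentile of the whole trace, default 10th), ``"min"``, or
    ``"pre-window"`` (mean of the first ``f0_param`` seconds).
    """
    f = trace.intensity
    if f0_method == "percentile":
        f0 = float(np.percentile(f, f0_param))
    elif f0_method == "min":
        f0 = float(f.min())
    elif f0_method == "pre-window":
        n = max(1, int(round(f0_param / trace.dt)))
        f0 = float(f[:n].mean())
    else:
        raise InvalidParameterError(f"unknown f0_method {f0_method!r}")
    if f0 <= 0:
        raise InvalidParameterError(f"estimated F0 = {f0} is not positive; corrupted baseline")
    return FluorescenceTrace(
        time=trace.time,
        intensity=(f - f0) / f0,
        roi_id=trace.roi_id,
        chip_id=trace.chip_id,
        tissue_id=trace.tissue_id,
        units="dff",
        f0=f0,
    )


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    """Time at which the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t1
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_beats(
    dff: FluorescenceTrace,
    min_prominence: float | None = None,
    min_ibi: float = 0.2,
    onset_fraction: float = 0.1,
) -> list[Beat]:
    """Detect individual calcium transients in a ΔF/F0 trace.

    Peaks are local maxima with prominence >= ``min_prominence`` (default:
    0.2 × the 5th–95th percentile range of the trace) separated by at least
    ``min_ibi`` seconds.  For each peak, the local baseline is the minimum
    between the previous peak (or the trace start) and this peak; the onset
    is the last upward crossing of baseline + ``onset_fraction`` × amplitude
    before the peak (linearly interpolated), and the 80 %-decay time is the
    first post-peak time at which the signal falls to
    peak − 0.8 × amplitude (linearly interpolated).

    An empty list (no beats) is a valid result.
    """
    y = np.asarray(dff.intensity, dtype=float)
    t = np.asarray(dff.time, dtype=float)
    lo, hi = np.percentile(y, [5.0, 95.0])
    if min_prominence is None:
        min_prominence = 0.2 * (hi - lo)
    if min_prominence <= 0:
        return []
    distance = max(1, int(round(min_ibi / dff.dt)))
    peaks, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    beats: list[Beat] = []
    prev_peak = 0
    for k, p in enumerate(peaks):
        seg = y[prev_peak : p + 1]
        base = float(seg.min())
        amplitude = float(y[p] - base)
        if amplitude <= 0:
            prev_peak = p
            continue
        level = base + onset_fraction * amplitude
        # last upward crossing of `level` before the peak
        onset_time = None
        for j in range(p - 1, prev_peak - 1, -1):
            if y[j] <= level < y[j + 1] or (y[j] <= level and y[j + 1] > level):
                onset_time = _interp_crossing(t[j], t[j + 1], y[j], y[j + 1], level)
                break
        if onset_time is None:
            # rising edge truncated by segment start
            onset_time = float(t[prev_peak])
        if onset_time >= t[p]:
            onset_time = float(t[p] - dff.dt)
        # 80% decay: first post-peak crossing of peak − 0.8*amplitude
        decay_level = y[p] - 0.8 * amplitude
        nxt = peaks[k + 1] if k + 1 < len(peaks) else len(y) - 1
        decay80: float | None = None
        for j in range(p, nxt):
            if y[j + 1] <= decay_level:
                ct = _interp_crossing(t[j], t[j + 1], y[j], y[j + 1], decay_level)
                decay80 = float(ct - t[p])
                break
        beats.append(
            Beat(
                onset_time=float(onset_time),
                peak_time=float(t[p]),
                peak_dff=float(y[p]),
                amplitude=amplitude,
                time_to_peak=float(t[p] - onset_time),
                decay80_time=decay80,
            )
        )
        prev_peak = p
    return beats


def _cv(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.mean(values))


def summarize_transients(beats: Sequence[Beat], duration: float) -> TransientSummary:
    """Aggregate per-beat parameters into one record per recording.

    Instantaneous frequencies are reciprocals of consecutive peak-to-peak
    intervals; the summary frequency is 1/mean(IBI).  Fewer than two beats
    give no frequency; fewer than three give no CVs.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    n = len(beats)
    freq = cv_f = mean_amp = cv_amp = mean_ttp = mean_d80 = None
    if n >= 1:
        amps = np.array([b.amplitude for b in beats])
        mean_amp = float(amps.mean())
        mean_ttp = float(np.mean([b.time_to_peak for b in beats]))
        d80 = [b.decay80_time for b in beats if b.decay80_time is not None]
        mean_d80 = float(np.mean(d80)) if d80 else None
    if n >= 2:
        ibis = np.diff([b.peak_time for b in beats])
        freq = float(1.0 / ibis.mean())
    if n >= 3:
        inst_f = 1.0 / ibis
        cv_f = _cv(inst_f)
        cv_amp = _cv(amps)
    return TransientSummary(
        frequency=freq,
        cv_frequency=cv_f,
        mean_amplitude=mean_amp,
        cv_amplitude=cv_amp,
        mean_time_to_peak=mean_ttp,
        mean_decay80=mean_d80,
        n_beats=n,
        duration=float(duration),
    )


def analyze_trace(
    trace: FluorescenceTrace,
    f0_method: str = "percentile",
    f0_param: float = 10.0,
    min_prominence: float | None = None,
    min_ibi: float = 0.2,
    onset_fraction: float = 0.1,
) -> TransientSummary:
    """ΔF/F0 conversion, beat detection, and summary in one call.

    If the trace is already in ΔF/F0 units the conversion is skipped.
    """
    dff = trace if trace.units == "dff" else compute_dff(trace, f0_method, f0_param)
    beats = detect_beats(dff, min_prominence, min_ibi, onset_fraction)
    return summarize_transients(beats, dff.duration)


def normalize_to_day0(
    table: pd.DataFrame,
    chip_col: str = "chip",
    day_col: str = "day",
    metrics: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fold change of each metric against the same chip's day-0 value.

    Day-0 rows become exactly 1.  A chip without a day-0 record, or with a
    zero day-0 value, raises an error naming the chip.
    """
    df = table.copy()
    if metrics is None:
        metrics = [
            c
            for c in df.columns
            if c not in (chip_col, day_col) and pd.api.types.is_numeric_dtype(df[c])
        ]
    metrics = list(metrics)
    out = df.copy()
    for chip, grp in df.groupby(chip_col):
        day0 = grp[grp[day_col] == 0]
        if day0.empty:
            raise InvalidParameterError(f"chip {chip!r} has no day-0 record")
        base = day0.iloc[0][metrics].astype(float)
        if (base == 0).any() or base.isna().any():
            raise InvalidParameterError(f"chip {chip!r} has zero/missing day-0 values")
        out.loc[grp.index, metrics] = grp[metrics].astype(float) / base.values
    return out
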