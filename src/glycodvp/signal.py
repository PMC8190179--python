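"""Preprocessing of raw three-channel DVP recordings.

Pipeline: zero-phase Butterworth low-pass -> trough-to-trough beat
segmentation on the red (615 nm) channel -> per-beat optical features
(``I_min``/``I_max``/``I_mean`` per channel) -> per-beat ratio pairs for each
finger model -> statistical cleaning of the ratio table.

Conventions
-----------
* ``I_min`` is the systolic transmitted intensity (blood inflow lengthens the
  optical path, so transmission is lowest) and ``I_max`` the diastolic one;
  every pulsatile absorbance ``log10(I_max/I_min)`` is therefore positive.
* Beat windows are 0-based, half-open sample ranges.
* The whole-finger model's AC/DC fraction uses the per-beat *mean* intensity
  as the DC operating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .fingermodel import RatioPair

__all__ = [
    "DVPRecording",
    "BeatSegment",
    "lowpass_filter",
    "segment_beats",
    "beat_ratios_blood_vessel",
    "beat_ratios_whole_finger",
    "beat_ratio_table",
    "clean_ratios",
    "read_device_csv",
    "write_device_csv",
]

log = logging.getLogger(__name__)

CHANNELS = (465, 525, 615)

#: Default low-pass cutoff [Hz] and filter order.
LOWPASS_CUTOFF_HZ = 8.0
LOWPASS_ORDER = 2

#: Minimum beat period [s] for trough detection (~180 bpm ceiling).
MIN_BEAT_PERIOD_S = 0.33
#: Trough prominence threshold as a fraction of the channel's AC range.
PROMINENCE_FRACTION = 0.25

#: Central-normal-interval half width for the 60 % confidence band used in
#: ratio cleaning: z such that P(|Z| < z) = 0.60.
CLEAN_Z = float(norm.ppf(0.8))


class EmptyAfterCleaningError(RuntimeError):
    """Statistical cleaning removed every beat."""


@dataclass
class DVPRecording:
    """A three-channel transmissive DVP intensity recording.

    ``channels`` maps wavelength [nm] -> intensity array; all arrays equal
    length.  Intensities must be strictly positive in the analysis window
    (log-ratios are taken).
    """

    sample_rate: float
    channels: dict[int, np.ndarray]
    subject_id: str = ""
    mode: str = "transmissive"

    def __post_init__(self) -> None:
        lengths = {len(np.asarray(v)) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        self.channels = {
            int(k): np.asarray(v, dtype=float) for k, v in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class BeatSegment:
    """Per-beat optical features over a half-open sample window."""

    start: int
    stop: int
    i_min: dict[int, float] = field(default_factory=dict)
    i_max: dict[int, float] = field(default_factory=dict)
    i_mean: dict[int, float] = field(default_factory=dict)


def lowpass_filter(
    rec: DVPRecording,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    order: int = LOWPASS_ORDER,
) -> DVPRecording:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase filtering preserves the timing of the systolic/diastolic
    landmarks that the ratio extraction depends on.  Note the effective
    magnitude response is the squared single-pass Butterworth response.
    """
    nyquist = rec.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate)
    filtered = {wl: sps.filtfilt(b, a, x) for wl, x in rec.channels.items()}
    return replace(rec, channels=filtered)


def segment_beats(
    rec: DVPRecording,
    reference_channel: int = 615,
    min_period_s: float = MIN_BEAT_PERIOD_S,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> list[BeatSegment]:
    """Trough-to-trough beat segmentation on the reference (red) channel.

    Systolic troughs of the transmitted intensity are found with a
    minimum-distance peak finder on the inverted signal; the prominence
    threshold adapts to the channel's AC range.  The same windows are applied
    to all channels.  Returns an empty list (with a warning) when no
    periodicity is detectable.

    Per-beat systolic (``i_min``) and diastolic (``i_max``) intensities are
    read on every channel at the two *instants* located on the channel with
    the strongest relative pulsation, rather than as per-channel sample
    extrema.  Sampling all channels at common instants keeps the
    inter-channel ratio identities exact (the pulse phase is shared), and it
    avoids the extreme-value selection bias that per-channel min/max over
    noisy samples would add to the weakly pulsatile red channel -- that bias
    varies with beat length and would masquerade as subject physiology.
    """
    if rec.duration_s < 2.0:
        raise ValueError("recording must be at least 2 s long")
    x = rec.channels[reference_channel]
    ac_range = float(np.ptp(x))
    if ac_range <= 0:
        warnings.warn("constant reference channel: no beats detected")
        return []
    distance = max(1, int(round(min_period_s * rec.sample_rate)))
    troughs, _ = sps.find_peaks(
        -x, distance=distance, prominence=prominence_fraction * ac_range
    )
    if len(troughs) < 2:
        warnings.warn("no detectable periodicity: no beats segmented")
        return []
    # landmark channel: largest relative AC range (best landmark SNR)
    landmark = max(
        rec.channels,
        key=lambda wl: np.ptp(rec.channels[wl]) / max(np.median(rec.channels[wl]), 1e-30),
    )
    lm = rec.channels[landmark]
    beats = []
    for start, stop in zip(troughs[:-1], troughs[1:]):
        start, stop = int(start), int(stop)
        idx_sys = start + int(np.argmin(lm[start:stop]))
        idx_dia = start + int(np.argmax(lm[start:stop]))
        seg = BeatSegment(
            start=start,
            stop=stop,
            i_min={wl: float(c[idx_sys]) for wl, c in rec.channels.items()},
            i_max={wl: float(c[idx_dia]) for wl, c in rec.channels.items()},
            i_mean={wl: float(np.mean(c[start:stop])) for wl, c in rec.channels.items()},
        )
        beats.append(seg)
    return beats


def _check_beat(beat: BeatSegment) -> None:
    for wl in beat.i_min:
        if not (beat.i_max[wl] > beat.i_min[wl] > 0):
            raise ValueError(
                f"beat [{beat.start}, {beat.stop}) has no positive pulsation at {wl} nm"
            )


def beat_ratios_blood_vessel(
    beat: BeatSegment, wavelengths: tuple[int, int, int] = (525, 465, 615)
) -> RatioPair:
    """Pulsatile-absorbance ratios: R = log(I_max/I_min) between channels.

    Exact under the blood-vessel hypothesis (path-length pulsation at fixed
    composition), at any pulsation amplitude.
    """
    _check_beat(beat)
    l1, l2, l3 = wavelengths
    da = {wl: np.log10(beat.i_max[wl] / beat.i_min[wl]) for wl in (l1, l2, l3)}
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = da[l1] / da[l3]
        r2 = da[l2] / da[l3]
    return RatioPair(r1=float(r1), r2=float(r2), provenance="signal")


def beat_ratios_whole_finger(
    beat: BeatSegment, wavelengths: tuple[int, int, int] = (525, 465, 615)
) -> RatioPair:
    """AC/DC fraction ratios: R = (dI/I)_num / (dI/I)_den.

    First-order accurate in the pulsatile absorbance (the whole-finger
    derivation linearises the Beer-Lambert exponential), so amplitudes should
    be a small fraction of DC.
    """
    _check_beat(beat)
    l1, l2, l3 = wavelengths

    def acdc(wl: int) -> float:
        return (beat.i_max[wl] - beat.i_min[wl]) / beat.i_mean[wl]

    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = acdc(l1) / acdc(l3)
        r2 = acdc(l2) / acdc(l3)
    return RatioPair(r1=float(r1), r2=float(r2), provenance="signal")


def beat_ratio_table(
    beats: list[BeatSegment],
    model: str,
    wavelengths: tuple[int, int, int] = (525, 465, 615),
) -> pd.DataFrame:
    """Per-beat ratio pairs for a model as a DataFrame (columns r1, r2).

    Beats with non-positive pulsation on any channel yield non-finite rows
    (flagged, removed later by :func:`clean_ratios`), mirroring how numeric
    error values arise in device data.
    """
    extract = (
        beat_ratios_blood_vessel if model == "blood_vessel" else beat_ratios_whole_finger
    )
    rows = []
    for beat in beats:
        try:
            rp = extract(beat, wavelengths)
            rows.append((beat.start, beat.stop, rp.r1, rp.r2))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            rows.append((beat.start, beat.stop, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["start", "stop", "r1", "r2"])


def clean_ratios(ratios: pd.DataFrame, z: float = CLEAN_Z) -> pd.DataFrame:
    """Drop non-finite rows, then keep rows inside the central 60 % band.

    The band is the normal central interval mean +/- z*SD (z = 0.8416 for
    60 %), evaluated per ratio column and intersected across columns.
    Zero-spread columns keep all rows.  Output rows are a subset of input
    rows, so the operation is shrinking (and idempotent at its fixed point).
    """
    if len(ratios) == 0:
        raise ValueError("empty ratio table")
    cols = [c for c in ("r1", "r2") if c in ratios.columns]
    finite = ratios[np.isfinite(ratios[cols]).all(axis=1)]
    if len(finite) == 0:
        raise EmptyAfterCleaningError("no finite ratio rows to clean")
    keep = pd.Series(True, index=finite.index)
    for c in cols:
        mu = finite[c].mean()
        sd = finite[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        keep &= (finite[c] - mu).abs() <= z * sd
    cleaned = finite[keep]
    if len(cleaned) == 0:
        raise EmptyAfterCleaningError("statistical cleaning removed every beat")
    return cleaned


# ---------------------------------------------------------------------------
# device CSV dialect
# ---------------------------------------------------------------------------

def read_device_csv(path, subject_id: str = "") -> DVPRecording:
    """Read a device-format CSV (``time_ms,ch465,ch525,ch615,mode``).

    Only transmissive rows (``mode == 'T'``) are used; the sample rate is
    inferred from the median transmissive time step.
    """
    df = pd.read_csv(path)
    expected = {"time_ms", "ch465", "ch525", "ch615", "mode"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"device CSV missing columns: {sorted(missing)}")
    df = df[df["mode"].astype(str).str.upper() == "T"]
    if len(df) < 2:
        raise ValueError("no transmissive samples in device CSV")
    dt_ms = float(np.median(np.diff(df["time_ms"].to_numpy())))
    return DVPRecording(
        sample_rate=1000.0 / dt_ms,
        channels={wl: df[f"ch{wl}"].to_numpy(dtype=float) for wl in CHANNELS},
        subject_id=subject_id or str(path),
        mode="transmissive",
    )


def write_device_csv(rec: DVPRecording, path) -> None:
    """Write a recording in the device CSV dialect."""
    t_ms = np.arange(rec.n_samples) / rec.sample_rate * 1000.0
    df = pd.DataFrame({"time_ms": np.round(t_ms, 3)})
    for wl in CHANNELS:
        df[f"ch{wl}"] = rec.channels[wl]
    df["mode"] = "T" if rec.mode == "transmissive" else "R"
    df.to_csv(path, index=False)
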