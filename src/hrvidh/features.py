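"""Phase-wise HRV features: time domain, Welch spectra and delta features.

Nine parameters are computed per 5-minute segment — mean heart rate (HR),
mean RR interval (RRI), SDNN, RMSSD, and the Welch-periodogram band powers
VLF, LF, HF, total power (TP) and the LF/HF ratio — then averaged over the
two segments of each analysis phase.  Delta features are middle-phase minus
early-phase values, the within-session autonomic response to ultrafiltration.

Spectral analysis follows the common short-term HRV recipe: the tachogram is
resampled at 4 Hz with linear interpolation and a Welch periodogram with
64-second Hann windows at 75% overlap is integrated over the standard bands
(VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz).  Total power is
defined as the integral over the union of the three bands, so
``vlf + lf + hf == tp`` holds exactly on the bin grid.  Note the 64-s window
limits spectral resolution to 1/64 Hz; VLF content below ~0.016 Hz is not
resolvable at this window length, which the band integral silently truncates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import SegmentGrid, select_phase_segments

#: Frequency bands (Hz), half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: Canonical order of the nine HRV parameters in all output tables.
FEATURE_NAMES = ["hr", "rri", "sdnn", "rmssd", "vlf", "lf", "hf", "tp", "lf_hf"]

RESAMPLE_HZ = 4.0
WELCH_WINDOW_S = 64.0
WELCH_OVERLAP = 0.75


@dataclasses.dataclass(frozen=True)
class TimeDomainFeatures:
    mean_hr: float   # beats/min, 60000 / mean_rri
    mean_rri: float  # ms
    sdnn: float      # ms, sample SD (n-1)
    rmssd: float     # ms


@dataclasses.dataclass(frozen=True)
class SpectralFeatures:
    vlf: float    # ms^2
    lf: float     # ms^2
    hf: float     # ms^2
    tp: float     # ms^2, = vlf + lf + hf by construction
    lf_hf: float  # dimensionless; NaN when hf == 0


@dataclasses.dataclass(frozen=True)
class PhaseFeatureSet:
    """The nine parameters of one phase (mean of its two segments)."""

    phase: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def time_domain_features(rr) -> TimeDomainFeatures:
    """Time-domain HRV statistics of one segment's RR intervals (ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("time-domain features need at least 3 beats")
    mean_rri = float(rr.mean())
    d = np.diff(rr)
    return TimeDomainFeatures(
        mean_hr=60000.0 / mean_rri,
        mean_rri=mean_rri,
        sdnn=float(rr.std(ddof=1)),
        rmssd=float(np.sqrt(np.mean(d * d))),
    )


def resample_tachogram(
    time, rr, start: float, stop: float, fs: float = RESAMPLE_HZ
) -> np.ndarray:
    """Evenly resample the tachogram over ``[start, stop)`` at ``fs`` Hz.

    RR is treated as a function of beat time and linearly interpolated;
    samples before the first or after the last beat hold the nearest beat's
    value.  A 300-s window at 4 Hz yields exactly 1200 samples.
    """
    time = np.asarray(time, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if time.size < 2:
        raise ValueError("resampling needs at least 2 beats")
    n = int(round((stop - start) * fs))
    grid = start + np.arange(n) / fs
    return np.interp(grid, time, rr)


def welch_psd(
    x,
    fs: float = RESAMPLE_HZ,
    window_seconds: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (ms^2/Hz) with Hann-tapered, mean-removed windows.

    Power normalisation is scipy's density convention: the PSD integrates to
    the variance of the (mean-removed) signal, with the taper's power loss
    corrected.  Defaults give 64-s windows (256 samples at 4 Hz) with 75%
    overlap, i.e. a 1/64 Hz frequency grid.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_seconds * fs))
    if x.size < nperseg:
        raise ValueError(
            f"series of {x.size} samples is shorter than one "
            f"{window_seconds:.0f}-s window ({nperseg} samples)"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def band_powers(freqs, psd) -> SpectralFeatures:
    """Integrate a PSD over the VLF/LF/HF bands.

    Bins are assigned to a band when their centre frequency lies in the
    half-open interval [low, high), so no bin is double-counted at the
    shared 0.04 and 0.15 Hz edges.  TP is the integral over the union of
    the three bands.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size < 2:
        raise ValueError("PSD grid too short")
    df = freqs[1] - freqs[0]
    powers = {}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        powers[name] = float(psd[mask].sum() * df)
    tp = powers["vlf"] + powers["lf"] + powers["hf"]
    if powers["hf"] == 0.0:
        warnings.warn("HF power is zero; LF/HF ratio reported as missing")
        lf_hf = float("nan")
    else:
        lf_hf = powers["lf"] / powers["hf"]
    return SpectralFeatures(tp=tp, lf_hf=lf_hf, **powers)


def segment_features(grid: SegmentGrid, k: int) -> dict[str, float]:
    """All nine HRV parameters of 1-based segment ``k``."""
    idx = grid.indices(k)
    if idx.size < 3:
        raise ValueError(f"segment {k} has {idx.size} beats; at least 3 needed")
    rr = grid.series.rr[idx]
    td = time_domain_features(rr)
    start, stop = grid.window(k)
    x = resample_tachogram(grid.series.time[idx], rr, start, stop)
    freqs, psd = welch_psd(x)
    sp = band_powers(freqs, psd)
    return {
        "hr": td.mean_hr,
        "rri": td.mean_rri,
        "sdnn": td.sdnn,
        "rmssd": td.rmssd,
        "vlf": sp.vlf,
        "lf": sp.lf,
        "hf": sp.hf,
        "tp": sp.tp,
        "lf_hf": sp.lf_hf,
    }


def phase_features(grid: SegmentGrid, phase: str) -> PhaseFeatureSet:
    """Phase value of each parameter: the arithmetic mean over the phase's
    two segments.  The LF/HF ratio is averaged as a ratio, not recomputed
    from the averaged LF and HF powers."""
    k1, k2 = select_phase_segments(grid, phase)
    try:
        f1 = segment_features(grid, k1)
    except ValueError as e:
        raise ValueError(f"phase {phase!r}, segment {k1}: {e}") from e
    try:
        f2 = segment_features(grid, k2)
    except ValueError as e:
        raise ValueError(f"phase {phase!r}, segment {k2}: {e}") from e
    return PhaseFeatureSet(
        phase=phase,
        values={name: 0.5 * (f1[name] + f2[name]) for name in FEATURE_NAMES},
    )


def delta_features(early: PhaseFeatureSet, middle: PhaseFeatureSet) -> dict[str, float]:
    """Delta features: middle-phase minus early-phase value per parameter.

    Keys carry a ``d_`` prefix.  A parameter missing (NaN) in either phase
    yields a NaN delta.
    """
    return {
        f"d_{name}": middle[name] - early[name] for name in FEATURE_NAMES
    }


def session_features(grid: SegmentGrid) -> pd.Series:
    """Phase features for early/middle/late plus deltas, as one flat row.

    Columns are ``<phase>_<param>`` and ``d_<param>``.
    """
    phases = {p: phase_features(grid, p) for p in ("early", "middle", "late")}
    row: dict[str, float] = {}
    for p, fs in phases.items():
        for name in FEATURE_NAMES:
            row[f"{p}_{name}"] = fs[name]
    row.update(delta_features(phases["early"], phases["middle"]))
    return pd.Series(row)
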