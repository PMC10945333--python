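"""Spectral scoring of passive cavitation detector recordings.

The quantification chain mirrors standard cavitation-dose analysis:

1. 5th-order Butterworth band-pass (0.3–10 MHz), applied zero-phase.
2. Windowing — either a single 500 µs rectangular window at sonication onset
   (overall cavitation in the pulse) or 200 µs Hanning windows sliding by
   100 µs (temporal evolution).  A matching-length noise window is taken
   from the pre-onset segment.
3. One-sided, window-power-normalized periodogram, zero-padded to a
   frequency resolution of ≤ 200 Hz, so that the integral of the PSD over
   frequency equals the windowed mean-square amplitude (Parseval).
4. Normalization of signal and noise PSDs by the scalar mean noise power
   over [f0, 3f0].
5. Band powers: 10 kHz integrals centred at the located sub/ultra-harmonic
   peaks (1/2 f0, 3/2 f0, the 1/3-order pairs 1/3+2/3 and 4/3+5/3), the
   broadband inertial-cavitation (IC) level as the mean of two 40 kHz
   integrals at 3.42 f0 and 3.58 f0, and relative peaks (peak-band mean PSD
   over the pooled flanking reference bands).
6. Right-tail equal-variance t-tests across pressure groups and against
   noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal as sp_signal
from scipy import stats

from mbcav.core import RFRecording

#: Flanking reference bands (in multiples of f0) used for relative peaks.
REFERENCE_BANDS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "1/2f0": ((0.45, 0.47), (0.53, 0.55)),
    "3/2f0": ((1.45, 1.47), (1.53, 1.55)),
    "1/3f0": ((0.28, 0.30), (0.36, 0.38)),
    "2/3f0": ((0.61, 0.63), (0.69, 0.71)),
    "4/3f0": ((1.28, 1.30), (1.36, 1.38)),
    "5/3f0": ((1.61, 1.63), (1.69, 1.71)),
}

PEAK_ORDERS = {
    "1/2f0": 0.5,
    "3/2f0": 1.5,
    "1/3f0": 1.0 / 3.0,
    "2/3f0": 2.0 / 3.0,
    "4/3f0": 4.0 / 3.0,
    "5/3f0": 5.0 / 3.0,
}

#: Band-power columns produced by :func:`band_power_summary`.
SUMMARY_BANDS = ["ic_power", "sub_half", "ultra_3half", "sub_thirds",
                 "ultra_thirds", "f0_power"]


@dataclass(frozen=True)
class SpectralWindowSpec:
    """Window recipe: a single window or a sliding (hop) sequence.

    ``length`` and ``offset`` are in seconds relative to sonication onset;
    ``hop`` enables sliding mode (defaults to 50% overlap when set to None
    in :func:`sliding_offsets`).
    """

    kind: str = "rectangular"  # or "hanning"
    length: float = 500e-6
    offset: float = 0.0
    hop: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rectangular", "hanning"):
            raise ValueError("window kind must be 'rectangular' or 'hanning'")
        if self.length <= 0:
            raise ValueError("window length must be positive")

    def taper(self, n: int) -> np.ndarray:
        if self.kind == "rectangular":
            return np.ones(n)
        return np.hanning(n)


#: Overall-cavitation window: 500 µs rectangular at onset.
OVERALL_WINDOW = SpectralWindowSpec("rectangular", 500e-6, 0.0, None)
#: Temporal-evolution window: 200 µs Hanning sliding by 100 µs.
SLIDING_WINDOW = SpectralWindowSpec("hanning", 200e-6, 0.0, 100e-6)


@dataclass
class WindowedSegment:
    samples: np.ndarray  # tapered samples
    window: np.ndarray  # taper values
    sampling_rate: float
    start_time: float  # absolute time of the first sample in the record
    spec: SpectralWindowSpec


@dataclass
class PowerSpectrum:
    """One-sided PSD on a uniform grid (spacing ≤ 200 Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    normalization: str = "raw"  # or "noise-normalized"
    source_window: SpectralWindowSpec | None = None

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class BandDefinitionSet:
    """Peak, broadband-IC and reference band geometry for a drive at f0."""

    f0: float
    peak_bandwidth: float = 10e3
    ic_bandwidth: float = 40e3
    ic_orders: tuple[float, float] = (3.42, 3.58)
    search_halfwidth: float = 10e3

    def nominal(self, label: str) -> float:
        return PEAK_ORDERS[label] * self.f0

    def reference_bands(self, label: str) -> list[tuple[float, float]]:
        return [
            (lo * self.f0, hi * self.f0) for lo, hi in REFERENCE_BANDS[label]
        ]


@dataclass
class BandPowerSummary:
    """Integrated band powers (noise-normalized linear units) for one window."""

    offset: float
    ic_power: float
    sub_half: float
    ultra_3half: float
    sub_thirds: float
    ultra_thirds: float
    f0_power: float
    relative_peaks: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in ("offset", *SUMMARY_BANDS)}
        for label, value in self.relative_peaks.items():
            d[f"rel_{label}"] = value
        return d


# ---------------------------------------------------------------------------
# filtering and windowing

def bandpass_filter(
    rec: RFRecording,
    low: float = 0.3e6,
    high: float = 10e6,
    order: int = 5,
) -> RFRecording:
    """Zero-phase 5th-order Butterworth band-pass of the raw RF record.

    The filter is applied forward-backward so the sonication-onset timing is
    not skewed; the effective magnitude response is the square of the
    single-pass Butterworth response.
    """
    nyquist = rec.sampling_rate / 2.0
    if high >= nyquist:
        raise ValueError(
            f"low-pass corner {high:g} Hz must be below the Nyquist "
            f"frequency {nyquist:g} Hz"
        )
    if not 0 < low < high:
        raise ValueError("corners must satisfy 0 < low < high")
    sos = sp_signal.butter(
        order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    return rec.replace_samples(sp_signal.sosfiltfilt(sos, rec.samples))


def extract_window(rec: RFRecording, spec: SpectralWindowSpec) -> WindowedSegment:
    """Extract and taper one window, positioned relative to sonication onset."""
    start = rec.onset_time + spec.offset
    return _extract_absolute(rec, start, spec)


def extract_noise_window(
    rec: RFRecording, spec: SpectralWindowSpec, guard: float = 1e-3
) -> WindowedSegment:
    """Matching-length window from the pre-onset (noise-only) segment.

    Uses the rightmost placement ending ``guard`` seconds before onset to
    avoid trigger transients; if the pre-onset segment is too short for the
    guard, the window is placed flush against the onset.
    """
    if rec.onset_time < spec.length:
        raise ValueError("pre-onset segment shorter than the window length")
    end = rec.onset_time - guard
    if end < spec.length:
        end = rec.onset_time
    return _extract_absolute(rec, end - spec.length, spec)


def _extract_absolute(
    rec: RFRecording, start: float, spec: SpectralWindowSpec
) -> WindowedSegment:
    i0 = int(round(start * rec.sampling_rate))
    n = int(round(spec.length * rec.sampling_rate))
    if i0 < 0 or i0 + n > rec.samples.size:
        raise ValueError(
            f"window [{start:g}, {start + spec.length:g}] s extends outside "
            f"the record of duration {rec.duration:g} s"
        )
    taper = spec.taper(n)
    return WindowedSegment(
        samples=rec.samples[i0 : i0 + n] * taper,
        window=taper,
        sampling_rate=rec.sampling_rate,
        start_time=i0 / rec.sampling_rate,
        spec=spec,
    )


def sliding_offsets(rec: RFRecording, spec: SpectralWindowSpec) -> np.ndarray:
    """Window offsets (s, relative to onset) covering the sonication pulse."""
    hop = spec.hop if spec.hop is not None else spec.length / 2.0
    if hop <= 0:
        raise ValueError("hop must be positive")
    n = int(np.floor((rec.pulse_length - spec.length) / hop + 1e-9)) + 1
    if n < 1:
        raise ValueError("pulse shorter than the window length")
    return spec.offset + hop * np.arange(n)


# ---------------------------------------------------------------------------
# PSD and normalization

def compute_psd(
    segment: WindowedSegment, resolution: float = 200.0
) -> PowerSpectrum:
    """One-sided window-power-normalized periodogram, zero-padded to ≤
    ``resolution`` Hz spacing.

    Scaling satisfies Parseval: ``∫ PSD df`` equals the mean square of the
    windowed segment divided by the window power factor ``mean(w²)``.
    """
    if segment.samples.size == 0:
        raise ValueError("empty segment")
    fs = segment.sampling_rate
    nfft = sp_fft.next_fast_len(int(np.ceil(fs / resolution)))
    nfft = max(nfft, segment.samples.size)
    spectrum = np.fft.rfft(segment.samples, nfft)
    scale = 1.0 / (fs * np.sum(segment.window**2))
    psd = (np.abs(spectrum) ** 2) * scale
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(
        frequencies=freqs, power=psd, normalization="raw",
        source_window=segment.spec,
    )


def noise_band_mean(psd_noise: PowerSpectrum, f0: float) -> float:
    """Scalar mean noise PSD over the [f0, 3 f0] band."""
    lo, hi = f0, 3.0 * f0
    sel = (psd_noise.frequencies >= lo) & (psd_noise.frequencies <= hi)
    if not np.any(sel):
        raise ValueError("noise PSD grid does not cover [f0, 3 f0]")
    return float(np.mean(psd_noise.power[sel]))


def normalize_to_noise(
    psd_signal: PowerSpectrum, psd_noise: PowerSpectrum, f0: float
) -> tuple[PowerSpectrum, PowerSpectrum]:
    """Divide both spectra by the scalar mean noise power over [f0, 3 f0]."""
    if psd_signal.frequencies.shape != psd_noise.frequencies.shape or not np.allclose(
        psd_signal.frequencies, psd_noise.frequencies
    ):
        raise ValueError("signal and noise PSDs must share a frequency grid")
    denom = noise_band_mean(psd_noise, f0)
    if denom <= 0:
        raise ValueError(
            "zero noise power on [f0, 3 f0]: normalization is degenerate"
        )
    out = []
    for psd in (psd_signal, psd_noise):
        out.append(
            PowerSpectrum(
                frequencies=psd.frequencies,
                power=psd.power / denom,
                normalization="noise-normalized",
                source_window=psd.source_window,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# band arithmetic

def locate_peak(
    psd: PowerSpectrum, nominal: float, search_halfwidth: float = 10e3
) -> float:
    """Frequency of the maximum PSD bin within nominal ± halfwidth."""
    lo, hi = nominal - search_halfwidth, nominal + search_halfwidth
    if lo < psd.frequencies[0] or hi > psd.frequencies[-1]:
        raise ValueError("search interval outside the PSD grid")
    sel = np.flatnonzero((psd.frequencies >= lo) & (psd.frequencies <= hi))
    return float(psd.frequencies[sel[np.argmax(psd.power[sel])]])


def _band_integral(psd: PowerSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], edges clipped to the
    band by linear interpolation."""
    f, p = psd.frequencies, psd.power
    if lo < f[0] or hi > f[-1]:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] Hz exceeds the PSD grid "
            f"[{f[0]:g}, {f[-1]:g}] Hz"
        )
    if hi <= lo:
        raise ValueError("band width must be positive")
    inner = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inner], [hi]])
    vals = np.concatenate([
        [np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]
    ])
    return float(np.trapezoid(vals, grid))


def integrate_band(psd: PowerSpectrum, center: float, width: float) -> float:
    """Numerical integral of the PSD over center ± width/2."""
    return _band_integral(psd, center - width / 2.0, center + width / 2.0)


def broadband_ic_power(psd: PowerSpectrum, bands: BandDefinitionSet) -> float:
    """Broadband (inertial cavitation) level: mean of the two 40 kHz band
    integrals centred at 3.42 f0 and 3.58 f0 (between-harmonic loci)."""
    integrals = [
        integrate_band(psd, order * bands.f0, bands.ic_bandwidth)
        for order in bands.ic_orders
    ]
    return float(np.mean(integrals))


def relative_peak(
    psd: PowerSpectrum, label: str, bands: BandDefinitionSet
) -> float:
    """Mean PSD in the 10 kHz peak band over the pooled mean PSD of the
    component's two flanking reference bands."""
    if label not in REFERENCE_BANDS:
        raise ValueError(f"no reference bands defined for component {label!r}")
    center = locate_peak(psd, bands.nominal(label), bands.search_halfwidth)
    peak_mean = integrate_band(psd, center, bands.peak_bandwidth) / bands.peak_bandwidth
    ref_integral = 0.0
    ref_width = 0.0
    for lo, hi in bands.reference_bands(label):
        ref_integral += _band_integral(psd, lo, hi)
        ref_width += hi - lo
    ref_mean = ref_integral / ref_width
    if ref_mean <= 0:
        raise ValueError(
            f"zero reference-band power for {label}: ratio undefined"
        )
    return float(peak_mean / ref_mean)


def band_power_summary(
    psd: PowerSpectrum,
    bands: BandDefinitionSet,
    offset: float = 0.0,
    with_relative_peaks: bool = True,
) -> BandPowerSummary:
    """Score one (noise-normalized) PSD into the standard band powers."""

    def peak_band(label: str) -> float:
        center = locate_peak(psd, bands.nominal(label), bands.search_halfwidth)
        return integrate_band(psd, center, bands.peak_bandwidth)

    rel = {}
    if with_relative_peaks:
        rel = {label: relative_peak(psd, label, bands) for label in REFERENCE_BANDS}
    return BandPowerSummary(
        offset=offset,
        ic_power=broadband_ic_power(psd, bands),
        sub_half=peak_band("1/2f0"),
        ultra_3half=peak_band("3/2f0"),
        sub_thirds=peak_band("1/3f0") + peak_band("2/3f0"),
        ultra_thirds=peak_band("4/3f0") + peak_band("5/3f0"),
        f0_power=integrate_band(
            psd,
            locate_peak(psd, bands.f0, bands.search_halfwidth),
            bands.peak_bandwidth,
        ),
        relative_peaks=rel,
    )


# ---------------------------------------------------------------------------
# high-level analyses

def analyze_overall(
    rec: RFRecording,
    spec: SpectralWindowSpec = OVERALL_WINDOW,
    bands: BandDefinitionSet | None = None,
    prefilter: bool = True,
) -> tuple[BandPowerSummary, BandPowerSummary]:
    """Overall-cavitation scoring of one recording.

    Returns (signal summary, noise summary), both computed from
    noise-normalized PSDs of the onset window and of a matching pre-onset
    noise window.
    """
    bands = bands or BandDefinitionSet(f0=rec.f0)
    if prefilter:
        rec = bandpass_filter(rec)
    psd_sig = compute_psd(extract_window(rec, spec))
    psd_noise = compute_psd(extract_noise_window(rec, spec))
    psd_sig, psd_noise = normalize_to_noise(psd_sig, psd_noise, rec.f0)
    return (
        band_power_summary(psd_sig, bands, offset=spec.offset),
        band_power_summary(psd_noise, bands, offset=np.nan),
    )


def spectrogram(
    rec: RFRecording,
    spec: SpectralWindowSpec = SLIDING_WINDOW,
    bands: BandDefinitionSet | None = None,
    prefilter: bool = True,
    with_relative_peaks: bool = False,
) -> list[BandPowerSummary]:
    """Sliding-window band-power evolution through the sonication pulse.

    Every window PSD is normalized by the scalar mean noise power of a
    single matching-length pre-onset window, so offsets are mutually
    comparable.
    """
    bands = bands or BandDefinitionSet(f0=rec.f0)
    if prefilter:
        rec = bandpass_filter(rec)
    noise_psd = compute_psd(extract_noise_window(rec, spec))
    denom = noise_band_mean(noise_psd, rec.f0)
    if denom <= 0:
        raise ValueError("zero noise power on [f0, 3 f0]")
    summaries = []
    for offset in sliding_offsets(rec, spec):
        seg = _extract_absolute(rec, rec.onset_time + offset, spec)
        psd = compute_psd(seg)
        psd = PowerSpectrum(
            psd.frequencies, psd.power / denom, "noise-normalized", spec
        )
        summaries.append(
            band_power_summary(
                psd, bands, offset=float(offset),
                with_relative_peaks=with_relative_peaks,
            )
        )
    return summaries


def summaries_to_frame(summaries: Iterable[BandPowerSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


# ---------------------------------------------------------------------------
# group statistics

def compare_groups(
    groups: Mapping[str, pd.DataFrame],
    order: list[str] | None = None,
    bands: list[str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Right-tail equal-variance t-tests between consecutive groups.

    ``groups`` maps a group label (e.g. pressure group) to a DataFrame of
    per-observation band powers.  For each band and each consecutive ordered
    pair, tests whether the later group's mean power exceeds the earlier
    one's.  Raw one-sided p-values are reported; ``holm=True`` adds a
    Holm-adjusted column across all reported tests.
    """
    order = order or list(groups)
    if len(order) < 2:
        raise ValueError("need at least two groups to compare")
    first = groups[order[0]]
    bands = bands or [c for c in SUMMARY_BANDS if c in first.columns]
    rows = []
    for lo_label, hi_label in zip(order[:-1], order[1:]):
        for band in bands:
            a = np.asarray(groups[lo_label][band], dtype=float)
            b = np.asarray(groups[hi_label][band], dtype=float)
            if a.size < 2 or b.size < 2:
                raise ValueError("need at least 2 observations per group")
            pooled_var = (
                (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
            ) / (a.size + b.size - 2)
            if pooled_var == 0:
                raise ValueError(
                    f"zero pooled variance for band {band} between "
                    f"{lo_label} and {hi_label}"
                )
            t, p = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
            rows.append(
                {
                    "band": band,
                    "group_low": lo_label,
                    "group_high": hi_label,
                    "t": float(t),
                    "p": float(p),
                }
            )
    result = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        result["p_holm"] = multipletests(result["p"], method="holm")[1]
    return result


def signal_vs_noise_test(
    signal_powers: np.ndarray, noise_powers: np.ndarray
) -> tuple[float, float]:
    """Right-tail equal-variance t-test of signal band powers against the
    matching noise-window band powers."""
    a = np.asarray(noise_powers, dtype=float)
    b = np.asarray(signal_powers, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("zero variance: test undefined")
    t, p = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
    return float(t), float(p)
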