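"""Dynamics statistics: binned rates, Fano factor, oscillation index,
coherence with analytic significance level, phase-relation histograms, and
the action-selection outcome classifier.

Spike trains are binned at the in vivo reference sampling rate of 256 Hz
(bin width 1000/256 ~ 3.9 ms).  Population synchrony is quantified by the
Fano factor of the summed population count per bin; rhythmicity by the
oscillation index (fraction of spectral power in a band, spectra averaged
over single-unit periodograms); and pairwise locking by Welch coherence
over disjoint Hanning segments and by Hilbert-phase differences of
band-passed binned trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FS_DEFAULT",
    "BIN_MS",
    "BinnedRates",
    "CoherenceResult",
    "PhaseHistogram",
    "SelectionOutcome",
    "bin_spike_times",
    "fano_factor",
    "oscillation_index",
    "coherence",
    "coherence_significance",
    "phase_relation",
    "circular_mean",
    "classify_selection",
    "outcome_grid_summary",
]

FS_DEFAULT = 256.0            # Hz
BIN_MS = 1000.0 / 256.0       # ~3.9 ms
BETA_BAND = (15.0, 25.0)      # Hz
SLOW_BAND = (0.5, 1.5)        # Hz

OUTCOMES = ("none", "action1", "action2", "dual")


@dataclass
class BinnedRates:
    bin_width: float          # ms
    counts: np.ndarray        # (n_bins,) population or (n_neurons, n_bins)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    significance: float
    n_segments: int
    window: int


@dataclass
class PhaseHistogram:
    edges: np.ndarray         # 101 edges over [-pi, pi]
    mass: np.ndarray          # 100 fractions summing to 1
    band: tuple
    circ_mean: float


@dataclass
class SelectionOutcome:
    outcome: str
    rates: tuple              # per-action SNr rate during the burst, Hz
    baseline: float           # control SNr rate, Hz


def bin_spike_times(times, t0: float, t1: float,
                    fs: float = FS_DEFAULT) -> np.ndarray:
    """Spike counts per bin of width 1000/fs ms over [t0, t1)."""
    width = 1000.0 / fs
    n_bins = int((t1 - t0) / width)
    times = np.asarray(times, dtype=float)
    keep = (times >= t0) & (times < t0 + n_bins * width)
    idx = ((times[keep] - t0) / width).astype(np.int64)
    return np.bincount(idx, minlength=n_bins)


def fano_factor(counts) -> float:
    """Variance over mean of the summed population count per time bin; 1
    for Poisson firing, >1 under population synchrony."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 2:
        counts = counts.sum(axis=0)
    if counts.size < 2:
        raise ValueError("need at least two bins")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("Fano factor undefined for a silent population")
    return float(counts.var() / mean)


def _unit_spectra(trains, t0, t1, fs, nperseg):
    """Welch periodograms of mean-subtracted binned single-unit trains,
    averaged over units."""
    spectra = []
    freqs = None
    for tr in trains:
        x = bin_spike_times(tr, t0, t1, fs).astype(float)
        if x.size < 2:
            continue
        x = x - x.mean()
        nps = min(nperseg, x.size)
        f, p = signal.welch(x, fs=fs, window="hann", nperseg=nps,
                            noverlap=0, detrend=False)
        freqs = f
        spectra.append(p)
    if not spectra:
        raise ValueError("no spikes to analyse")
    return freqs, np.mean(spectra, axis=0)


def oscillation_index(trains, t0: float, t1: float,
                      band: tuple = BETA_BAND, fs: float = FS_DEFAULT,
                      nperseg: int = 256) -> float:
    """Relative spectral power in ``band``: the band integral of the
    unit-averaged spectrum over its full-bandwidth integral (flat spectrum
    gives (b-a)/(fs/2))."""
    freqs, S = _unit_spectra(trains, t0, t1, fs, nperseg)
    total = np.trapezoid(S, freqs)
    if total <= 0:
        raise ValueError("empty spectrum")
    a, b = band
    fine = np.linspace(freqs[0], freqs[-1], 4 * freqs.size)
    Sf = np.interp(fine, freqs, S)
    sel = (fine >= a) & (fine <= b)
    bandpow = np.trapezoid(Sf[sel], fine[sel])
    return float(bandpow / np.trapezoid(Sf, fine))


def coherence_significance(n_segments: int, p: float = 0.95) -> float:
    """Analytic null threshold for magnitude-squared coherence estimated
    from L disjoint segments: 1 - (1-p)^(1/(L-1))."""
    if n_segments < 2:
        raise ValueError("need at least two segments")
    return 1.0 - (1.0 - p) ** (1.0 / (n_segments - 1))


def coherence(times_a, times_b, t0: float, t1: float, window: int = 256,
              fs: float = FS_DEFAULT, p: float = 0.95) -> CoherenceResult:
    """Magnitude-squared coherence of two binned spike trains from
    Hanning-windowed disjoint segment averages, with the analytic
    significance level for the segment count."""
    xa = bin_spike_times(times_a, t0, t1, fs).astype(float)
    xb = bin_spike_times(times_b, t0, t1, fs).astype(float)
    n = min(xa.size, xb.size)
    L = n // window
    if L < 2:
        raise ValueError("need at least two disjoint segments")
    xa = xa[:L * window] - xa[:L * window].mean()
    xb = xb[:L * window] - xb[:L * window].mean()
    f, c = signal.coherence(xa, xb, fs=fs, window="hann", nperseg=window,
                            noverlap=0, detrend=False)
    return CoherenceResult(freqs=f, coherence=c,
                           significance=coherence_significance(L, p),
                           n_segments=L, window=window)


def _bandpass(x: np.ndarray, band: tuple, fs: float) -> np.ndarray:
    """Zero-phase band filter (forward-backward Butterworth); stop-band
    attenuation well beyond 20 dB an octave outside the band."""
    lo, hi = band
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def circular_mean(phases: np.ndarray) -> float:
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(np.angle(z))


def phase_relation(times_a, times_b, t0: float, t1: float,
                   band: tuple = BETA_BAND, fs: float = FS_DEFAULT,
                   n_bins: int = 100) -> PhaseHistogram:
    """Instantaneous-phase difference histogram of two spike trains.

    Binned trains are band-passed (zero-phase), Hilbert-transformed, and
    the pointwise phase difference is histogrammed over 100 bins spanning
    [-pi, pi).
    """
    duration_s = (t1 - t0) / 1000.0
    if duration_s * band[1] < 10:
        raise ValueError("need at least ~10 cycles of the band of interest")
    xa = bin_spike_times(times_a, t0, t1, fs).astype(float)
    xb = bin_spike_times(times_b, t0, t1, fs).astype(float)
    if xa.sum() == 0 or xb.sum() == 0:
        raise ValueError("empty spike train")
    pa = np.angle(signal.hilbert(_bandpass(xa - xa.mean(), band, fs)))
    pb = np.angle(signal.hilbert(_bandpass(xb - xb.mean(), band, fs)))
    dphi = np.angle(np.exp(1j * (pa - pb)))
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(dphi, bins=edges)
    mass = hist / hist.sum()
    return PhaseHistogram(edges=edges, mass=mass, band=band,
                          circ_mean=circular_mean(dphi))


def classify_selection(rates, baseline: float,
                       threshold_fraction: float = 0.5) -> SelectionOutcome:
    """Four-way selection outcome: action i is selected iff its SNr pool
    rate during the selection phase drops below ``threshold_fraction`` of
    the control baseline."""
    if baseline is None or not math.isfinite(baseline) or baseline <= 0:
        raise ValueError("control baseline required")
    r1, r2 = rates
    sel1 = r1 < threshold_fraction * baseline
    sel2 = r2 < threshold_fraction * baseline
    outcome = ("dual" if sel1 and sel2 else
               "action1" if sel1 else
               "action2" if sel2 else "none")
    return SelectionOutcome(outcome=outcome, rates=(r1, r2),
                            baseline=baseline)


def outcome_grid_summary(outcomes: dict) -> dict:
    """Per-cell outcome proportions over {none, action1, action2, dual};
    ``outcomes`` maps a grid cell to its list of per-trial outcomes."""
    summary = {}
    for cell, items in outcomes.items():
        if not items:
            raise ValueError(f"cell {cell}: no trials")
        names = [o.outcome if isinstance(o, SelectionOutcome) else o
                 for o in items]
        n = len(names)
        summary[cell] = tuple(names.count(k) / n for k in OUTCOMES)
    return summary
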