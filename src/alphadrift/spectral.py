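"""Split-half FFT analysis of trial baselines.

Each 1 s pre-stimulus baseline is Hamming-windowed, zero-padded to a 0.1 Hz
frequency grid and Fourier transformed; power spectra are averaged over
trials separately for the first and second half of the session.  The
individual alpha frequency (IAF) is the frequency of maximal power within
8-13 Hz at the electrode with the highest mean alpha power, and session
drifts are tested with paired t-tests on the second-minus-first-half
differences across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from alphadrift.epochs import EpochSet

__all__ = [
    "PowerSpectrum",
    "AlphaPeak",
    "SplitHalfResult",
    "baseline_spectrum",
    "select_peak_electrode",
    "extract_alpha_peak",
    "split_half_analysis",
    "split_half_indices",
]

FREQ_RESOLUTION_HZ = 0.1
ALPHA_BAND = (8.0, 13.0)


@dataclass
class PowerSpectrum:
    """Trial-averaged baseline power spectrum on a uniform 0.1 Hz grid."""

    freqs_hz: np.ndarray  # (n_freqs,)
    power: np.ndarray  # (n_channels, n_freqs)
    ch_names: list[str]
    n_trials_averaged: int
    half_label: str = "all"  # "first" | "second" | "all"

    def band_slice(self, band: tuple[float, float] = ALPHA_BAND) -> np.ndarray:
        """Boolean mask over the frequency grid, band edges inclusive."""
        lo, hi = band
        eps = FREQ_RESOLUTION_HZ / 2.0
        return (self.freqs_hz >= lo - eps) & (self.freqs_hz <= hi + eps)


@dataclass
class AlphaPeak:
    peak_freq_hz: float
    peak_power: float
    electrode: str


@dataclass
class SplitHalfResult:
    """Group statistics of split-half alpha peak frequency and power.

    Deltas are second-half minus first-half (positive = increase over time);
    with ``proportional=True`` they are divided by the first-half value.
    """

    freq_first: np.ndarray
    freq_second: np.ndarray
    power_first: np.ndarray
    power_second: np.ndarray
    freq_delta: np.ndarray
    power_delta: np.ndarray
    electrodes: list[str]
    freq_t: float
    freq_p: float
    freq_d: float
    power_t: float
    power_p: float
    power_d: float
    dof: int
    delta_spearman_rho: float
    delta_spearman_p: float
    proportional: bool = False


def baseline_spectrum(
    epochs: EpochSet,
    trial_subset: np.ndarray | None = None,
    half_label: str = "all",
) -> PowerSpectrum:
    """Hamming-windowed, zero-padded FFT power of 1 s baselines, trial-averaged.

    ``trial_subset`` holds positional trial indices; None means all trials.
    The zero-padded FFT length is ``fs / 0.1`` samples, giving the 0.1 Hz
    grid; power is the squared magnitude of the transform.
    """
    base = epochs.baseline()
    n_base = base.shape[2]
    if n_base < int(round(epochs.fs_hz)) :
        raise ValueError("baseline shorter than 1 s")
    if trial_subset is None:
        trial_subset = np.arange(epochs.n_trials)
    trial_subset = np.asarray(trial_subset)
    if trial_subset.size == 0:
        raise ValueError("trial_subset is empty")
    x = base[:, trial_subset, :]
    win = np.hamming(n_base)
    nfft = int(round(epochs.fs_hz / FREQ_RESOLUTION_HZ))
    spec = np.fft.rfft(x * win, n=nfft, axis=-1)
    power = np.mean(np.abs(spec) ** 2, axis=1)
    freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs_hz)
    return PowerSpectrum(
        freqs_hz=freqs,
        power=power,
        ch_names=list(epochs.ch_names),
        n_trials_averaged=trial_subset.size,
        half_label=half_label,
    )


def select_peak_electrode(
    spectrum: PowerSpectrum, band: tuple[float, float] = ALPHA_BAND
) -> str:
    """Channel with the highest mean power over the (inclusive) alpha band.

    Ties resolve to the lowest channel index.
    """
    m = spectrum.band_slice(band)
    mean_alpha = spectrum.power[:, m].mean(axis=1)
    return spectrum.ch_names[int(np.argmax(mean_alpha))]


def extract_alpha_peak(
    spectrum: PowerSpectrum,
    electrode: str | int,
    band: tuple[float, float] = ALPHA_BAND,
    smoothing: str = "none",
) -> AlphaPeak | None:
    """Alpha peak of one channel's spectrum.

    smoothing="none" (split-half use): raw argmax within the closed band;
    ties resolve to the lowest frequency.

    smoothing="savitzky_golay" (component-selection use): the spectrum is
    smoothed with an 11-point, 3rd-order Savitzky-Golay filter and the peak
    must be a strict local maximum strictly inside the open band -- a
    monotone 1/f spectrum, or a bump pinned to a band edge, yields None.
    """
    if isinstance(electrode, str):
        ch = spectrum.ch_names.index(electrode)
        name = electrode
    else:
        ch = int(electrode)
        name = spectrum.ch_names[ch]
    lo, hi = band
    if lo < spectrum.freqs_hz[0] or hi > spectrum.freqs_hz[-1]:
        raise ValueError("band outside the frequency grid")
    m = spectrum.band_slice(band)
    p = spectrum.power[ch]

    if smoothing == "none":
        idx = np.flatnonzero(m)
        best = idx[int(np.argmax(p[m]))]
        return AlphaPeak(float(spectrum.freqs_hz[best]), float(p[best]), name)
    if smoothing != "savitzky_golay":
        raise ValueError(f"unknown smoothing {smoothing!r}")

    sm = signal.savgol_filter(p, window_length=11, polyorder=3)
    interior = m.copy()
    eps = FREQ_RESOLUTION_HZ / 2.0
    interior &= (spectrum.freqs_hz > lo + eps) & (spectrum.freqs_hz < hi - eps)
    cand = np.flatnonzero(interior)
    cand = cand[(cand > 0) & (cand < len(sm) - 1)]
    is_max = (sm[cand] > sm[cand - 1]) & (sm[cand] > sm[cand + 1])
    cand = cand[is_max]
    if cand.size == 0:
        return None
    best = cand[int(np.argmax(sm[cand]))]
    return AlphaPeak(float(spectrum.freqs_hz[best]), float(sm[best]), name)


def split_half_indices(n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices of the first/second session halves.

    Trials are assumed sorted by ascending acquisition order; with an odd
    count the first half receives the extra trial (ceil(N/2)).
    """
    n1 = math.ceil(n_trials / 2)
    return np.arange(n1), np.arange(n1, n_trials)


def split_half_analysis(
    cohort: list[EpochSet],
    proportional: bool = False,
    band: tuple[float, float] = ALPHA_BAND,
) -> SplitHalfResult:
    """Split-half IAF / alpha-power drift test across a cohort.

    Per subject: the peak electrode is chosen from the all-trials spectrum,
    then the raw-argmax alpha peak is extracted from the first- and
    second-half trial-averaged spectra at that electrode.  Group-level
    paired t-tests (equivalently one-sample t on the deltas), paired
    Cohen's d (mean delta / SD of deltas) and the Spearman correlation
    between the frequency and power deltas are reported.

    ``cohort`` may be any iterable of EpochSet (a generator keeps only one
    subject's data in memory at a time).
    """
    f1, f2, p1, p2, electrodes = [], [], [], [], []
    for epochs in cohort:
        idx1, idx2 = split_half_indices(epochs.n_trials)
        # one windowed-FFT pass; per-half power sums accumulated in chunks
        base = epochs.baseline()
        if base.shape[2] < int(round(epochs.fs_hz)):
            raise ValueError("baseline shorter than 1 s")
        win = np.hamming(base.shape[2])
        nfft = int(round(epochs.fs_hz / FREQ_RESOLUTION_HZ))
        freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs_hz)
        n_half1 = idx1.size
        sums = [
            np.zeros((epochs.n_channels, freqs.size)),
            np.zeros((epochs.n_channels, freqs.size)),
        ]
        for start in range(0, epochs.n_trials, 128):
            stop = min(start + 128, epochs.n_trials)
            pw = np.abs(np.fft.rfft(base[:, start:stop] * win, n=nfft, axis=-1)) ** 2
            split = np.clip(n_half1 - start, 0, stop - start)
            sums[0] += pw[:, :split].sum(axis=1)
            sums[1] += pw[:, split:].sum(axis=1)
        spec1 = PowerSpectrum(freqs, sums[0] / idx1.size, list(epochs.ch_names), idx1.size, "first")
        spec2 = PowerSpectrum(freqs, sums[1] / idx2.size, list(epochs.ch_names), idx2.size, "second")
        full = PowerSpectrum(
            freqs,
            (sums[0] + sums[1]) / epochs.n_trials,
            list(epochs.ch_names),
            epochs.n_trials,
            "all",
        )
        electrode = select_peak_electrode(full, band)
        pk1 = extract_alpha_peak(spec1, electrode, band)
        pk2 = extract_alpha_peak(spec2, electrode, band)
        f1.append(pk1.peak_freq_hz)
        f2.append(pk2.peak_freq_hz)
        p1.append(pk1.peak_power)
        p2.append(pk2.peak_power)
        electrodes.append(electrode)
    if len(f1) < 2:
        raise ValueError("need >= 2 subjects for group tests")
    f1, f2 = np.array(f1), np.array(f2)
    p1, p2 = np.array(p1), np.array(p2)
    fd = (f2 - f1) / f1 if proportional else f2 - f1
    pd_ = (p2 - p1) / p1 if proportional else p2 - p1

    def _one_sample(d: np.ndarray) -> tuple[float, float, float]:
        sd = d.std(ddof=1)
        if sd == 0:  # degenerate: all deltas identical
            if d.mean() == 0:
                return 0.0, 1.0, 0.0
            s = float(np.sign(d.mean()))
            return s * np.inf, 0.0, s * np.inf
        res = stats.ttest_1samp(d, 0.0)
        return float(res.statistic), float(res.pvalue), float(d.mean() / sd)

    ft, fp, fdh = _one_sample(fd)
    pt, pp, pdh = _one_sample(pd_)
    if np.ptp(fd) == 0 or np.ptp(pd_) == 0:
        rho, rho_p = np.nan, np.nan  # correlation undefined for constant deltas
    else:
        rho, rho_p = stats.spearmanr(fd, pd_)
    return SplitHalfResult(
        freq_first=f1,
        freq_second=f2,
        power_first=p1,
        power_second=p2,
        freq_delta=fd,
        power_delta=pd_,
        electrodes=electrodes,
        freq_t=ft,
        freq_p=fp,
        freq_d=fdh,
        power_t=pt,
        power_p=pp,
        power_d=pdh,
        dof=len(f1) - 1,
        delta_spearman_rho=float(rho),
        delta_spearman_p=float(rho_p),
        proportional=proportional,
    )
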