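"""Histogram-based trial stratification across session halves.

If the session-long frequency decrease and power increase were two faces of
one process, equalising the trial distribution of one measure between the
first and second half of the session should abolish the drift of the other.
The histogram method bins the pooled values of the equalised measure into
100 equal-width bins and, within each bin, randomly subsamples the
larger half down to the smaller half's count, so the retained per-bin
histograms are identical across halves (matching mean, variance and higher
moments up to bin resolution).  Because the subsampling is stochastic, the
split-half spectral analysis is repeated over many iterations and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from alphadrift.epochs import EpochSet
from alphadrift.instfreq import epoch_instfreq
from alphadrift.spectral import (
    ALPHA_BAND,
    FREQ_RESOLUTION_HZ,
    split_half_indices,
)

__all__ = [
    "StratificationResult",
    "histogram_stratify",
    "trial_measures",
    "stratified_subject",
    "stratified_split_half",
]


@dataclass
class StratificationResult:
    """Group outcome of the stratified split-half analysis.

    The iteration-averaged per-subject peak frequency and power for each
    half, with paired t statistics on both measures computed on those
    averages.  ``equalized_on`` names the measure whose distributions were
    matched; the scientific question is whether the *other* measure's drift
    survives.
    """

    equalized_on: str
    n_iterations: int
    freq_first: np.ndarray
    freq_second: np.ndarray
    power_first: np.ndarray
    power_second: np.ndarray
    retained_first: np.ndarray  # mean retained trial count per subject
    retained_second: np.ndarray
    freq_t: float
    freq_p: float
    power_t: float
    power_p: float
    dof: int
    achieved_mean_diff: np.ndarray  # per-subject |mean2-mean1| of equalised measure, in SD


def histogram_stratify(
    values_half1: np.ndarray,
    values_half2: np.ndarray,
    n_bins: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalise two value distributions by per-bin random subsampling.

    Common equal-width bin edges span the pooled range; within each bin the
    larger half is subsampled (without replacement) down to the smaller
    count.  Returns the retained indices into each half (sorted).
    """
    v1 = np.asarray(values_half1, dtype=float)
    v2 = np.asarray(values_half2, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both halves must be non-empty")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate([v1, v2])
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    b1 = np.clip(np.searchsorted(edges, v1, side="right") - 1, 0, n_bins - 1)
    b2 = np.clip(np.searchsorted(edges, v2, side="right") - 1, 0, n_bins - 1)
    keep1, keep2 = [], []
    for b in range(n_bins):
        i1 = np.flatnonzero(b1 == b)
        i2 = np.flatnonzero(b2 == b)
        k = min(i1.size, i2.size)
        if k == 0:
            continue
        keep1.append(i1 if i1.size == k else rng.choice(i1, size=k, replace=False))
        keep2.append(i2 if i2.size == k else rng.choice(i2, size=k, replace=False))
    idx1 = np.sort(np.concatenate(keep1)) if keep1 else np.array([], dtype=int)
    idx2 = np.sort(np.concatenate(keep2)) if keep2 else np.array([], dtype=int)
    if idx1.size < max(2, v1.size // 20):
        warnings.warn(
            "stratification retained very few trials (nearly disjoint supports)",
            stacklevel=2,
        )
    return idx1, idx2


def trial_measures(epochs: EpochSet, denoise: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial baseline-averaged alpha power and Inst-AF, plus band spectra.

    Returns ``(power, instaf, band_spectra)`` where power/instaf are
    (n_trials,) averages over the [-1, 0) baseline and all electrodes, and
    band_spectra is (n_trials, n_channels, n_band_bins) single-trial 8-13 Hz
    FFT power used to recompute split-half peaks on retained subsets.
    """
    base = epochs.baseline()
    n_base = base.shape[2]
    win = np.hamming(n_base)
    nfft = int(round(epochs.fs_hz / FREQ_RESOLUTION_HZ))
    freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs_hz)
    eps = FREQ_RESOLUTION_HZ / 2.0
    m = (freqs >= ALPHA_BAND[0] - eps) & (freqs <= ALPHA_BAND[1] + eps)
    spec = np.fft.rfft(base * win, n=nfft, axis=-1)
    band = np.moveaxis(np.abs(spec[:, :, m]) ** 2, 0, 1)  # (n_trials, nc, n_band)
    power = band.mean(axis=(1, 2))
    instaf = epoch_instfreq(epochs, tmax=0.0, denoise=denoise).baseline_average()
    return power, instaf, band


def stratified_subject(
    epochs: EpochSet,
    equalize_on: str,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    n_bins: int = 100,
    measures: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Stratified split-half peaks for one subject, averaged over iterations.

    ``equalize_on`` is ``"power"`` or ``"instfreq"``.  Per iteration the
    chosen measure's first/second-half distributions are equalised, then the
    peak electrode (highest mean alpha power over retained trials) and the
    raw-argmax alpha peak are recomputed per half from the retained trials'
    trial-averaged FFT spectra.
    """
    if equalize_on not in ("power", "instfreq"):
        raise ValueError("equalize_on must be 'power' or 'instfreq'")
    rng = np.random.default_rng(rng)
    if measures is None:
        measures = trial_measures(epochs)
    power, instaf, band = measures
    v = power if equalize_on == "power" else instaf
    idx1_all, idx2_all = split_half_indices(epochs.n_trials)
    band_freqs = None  # peak frequency axis reconstructed below
    nfft = int(round(epochs.fs_hz / FREQ_RESOLUTION_HZ))
    freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs_hz)
    eps = FREQ_RESOLUTION_HZ / 2.0
    band_freqs = freqs[(freqs >= ALPHA_BAND[0] - eps) & (freqs <= ALPHA_BAND[1] + eps)]

    f1s, f2s, p1s, p2s, n1s, n2s, dmeans = [], [], [], [], [], [], []
    pooled_sd = np.std(v, ddof=1)
    for _ in range(n_iter):
        k1, k2 = histogram_stratify(v[idx1_all], v[idx2_all], n_bins=n_bins, rng=rng)
        r1 = idx1_all[k1]
        r2 = idx2_all[k2]
        if r1.size == 0 or r2.size == 0:
            continue
        s1 = band[r1].mean(axis=0)  # (nc, n_band)
        s2 = band[r2].mean(axis=0)
        sall = (band[r1].sum(axis=0) + band[r2].sum(axis=0)) / (r1.size + r2.size)
        ch = int(np.argmax(sall.mean(axis=1)))
        i1 = int(np.argmax(s1[ch]))
        i2 = int(np.argmax(s2[ch]))
        f1s.append(band_freqs[i1])
        f2s.append(band_freqs[i2])
        p1s.append(s1[ch, i1])
        p2s.append(s2[ch, i2])
        n1s.append(r1.size)
        n2s.append(r2.size)
        dmeans.append(abs(v[r2].mean() - v[r1].mean()) / pooled_sd)
    if not f1s:
        raise ValueError("stratification retained no trials in any iteration")
    return {
        "freq_first": float(np.mean(f1s)),
        "freq_second": float(np.mean(f2s)),
        "power_first": float(np.mean(p1s)),
        "power_second": float(np.mean(p2s)),
        "retained_first": float(np.mean(n1s)),
        "retained_second": float(np.mean(n2s)),
        "achieved_mean_diff": float(np.mean(dmeans)),
    }


def stratified_split_half(
    cohort: list[EpochSet],
    equalize_on: str,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    n_bins: int = 100,
    measures: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
) -> StratificationResult:
    """Group stratified split-half analysis.

    Paired t-tests are computed on the iteration-averaged per-subject peak
    frequency and power; precomputed ``measures`` (from
    :func:`trial_measures`) may be passed to avoid recomputation.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 subjects for group tests")
    rng = np.random.default_rng(rng)
    rows = []
    for i, epochs in enumerate(cohort):
        m = None if measures is None else measures[i]
        rows.append(
            stratified_subject(
                epochs, equalize_on, n_iter=n_iter, rng=rng, n_bins=n_bins, measures=m
            )
        )
    f1 = np.array([r["freq_first"] for r in rows])
    f2 = np.array([r["freq_second"] for r in rows])
    p1 = np.array([r["power_first"] for r in rows])
    p2 = np.array([r["power_second"] for r in rows])
    def _paired(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        d = a - b
        if d.std(ddof=1) == 0:  # e.g. perfect abolition: all deltas zero
            if d.mean() == 0:
                return 0.0, 1.0
            s = float(np.sign(d.mean()))
            return s * np.inf, 0.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    ft, fp = _paired(f2, f1)
    pt, pp = _paired(p2, p1)
    return StratificationResult(
        equalized_on=equalize_on,
        n_iterations=n_iter,
        freq_first=f1,
        freq_second=f2,
        power_first=p1,
        power_second=p2,
        retained_first=np.array([r["retained_first"] for r in rows]),
        retained_second=np.array([r["retained_second"] for r in rows]),
        freq_t=float(ft),
        freq_p=float(fp),
        power_t=float(pt),
        power_p=float(pp),
        dof=len(cohort) - 1,
        achieved_mean_diff=np.array([r["achieved_mean_diff"] for r in rows]),
    )
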