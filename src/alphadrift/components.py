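"""ICA separation of alpha sources and component-level drift classification.

Scalp alpha reflects a superposition of generators.  To ask whether the
session-long power increase and frequency decrease live in the same or in
different generators, the (5-15 Hz filtered, baseline-only) epochs are
decomposed by PCA-reduced ICA; components with a validated interior alpha
peak in their smoothed power spectrum are retained, and for each one the
per-trial baseline Hilbert power and instantaneous frequency are correlated
with trial order.  Permutation z-scores of the two trends classify each
component as showing mixed, unique-power, unique-frequency or no drift, and
the 2-D (power-z, frequency-z) distribution across components is summarised
with circular statistics (Rayleigh test, T2circ, BCa bootstrap CIs of the
centroid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from alphadrift.epochs import EpochSet
from alphadrift.instfreq import instantaneous_frequency, plateau_bandpass
from alphadrift.spectral import FREQ_RESOLUTION_HZ

__all__ = [
    "AlphaComponent",
    "ComponentTrend",
    "CircularSummary",
    "extract_alpha_components",
    "select_alpha_peaked",
    "component_trend",
    "classify_components",
    "circular_summary",
    "compare_class_peak_frequencies",
]

ALPHA_BAND = (8.0, 13.0)
ICA_BAND = (5.0, 15.0)


@dataclass
class AlphaComponent:
    """One ICA component: spatial filter plus unfiltered-epoch activations."""

    spatial_filter: np.ndarray  # (n_channels,)
    activation: np.ndarray  # (n_trials, n_samples), unfiltered projection
    fs_hz: float
    times: np.ndarray
    trial_order: np.ndarray
    psd_freqs: np.ndarray
    psd_smoothed: np.ndarray  # Savitzky-Golay smoothed baseline PSD
    peak_freq_hz: float | None  # interior 8-13 Hz peak of the smoothed PSD
    subject_id: int = 0
    index: int = 0

    def baseline_mask(self) -> np.ndarray:
        return (self.times >= -1.0) & (self.times < 0.0)


@dataclass
class ComponentTrend:
    """Trial-order trend statistics of one component."""

    power_rho: float
    power_z: float
    power_p: float
    freq_rho: float
    freq_z: float
    freq_p: float
    n_shuffles: int
    peak_freq_hz: float | None = None
    subject_id: int = 0
    label: str = "unclassified"

    @property
    def angle(self) -> float:
        """Direction of the drift in (power-z, frequency-z) space, radians."""
        return float(np.arctan2(self.freq_z, self.power_z))


@dataclass
class CircularSummary:
    n: int
    mean_angle: float  # radians, atan2 convention
    resultant_length: float  # mean resultant, in [0, 1]
    mean_angle_ci: tuple[float, float]  # 95% circular CI (radians)
    rayleigh_z: float
    rayleigh_p: float
    t2circ: float
    t2circ_f: float
    t2circ_dof: tuple[int, int]
    t2circ_p: float
    centroid: tuple[float, float]  # (mean power-z, mean frequency-z)
    centroid_ci_power: tuple[float, float]  # BCa 95%
    centroid_ci_freq: tuple[float, float]


# ---------------------------------------------------------------------------
# extraction and selection


def _component_psd(
    act: np.ndarray, fs: float, base_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged, zero-padded baseline FFT power of one activation."""
    x = act[:, base_mask]
    win = np.hamming(x.shape[1])
    nfft = int(round(fs / FREQ_RESOLUTION_HZ))
    spec = np.fft.rfft(x * win, n=nfft, axis=-1)
    power = np.mean(np.abs(spec) ** 2, axis=0)
    return np.fft.rfftfreq(nfft, 1.0 / fs), power


def _interior_alpha_peak(
    freqs: np.ndarray, power: np.ndarray
) -> tuple[float | None, np.ndarray]:
    """Savitzky-Golay smoothed spectrum and its strict interior 8-13 Hz peak."""
    sm = signal.savgol_filter(power, window_length=11, polyorder=3)
    lo, hi = ALPHA_BAND
    eps = FREQ_RESOLUTION_HZ / 2.0
    cand = np.flatnonzero((freqs > lo + eps) & (freqs < hi - eps))
    cand = cand[(cand > 0) & (cand < len(sm) - 1)]
    is_max = (sm[cand] > sm[cand - 1]) & (sm[cand] > sm[cand + 1])
    cand = cand[is_max]
    # a reliable alpha peak must also rise above the band-edge background,
    # otherwise every smoothed 1/f wiggle would qualify
    edge_lo = sm[np.argmin(np.abs(freqs - lo))]
    edge_hi = sm[np.argmin(np.abs(freqs - hi))]
    cand = cand[sm[cand] > max(edge_lo, edge_hi)]
    if cand.size == 0:
        return None, sm
    best = cand[int(np.argmax(sm[cand]))]
    return float(freqs[best]), sm


def extract_alpha_components(
    epochs: EpochSet,
    n_components: int = 20,
    rng: np.random.Generator | int | None = None,
    subject_id: int = 0,
    max_retries: int = 3,
) -> list[AlphaComponent]:
    """PCA-reduced ICA on 5-15 Hz filtered, baseline-only concatenated epochs.

    The unmixing is estimated on the filtered baselines; the resulting
    spatial filters are then applied to the *unfiltered* epochs to obtain
    activations, so downstream spectra retain the broadband background.
    Non-convergence triggers a retry with a fresh seed (up to
    ``max_retries``); the unmixing is deterministic under the given rng.
    """
    rng = np.random.default_rng(rng)
    n_components = min(n_components, epochs.n_channels)
    filt = plateau_bandpass(epochs.data, epochs.fs_hz, band=ICA_BAND)
    base = filt[:, :, epochs.baseline_mask()]
    X = base.reshape(epochs.n_channels, -1).T  # (samples, channels)

    W = None
    for _attempt in range(max_retries):
        seed = int(rng.integers(2**31 - 1))
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            random_state=seed,
            max_iter=500,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ica.fit(X)
            converged = not any(
                "did not converge" in str(w.message) for w in caught
            )
        W = ica.components_  # (n_components, n_channels)
        if converged:
            break
    assert W is not None

    acts = np.einsum("kc,ctn->ktn", W, epochs.data)
    bmask = epochs.baseline_mask()
    out = []
    for k in range(n_components):
        freqs, power = _component_psd(acts[k], epochs.fs_hz, bmask)
        peak, sm = _interior_alpha_peak(freqs, power)
        out.append(
            AlphaComponent(
                spatial_filter=W[k].copy(),
                activation=acts[k],
                fs_hz=epochs.fs_hz,
                times=epochs.times.copy(),
                trial_order=epochs.trial_order.copy(),
                psd_freqs=freqs,
                psd_smoothed=sm,
                peak_freq_hz=peak,
                subject_id=subject_id,
                index=k,
            )
        )
    return out


def select_alpha_peaked(candidates: list[AlphaComponent]) -> list[AlphaComponent]:
    """Keep only components whose smoothed PSD has an interior 8-13 Hz peak."""
    return [c for c in candidates if c.peak_freq_hz is not None]


# ---------------------------------------------------------------------------
# per-component trends


def _spearman_with_null(
    values: np.ndarray,
    order_ranks: np.ndarray,
    perm_ranks: np.ndarray,
) -> tuple[float, float, float]:
    """Observed Spearman rho vs trial order, with permutation z and p.

    ``perm_ranks`` is an (n_shuffles, n_trials) array of shuffled order
    ranks; the two-sided p uses the (b+1)/(n+1) correction.
    """
    rv = stats.rankdata(values)
    rv_c = rv - rv.mean()
    ro_c = order_ranks - order_ranks.mean()
    denom = np.sqrt(np.sum(rv_c**2) * np.sum(ro_c**2))
    if denom == 0:
        raise ValueError("constant measure: rank correlation undefined")
    rho = float(np.dot(ro_c, rv_c) / denom)
    pc = perm_ranks - perm_ranks.mean(axis=1, keepdims=True)
    null = (pc @ rv_c) / denom
    mu, sd = null.mean(), null.std(ddof=0)
    z = (rho - mu) / sd if sd > 0 else 0.0
    b = int(np.sum(np.abs(null) >= abs(rho)))
    p = (b + 1) / (len(null) + 1)
    return rho, float(z), float(p)


def component_trend(
    component: AlphaComponent,
    n_shuffles: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> ComponentTrend:
    """Trial-order trends of baseline Hilbert power and Inst-AF of a component.

    The activation is 8-13 Hz band-passed (zero-phase plateau filter);
    instantaneous power is the squared magnitude of the analytic signal and
    instantaneous frequency the denoised phase derivative, both averaged
    over the [-1, 0) baseline of each trial.  Both trends are invariant to
    the ICA sign/scale ambiguity.
    """
    if component.activation.shape[0] < 10:
        raise ValueError("need >= 10 trials for trend estimation")
    rng = np.random.default_rng(rng)
    flt = plateau_bandpass(component.activation, component.fs_hz, band=ALPHA_BAND)
    analytic = signal.hilbert(flt, axis=-1)
    bmask = component.baseline_mask()
    power = np.mean(np.abs(analytic[:, bmask]) ** 2, axis=1)
    instf = instantaneous_frequency(flt, component.fs_hz)
    instaf = np.nanmean(instf[:, bmask[:-1]], axis=1)

    n = len(component.trial_order)
    ro = stats.rankdata(component.trial_order)
    perm = rng.permuted(np.broadcast_to(ro, (n_shuffles, n)), axis=1)
    p_rho, p_z, p_p = _spearman_with_null(power, ro, perm)
    f_rho, f_z, f_p = _spearman_with_null(instaf, ro, perm)
    return ComponentTrend(
        power_rho=p_rho,
        power_z=p_z,
        power_p=p_p,
        freq_rho=f_rho,
        freq_z=f_z,
        freq_p=f_p,
        n_shuffles=n_shuffles,
        peak_freq_hz=component.peak_freq_hz,
        subject_id=component.subject_id,
    )


def classify_components(
    trends: list[ComponentTrend], alpha: float = 0.05
) -> list[ComponentTrend]:
    """Label each trend: mixed / unique-power / unique-frequency / none.

    mixed = both permutation p-values < alpha; unique-X = only X's p < alpha
    (uncorrected, as in the component-level masking convention).
    """
    for t in trends:
        ps = t.power_p < alpha
        fs = t.freq_p < alpha
        if ps and fs:
            t.label = "mixed"
        elif ps:
            t.label = "unique-power"
        elif fs:
            t.label = "unique-frequency"
        else:
            t.label = "none"
    return trends


# ---------------------------------------------------------------------------
# circular statistics


def _rayleigh(angles: np.ndarray) -> tuple[float, float, float, float]:
    """Mean angle, resultant length, Rayleigh z and p (Zar's approximation)."""
    n = len(angles)
    C = np.cos(angles).sum()
    S = np.sin(angles).sum()
    R = np.hypot(C, S)
    rbar = R / n
    z = R**2 / n  # = n * rbar^2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2.0 * n))
    return float(np.arctan2(S, C)), float(rbar), float(z), float(min(p, 1.0))


def _circ_mean_ci(angles: np.ndarray, mean_angle: float, rbar: float) -> tuple[float, float]:
    """Large-sample 95% CI of the mean direction (circular dispersion method)."""
    n = len(angles)
    if rbar >= 1.0 - 1e-12:
        return (mean_angle, mean_angle)
    rho2 = np.abs(np.mean(np.exp(2j * angles)))
    disp = (1.0 - rho2) / (2.0 * rbar**2)
    se = np.sqrt(disp / n)
    arg = 1.959963984540054 * se
    half = np.arcsin(min(arg, 1.0)) if arg <= 1.0 else np.pi
    return (mean_angle - half, mean_angle + half)


def circular_summary(
    trends: list[ComponentTrend],
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CircularSummary:
    """Circular and bivariate tests of the component drift-direction cloud.

    Each component contributes the angle of the surrogate complex number
    power-z + i*frequency-z.  Non-uniformity of the angles is tested with a
    Rayleigh test; the magnitude-aware T2circ statistic tests whether the
    bivariate centroid differs from the origin (F = n*T2 on F(2, 2n-2));
    the centroid coordinates get BCa bootstrap 95% CIs.
    """
    if len(trends) < 3:
        raise ValueError("need >= 3 components")
    rng = np.random.default_rng(rng)
    pz = np.array([t.power_z for t in trends])
    fz = np.array([t.freq_z for t in trends])
    angles = np.arctan2(fz, pz)
    mean_angle, rbar, ray_z, ray_p = _rayleigh(angles)
    ci_angle = _circ_mean_ci(angles, mean_angle, rbar)

    z = pz + 1j * fz
    n = len(z)
    zbar = z.mean()
    s2 = np.sum(np.abs(z - zbar) ** 2) / (n - 1)
    t2 = float(np.abs(zbar) ** 2 / s2)
    f_stat = n * t2
    dof = (2, 2 * n - 2)
    t2_p = float(stats.f.sf(f_stat, *dof))

    def _boot_ci(x: np.ndarray) -> tuple[float, float]:
        res = stats.bootstrap(
            (x,),
            np.mean,
            n_resamples=n_boot,
            confidence_level=0.95,
            method="BCa",
            random_state=rng,
        )
        return (float(res.confidence_interval.low), float(res.confidence_interval.high))

    return CircularSummary(
        n=n,
        mean_angle=mean_angle,
        resultant_length=rbar,
        mean_angle_ci=ci_angle,
        rayleigh_z=ray_z,
        rayleigh_p=ray_p,
        t2circ=t2,
        t2circ_f=float(f_stat),
        t2circ_dof=dof,
        t2circ_p=t2_p,
        centroid=(float(pz.mean()), float(fz.mean())),
        centroid_ci_power=_boot_ci(pz),
        centroid_ci_freq=_boot_ci(fz),
    )


# ---------------------------------------------------------------------------
# class-wise peak-frequency comparisons


def first_quarter_peak(component: AlphaComponent) -> float | None:
    """Interior alpha peak recomputed from the first quarter of trials only.

    Excludes the possibility that class differences in peak frequency are an
    artifact of the drifts themselves.
    """
    n = component.activation.shape[0]
    k = max(1, int(np.ceil(n / 4)))
    freqs, power = _component_psd(
        component.activation[:k], component.fs_hz, component.baseline_mask()
    )
    peak, _ = _interior_alpha_peak(freqs, power)
    return peak


def compare_class_peak_frequencies(
    trends: list[ComponentTrend],
    peaks: dict | None = None,
) -> list[dict]:
    """Independent two-sample t-tests of peak frequency between drift classes.

    Compares mixed vs unique-frequency, mixed vs unique-power and
    unique-frequency vs unique-power.  ``peaks`` may map a class label to an
    explicit array of peak frequencies (e.g. first-quarter recomputations);
    by default the trends' stored peaks are used.  Classes with fewer than
    two members are skipped; at least two classes must be non-empty.
    """
    classes = ("mixed", "unique-frequency", "unique-power")
    if peaks is None:
        peaks = {
            c: np.array(
                [t.peak_freq_hz for t in trends if t.label == c and t.peak_freq_hz is not None]
            )
            for c in classes
        }
    non_empty = [c for c in classes if len(peaks.get(c, [])) >= 2]
    if len(non_empty) < 2:
        raise ValueError("need at least two non-empty classes")
    rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            xa = np.asarray(peaks.get(a, []), dtype=float)
            xb = np.asarray(peaks.get(b, []), dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                continue
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf * np.sign(xa.mean() - xb.mean()), 0.0)
            else:
                t, p = stats.ttest_ind(xa, xb)
            rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "t": float(t),
                    "dof": len(xa) + len(xb) - 2,
                    "p": float(p),
                }
            )
    return rows
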