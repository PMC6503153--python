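"""Synthetic multichannel EEG with planted alpha-band non-stationarities.

The generator builds cohorts of epoched "EEG" in which every drift is known
exactly, so each downstream analysis stage can be validated by parameter
recovery.  Each subject's data are a sum of alpha sources -- sinusoids whose
per-trial frequency and amplitude follow configured linear session drifts,
projected to the scalp through smooth unit-norm topographies -- plus
channel-independent 1/f background noise.

Three canonical generative scenarios are provided as presets:

- ``A`` : a single oscillator that both slows down and gains power,
- ``B`` : two oscillators with independent drifts (one power-only, one
  frequency-only),
- ``C`` : two oscillators at offset centre frequencies with *no* frequency
  drift at all; a power increase of the lower-frequency one shifts the
  sensor-level spectral peak downward purely through the changing power
  ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from alphadrift.epochs import EpochSet
from alphadrift.layout import fibonacci_cap_layout

__all__ = [
    "SourceSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "scenario_preset",
]

ALPHA_BAND = (8.0, 13.0)
_ANALYSIS_BAND = (5.0, 15.0)


@dataclass
class SourceSpec:
    """One oscillatory alpha source.

    ``freq_drift_hz_per_session`` and ``power_drift_fraction_per_session``
    are total changes over the whole session: a frequency drift of -0.25
    means the mean oscillation frequency of the last trial sits 0.25 Hz
    below that of the first; a power drift of +0.2 scales the amplitude of
    the last trial by 1.2 relative to the first.  ``bandwidth_hz`` is the SD
    of the spontaneous trial-to-trial frequency jitter around the drifting
    mean (the peak width of the source's trial-averaged spectrum).
    """

    centre_freq_hz: float
    freq_drift_hz_per_session: float = 0.0
    base_amplitude: float = 1.0
    power_drift_fraction_per_session: float = 0.0
    bandwidth_hz: float = 0.5
    quadratic_freq_hz: float = 0.0
    amplitude_jitter_frac: float = 0.0
    freq_power_coupling_hz: float = 0.0
    burst_modulation: float = 0.2
    topo_width_cm: float = 4.0
    topography: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = ALPHA_BAND
        if not lo <= self.centre_freq_hz <= hi:
            raise ValueError(f"centre_freq_hz must lie in [{lo}, {hi}]")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be > 0")
        end = (
            self.centre_freq_hz
            + self.freq_drift_hz_per_session
            + self.quadratic_freq_hz
        )
        blo, bhi = _ANALYSIS_BAND
        if not blo <= end <= bhi:
            raise ValueError(
                "freq drift would carry the source outside the "
                f"[{blo}, {bhi}] Hz analysis band"
            )
        if not 0.0 <= self.burst_modulation < 1.0:
            raise ValueError("burst_modulation must lie in [0, 1)")
        if self.topography is not None:
            self.topography = np.asarray(self.topography, dtype=float)
            nrm = np.linalg.norm(self.topography)
            if not np.isclose(nrm, 1.0, atol=1e-6):
                raise ValueError("topography must have unit Euclidean norm")

    @property
    def label(self) -> str:
        """Planted drift class: mixed / unique-power / unique-frequency / stationary."""
        f = self.freq_drift_hz_per_session != 0 or self.quadratic_freq_hz != 0
        p = self.power_drift_fraction_per_session != 0
        if f and p:
            return "mixed"
        if p:
            return "unique-power"
        if f:
            return "unique-frequency"
        return "stationary"


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; ``seed`` determines everything."""

    sources: list[SourceSpec]
    n_subjects: int = 20
    n_trials: int = 750
    n_channels: int = 60
    fs_hz: float = 250.0
    epoch_span_s: tuple[float, float] = (-1.0, 1.0)
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    within_trial_walk_sd_hz: float = 0.0
    shared_topography: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.fs_hz < 100.0:
            raise ValueError("fs_hz must be >= 100 Hz")
        if self.epoch_span_s[1] <= self.epoch_span_s[0]:
            raise ValueError("epoch_span_s must be increasing")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


@dataclass
class GroundTruth:
    """Exactly what was planted for one subject."""

    freq_trajectories: np.ndarray  # (n_sources, n_trials) Hz
    amp_trajectories: np.ndarray  # (n_sources, n_trials) a.u.
    topographies: np.ndarray  # (n_sources, n_channels), unit norm rows
    labels: list[str]
    source_waveforms: np.ndarray | None = None  # (n_sources, n_trials, n_samples)

    def to_dict(self) -> dict:
        return {
            "freq_trajectories": self.freq_trajectories.tolist(),
            "amp_trajectories": self.amp_trajectories.tolist(),
            "topographies": self.topographies.tolist(),
            "labels": list(self.labels),
        }


def _gaussian_topography(
    pos: np.ndarray, centre: np.ndarray, width_cm: float = 4.0
) -> np.ndarray:
    d2 = np.sum((pos - centre) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * width_cm**2))
    return w / np.linalg.norm(w)


def _draw_topographies(
    rng: np.random.Generator,
    pos: np.ndarray,
    widths_cm: list[float],
    min_sep_cm: float = 6.0,
) -> np.ndarray:
    """Smooth pseudo-scalp maps: Gaussian bumps with mutually separated centres.

    Bump centres are drawn from the electrode grid with a minimum mutual
    separation (keeps distinct sources spatially identifiable); the bump
    width sets how broadly a source projects -- wide maps overlap heavily,
    as occipital alpha generators do on a real scalp.
    """
    centres: list[np.ndarray] = []
    for _ in widths_cm:
        for _attempt in range(200):
            c = pos[rng.integers(len(pos))]
            if all(np.linalg.norm(c - o) >= min_sep_cm for o in centres):
                break
        centres.append(c)
    return np.stack(
        [_gaussian_topography(pos, c, w) for c, w in zip(centres, widths_cm)]
    )


def _one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    fs: float,
    exponent: float,
    amplitude: float,
) -> np.ndarray:
    """Channel- and trial-independent noise with a 1/f^exponent power spectrum.

    The spectral mask is normalised to preserve total variance, so the output
    SD equals ``amplitude`` in expectation.
    """
    if amplitude == 0.0:
        return np.zeros(shape + (n_samples,))
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = np.zeros_like(freqs)
    mask[1:] = freqs[1:] ** (-exponent / 2.0)
    # Parseval weights: DC and Nyquist bins count once, the rest twice.
    w = np.full(freqs.shape, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    mask /= np.sqrt(np.sum(w * mask**2) / n_samples)
    spec = np.fft.rfft(white, axis=-1) * mask
    return amplitude * np.fft.irfft(spec, n=n_samples, axis=-1)


def generate_subject(
    config: CohortConfig, subject_index: int
) -> tuple[EpochSet, GroundTruth]:
    """Generate one subject's epochs plus the planted ground truth.

    Reproducible: output is a pure function of ``(config, subject_index)``.
    Per-trial source frequency is ``centre + drift * i/(N-1) + jitter`` and
    amplitude ``base * (1 + power_drift * i/(N-1))`` for trial i = 0..N-1.
    """
    rng = np.random.default_rng([config.seed, subject_index])
    t0, t1 = config.epoch_span_s
    n_samples = int(round((t1 - t0) * config.fs_hz))
    times = t0 + np.arange(n_samples) / config.fs_hz
    n_trials = config.n_trials
    frac = np.arange(n_trials) / (n_trials - 1)

    ch_names, ch_pos = fibonacci_cap_layout(config.n_channels)
    n_src = len(config.sources)
    if config.shared_topography:
        # all sources project through one scalp map: spectrally offset
        # assemblies within the same cortical patch, inseparable at the
        # sensor (the premise of the power-ratio scenario)
        one = _draw_topographies(rng, ch_pos, [config.sources[0].topo_width_cm])
        auto_topo = np.repeat(one, n_src, axis=0)
    else:
        auto_topo = _draw_topographies(
            rng, ch_pos, [s.topo_width_cm for s in config.sources]
        )

    freq_traj = np.empty((n_src, n_trials))
    amp_traj = np.empty((n_src, n_trials))
    topos = np.empty((n_src, config.n_channels))
    waves = np.empty((n_src, n_trials, n_samples))

    for s, spec in enumerate(config.sources):
        mean_f = (
            spec.centre_freq_hz
            + spec.freq_drift_hz_per_session * frac
            + spec.quadratic_freq_hz * frac**2
        )
        a_trial = spec.base_amplitude * (
            1.0 + spec.power_drift_fraction_per_session * frac
        )
        if spec.amplitude_jitter_frac > 0.0:
            a_trial = a_trial * (
                1.0 + spec.amplitude_jitter_frac * rng.standard_normal(n_trials)
            )
        a_trial = np.clip(a_trial, 0.0, None)
        f_trial = mean_f + spec.bandwidth_hz * rng.standard_normal(n_trials)
        if spec.freq_power_coupling_hz != 0.0:
            # frequency as a (deterministic, up to bandwidth jitter) function
            # of the realised per-trial amplitude: the "single coupled
            # process" world in which equalising power must abolish the
            # frequency trend
            f_trial = f_trial + spec.freq_power_coupling_hz * (
                a_trial / spec.base_amplitude - 1.0
            )
        phase0 = rng.uniform(0.0, 2.0 * np.pi, n_trials)
        if config.within_trial_walk_sd_hz > 0.0:
            step = config.within_trial_walk_sd_hz * rng.standard_normal(
                (n_trials, n_samples)
            )
            inst_f = f_trial[:, None] + np.cumsum(step, axis=1) / np.sqrt(
                np.arange(1, n_samples + 1)
            )
            phase = phase0[:, None] + 2.0 * np.pi * np.cumsum(inst_f, axis=1) / config.fs_hz
            freq_traj[s] = inst_f.mean(axis=1)
        else:
            phase = phase0[:, None] + 2.0 * np.pi * f_trial[:, None] * (times - t0)[None, :]
            freq_traj[s] = f_trial
        wave = a_trial[:, None] * np.sin(phase)
        if spec.burst_modulation > 0.0:
            # waxing-and-waning envelope: smooth (~0.1 s kernel) unit-SD
            # noise scaled by the modulation depth around a mean of 1 --
            # makes the source amplitude distribution realistically
            # super-Gaussian (alpha occurs in bursts), which is also what
            # renders distinct sources identifiable to ICA
            kernel_sd = max(int(round(0.1 * config.fs_hz)), 1)
            klen = 6 * kernel_sd + 1
            kt = np.arange(klen) - klen // 2
            kernel = np.exp(-(kt**2) / (2.0 * kernel_sd**2))
            kernel /= np.sqrt(np.sum(kernel**2))
            rough = rng.standard_normal((n_trials, n_samples + klen - 1))
            smooth = np.apply_along_axis(
                lambda r: np.convolve(r, kernel, mode="valid"), 1, rough
            )
            env = np.clip(1.0 + spec.burst_modulation * smooth, 0.05, None)
            wave = wave * env
        waves[s] = wave
        amp_traj[s] = a_trial
        topos[s] = auto_topo[s] if spec.topography is None else spec.topography

    data = np.einsum("sc,stn->ctn", topos, waves)
    data += _one_over_f_noise(
        rng,
        (config.n_channels, n_trials),
        n_samples,
        config.fs_hz,
        config.noise_exponent,
        config.noise_amplitude,
    )

    epochs = EpochSet(
        data=data,
        fs_hz=config.fs_hz,
        times=times,
        trial_order=np.arange(1, n_trials + 1),
        ch_names=ch_names,
        ch_pos=ch_pos,
    )
    truth = GroundTruth(
        freq_trajectories=freq_traj,
        amp_trajectories=amp_traj,
        topographies=topos,
        labels=[s.label for s in config.sources],
        source_waveforms=waves,
    )
    return epochs, truth


def generate_cohort(config: CohortConfig) -> list[tuple[EpochSet, GroundTruth]]:
    """One (EpochSet, GroundTruth) pair per subject, deterministic under seed."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def scenario_preset(name: str, **overrides) -> CohortConfig:
    """Canonical generative scenarios A / B / C (see module docstring).

    Keyword overrides are passed through to :class:`CohortConfig` (e.g.
    ``n_subjects=10, n_channels=20`` to scale a test cohort down).
    """
    if name == "A":
        sources = [
            SourceSpec(
                centre_freq_hz=10.0,
                freq_drift_hz_per_session=-0.25,
                base_amplitude=2.0,
                power_drift_fraction_per_session=0.20,
            )
        ]
    elif name == "B":
        # broad, overlapping maps so the peak electrode sees both
        # generators (as parieto-occipital alpha sources do on a real
        # scalp); the frequency-drifting high-alpha source dominates the
        # spectral peak while the low-alpha source drives the power trend
        sources = [
            SourceSpec(
                centre_freq_hz=9.5,
                base_amplitude=1.8,
                power_drift_fraction_per_session=0.30,
                topo_width_cm=8.0,
            ),
            SourceSpec(
                centre_freq_hz=11.5,
                freq_drift_hz_per_session=-0.30,
                base_amplitude=2.4,
                topo_width_cm=8.0,
            ),
        ]
    elif name == "C":
        # the high-alpha assembly dominates the spectrum at session start;
        # the low-alpha assembly's power growth overtakes it by session end,
        # so the summed-spectrum peak migrates downward although neither
        # component frequency moves
        sources = [
            SourceSpec(
                centre_freq_hz=9.0,
                base_amplitude=1.5,
                power_drift_fraction_per_session=0.80,
                bandwidth_hz=0.7,
                topo_width_cm=8.0,
            ),
            SourceSpec(
                centre_freq_hz=11.0,
                base_amplitude=2.1,
                bandwidth_hz=0.7,
                topo_width_cm=8.0,
            ),
        ]
    else:
        raise ValueError(f"unknown scenario {name!r}; expected 'A', 'B' or 'C'")
    if name == "C":
        overrides.setdefault("shared_topography", True)
    return CohortConfig(sources=sources, **overrides)
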