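"""Synthetic trial-structured ECoG with known category-dependent effects.

Real intracranial recordings from the semantic task are not publicly
deposited, so every downstream stage is exercised on simulated sessions
with injected ground truth.  A session consists of 1/f-shaped Gaussian
background noise per channel; on trials of a chosen category, the
70-150 Hz band content of a region's channels is scaled up inside a
latency window (with raised-cosine ramps).  Scaling the band component of
the background — rather than adding an independent oscillation — keeps
the high-gamma envelope statistics realistic and makes the gain directly
interpretable: in-band amplitude is multiplied by ``gain`` at plateau,
in-band power by ``gain**2``.

The default paradigm matches the semantic task: 20 words per category
presented twice in pseudorandom order (80 trials), 500-ms word
presentation, 2500 +/- 500 ms intertrial interval, 2000 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .io_core import CATEGORIES, ElectrodeTable, EventList, Recording
import pandas as pd

__all__ = ["EffectSpec", "SimulationSpec", "make_trial_sequence",
           "inject_band_effect", "simulate_session"]


@dataclass(frozen=True)
class EffectSpec:
    """A category-dependent band-limited amplitude increase.

    Parameters
    ----------
    region : str
        Region label whose channels carry the effect.
    window_ms : (float, float)
        Latency window relative to stimulus onset, e.g. ``(250, 1250)``.
    favored_category : {'abstract', 'concrete'}
        Trials of this category receive the effect.
    gain : float
        Multiplicative in-band amplitude gain at plateau, >= 1.
    ramp_ms : float
        Raised-cosine rise/fall time inside the window.
    """

    region: str
    window_ms: tuple
    favored_category: str
    gain: float = 2.0
    ramp_ms: float = 50.0

    def __post_init__(self):
        if self.favored_category not in CATEGORIES:
            raise ValueError(f"favored_category must be one of {CATEGORIES}")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("effect window is empty")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic session.

    ``channels_per_region`` maps region labels to channel counts; the
    background is Gaussian noise spectrally shaped to 1/f**alpha with RMS
    ``noise_rms_uv`` microvolts per channel.  ``burst_trials`` optionally
    lists trial indices contaminated with a large-amplitude broadband
    burst (a stand-in for epileptiform activity, used to test automated
    trial rejection).
    """

    channels_per_region: dict = field(default_factory=lambda: {"IFG": 6, "SM1": 6, "STG": 6, "other": 6})
    effects: tuple = ()
    noise_alpha: float = 1.0
    noise_rms_uv: float = 20.0
    band: tuple = (70.0, 150.0)
    rate: float = 2000.0
    n_words_per_category: int = 20
    repetitions: int = 2
    word_duration_ms: float = 500.0
    iti_mean_ms: float = 2500.0
    iti_jitter_ms: float = 500.0
    lead_in_s: float = 2.0
    burst_trials: tuple = ()
    burst_gain: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.iti_jitter_ms >= self.iti_mean_ms:
            raise ValueError("iti_jitter must be smaller than iti_mean")
        for eff in self.effects:
            if eff.region not in self.channels_per_region:
                raise ValueError(
                    f"effect region {eff.region!r} absent from channels_per_region"
                )

    @property
    def n_trials(self) -> int:
        return self.n_words_per_category * len(CATEGORIES) * self.repetitions


def make_trial_sequence(spec: SimulationSpec, seed=None) -> EventList:
    """Pseudorandomized trial sequence for a session.

    Each of the ``2 * n_words_per_category`` synthetic word tokens
    (w01, w02, ...) appears ``repetitions`` times; categories are balanced.
    Onsets are spaced by word duration plus an intertrial interval drawn
    uniformly from ``iti_mean +/- iti_jitter``.  Deterministic given the
    seed (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_words_per_category
    words = [f"w{i + 1:02d}" for i in range(2 * n)]
    cats = ["abstract"] * n + ["concrete"] * n
    word_ids = np.asarray(words * spec.repetitions, dtype=object)
    categories = np.asarray(cats * spec.repetitions, dtype=object)
    order = rng.permutation(len(word_ids))
    itis = rng.uniform(
        spec.iti_mean_ms - spec.iti_jitter_ms,
        spec.iti_mean_ms + spec.iti_jitter_ms,
        size=len(word_ids),
    )
    steps = (spec.word_duration_ms + itis) / 1000.0
    onsets = spec.lead_in_s + np.concatenate([[0.0], np.cumsum(steps[:-1])])
    return EventList(onsets, word_ids[order], categories[order])


def _raised_cosine_window(n: int, n_ramp: int) -> np.ndarray:
    """Unit plateau with raised-cosine rise/fall of ``n_ramp`` samples."""
    w = np.ones(n)
    if n_ramp > 0:
        n_ramp = min(n_ramp, n // 2)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        w[:n_ramp] = ramp
        w[-n_ramp:] = ramp[::-1]
    return w


def _band_sos(band, rate):
    return scipy.signal.butter(4, np.asarray(band) / (rate / 2), btype="bandpass", output="sos")


def inject_band_effect(segment: np.ndarray, gain: float, band, ramp_ms: float,
                       rate: float) -> np.ndarray:
    """Scale the band-limited content of ``segment`` by ``gain``.

    The segment (1-D, or channels x samples) is band-pass filtered
    (zero-phase), the band component is multiplied by ``gain - 1`` under
    a raised-cosine window, and added back; out-of-band content is
    unchanged up to filter leakage.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    n = segment.shape[1]
    n_ramp = int(round(ramp_ms / 1000.0 * rate))
    if n <= 2 * n_ramp:
        raise ValueError("segment must be longer than two ramps")
    if gain == 1.0:
        out = segment.copy()
    else:
        sos = _band_sos(band, rate)
        band_part = scipy.signal.sosfiltfilt(sos, segment, axis=1)
        out = segment + (gain - 1.0) * _raised_cosine_window(n, n_ramp) * band_part
    return out[0] if out.shape[0] == 1 else out


def _pink_noise(rng, n_channels, n_samples, alpha, rms):
    """Gaussian noise with power spectrum ~ 1/f**alpha, scaled to RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC offset
    sig = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sig *= rms / np.sqrt(np.mean(sig ** 2, axis=1, keepdims=True))
    return sig


def simulate_session(spec: SimulationSpec):
    """Generate a full session: (Recording, EventList, ElectrodeTable).

    A pure function of the SimulationSpec (including its seed).  Channels are
    labelled ``<REGION><k>``; all are assigned to the left (dominant)
    hemisphere.  Effects are applied per trial to the channels of their
    region when the trial category matches ``favored_category``.
    """
    rng = np.random.default_rng(spec.seed)
    events = make_trial_sequence(spec, seed=rng.integers(2 ** 31))

    channel_ids, regions = [], []
    for region, count in spec.channels_per_region.items():
        for k in range(count):
            channel_ids.append(f"{region}{k + 1:02d}")
            regions.append(region)
    electrodes = ElectrodeTable(pd.DataFrame({
        "channel_id": channel_ids,
        "region": regions,
        "hemisphere": "left",
        "dominant": True,
    }))

    tail_s = 2.5  # covers the post-stimulus epoch of the last trial
    n_samples = int(np.ceil((events.onset[-1] + tail_s) * spec.rate))
    signal = _pink_noise(rng, len(channel_ids), n_samples, spec.noise_alpha, spec.noise_rms_uv)

    region_rows = {r: np.flatnonzero(np.asarray(regions) == r) for r in spec.channels_per_region}
    for eff in spec.effects:
        rows = region_rows[eff.region]
        for t in np.flatnonzero(events.category == eff.favored_category):
            i0 = int(round((events.onset[t] + eff.window_ms[0] / 1000.0) * spec.rate))
            i1 = int(round((events.onset[t] + eff.window_ms[1] / 1000.0) * spec.rate))
            signal[rows, i0:i1] = inject_band_effect(
                signal[rows, i0:i1], eff.gain, spec.band, eff.ramp_ms, spec.rate
            )

    for t in spec.burst_trials:
        i0 = int(round(events.onset[t] * spec.rate))
        i1 = int(round((events.onset[t] + 0.5) * spec.rate))
        signal[:, i0:i1] *= spec.burst_gain

    rec = Recording(signal=signal, rate=spec.rate, channel_ids=tuple(channel_ids))
    return rec, events, electrodes
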