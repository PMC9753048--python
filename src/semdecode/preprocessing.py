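"""From continuous recordings to trial x channel x time-bin high-gamma power.

The chain is: common average reference -> 70-150 Hz band-pass (zero-phase,
4th-order Butterworth per pass) -> Hilbert envelope -> epoching around
stimulus onsets (-500 to +2000 ms) -> 250-ms bin-power averaging ->
baseline Z-scoring against the pooled pre-stimulus bins of a designated
trial set (the training trials of a cross-validation fold, so that the
held-out trial never influences the normalization).

Also provides automated rejection of artifact-contaminated trials (a
reproducible surrogate for visual inspection) and the 25-ms smoothed
per-gyrus envelope time courses with per-window category tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .io_core import AnalysisConfig, ElectrodeTable, EventList, Recording

__all__ = [
    "TrialEpochs",
    "BinnedPower",
    "FeatureTensor",
    "common_average_reference",
    "extract_hgp",
    "epoch_envelope",
    "reject_trials",
    "epoch_and_bin",
    "baseline_zscore",
    "gyral_timecourse",
    "preprocess_session",
]


@dataclass
class TrialEpochs:
    """Event-locked envelope (and optionally raw) epochs.

    ``envelope`` has shape (n_trials, n_channels, n_samples) covering
    ``epoch_start_ms`` .. ``epoch_end_ms`` at the recording rate.
    ``kept`` flags trials that survived artifact rejection.
    """

    envelope: np.ndarray
    rate: float
    epoch_start_ms: float
    channel_ids: tuple
    categories: np.ndarray
    kept: np.ndarray
    raw: np.ndarray = None

    @property
    def times_ms(self) -> np.ndarray:
        n = self.envelope.shape[2]
        return self.epoch_start_ms + 1000.0 * np.arange(n) / self.rate

    def subset_kept(self) -> "TrialEpochs":
        k = self.kept
        return TrialEpochs(self.envelope[k], self.rate, self.epoch_start_ms,
                           self.channel_ids, self.categories[k],
                           np.ones(int(k.sum()), dtype=bool),
                           None if self.raw is None else self.raw[k])


@dataclass
class BinnedPower:
    """Trial x channel x bin tensor of averaged high-gamma envelope power."""

    power: np.ndarray
    bin_edges_ms: np.ndarray
    categories: np.ndarray
    channel_ids: tuple

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def labels(self) -> np.ndarray:
        from .io_core import CATEGORY_CODES

        return np.asarray([CATEGORY_CODES[c] for c in self.categories], dtype=int)

    def subset(self, trial_mask) -> "BinnedPower":
        m = np.asarray(trial_mask)
        return BinnedPower(self.power[m], self.bin_edges_ms, self.categories[m], self.channel_ids)


@dataclass
class FeatureTensor:
    """Baseline-normalized Z-scores on the analysis bins.

    ``z`` has shape (n_trials, n_channels, n_analysis_bins) and covers ALL
    trials, but the normalizing statistics (``baseline_mean``,
    ``baseline_sd``, per channel) come exclusively from the pooled
    baseline-window bins of the trials listed in ``baseline_trials``.
    """

    z: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    baseline_trials: np.ndarray


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference each channel to the instantaneous across-channel mean."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    signal = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return Recording(signal=signal, rate=rec.rate, channel_ids=rec.channel_ids)


def extract_hgp(rec: Recording, band=(70.0, 150.0)) -> Recording:
    """High-gamma envelope: zero-phase band-pass then Hilbert magnitude.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (no group delay, so bin timing stays interpretable); the returned
    Recording holds the nonnegative analytic-signal magnitude.
    """
    if rec.rate <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {rec.rate} Hz too low for band up to {band[1]} Hz"
        )
    sos = scipy.signal.butter(4, np.asarray(band) / (rec.rate / 2),
                              btype="bandpass", output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.signal, axis=1)
    n = filtered.shape[1]
    nfft = scipy.fft.next_fast_len(n)
    analytic = scipy.signal.hilbert(filtered, N=nfft, axis=1)[:, :n]
    return Recording(signal=np.abs(analytic), rate=rec.rate, channel_ids=rec.channel_ids)


def _epoch_array(signal: np.ndarray, rate: float, onsets_s: np.ndarray,
                 config: AnalysisConfig) -> np.ndarray:
    """Cut (n_trials, n_channels, n_samples) epochs; half-open sample ranges."""
    start_off = int(round(config.epoch_start_ms / 1000.0 * rate))
    n_samp = int(round((config.epoch_end_ms - config.epoch_start_ms) / 1000.0 * rate))
    out = np.empty((len(onsets_s), signal.shape[0], n_samp))
    for t, onset in enumerate(onsets_s):
        i0 = int(round(onset * rate)) + start_off
        i1 = i0 + n_samp
        if i0 < 0 or i1 > signal.shape[1]:
            raise ValueError(
                f"epoch of trial {t} (onset {onset:.3f} s) falls outside the recording"
            )
        out[t] = signal[:, i0:i1]
    return out


def epoch_envelope(envelope: Recording, events: EventList, config: AnalysisConfig,
                   raw: Recording = None) -> TrialEpochs:
    """Cut event-locked epochs from an envelope Recording (and optionally
    the corresponding raw Recording, used by trial rejection)."""
    env = _epoch_array(envelope.signal, envelope.rate, events.onset, config)
    raw_ep = None
    if raw is not None:
        raw_ep = _epoch_array(raw.signal, raw.rate, events.onset, config)
    return TrialEpochs(
        envelope=env, rate=envelope.rate, epoch_start_ms=config.epoch_start_ms,
        channel_ids=envelope.channel_ids, categories=events.category.copy(),
        kept=np.ones(len(events), dtype=bool), raw=raw_ep,
    )


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def reject_trials(epochs: TrialEpochs, k: float = 5.0) -> TrialEpochs:
    """Flag artifact-contaminated trials automatically.

    A trial is rejected when its peak absolute amplitude (raw epochs if
    available, else envelope) or its envelope variance exceeds ``k``
    robust standard deviations (median +/- 1.4826 MAD) of the
    across-trial distribution.  ``k = inf`` keeps everything.
    """
    amp_src = epochs.raw if epochs.raw is not None else epochs.envelope
    peak = np.abs(amp_src).max(axis=(1, 2))
    env_var = epochs.envelope.var(axis=2).mean(axis=1)
    bad = (_robust_z(peak) > k) | (_robust_z(env_var) > k)
    kept = epochs.kept & ~bad
    if not kept.any():
        raise ValueError("all trials rejected")
    return TrialEpochs(epochs.envelope, epochs.rate, epochs.epoch_start_ms,
                       epochs.channel_ids, epochs.categories, kept, epochs.raw)


def epoch_and_bin(envelope: Recording, events: EventList,
                  config: AnalysisConfig) -> BinnedPower:
    """Average the envelope in consecutive 250-ms bins per trial and channel.

    Bin b of trial t, channel c is the mean envelope over the half-open
    sample range [edge_b, edge_{b+1}); the canonical epoch yields 10 bins
    from -500 to +2000 ms.
    """
    epochs = _epoch_array(envelope.signal, envelope.rate, events.onset, config)
    spb = int(round(config.bin_width_ms / 1000.0 * envelope.rate))
    n_bins = config.n_bins
    epochs = epochs[:, :, : n_bins * spb]
    power = epochs.reshape(epochs.shape[0], epochs.shape[1], n_bins, spb).mean(axis=3)
    return BinnedPower(power=power, bin_edges_ms=config.bin_edges_ms,
                       categories=events.category.copy(),
                       channel_ids=envelope.channel_ids)


def baseline_zscore(binned: BinnedPower, baseline_trials,
                    config: AnalysisConfig) -> FeatureTensor:
    """Z-score the analysis bins against pooled pre-stimulus baselines.

    Per channel, mu and sigma (population SD, divisor N) are computed
    from the baseline-window bins of ``baseline_trials`` pooled into one
    sample; ``z = (power - mu) / sigma`` is applied to the analysis bins
    of ALL trials.  In leave-one-out decoding ``baseline_trials`` is the
    training set, so the held-out trial never leaks into mu or sigma.
    """
    bt = np.asarray(baseline_trials, dtype=int)
    if bt.size == 0:
        raise ValueError("baseline_trials is empty")
    base = binned.power[np.ix_(bt, np.arange(len(binned.channel_ids)), config.baseline_bins)]
    pooled = base.transpose(1, 0, 2).reshape(len(binned.channel_ids), -1)
    mu = pooled.mean(axis=1)
    sd = pooled.std(axis=1)  # population convention
    if np.any(sd == 0):
        ch = np.asarray(binned.channel_ids)[sd == 0]
        raise ValueError(f"zero baseline variance on channel(s) {ch.tolist()}")
    analysis = binned.power[:, :, config.analysis_bins]
    z = (analysis - mu[None, :, None]) / sd[None, :, None]
    return FeatureTensor(z=z, baseline_mean=mu, baseline_sd=sd, baseline_trials=bt)


def gyral_timecourse(epochs: TrialEpochs, electrodes: ElectrodeTable,
                     window_ms: float = 25.0) -> pd.DataFrame:
    """Smoothed per-region envelope time courses with category tests.

    The envelope is window-averaged in consecutive ``window_ms`` windows;
    per region, the trial-and-channel mean and SEM are reported for each
    category together with a two-sided rank-sum p-value comparing the
    per-trial (channel-averaged) window values between categories.
    Regions with no channels are skipped with a warning.
    """
    ep = epochs.subset_kept()
    region_ix = electrodes.region_indices(ep.channel_ids)
    n = ep.envelope.shape[2]
    spw = max(1, int(round(window_ms / 1000.0 * ep.rate)))
    n_win = n // spw
    windowed = ep.envelope[:, :, : n_win * spw].reshape(
        ep.envelope.shape[0], ep.envelope.shape[1], n_win, spw
    ).mean(axis=3)
    t_ms = ep.epoch_start_ms + (np.arange(n_win) + 0.5) * 1000.0 * spw / ep.rate

    rows = []
    for region in electrodes.table["region"].unique():
        ix = region_ix.get(region)
        if ix is None or len(ix) == 0:
            warnings.warn(f"region {region!r} has no channels; skipped")
            continue
        per_trial = windowed[:, ix, :].mean(axis=1)  # (trials, windows)
        for cat in ("abstract", "concrete"):
            grp = per_trial[ep.categories == cat]
            mean = grp.mean(axis=0)
            sem = grp.std(axis=0, ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else np.zeros(n_win)
            for w in range(n_win):
                rows.append((region, t_ms[w], cat, mean[w], sem[w]))
    df = pd.DataFrame(rows, columns=["region", "time_ms", "category", "mean", "sem"])

    # per-window two-sample test between categories, one p per region/window
    pvals = []
    for region in df["region"].unique():
        ix = region_ix[region]
        per_trial = windowed[:, ix, :].mean(axis=1)
        a = per_trial[ep.categories == "abstract"]
        c = per_trial[ep.categories == "concrete"]
        for w in range(n_win):
            if np.array_equal(a[:, w], c[:, w]) or (a[:, w].std() == 0 and c[:, w].std() == 0
                                                    and a[0, w] == c[0, w]):
                p = 1.0
            else:
                p = scipy.stats.mannwhitneyu(a[:, w], c[:, w], alternative="two-sided").pvalue
            pvals.append((region, t_ms[w], p))
    pdf = pd.DataFrame(pvals, columns=["region", "time_ms", "p"])
    return df.merge(pdf, on=["region", "time_ms"])


def preprocess_session(rec: Recording, events: EventList, config: AnalysisConfig,
                       reject: bool = True):
    """Full preprocessing chain for one session.

    Returns ``(binned, epochs)`` where ``binned`` contains only the kept
    trials.  Rejection uses the robust amplitude/variance criterion with
    ``config.reject_k``.
    """
    car = common_average_reference(rec)
    env = extract_hgp(car, band=(config.band_low, config.band_high))
    epochs = epoch_envelope(env, events, config, raw=car)
    if reject and np.isfinite(config.reject_k):
        epochs = reject_trials(epochs, k=config.reject_k)
    binned = epoch_and_bin(env, events, config).subset(epochs.kept)
    return binned, epochs
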