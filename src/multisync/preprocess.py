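"""Filtering, referencing, bad-channel detection and epoch extraction.

The phase-locking analyses use zero-phase band-pass filtering (1-3000 Hz
Butterworth applied forward-backward), mastoid re-referencing, and
exclusion of channels whose summary statistics are outliers — the
variance / mean-correlation / Hurst-exponent triplet popularized by the
FASTER pipeline.  Epoch windows are matched to the timescale being
analyzed: one stimulus cycle for carrier-locked (FFR) analysis, one token
for envelope-locked (EFR) analysis, and two tokens — centered on the
starts of alternating tokens so windows never overlap — for the
envelope-change (ECFR) analysis.  Two-token epochs carry a signed "AM
step" label: the difference in AM multiple between the two tokens they
span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import EEGData
from .target_stimulus import StimulusSpec

__all__ = [
    "EpochSet",
    "bandpass_and_reref",
    "detect_bad_channels",
    "extract_epochs",
    "hurst_exponent",
]

WINDOW_KINDS = ("cycle", "token", "two-token", "beat")


def zero_phase_bandpass(data: np.ndarray, fs: float,
                        band: tuple[float, float], order: int,
                        axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass as a low-pass / high-pass cascade.

    The two edges are applied as separate forward-backward passes (low-pass
    first) because a single band-pass whose low edge sits orders of
    magnitude below Nyquist is numerically fragile; the high-pass gets a
    reflection pad matched to its long impulse response.  An upper edge the
    sample rate cannot represent degrades gracefully to the high-pass
    alone.
    """
    low, high = band
    n = data.shape[axis]
    if high < 0.45 * fs:
        sos_lp = signal.butter(order, high, btype="lowpass", fs=fs,
                               output="sos")
        data = signal.sosfiltfilt(sos_lp, data, axis=axis)
    sos_hp = signal.butter(order, low, btype="highpass", fs=fs,
                           output="sos")
    padlen = int(min(n - 1, 3 * fs / low))
    return signal.sosfiltfilt(sos_hp, data, axis=axis, padlen=padlen)


def bandpass_and_reref(eeg: EEGData, band: tuple[float, float] = (1.0, 3000.0),
                       order: int = 4) -> EEGData:
    """Zero-phase Butterworth band-pass, then re-reference every channel to
    the mean of the two mastoids."""
    for lab in eeg.mastoid_labels:
        if lab not in eeg.channel_labels:
            raise ValueError(f"mastoid channel {lab!r} missing")
    filtered = zero_phase_bandpass(eeg.data, eeg.sample_rate_hz, band, order,
                                   axis=1)
    mast_idx = [eeg.channel_index(lab) for lab in eeg.mastoid_labels]
    ref = filtered[mast_idx].mean(axis=0)
    return eeg.copy_with(data=filtered - ref[None, :])


def hurst_exponent(x: np.ndarray, min_scale: int = 8,
                   n_scales: int = 10) -> float:
    """Detrended fluctuation analysis exponent of a 1-D series.

    ~0.5 for white noise and ~1.0 for 1/f noise, which is what makes it a
    useful "does this channel look like EEG" statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    n = y.size
    scales = np.unique(np.geomspace(min_scale, n // 4,
                                    n_scales).astype(int))
    flucts = []
    for s in scales:
        n_seg = n // s
        segs = y[:n_seg * s].reshape(n_seg, s)
        t = np.arange(s)
        # Least-squares linear detrend per segment, vectorized.
        t0 = t - t.mean()
        slope = segs @ t0 / (t0 @ t0)
        trend = segs.mean(axis=1, keepdims=True) + slope[:, None] * t0
        flucts.append(np.sqrt(np.mean((segs - trend) ** 2)))
    coeffs = np.polyfit(np.log(scales), np.log(flucts), 1)
    return float(coeffs[0])


def detect_bad_channels(eeg: EEGData, threshold: float = 3.0,
                        max_samples: int = 8192) -> np.ndarray:
    """Flag scalp channels whose variance, mean correlation with the other
    channels, or Hurst exponent deviates by more than ``threshold``
    z-scores from the across-channel distribution.

    Returns a boolean mask over all channels (mastoids never flagged).
    Statistics are computed on up to ``max_samples`` samples, strided
    evenly across the recording.
    """
    scalp = np.flatnonzero(eeg.scalp_mask)
    if scalp.size < 8:
        raise ValueError("need at least 8 scalp channels")
    step = max(1, eeg.n_samples // max_samples)
    x = eeg.data[scalp, ::step]

    variance = np.var(x, axis=1)
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(np.abs(corr), axis=1)
    hurst = np.array([hurst_exponent(ch) for ch in x])

    flags = np.zeros(eeg.n_channels, dtype=bool)
    for stat in (variance, mean_corr, hurst):
        sd = np.std(stat)
        if sd == 0:
            continue
        z = (stat - np.mean(stat)) / sd
        flags[scalp] |= np.abs(z) > threshold
    return flags


@dataclass
class EpochSet:
    """Equal-length epochs (epochs x channels x samples) with metadata.

    ``meta`` has one row per epoch: trial_index, cycle_index, token_index,
    polarity, and for two-token windows the signed AM-multiple step
    ``delta_m`` plus its nominal Hz value ``delta_hz_nominal``.
    """

    data: np.ndarray
    sample_rate_hz: float
    window_kind: str
    meta: pd.DataFrame
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be epochs x channels x samples")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta must have one row per epoch")
        if self.window_kind not in WINDOW_KINDS:
            raise ValueError(f"unknown window kind {self.window_kind!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def window_duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return EpochSet(self.data[mask], self.sample_rate_hz,
                        self.window_kind,
                        self.meta.iloc[mask].reset_index(drop=True),
                        self.channel_labels)


def extract_epochs(eeg: EEGData, window_kind: str,
                   spec: StimulusSpec | None = None,
                   am_multiple: int | None = None,
                   last_n_cycles: int | None = None,
                   channel_mask: np.ndarray | None = None,
                   trial_info: pd.DataFrame | None = None,
                   beat_rate_hz: float = 3.9,
                   beats_per_window: int = 2) -> EpochSet:
    """Cut timescale-specific epochs out of a recording.

    * ``"cycle"``: one window per cycle, locked to the cycle start.
    * ``"token"``: one window per token of rate ``am_multiple`` (required),
      locked to the token start.
    * ``"two-token"``: windows centered on the start of every second token
      (token indices 1, 3, 5, ... within each trial), i.e. contiguous
      non-overlapping two-token spans labeled with the signed AM step
      between the two tokens.
    * ``"beat"``: non-overlapping windows of ``beats_per_window`` distractor
      beat periods tiling each trial from its onset, so the beat rate and
      its harmonics (e.g. the 19.5 Hz distractor envelope) fall on exact
      FFT bins.

    ``last_n_cycles`` keeps only epochs whose cycle index falls in the
    final n cycles of each trial.  ``trial_info`` (indexed or keyed by
    ``trial_index``) is merged into the epoch metadata, which is how
    correctness labels and attention states reach the analyses.  Epochs
    that would run past the recording are dropped with a warning.
    """
    spec = spec or StimulusSpec()
    fs = eeg.sample_rate_hz
    base = spec.base_rate_hz
    n_tok_samples = int(round(fs / base))
    tokens = eeg.events[eeg.events["kind"] == "token"].reset_index(drop=True)
    if tokens.empty:
        raise ValueError("no token events in recording")
    n_cycles_per_trial = int(tokens["cycle_index"].max()) + 1

    if window_kind == "cycle":
        ev = eeg.events[eeg.events["kind"] == "cycle"].reset_index(drop=True)
        starts = ev["sample_index"].to_numpy()
        n_win = int(round(spec.tokens_per_cycle * fs / base))
        meta = ev[["trial_index", "cycle_index", "token_index",
                   "polarity"]].copy()
    elif window_kind == "token":
        if am_multiple is None:
            raise ValueError("token windows require am_multiple")
        ev = tokens[tokens["am_multiple"] == am_multiple].reset_index(drop=True)
        starts = ev["sample_index"].to_numpy()
        n_win = n_tok_samples
        meta = ev[["trial_index", "cycle_index", "token_index",
                   "polarity", "am_multiple"]].copy()
    elif window_kind == "two-token":
        centers = tokens[tokens["token_index"] % 2 == 1].reset_index(drop=True)
        prev = tokens.set_index(["trial_index", "token_index"])
        starts = centers["sample_index"].to_numpy() - n_tok_samples
        n_win = 2 * n_tok_samples
        prev_mult = prev.loc[
            list(zip(centers["trial_index"], centers["token_index"] - 1)),
            "am_multiple"].to_numpy()
        delta = centers["am_multiple"].to_numpy() - prev_mult
        meta = centers[["trial_index", "cycle_index", "token_index",
                        "polarity", "am_multiple"]].copy()
        meta["delta_m"] = delta
        # nominal label: signed AM-multiple step times base rate, printed Hz
        meta["delta_hz_nominal"] = (np.sign(delta)
                                    * np.round(np.abs(delta) * base)).astype(int)
    elif window_kind == "beat":
        trials_ev = eeg.events[eeg.events["kind"] == "trial"]
        n_win = int(round(beats_per_window * fs / beat_rate_hz))
        n_tokens = int(tokens["token_index"].max()) + 1
        trial_len = int(round(n_tokens * fs / base))
        starts_list, meta_rows = [], []
        for _, tr in trials_ev.iterrows():
            o = int(tr["sample_index"])
            j = 0
            while (j + 1) * n_win <= trial_len:
                s = o + int(round(j * beats_per_window * fs / beat_rate_hz))
                starts_list.append(s)
                cyc = int((j * n_win) // (spec.tokens_per_cycle * fs / base))
                meta_rows.append(dict(trial_index=int(tr["trial_index"]),
                                      cycle_index=cyc, token_index=-1,
                                      polarity=0, beat_window=j))
                j += 1
        starts = np.array(starts_list, dtype=int)
        meta = pd.DataFrame(meta_rows)
    else:
        raise ValueError(f"unknown window kind {window_kind!r}")

    if last_n_cycles is not None:
        keep = meta["cycle_index"] >= n_cycles_per_trial - last_n_cycles
        starts = starts[keep.to_numpy()]
        meta = meta[keep].reset_index(drop=True)

    in_range = (starts >= 0) & (starts + n_win <= eeg.n_samples)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} epochs outside the recording",
                      stacklevel=2)
        starts = starts[in_range]
        meta = meta[in_range].reset_index(drop=True)

    if channel_mask is None:
        channel_mask = np.ones(eeg.n_channels, dtype=bool)
    ch_idx = np.flatnonzero(channel_mask)
    labels = [eeg.channel_labels[i] for i in ch_idx]
    data = np.stack([eeg.data[np.ix_(ch_idx, np.arange(s, s + n_win))]
                     for s in starts]) if starts.size else np.empty(
                         (0, ch_idx.size, n_win))

    if trial_info is not None:
        meta = meta.merge(trial_info, on="trial_index", how="left",
                          suffixes=("", "_trial"))
    return EpochSet(data, fs, window_kind, meta, labels)
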