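"""Sustained pattern-recognition-potential pipeline.

The slow, non-synchronized counterpart of the phase-locking analyses: a
sustained scalp potential that, in earlier regularity-detection work,
rises when a random tone sequence switches to a repeating pattern.  The
pipeline (in this order): band-pass 0.1-110 Hz (5th-order zero-phase
Butterworth), downsample to 256 Hz, average-reference over scalp
channels, subtract the 1 s prestimulus baseline, reject trials whose
average power exceeds the across-trial mean by two standard deviations
(upper tail only), low-pass at 30 Hz, denoise with DSS biased toward
trial-reproducible activity (keeping the first five components), and take
the RMS across channels of the trial average.

The pattern statistic subtracts the mean sustained amplitude over the two
cycles before the transition point from the mean over the third and
fourth cycles after it; the same windows are applied to random-random
trials at the nominal transition.  A bootstrap floor re-evaluates the
statistic at uniformly drawn fake transition points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EEGData

__all__ = [
    "SustainedResult",
    "preprocess_sustained",
    "reject_high_power_trials",
    "lowpass_trials",
    "dss_trial_average",
    "sustained_timecourse",
    "transition_difference",
    "bootstrap_transition_floor",
    "sustained_pipeline",
]


def preprocess_sustained(eeg: EEGData, trial_duration_s: float,
                         band: tuple[float, float] = (0.1, 110.0),
                         order: int = 5, fs_out: float = 256.0,
                         prestim_s: float = 1.0,
                         channel_mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Slow-band preprocessing: filter, downsample, average-reference,
    epoch around trial onsets, baseline-correct.

    Returns ``(trials, times, fs_out)`` with ``trials`` shaped trials x
    channels x samples and ``times`` in seconds relative to trial onset
    (starting at ``-prestim_s``).
    """
    from .preprocess import zero_phase_bandpass

    fs = eeg.sample_rate_hz
    if channel_mask is None:
        channel_mask = eeg.scalp_mask
    data = zero_phase_bandpass(eeg.data[channel_mask], fs, band, order,
                               axis=1)

    frac = Fraction(fs_out / fs).limit_denominator(10000)
    data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                axis=1)
    data = data - data.mean(axis=0, keepdims=True)  # average reference

    onsets = eeg.events.loc[eeg.events["kind"] == "trial",
                            "sample_index"].to_numpy()
    onsets = np.round(onsets * fs_out / fs).astype(int)
    n_pre = int(round(prestim_s * fs_out))
    n_win = n_pre + int(round(trial_duration_s * fs_out))
    trials = []
    for o in onsets:
        if o - n_pre < 0:
            raise ValueError("insufficient prestimulus interval before trial")
        if o - n_pre + n_win > data.shape[1]:
            warnings.warn("trial extends past recording; dropped",
                          stacklevel=2)
            continue
        ep = data[:, o - n_pre:o - n_pre + n_win].copy()
        ep -= ep[:, :n_pre].mean(axis=1, keepdims=True)
        trials.append(ep)
    times = (np.arange(n_win) - n_pre) / fs_out
    return np.stack(trials), times, fs_out


def reject_high_power_trials(trials: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass rejection of trials whose mean power exceeds the
    across-trial mean by two standard deviations (power excesses only;
    unusually quiet trials are kept).

    Returns (retained trials, boolean keep-mask).
    """
    if trials.shape[0] < 5:
        raise ValueError("need at least 5 trials")
    power = np.mean(trials ** 2, axis=(1, 2))
    sd = power.std(ddof=1)
    keep = power <= power.mean() + 2 * sd
    return trials[keep], keep


def lowpass_trials(trials: np.ndarray, fs: float, cutoff_hz: float = 30.0,
                   order: int = 5) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, trials, axis=-1)


def dss_trial_average(trials: np.ndarray, n_keep: int = 5,
                      rank_tol: float = 1e-9,
                      return_components: bool = False):
    """Denoising source separation biased toward trial-reproducible
    activity.

    Whiten by the total covariance (discarding dimensions whose
    eigenvalues fall below ``rank_tol`` relative to the largest), rank
    whitened directions by the covariance of the across-trial average,
    and reconstruct the sensor data from the first ``n_keep`` components.
    """
    n_trials, n_ch, n_samp = trials.shape
    x = trials.transpose(1, 0, 2).reshape(n_ch, -1)
    x = x - x.mean(axis=1, keepdims=True)
    c0 = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(c0)
    keep = evals > rank_tol * evals.max()
    rank = int(keep.sum())
    if rank < n_keep:
        warnings.warn(f"data rank {rank} below n_keep={n_keep}; "
                      "keeping available rank", stacklevel=2)
    whitener = evecs[:, keep] / np.sqrt(evals[keep])  # channels x rank

    avg = trials.mean(axis=0)
    avg = avg - avg.mean(axis=1, keepdims=True)
    c1 = avg @ avg.T / n_samp
    c1w = whitener.T @ c1 @ whitener
    bias_evals, q = np.linalg.eigh(c1w)
    order = np.argsort(bias_evals)[::-1]
    q = q[:, order]

    unmix = whitener @ q            # channels x rank; comps = unmix.T @ x
    mix = np.linalg.pinv(unmix.T)   # channels x rank; x_hat = mix @ comps
    k = min(n_keep, rank)
    proj = mix[:, :k] @ unmix[:, :k].T  # sensor-space projector
    denoised = np.einsum("ij,tjs->tis", proj, trials)
    if return_components:
        comps = np.einsum("jc,tjs->tcs", unmix, trials)
        return denoised, comps, unmix, mix
    return denoised


def sustained_timecourse(trials: np.ndarray) -> np.ndarray:
    """RMS across channels of the across-trial average."""
    avg = trials.mean(axis=0)
    return np.sqrt(np.mean(avg ** 2, axis=0))


def transition_difference(timecourse: np.ndarray, times: np.ndarray,
                          transition_time_s: float,
                          cycle_duration_s: float) -> float:
    """Post-minus-pre sustained amplitude around a transition point:
    mean over [transition + 2T, transition + 4T) minus mean over
    [transition - 2T, transition), with T one cycle."""
    t, tc = np.asarray(times), np.asarray(timecourse)
    pre = (t >= transition_time_s - 2 * cycle_duration_s) & (t < transition_time_s)
    post = (t >= transition_time_s + 2 * cycle_duration_s) & \
           (t < transition_time_s + 4 * cycle_duration_s)
    if not pre.any() or not post.any() \
            or transition_time_s - 2 * cycle_duration_s < t[0] \
            or transition_time_s + 4 * cycle_duration_s > t[-1] + (t[1] - t[0]):
        raise ValueError("transition windows fall outside the trial")
    return float(tc[post].mean() - tc[pre].mean())


def bootstrap_transition_floor(timecourse: np.ndarray, times: np.ndarray,
                               cycle_duration_s: float,
                               rng: np.random.Generator,
                               n_boot: int = 1000,
                               valid_range_s: tuple[float, float] | None = None
                               ) -> np.ndarray:
    """Null distribution of the transition statistic at uniformly drawn
    fake transition points."""
    t = np.asarray(times)
    lo = (valid_range_s[0] if valid_range_s
          else t[0] + 2 * cycle_duration_s)
    hi = (valid_range_s[1] if valid_range_s
          else t[-1] - 4 * cycle_duration_s)
    if hi <= lo:
        raise ValueError("trial too short for bootstrap transitions")
    draws = rng.uniform(lo, hi, size=n_boot)
    return np.array([transition_difference(timecourse, times, d,
                                           cycle_duration_s)
                     for d in draws])


@dataclass
class SustainedResult:
    timecourse: np.ndarray
    times: np.ndarray
    sample_rate_hz: float
    statistic: float
    floor: np.ndarray
    n_trials_used: int

    def floor_envelope(self, level: float = 95.0) -> tuple[float, float]:
        half = (100.0 - level) / 2.0
        return (float(np.percentile(self.floor, half)),
                float(np.percentile(self.floor, 100.0 - half)))


def sustained_pipeline(eeg: EEGData, trial_duration_s: float,
                       transition_time_s: float, cycle_duration_s: float,
                       rng: np.random.Generator, n_keep: int = 5,
                       n_boot: int = 1000, prestim_s: float = 1.0,
                       channel_mask: np.ndarray | None = None,
                       trace: list[str] | None = None) -> SustainedResult:
    """End-to-end sustained-response analysis in the canonical stage
    order.  ``trace``, when given, records the stage names as they run
    (used by the order-fidelity integration test)."""

    def mark(name: str) -> None:
        if trace is not None:
            trace.append(name)

    mark("filter+downsample+reref+baseline")
    trials, times, fs = preprocess_sustained(
        eeg, trial_duration_s, prestim_s=prestim_s,
        channel_mask=channel_mask)
    mark("reject")
    trials, keep = reject_high_power_trials(trials)
    mark("lowpass30")
    trials = lowpass_trials(trials, fs)
    mark("dss")
    trials = dss_trial_average(trials, n_keep=n_keep)
    mark("rms")
    tc = sustained_timecourse(trials)
    mark("statistic")
    stat = transition_difference(tc, times, transition_time_s,
                                 cycle_duration_s)
    mark("bootstrap")
    floor = bootstrap_transition_floor(tc, times, cycle_duration_s, rng,
                                       n_boot=n_boot)
    return SustainedResult(tc, times, fs, stat, floor, int(keep.sum()))
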