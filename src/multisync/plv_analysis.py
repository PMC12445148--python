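"""Phase-locking value spectra, noise floors, and derived statistics.

For each channel and FFT bin the phase-locking value (PLV) is the length
of the mean unit phasor of the bin's phase across epochs; the reported
spectrum is the root mean square of the per-channel PLVs across retained
channels.  Because every stimulus rate is an integer multiple of the base
rate and epoch windows are whole numbers of base-rate periods, each
response frequency falls exactly on a bin center, so phases are taken
from a plain rectangular-window FFT (an optional Hann window is provided
for imported recordings whose rates are not bin-centered).

For N epochs of pure noise the per-channel PLV has expectation
``sqrt(pi / (4 N))`` — the mean resultant length of N uniform phasors —
which is why comparisons between conditions with unequal trial counts
subsample the larger sets (600 bootstrap iterations by default) down to
the smallest count before averaging.

Carrier-locked (FFR) responses flip sign with stimulus polarity while
envelope-locked responses do not.  The default FFR statistic therefore
pairs consecutive opposite-polarity cycle epochs and subtracts their
waveforms before the PLV: envelope-locked components cancel and
carrier-locked components add.  The literal alternative — per-channel
PLV(positive) minus PLV(negative) — is also provided; its expectation is
near zero for any polarity-symmetric response, which is why it is not
the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .target_stimulus import StimulusSpec

__all__ = [
    "PLVSpectrum",
    "AsymmetryResult",
    "plv_spectrum",
    "ffr_plv",
    "stimulus_related_freqs",
    "noise_floor",
    "equalize_and_average",
    "ecfr_by_delta",
    "asymmetry_index",
    "participant_asymmetry",
]


@dataclass
class PLVSpectrum:
    """PLV per frequency bin: RMS across channels, with the per-channel
    matrix retained for diagnostics."""

    freqs_hz: np.ndarray
    plv: np.ndarray
    per_channel: np.ndarray  # channels x bins
    n_epochs: int
    window_duration_s: float

    @property
    def resolution_hz(self) -> float:
        return 1.0 / self.window_duration_s

    def bin_of(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - freq_hz)))

    def value_at(self, freq_hz: float) -> float:
        return float(self.plv[self.bin_of(freq_hz)])

    def to_frame(self, **extra) -> pd.DataFrame:
        df = pd.DataFrame(dict(freq_hz=self.freqs_hz, plv=self.plv))
        df["n_epochs"] = self.n_epochs
        for k, v in extra.items():
            df[k] = v
        return df


def _phasors(data: np.ndarray, window: str = "rect") -> np.ndarray:
    """Unit phasors of the FFT of each epoch (epochs x channels x bins).

    Bins with (numerically) zero magnitude get a zero phasor so they pull
    the PLV toward zero instead of injecting an arbitrary phase.
    """
    if window == "hann":
        data = data * np.hanning(data.shape[-1])
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(data, axis=-1)
    mag = np.abs(spec)
    out = np.zeros_like(spec)
    nz = mag > 1e-300
    out[nz] = spec[nz] / mag[nz]
    return out


def _plv_from_phasors(ph: np.ndarray) -> np.ndarray:
    """Per-channel PLV (channels x bins) from epoch phasors."""
    return np.abs(ph.mean(axis=0))


def plv_spectrum(epochs: EpochSet, window: str = "rect") -> PLVSpectrum:
    """PLV spectrum of an epoch set: per-channel phase locking across
    epochs, RMS-aggregated over channels."""
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs for a PLV")
    ph = _phasors(epochs.data, window)
    per_channel = _plv_from_phasors(ph)
    plv = np.sqrt(np.mean(per_channel ** 2, axis=0))
    freqs = np.fft.rfftfreq(epochs.n_samples, 1 / epochs.sample_rate_hz)
    return PLVSpectrum(freqs, plv, per_channel, epochs.n_epochs,
                       epochs.window_duration_s)


def ffr_plv(pos: EpochSet, neg: EpochSet,
            mode: str = "waveform-difference") -> PLVSpectrum:
    """Carrier-locked PLV from positive- and negative-polarity epoch sets.

    ``"waveform-difference"`` (default): pair epochs across polarities,
    subtract waveforms, then PLV of the differences — envelope-locked
    activity cancels while carrier-locked activity doubles.
    ``"plv-difference"``: the literal signed per-channel PLV difference,
    RMS-aggregated; retained for comparison.
    """
    n = min(pos.n_epochs, neg.n_epochs)
    if n < 2:
        raise ValueError("need at least 2 epochs per polarity")
    if pos.n_epochs != neg.n_epochs:
        import warnings

        warnings.warn("unequal polarity counts; trailing epochs dropped",
                      stacklevel=2)
    if mode == "waveform-difference":
        diff = pos.data[:n] - neg.data[:n]
        ph = _phasors(diff)
        per_channel = _plv_from_phasors(ph)
    elif mode == "plv-difference":
        d = (_plv_from_phasors(_phasors(pos.data[:n]))
             - _plv_from_phasors(_phasors(neg.data[:n])))
        per_channel = d
    else:
        raise ValueError(f"unknown mode {mode!r}")
    plv = np.sqrt(np.mean(per_channel ** 2, axis=0))
    freqs = np.fft.rfftfreq(pos.n_samples, 1 / pos.sample_rate_hz)
    return PLVSpectrum(freqs, plv, per_channel, n, pos.window_duration_s)


def stimulus_related_freqs(spec: StimulusSpec | None = None,
                           beat_rate_hz: float | None = 3.9,
                           distractor_am_hz: float | None = 19.5,
                           mains_hz: tuple[float, ...] = (50.0, 60.0),
                           max_freq_hz: float = 4000.0,
                           n_harmonics: int = 4) -> np.ndarray:
    """Frequencies to exclude from noise-floor estimation: base-rate
    harmonics, AM rates with their first base-rate sidebands, the carrier
    and its AM sidebands, distractor beat/envelope rates with harmonics,
    and mains.  Deliberately targeted rather than exhaustive — excluding
    too liberally starves the floor estimate of bins at coarse
    resolutions."""
    spec = spec or StimulusSpec()
    freqs: set[float] = set()
    base = spec.base_rate_hz
    for k in range(1, n_harmonics + 1):
        freqs.add(k * base)
    for r in spec.am_rates_hz:
        for k in (-1, 0, 1):
            freqs.add(r + k * base)
    for r in spec.am_rates_hz:
        freqs.add(spec.carrier_hz - r)
        freqs.add(spec.carrier_hz + r)
    freqs.add(spec.carrier_hz)
    if beat_rate_hz:
        for k in range(1, n_harmonics + 1):
            freqs.add(k * beat_rate_hz)
    if distractor_am_hz:
        freqs.update((distractor_am_hz, 2 * distractor_am_hz))
    for f0 in mains_hz:
        freqs.update((f0, 2 * f0))
    return np.array(sorted(f for f in freqs if 0 < f <= max_freq_hz))


def noise_floor(spectrum: PLVSpectrum, freqs_of_interest,
                related_freqs: np.ndarray | None = None,
                spec: StimulusSpec | None = None,
                half_bins: int = 20) -> np.ndarray:
    """Noise floor at each frequency of interest: mean PLV over the
    ``+/- half_bins`` neighborhood, excluding every stimulus-related bin
    (and bin 0)."""
    if related_freqs is None:
        related_freqs = stimulus_related_freqs(spec)
    freqs_of_interest = np.atleast_1d(np.asarray(freqs_of_interest, float))
    related_bins = {0}
    for f in related_freqs:
        b = int(np.argmin(np.abs(spectrum.freqs_hz - f)))
        if abs(spectrum.freqs_hz[b] - f) <= spectrum.resolution_hz / 2 + 1e-9:
            related_bins.add(b)
    floors = np.empty(freqs_of_interest.shape)
    n_bins = spectrum.freqs_hz.size
    for i, f in enumerate(freqs_of_interest):
        b = spectrum.bin_of(f)
        lo, hi = max(0, b - half_bins), min(n_bins, b + half_bins + 1)
        eligible = [j for j in range(lo, hi) if j not in related_bins]
        if not eligible:
            raise ValueError(f"no stimulus-unrelated bins near {f} Hz")
        floors[i] = float(np.mean(spectrum.plv[eligible]))
    return floors


def equalize_and_average(epoch_sets: dict[str, EpochSet],
                         rng: np.random.Generator,
                         n_iter: int = 600,
                         window: str = "rect") -> dict[str, PLVSpectrum]:
    """PLV per condition with trial counts equalized by bootstrap
    subsampling.

    Conditions with more epochs than the smallest set are randomly
    subsampled to the minimum count on each of ``n_iter`` iterations and
    the per-channel PLVs averaged over iterations, keeping every
    condition's noise floor at the same effective epoch count.  Sets
    already at the minimum count are computed directly.
    """
    counts = {k: es.n_epochs for k, es in epoch_sets.items()}
    m = min(counts.values())
    if m < 2:
        raise ValueError("smallest condition has fewer than 2 epochs")
    out: dict[str, PLVSpectrum] = {}
    for key, es in epoch_sets.items():
        if es.n_epochs == m:
            out[key] = plv_spectrum(es, window)
            continue
        ph = _phasors(es.data, window)
        acc = np.zeros(ph.shape[1:])
        for _ in range(n_iter):
            idx = rng.choice(es.n_epochs, size=m, replace=False)
            acc += _plv_from_phasors(ph[idx])
        per_channel = acc / n_iter
        plv = np.sqrt(np.mean(per_channel ** 2, axis=0))
        freqs = np.fft.rfftfreq(es.n_samples, 1 / es.sample_rate_hz)
        out[key] = PLVSpectrum(freqs, plv, per_channel, m,
                               es.window_duration_s)
    return out


def ecfr_by_delta(two_token: EpochSet, rng: np.random.Generator,
                  spec: StimulusSpec | None = None,
                  n_iter: int = 600) -> pd.DataFrame:
    """Envelope-change PLV at the base rate, grouped by the signed AM step
    spanned by each two-token epoch, with class counts equalized.

    Returns a DataFrame (delta_m, delta_hz_nominal, n_epochs, n_effective,
    plv) sorted by signed step.
    """
    spec = spec or StimulusSpec()
    if "delta_m" not in two_token.meta.columns:
        raise ValueError("epochs lack AM-step labels; use two-token windows")
    groups = {int(d): two_token.select((two_token.meta["delta_m"] == d)
                                       .to_numpy())
              for d in sorted(two_token.meta["delta_m"].unique())}
    spectra = equalize_and_average(groups, rng, n_iter=n_iter)
    m_eff = min(g.n_epochs for g in groups.values())
    rows = []
    for d, g in groups.items():
        sp = spectra[d]
        rows.append(dict(
            delta_m=d,
            delta_hz_nominal=int(np.sign(d) * round(abs(d) * spec.base_rate_hz)),
            n_epochs=g.n_epochs, n_effective=m_eff,
            plv=sp.value_at(spec.base_rate_hz)))
    return pd.DataFrame(rows).sort_values("delta_m").reset_index(drop=True)


@dataclass
class AsymmetryResult:
    component: str
    value: float
    included: bool
    reason: str = ""


def asymmetry_index(correct: float, incorrect: float) -> float:
    """(C - I) / (C + I); NaN when both are zero."""
    s = correct + incorrect
    if s == 0:
        return float("nan")
    return (correct - incorrect) / s


def participant_asymmetry(component: str, plv_correct: float,
                          plv_incorrect: float, floor: float,
                          error_rate: float,
                          min_error_rate: float = 0.15) -> AsymmetryResult:
    """Asymmetry index with the participant-inclusion rules applied:
    enough error trials to estimate the incorrect-trial PLV, and at least
    one of the two category PLVs above the noise floor."""
    if error_rate < min_error_rate:
        return AsymmetryResult(component, float("nan"), False,
                               "fewer than the required fraction of errors")
    if max(plv_correct, plv_incorrect) <= floor:
        return AsymmetryResult(component, float("nan"), False,
                               "neither category above the noise floor")
    value = asymmetry_index(plv_correct, plv_incorrect)
    if np.isnan(value):
        return AsymmetryResult(component, value, False, "C + I = 0")
    return AsymmetryResult(component, value, True)
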