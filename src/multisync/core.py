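"""Shared containers: waveforms, event tables, and multichannel EEG data.

Events are kept as plain :class:`pandas.DataFrame` objects with a fixed
column convention so they serialize naturally to CSV and merge with trial
tables.  Expected columns (a subset may be present depending on context)::

    onset_s       float   event onset in seconds (stimulus- or recording-time)
    sample_index  int     onset in samples of the carrying signal
    kind          str     one of {"trial", "cycle", "token", "note", "rest"}
    trial_index   int
    cycle_index   int     cycle index within the trial
    token_index   int     token index within the trial
    am_multiple   int     integer AM multiple of the base rate (tokens)
    am_hz         float   true AM rate in Hz (tokens)
    am_nominal_hz int     rate as conventionally printed (e.g. 27 for 27.2)
    polarity      int     +1 / -1
    freq_hz       float   note frequency (melody events)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Waveform", "EEGData", "write_wav", "read_wav"]


@dataclass
class Waveform:
    """A single-channel audio signal with its sample rate.

    Samples are dimensionless amplitudes; stimulus synthesis peak-normalizes
    to ``|x| <= 1`` so waveforms can be written directly to WAV.
    """

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def peak_normalized(self) -> "Waveform":
        peak = np.max(np.abs(self.samples)) if self.n_samples else 0.0
        if peak == 0:
            return Waveform(self.samples.copy(), self.sample_rate_hz)
        return Waveform(self.samples / peak, self.sample_rate_hz)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def write_wav(path, wave: Waveform) -> None:
    """Write a waveform as a float32 WAV file."""
    from scipy.io import wavfile

    wavfile.write(path, int(round(wave.sample_rate_hz)),
                  wave.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.dtype.kind == "i":  # pragma: no cover - depends on writer
        data = data / np.iinfo(data.dtype).max
    if data.ndim > 1:
        data = data[:, 0]
    return Waveform(data, float(rate))


@dataclass
class EEGData:
    """Multichannel EEG: channels x samples with labels and an event table.

    Amplitudes are in microvolts.  ``events`` follows the column convention
    documented in this module; ``mastoid_labels`` names the reference
    electrodes carried alongside the scalp channels.
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    events: pd.DataFrame
    mastoid_labels: tuple[str, ...] = ("M1", "M2")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        if "sample_index" in self.events.columns and len(self.events):
            idx = self.events["sample_index"].to_numpy()
            if (idx < 0).any() or (idx >= self.n_samples).any():
                raise ValueError("event sample indices out of range")
            if not np.all(np.diff(idx) >= 0):
                self.events = self.events.sort_values(
                    "sample_index", kind="stable").reset_index(drop=True)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp_mask(self) -> np.ndarray:
        return np.array([lab not in self.mastoid_labels
                         for lab in self.channel_labels])

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy_with(self, **kwargs) -> "EEGData":
        params = {f.name: getattr(self, f.name)
                  for f in dataclasses.fields(self)}
        params.update(kwargs)
        return EEGData(**params)

    # --- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Save to an .npz archive with the event table embedded as CSV."""
        import io as _io

        buf = _io.StringIO()
        self.events.to_csv(buf, index=False)
        np.savez_compressed(
            path,
            data=self.data.astype(np.float32),
            sample_rate_hz=self.sample_rate_hz,
            channel_labels=np.array(self.channel_labels),
            mastoid_labels=np.array(self.mastoid_labels),
            events_csv=np.array(buf.getvalue()),
        )

    @classmethod
    def load(cls, path) -> "EEGData":
        import io as _io

        with np.load(path, allow_pickle=False) as npz:
            events = pd.read_csv(_io.StringIO(str(npz["events_csv"])))
            return cls(
                data=np.asarray(npz["data"], dtype=float),
                sample_rate_hz=float(npz["sample_rate_hz"]),
                channel_labels=[str(s) for s in npz["channel_labels"]],
                events=events,
                mastoid_labels=tuple(str(s) for s in npz["mastoid_labels"]),
            )

    def to_mne(self):
        """Export to an :class:`mne.io.RawArray` (volts) for interoperability."""
        import mne

        info = mne.create_info(
            ch_names=list(self.channel_labels),
            sfreq=self.sample_rate_hz,
            ch_types="eeg",
        )
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")

    @classmethod
    def from_mne(cls, raw, events: pd.DataFrame | str,
                 mastoid_labels: tuple[str, ...] = ("M1", "M2")) -> "EEGData":
        """Import from an MNE Raw object plus an event table (DataFrame or
        path to a sidecar CSV following this module's column convention)."""
        if isinstance(events, (str, bytes)) or hasattr(events, "__fspath__"):
            events = pd.read_csv(events)
        return cls(
            data=raw.get_data() * 1e6,
            sample_rate_hz=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            events=events,
            mastoid_labels=mastoid_labels,
        )
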