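"""Melodic distractor and melody-matched noise synthesis.

The melodic distractor is a sequence of pure-tone notes and rests whose
pitches avoid an energetic-masking "protected band" around the target's
spectral footprint: every note sits at least 1/3 octave below the lower
sideband of the fastest target AM rate, and the whole melody is duplicated
three octaves (x8) higher so the identical melody also appears at least
1/3 octave above the upper sideband.  Notes are amplitude modulated at a
slower SAM rate (19.5 Hz by default) with durations chosen so each note
holds an integer number of SAM periods, keeping note boundaries click-free.

Melodies here come from a seeded rule-based generator: a first-order
random walk over scale degrees of a diatonic key with whole-beat note and
rest durations, filtered to reject melodies that repeat a phrase several
times (repetition in the distractor must not be confusable with
repetition in the target).

The matched-noise distractor shares a melody's long-term magnitude
spectrum while destroying its note sequence: every distinct note frequency
is present for the entire stimulus as a stationary sinusoid with random
starting phase, scaled by the proportion of note-beats carrying that
pitch, and the whole complex is gated by the melody's note/rest + SAM
envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Waveform
from .target_stimulus import StimulusSpec

__all__ = [
    "ProtectedBand",
    "MelodySpec",
    "MelodyRejected",
    "band_edges",
    "compute_protected_band",
    "generate_melody",
    "transpose_and_duplicate",
    "render_melody",
    "make_matched_noise",
    "melody_to_csv",
    "melody_from_csv",
]

A4_HZ = 440.0
MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)


def midi_to_hz(midi: float) -> float:
    return A4_HZ * 2.0 ** ((midi - 69) / 12.0)


@dataclass(frozen=True)
class ProtectedBand:
    """Frequency region around the target that distractors must avoid."""

    low_band_max_hz: float
    high_band_min_hz: float

    def __post_init__(self) -> None:
        if self.low_band_max_hz > self.high_band_min_hz:
            raise ValueError("band edges out of order")


def band_edges(carrier_hz: float, max_am_hz: float,
               fraction_octave: float = 1 / 3) -> ProtectedBand:
    """Protected-band edges: a ``fraction_octave`` margin outside the
    carrier +/- max-AM sidebands."""
    return ProtectedBand(
        low_band_max_hz=(carrier_hz - max_am_hz) * 2.0 ** (-fraction_octave),
        high_band_min_hz=(carrier_hz + max_am_hz) * 2.0 ** (+fraction_octave),
    )


def compute_protected_band(spec: StimulusSpec | None = None,
                           fraction_octave: float = 1 / 3) -> ProtectedBand:
    spec = spec or StimulusSpec()
    return band_edges(spec.carrier_hz, max(spec.am_rates_hz), fraction_octave)


class MelodyRejected(ValueError):
    """Raised when a melody cannot satisfy the placement constraints."""


@dataclass(frozen=True)
class MelodySpec:
    """Note/rest sequence; pitches in Hz (``None`` = rest), durations in
    whole beats.

    ``register_multiple`` is set (to 8, i.e. three octaves) once the melody
    has been duplicated into its upper register.
    """

    events: tuple[tuple[float | None, int], ...]
    beat_rate_hz: float = 3.9
    note_am_rate_hz: float = 19.5
    register_multiple: int | None = None

    def __post_init__(self) -> None:
        ratio = self.note_am_rate_hz / self.beat_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "note_am_rate_hz must be an integer multiple of beat_rate_hz "
                "so every note holds whole SAM periods")
        for pitch, dur in self.events:
            if not (isinstance(dur, (int, np.integer)) and dur > 0):
                raise ValueError("durations must be positive whole beats")
            if pitch is not None and pitch <= 0:
                raise ValueError("pitches must be positive frequencies")

    @property
    def beat_duration_s(self) -> float:
        return 1.0 / self.beat_rate_hz

    @property
    def total_beats(self) -> int:
        return sum(d for _, d in self.events)

    @property
    def duration_s(self) -> float:
        return self.total_beats * self.beat_duration_s

    @property
    def pitches(self) -> tuple[float, ...]:
        return tuple(p for p, _ in self.events if p is not None)

    def sam_periods_per_note(self) -> list[int]:
        per_beat = self.note_am_rate_hz / self.beat_rate_hz
        return [int(round(per_beat * d)) for p, d in self.events
                if p is not None]


def _sideband_collision(pitches, am_rate_hz: float,
                        min_sep_hz: float) -> bool:
    """True if any note's SAM sideband falls within ``min_sep_hz`` of a
    different note frequency.

    Colliding lines would make the melody's spectrum depend on relative
    component phases, breaking the matched-noise contract (the noise
    randomizes phases), so such pitch sets are rejected at generation.
    """
    ps = np.array(sorted(set(pitches)))
    for f in ps:
        for sb in (f - am_rate_hz, f + am_rate_hz):
            if np.any((np.abs(ps - sb) < min_sep_hz) & (ps != f)):
                return True
    return False


def _phrase_repeats(pitch_seq: list[float], min_len: int = 3,
                    max_count: int = 2) -> bool:
    """True if any contiguous >=min_len-note phrase occurs more than
    ``max_count`` times."""
    n = len(pitch_seq)
    seen: dict[tuple, int] = {}
    for length in range(min_len, n // 2 + 1):
        seen.clear()
        for i in range(n - length + 1):
            key = tuple(pitch_seq[i:i + length])
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > max_count:
                return True
    return False


def generate_melody(rng: np.random.Generator,
                    n_events: int = 32,
                    band: ProtectedBand | None = None,
                    key_root_midi: int = 48,
                    scale: tuple[int, ...] = MAJOR_SCALE,
                    low_midi: int = 43, high_midi: int = 63,
                    rest_prob: float = 0.15,
                    duration_choices: tuple[int, ...] = (1, 1, 1, 2, 2, 4),
                    max_step: int = 3,
                    beat_rate_hz: float = 3.9,
                    note_am_rate_hz: float = 19.5,
                    min_line_sep_hz: float = 3.0,
                    min_pitch_beats: int = 2,
                    max_attempts: int = 500) -> MelodySpec:
    """Draw a melody by a first-order random walk over scale degrees.

    Pitches are 12-tone equal temperament within ``[low_midi, high_midi]``
    (the low register below the protected band with the default target).
    Candidates are regenerated until the phrase-repetition filter and,
    if ``band`` is given, the two-register placement constraint are met.
    """
    degrees = sorted({(oct_ * 12 + s + key_root_midi)
                      for oct_ in range(-1, 4) for s in scale})
    degrees = [d for d in degrees if low_midi <= d <= high_midi]
    if not degrees:
        raise ValueError("empty pitch set for the requested register")
    for _ in range(max_attempts):
        pos = int(rng.integers(len(degrees)))
        events: list[tuple[float | None, int]] = []
        pitch_seq: list[float] = []
        for _ in range(n_events):
            dur = int(rng.choice(duration_choices))
            if rng.random() < rest_prob and events and events[-1][0] is not None:
                events.append((None, dur))
                continue
            step = int(rng.integers(-max_step, max_step + 1))
            pos = int(np.clip(pos + step, 0, len(degrees) - 1))
            pitch = round(midi_to_hz(degrees[pos]), 6)
            events.append((pitch, dur))
            pitch_seq.append(pitch)
        if len(pitch_seq) < 4 or _phrase_repeats(pitch_seq):
            continue
        melody = MelodySpec(tuple(events), beat_rate_hz=beat_rate_hz,
                            note_am_rate_hz=note_am_rate_hz)
        # Every pitch must recur long enough to form a measurable spectral
        # line, or the matched-noise spectrum cannot be meaningfully equal.
        if min_pitch_beats:
            occ: dict[float, int] = {}
            for p, d in melody.events:
                if p is not None:
                    occ[p] = occ.get(p, 0) + d
            if occ and min(occ.values()) < min_pitch_beats:
                continue
        placed = melody
        if band is not None:
            try:
                placed = transpose_and_duplicate(melody, band)
            except MelodyRejected:
                continue
        # Spectral distinctness is judged at the performed register.
        if min_line_sep_hz and _sideband_collision(
                placed.pitches, note_am_rate_hz, min_line_sep_hz):
            continue
        return melody
    raise MelodyRejected(
        f"no admissible melody found in {max_attempts} attempts")


def transpose_and_duplicate(melody: MelodySpec, band: ProtectedBand,
                            register_multiple: int = 8) -> MelodySpec:
    """Shift the melody by whole octaves so it fits below the protected
    band while its x8 duplicate sits entirely above, then mark it
    two-register.

    Raises :class:`MelodyRejected` when no octave shift can place the
    melody (its span exceeds the usable window).
    """
    pitches = melody.pitches
    if not pitches:
        raise MelodyRejected("melody has no notes")
    lo, hi = min(pitches), max(pitches)
    # The note SAM spreads each tone by +/- the note AM rate; those
    # sidebands must stay outside the protected band as well.
    margin = melody.note_am_rate_hz
    # Prefer the smallest shift that places the melody.
    for octave in sorted(range(-6, 7), key=abs):
        factor = 2.0 ** octave
        if (hi * factor + margin <= band.low_band_max_hz
                and lo * factor * register_multiple - margin
                >= band.high_band_min_hz):
            events = tuple(
                (None if p is None else p * factor, d)
                for p, d in melody.events)
            return MelodySpec(events, melody.beat_rate_hz,
                              melody.note_am_rate_hz,
                              register_multiple=register_multiple)
    raise MelodyRejected("melody span does not fit the protected-band window")


def _beat_grid(melody: MelodySpec, sample_rate: float) -> np.ndarray:
    """Global sample indices of beat boundaries, rounded once."""
    return np.round(np.arange(melody.total_beats + 1)
                    * sample_rate / melody.beat_rate_hz).astype(int)


def _event_spans(melody: MelodySpec) -> list[tuple[float | None, int, int]]:
    """(pitch, first_beat, last_beat_exclusive) per event."""
    spans = []
    beat = 0
    for pitch, dur in melody.events:
        spans.append((pitch, beat, beat + dur))
        beat += dur
    return spans


def _sam_envelope(melody: MelodySpec, sample_rate: float) -> np.ndarray:
    """Note/rest gate times the per-note cosine-phase SAM envelope.

    Zero during rests; within notes, ``(1 - cos(2 pi r tau)) / 2`` with
    ``tau`` referenced to the note's ideal onset, so the envelope is zero
    at every note boundary.
    """
    grid = _beat_grid(melody, sample_rate)
    env = np.zeros(grid[-1])
    for pitch, b0, b1 in _event_spans(melody):
        if pitch is None:
            continue
        s0, s1 = grid[b0], grid[b1]
        tau = np.arange(s0, s1) / sample_rate - b0 / melody.beat_rate_hz
        env[s0:s1] = (1.0 - np.cos(2 * np.pi * melody.note_am_rate_hz * tau)) / 2.0
    return env


def render_melody(melody: MelodySpec, sample_rate: float
                  ) -> tuple[Waveform, pd.DataFrame]:
    """Render a melody to audio plus note/rest events.

    Each note is a pure tone; if the melody is two-register, the note and
    its ``register_multiple`` partner are summed at half amplitude each.
    The per-note SAM envelope guarantees click-free note boundaries.
    """
    grid = _beat_grid(melody, sample_rate)
    samples = np.zeros(grid[-1])
    rows = []
    reg = melody.register_multiple
    for pitch, b0, b1 in _event_spans(melody):
        s0, s1 = grid[b0], grid[b1]
        onset = s0 / sample_rate
        if pitch is None:
            rows.append(dict(onset_s=onset, sample_index=int(s0), kind="rest",
                             freq_hz=np.nan, duration_beats=b1 - b0))
            continue
        tau = np.arange(s0, s1) / sample_rate - b0 / melody.beat_rate_hz
        env = (1.0 - np.cos(2 * np.pi * melody.note_am_rate_hz * tau)) / 2.0
        # Tone phase runs on global time so repeated occurrences of a pitch
        # add coherently in the long-term spectrum (the matched-noise
        # contract depends on this); onsets stay click-free via the envelope.
        t = np.arange(s0, s1) / sample_rate
        if reg is None:
            tone = np.sin(2 * np.pi * pitch * t)
        else:
            tone = 0.5 * (np.sin(2 * np.pi * pitch * t)
                          + np.sin(2 * np.pi * pitch * reg * t))
        samples[s0:s1] = env * tone
        rows.append(dict(onset_s=onset, sample_index=int(s0), kind="note",
                         freq_hz=pitch, duration_beats=b1 - b0))
    return Waveform(samples, sample_rate), pd.DataFrame(rows)


def note_beat_proportions(melody: MelodySpec) -> dict[float, float]:
    """Fraction of note-carrying beats occupied by each distinct pitch."""
    counts: dict[float, int] = {}
    note_beats = 0
    for pitch, dur in melody.events:
        if pitch is None:
            continue
        counts[pitch] = counts.get(pitch, 0) + dur
        note_beats += dur
    if note_beats == 0:
        return {}
    return {p: c / note_beats for p, c in counts.items()}


def make_matched_noise(melody: MelodySpec, sample_rate: float,
                       rng: np.random.Generator) -> Waveform:
    """Synthesize the melody-matched noise distractor.

    A stationary complex of sinusoids — one per distinct note frequency
    (both registers), amplitude proportional to that pitch's beat-occupancy
    and starting phase randomized — multiplied by the melody's note/rest +
    SAM envelope.  The result shares the melody's long-term magnitude
    spectrum at the note frequencies but has a time-invariant spectral
    content during notes (a different spectrogram).
    """
    props = note_beat_proportions(melody)
    grid = _beat_grid(melody, sample_rate)
    n = grid[-1]
    t = np.arange(n) / sample_rate
    carrier = np.zeros(n)
    reg = melody.register_multiple
    amp_scale = 1.0 if reg is None else 0.5
    for pitch, prop in sorted(props.items()):
        freqs = (pitch,) if reg is None else (pitch, pitch * reg)
        for f in freqs:
            phase = rng.uniform(0, 2 * np.pi)
            carrier += amp_scale * prop * np.sin(2 * np.pi * f * t + phase)
    env = _sam_envelope(melody, sample_rate)
    return Waveform(carrier * env, sample_rate)


def component_magnitudes(wave: Waveform, freqs_hz,
                         model_freqs_hz=None) -> np.ndarray:
    """Spectral line magnitudes of ``wave`` at arbitrary frequencies.

    With ``model_freqs_hz=None`` this is the exact DTFT magnitude at each
    frequency (no bin scalloping).  When ``model_freqs_hz`` lists the full
    set of spectral lines known to be present (e.g. note frequencies plus
    their SAM sidebands), the amplitudes are instead estimated by harmonic
    regression — a joint least-squares fit of all lines — so that closely
    spaced lines are separated rather than allowed to interfere.
    """
    t = wave.times_s
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if model_freqs_hz is None:
        mags = np.empty(freqs.shape)
        for i, f in enumerate(freqs):
            mags[i] = np.abs(np.sum(wave.samples * np.exp(-2j * np.pi * f * t)))
        return mags / wave.n_samples
    model = np.unique(np.concatenate([freqs,
                                      np.asarray(model_freqs_hz, float)]))
    design = np.empty((t.size, 2 * model.size))
    design[:, 0::2] = np.cos(2 * np.pi * model[None, :] * t[:, None])
    design[:, 1::2] = np.sin(2 * np.pi * model[None, :] * t[:, None])
    coef, *_ = np.linalg.lstsq(design, wave.samples, rcond=None)
    amps = np.hypot(coef[0::2], coef[1::2]) / 2.0  # DTFT/N convention
    idx = [int(np.argmin(np.abs(model - f))) for f in freqs]
    return amps[idx]


def melody_line_freqs(melody: MelodySpec) -> np.ndarray:
    """Every spectral line a melody (or its matched noise) contains: each
    distinct note frequency in both registers plus its +/- SAM-rate
    sidebands."""
    base = sorted(set(melody.pitches))
    reg = melody.register_multiple
    freqs: list[float] = []
    for p in base:
        for f in ((p,) if reg is None else (p, p * reg)):
            freqs.extend((f - melody.note_am_rate_hz, f,
                          f + melody.note_am_rate_hz))
    return np.unique(np.array(freqs))


# --- serialization --------------------------------------------------------

def melody_to_csv(melody: MelodySpec, path) -> None:
    df = pd.DataFrame(
        [("REST" if p is None else p, d) for p, d in melody.events],
        columns=["pitch_hz", "duration_beats"])
    df.to_csv(path, index=False)


def melody_from_csv(path, beat_rate_hz: float = 3.9,
                    note_am_rate_hz: float = 19.5,
                    register_multiple: int | None = None) -> MelodySpec:
    df = pd.read_csv(path)
    events = tuple(
        (None if str(p).upper() == "REST" else float(p), int(d))
        for p, d in zip(df["pitch_hz"], df["duration_beats"]))
    return MelodySpec(events, beat_rate_hz, note_am_rate_hz,
                      register_multiple=register_multiple)
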