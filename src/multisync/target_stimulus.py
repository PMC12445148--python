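"""Random/patterned concatenated-SAM-tone target stimulus.

The target is a stream of sinusoidally amplitude-modulated (SAM) tone
tokens sharing one carrier.  All rates are integer multiples of a single
base (token presentation) rate, so every token contains an exact integer
number of carrier and modulator periods.  With the defaults the base rate
is 6.8 Hz, the carrier is 76 x 6.8 = 516.8 Hz and the five AM rates are
{4, 6, 8, 10, 12} x 6.8 = 27.2, 40.8, 54.4, 68 and 81.6 Hz (conventionally
printed as 27, 41, 54, 68 and 82 Hz).  Because both carrier and modulator
complete integer periods within a token, and the cosine-phase modulator is
zero-valued at both token endpoints, tokens concatenate without amplitude
discontinuities at any ordering.

Tokens are arranged into cycles, each cycle being a permutation of the
available AM rates.  A stimulus is either "random-random" (a fresh
pseudo-random permutation each cycle, never starting with the previous
cycle's final token) or "random-pattern" (random cycles up to a transition
point, then one permutation repeated verbatim).  Stimulus polarity
alternates between cycles so that carrier-locked and envelope-locked
neural responses can later be separated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import Waveform

__all__ = [
    "StimulusSpec",
    "CyclePlan",
    "make_sam_token",
    "enumerate_patterns",
    "draw_random_cycle",
    "make_cycle_plan",
    "build_target",
    "spec_from_yaml",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Arithmetic skeleton of the target stimulus.

    All component rates are integer multiples of ``base_rate_hz``; this is
    the constraint that guarantees click-free token concatenation and exact
    FFT-bin placement of every response frequency downstream.
    """

    base_rate_hz: float = 6.8
    carrier_multiple: int = 76
    am_multiples: tuple[int, ...] = (4, 6, 8, 10, 12)
    sample_rate_hz: float = 44100.0
    mod_depth: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be positive")
        if not (isinstance(self.carrier_multiple, int)
                and self.carrier_multiple > 0):
            raise ValueError("carrier_multiple must be a positive integer")
        if not all(isinstance(m, int) and m > 0 for m in self.am_multiples):
            raise ValueError("am_multiples must be positive integers")
        if len(set(self.am_multiples)) != len(self.am_multiples):
            raise ValueError("am_multiples must be distinct")
        if not 0 < self.mod_depth <= 1:
            raise ValueError("mod_depth must lie in (0, 1]")

    @property
    def tokens_per_cycle(self) -> int:
        return len(self.am_multiples)

    @property
    def carrier_hz(self) -> float:
        return self.carrier_multiple * self.base_rate_hz

    @property
    def am_rates_hz(self) -> tuple[float, ...]:
        return tuple(m * self.base_rate_hz for m in self.am_multiples)

    @property
    def am_nominal_hz(self) -> tuple[int, ...]:
        """Rates as conventionally printed (nearest integer Hz)."""
        return tuple(int(round(r)) for r in self.am_rates_hz)

    @property
    def token_duration_s(self) -> float:
        return 1.0 / self.base_rate_hz

    @property
    def cycle_duration_s(self) -> float:
        return self.tokens_per_cycle / self.base_rate_hz


def spec_from_yaml(path) -> tuple[StimulusSpec, int]:
    """Load a :class:`StimulusSpec` plus mandatory RNG seed from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("stimulus config must declare an RNG seed")
    seed = int(cfg.pop("seed"))
    if "am_multiples" in cfg:
        cfg["am_multiples"] = tuple(int(m) for m in cfg["am_multiples"])
    if "carrier_multiple" in cfg:
        cfg["carrier_multiple"] = int(cfg["carrier_multiple"])
    return StimulusSpec(**cfg), seed


def make_sam_token(am_index: int, spec: StimulusSpec,
                   n_samples: int | None = None,
                   start_time_s: float = 0.0) -> Waveform:
    """Render one SAM token.

    The modulator is cosine-phase starting at its minimum, so the envelope
    is zero at both endpoints:  ``env = depth * (1 - cos(2 pi m f t)) / 2``
    with ``m`` the token's AM multiple of base rate ``f``; the carrier is
    ``sin(2 pi M f t)``.  ``start_time_s`` offsets the sample grid (used by
    :func:`build_target` to keep long stimuli on one global time axis) while
    phases remain referenced to the token start.
    """
    try:
        m = spec.am_multiples[am_index]
    except (IndexError, TypeError) as exc:
        raise IndexError(f"am_index {am_index!r} invalid for spec") from exc
    if n_samples is None:
        n_samples = int(round(spec.sample_rate_hz * spec.token_duration_s))
    t = start_time_s + np.arange(n_samples) / spec.sample_rate_hz
    env = spec.mod_depth * (1.0 - np.cos(2 * np.pi * m * spec.base_rate_hz * t)) / 2.0
    carrier = np.sin(2 * np.pi * spec.carrier_multiple * spec.base_rate_hz * t)
    return Waveform(env * carrier, spec.sample_rate_hz)


def enumerate_patterns(spec: StimulusSpec) -> list[tuple[int, ...]]:
    """All permutations of the AM indices, in lexicographic order."""
    return list(itertools.permutations(range(spec.tokens_per_cycle)))


def draw_random_cycle(rng: np.random.Generator, n_tokens: int = 5,
                      prev_last: int | None = None) -> tuple[int, ...]:
    """Draw a uniform random permutation of AM indices.

    When ``prev_last`` is given, the draw is uniform over the permutations
    whose first element differs from it, so no token is heard twice in a
    row across a cycle boundary.  Rejection sampling keeps the conditional
    distribution exactly uniform on the allowed set.
    """
    while True:
        perm = tuple(int(i) for i in rng.permutation(n_tokens))
        if prev_last is None or perm[0] != prev_last:
            return perm


@dataclass
class CyclePlan:
    """Token ordering for one stimulus: a list of per-cycle permutations.

    ``context`` is "random-random" or "random-pattern"; for the latter,
    ``transition_cycle`` marks the first cycle of the repeating pattern.
    Polarity alternates +1/-1 starting from ``first_polarity``.
    """

    cycles: list[tuple[int, ...]]
    context: str
    transition_cycle: int | None = None
    first_polarity: int = 1

    def __post_init__(self) -> None:
        if self.context not in ("random-random", "random-pattern"):
            raise ValueError(f"unknown context {self.context!r}")
        n_tok = len(self.cycles[0]) if self.cycles else 0
        for cyc in self.cycles:
            if sorted(cyc) != list(range(n_tok)):
                raise ValueError(f"cycle {cyc!r} is not a permutation")
        for prev, nxt in zip(self.cycles, self.cycles[1:]):
            if nxt[0] == prev[-1]:
                raise ValueError(
                    "cycle may not start with the previous cycle's last token")
        if self.context == "random-pattern":
            if self.transition_cycle is None:
                raise ValueError("random-pattern plan needs transition_cycle")
            tail = self.cycles[self.transition_cycle:]
            if any(c != tail[0] for c in tail):
                raise ValueError("cycles after transition must be identical")
        if self.first_polarity not in (+1, -1):
            raise ValueError("first_polarity must be +1 or -1")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def polarities(self) -> list[int]:
        return [self.first_polarity * (-1) ** i for i in range(self.n_cycles)]

    def token_sequence(self) -> list[int]:
        return [tok for cyc in self.cycles for tok in cyc]


def make_cycle_plan(context: str, rng: np.random.Generator,
                    spec: StimulusSpec | None = None,
                    n_cycles: int = 12, n_random_prefix: int = 4,
                    pattern: tuple[int, ...] | None = None) -> CyclePlan:
    """Draw a stimulus plan: ``n_random_prefix`` random cycles, then either
    more random cycles or a repeated pattern permutation.

    For a random-pattern plan the prefix is redrawn (last cycle only) until
    its final token differs from the pattern's first token, preserving the
    no-immediate-repeat rule at the transition.
    """
    spec = spec or StimulusSpec()
    n_tok = spec.tokens_per_cycle
    if context == "random-random":
        cycles: list[tuple[int, ...]] = []
        for _ in range(n_cycles):
            prev_last = cycles[-1][-1] if cycles else None
            cycles.append(draw_random_cycle(rng, n_tok, prev_last))
        return CyclePlan(cycles, context)
    if context == "random-pattern":
        if pattern is None:
            pattern = draw_random_cycle(rng, n_tok)
        pattern = tuple(pattern)
        cycles = []
        for _ in range(n_random_prefix):
            prev_last = cycles[-1][-1] if cycles else None
            cycles.append(draw_random_cycle(rng, n_tok, prev_last))
        while cycles and cycles[-1][-1] == pattern[0]:
            prev_last = cycles[-2][-1] if len(cycles) > 1 else None
            cycles[-1] = draw_random_cycle(rng, n_tok, prev_last)
        cycles.extend([pattern] * (n_cycles - n_random_prefix))
        return CyclePlan(cycles, context, transition_cycle=n_random_prefix)
    raise ValueError(f"unknown context {context!r}")


def build_target(plan: CyclePlan, spec: StimulusSpec | None = None
                 ) -> tuple[Waveform, pd.DataFrame]:
    """Render a full target stimulus and its event table.

    Token boundaries live on a single global sample grid (sample
    ``round(k * fs / base_rate)`` for token k) and every token's phases are
    referenced to its ideal start time ``k / base_rate``, so the rendered
    stream is the exact sampling of a continuous, click-free waveform.
    Each cycle's waveform is multiplied by its alternating polarity sign.

    Returns the peak-normalized waveform and an event DataFrame with one
    "cycle" row per cycle and one "token" row per token.
    """
    spec = spec or StimulusSpec()
    n_tok = spec.tokens_per_cycle
    if plan.cycles and len(plan.cycles[0]) != n_tok:
        raise ValueError("plan cycle length does not match spec")
    fs = spec.sample_rate_hz
    base = spec.base_rate_hz
    total_tokens = plan.n_cycles * n_tok
    bounds = np.round(np.arange(total_tokens + 1) * fs / base).astype(int)
    samples = np.zeros(bounds[-1])
    rows = []
    polarities = plan.polarities
    k = 0
    for ci, cyc in enumerate(plan.cycles):
        pol = polarities[ci]
        for pi, am_index in enumerate(cyc):
            b0, b1 = bounds[k], bounds[k + 1]
            tok = make_sam_token(am_index, spec, n_samples=b1 - b0,
                                 start_time_s=b0 / fs - k / base)
            samples[b0:b1] = pol * tok.samples
            m = spec.am_multiples[am_index]
            common = dict(onset_s=b0 / fs, sample_index=int(b0),
                          cycle_index=ci, token_index=k, polarity=pol)
            if pi == 0:
                rows.append(dict(kind="cycle", am_multiple=-1,
                                 am_hz=np.nan, am_nominal_hz=-1, **common))
            rows.append(dict(kind="token", am_multiple=m,
                             am_hz=m * base,
                             am_nominal_hz=int(round(m * base)), **common))
            k += 1
    events = pd.DataFrame(rows)
    return Waveform(samples, fs).peak_normalized(), events
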