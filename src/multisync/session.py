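"""Trial blocks, SNR mixing, speeded scoring, and behavioral summaries.

A block pairs the target with one distractor condition (or none) and
balances the two stimulus contexts: "random-pattern" trials, which switch
to a repeating cycle partway through, and "random-random" trials, which
stay random throughout.  In the laboratory block every one of the 120
pattern permutations serves as the repeated cycle of exactly one
random-pattern trial.  The speeded variant additionally interleaves
distractor signal-to-noise ratios.

Scoring implements a speed/accuracy game: a hidden counter starts at
1,000 points at audio onset and counts down linearly over the stimulus
plus the response window; a response earns (correct) or forfeits
(incorrect) the points remaining, and a missed response costs a flat 350
points.

Percent-correct summaries are reported in rationalized arcsine units
(RAU), the variance-stabilizing transform standard in speech audiometry:
``theta = asin(sqrt(X/(N+1))) + asin(sqrt((X+1)/(N+1)))`` and
``RAU = (146/pi) * theta - 23``, which maps 0..100% roughly onto -23..123
with near-uniform variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import Waveform

__all__ = [
    "CONDITIONS",
    "TrialSpec",
    "BlockPlan",
    "MixResult",
    "mix_at_snr",
    "build_block",
    "build_speeded_block",
    "score_trial",
    "rau",
    "summarize_behavior",
]

CONDITIONS = ("target-alone", "target+melody", "target+noise")


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int
    condition: str
    snr_db: float | None
    context: str
    pattern_id: int | None  # permutation index for random-pattern trials

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.context not in ("random-random", "random-pattern"):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class BlockPlan:
    trials: list[TrialSpec]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def context_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.context] = counts.get(t.context, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])

    def to_yaml(self, path) -> None:
        payload = [dict(trial_index=t.trial_index, condition=t.condition,
                        snr_db=t.snr_db, context=t.context,
                        pattern_id=t.pattern_id) for t in self.trials]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BlockPlan":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls([TrialSpec(**row) for row in payload])


@dataclass
class MixResult:
    """Mixed waveform plus the gains applied to reach it."""

    waveform: Waveform
    distractor_gain: float
    normalization_gain: float


def mix_at_snr(target: Waveform, distractor: Waveform | None,
               snr_db: float | None, rms_mode: str = "full",
               normalize: bool = True) -> MixResult:
    """Mix target and distractor at a broadband RMS signal-to-noise ratio.

    The distractor is padded or cropped to the target length, scaled so
    that ``RMS(target) / RMS(scaled distractor) = 10**(snr_db/20)``, then
    summed and (by default) peak-normalized.  ``rms_mode`` selects the RMS
    reference for the distractor: "full" uses the whole duration (silent
    rests dilute the RMS), "active" uses only the distractor's non-silent
    samples.

    A ``None`` distractor (target-alone) returns the target untouched
    except for normalization.
    """
    if distractor is None:
        wave = target.peak_normalized() if normalize else target
        peak = np.max(np.abs(target.samples)) or 1.0
        return MixResult(wave, 0.0, 1.0 / peak if normalize else 1.0)
    if distractor.sample_rate_hz != target.sample_rate_hz:
        raise ValueError("sample rates must match")
    d = distractor.samples
    n = target.n_samples
    if d.size < n:
        d = np.pad(d, (0, n - d.size))
    else:
        d = d[:n]
    if rms_mode == "full":
        d_rms = float(np.sqrt(np.mean(d ** 2)))
    elif rms_mode == "active":
        active = np.abs(d) > 0
        d_rms = float(np.sqrt(np.mean(d[active] ** 2))) if active.any() else 0.0
    else:
        raise ValueError(f"unknown rms_mode {rms_mode!r}")
    if d_rms == 0:
        raise ValueError("distractor is silent: SNR undefined")
    gain = target.rms() / (d_rms * 10.0 ** (snr_db / 20.0))
    mixed = target.samples + gain * d
    peak = float(np.max(np.abs(mixed))) or 1.0
    norm = 1.0 / peak if normalize else 1.0
    return MixResult(Waveform(mixed * norm, target.sample_rate_hz),
                     gain, norm)


def build_block(rng: np.random.Generator, condition: str = "target+melody",
                snr_db: float | None = 12.0, n_patterns: int = 120,
                n_random: int | None = None) -> BlockPlan:
    """Laboratory block: ``n_patterns`` random-pattern trials (each pattern
    permutation used exactly once) and as many random-random trials,
    shuffled into one order."""
    if condition == "target-alone":
        snr_db = None
    n_random = n_patterns if n_random is None else n_random
    pattern_ids = rng.permutation(n_patterns)
    protos = ([("random-pattern", int(pid)) for pid in pattern_ids]
              + [("random-random", None)] * n_random)
    order = rng.permutation(len(protos))
    trials = [TrialSpec(i, condition, snr_db, *protos[j])
              for i, j in enumerate(order)]
    return BlockPlan(trials)


def build_speeded_block(rng: np.random.Generator,
                        snr_levels_db: tuple[float, ...] = (18, 12, 6, 0),
                        n_per_context: int = 120,
                        distractor_condition: str = "target+melody"
                        ) -> BlockPlan:
    """Speeded-task block: target-alone and each distractor SNR level
    interleaved, ``n_per_context`` trials per context in total, with the
    pattern permutations spread across all pattern trials."""
    levels: list[tuple[str, float | None]] = [("target-alone", None)]
    levels += [(distractor_condition, float(s)) for s in snr_levels_db]
    if n_per_context % len(levels):
        raise ValueError("n_per_context must divide evenly across levels")
    per_level = n_per_context // len(levels)
    pattern_ids = list(rng.permutation(n_per_context))
    protos = []
    for cond, snr in levels:
        for _ in range(per_level):
            protos.append((cond, snr, "random-pattern", int(pattern_ids.pop())))
            protos.append((cond, snr, "random-random", None))
    order = rng.permutation(len(protos))
    trials = [TrialSpec(i, *protos[j]) for i, j in enumerate(order)]
    return BlockPlan(trials)


def score_trial(correct: bool | None, rt_s: float,
                stimulus_duration_s: float, start_points: int = 1000,
                timeout_s: float = 1.0, timeout_penalty: int = 350) -> int:
    """Points for one trial of the speeded game.

    The counter falls linearly from ``start_points`` to 0 over the
    stimulus duration plus the response window.  ``correct=None`` means no
    response was registered in time and costs the flat penalty.
    """
    if correct is None:
        return -timeout_penalty
    if rt_s < 0:
        raise ValueError("reaction time must be non-negative")
    rate = start_points / (stimulus_duration_s + timeout_s)
    counter = max(0, start_points - int(round(rate * rt_s)))
    return counter if correct else -counter


def rau(correct_count: int, n_trials: int) -> float:
    """Rationalized arcsine transform of ``correct_count / n_trials``."""
    if not 0 <= correct_count <= n_trials:
        raise ValueError("correct_count must lie in [0, n_trials]")
    x, n = float(correct_count), float(n_trials)
    theta = (np.arcsin(np.sqrt(x / (n + 1)))
             + np.arcsin(np.sqrt((x + 1) / (n + 1))))
    return float((146.0 / np.pi) * theta - 23.0)


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy summary of a trial table.

    Expects columns ``condition``, ``correct`` (bool, NaN for no
    response) and optionally ``rt_s`` and ``score``; returns counts,
    percent correct, RAU and mean RT per condition.
    """
    rows = []
    for cond, grp in trials.groupby("condition", sort=False):
        answered = grp["correct"].notna()
        n = int(answered.sum())
        x = int(grp.loc[answered, "correct"].astype(bool).sum())
        row = dict(condition=cond, n_scored=n, n_correct=x,
                   pct_correct=100.0 * x / n if n else np.nan,
                   rau=rau(x, n) if n else np.nan)
        if "rt_s" in grp:
            row["mean_rt_s"] = float(grp.loc[answered, "rt_s"].mean())
        if "score" in grp:
            row["total_score"] = int(grp["score"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
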