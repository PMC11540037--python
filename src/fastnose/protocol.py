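"""Stimulus protocol: trial definitions, the full delivery inventory and
its randomization check.

A protocol is a list of :class:`Trial` records.  The full inventory mixes
single square pulses (10 ms - 1 s, 20-100% concentration) with correlated and
anticorrelated two-odor pulse trains (2-60 Hz); the standard inventory totals
1280 trials.  Trials are presented in fully randomized order with a 30 s
recovery phase after each stimulus; a chi-square test over time bins verifies
the randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy import stats

PULSE = "pulse"
CORR_TRAIN = "corr_train"
ANTICORR_TRAIN = "anticorr_train"
TRAIN_KINDS = (CORR_TRAIN, ANTICORR_TRAIN)
ALLOWED_FREQUENCIES = (2.0, 5.0, 10.0, 20.0, 40.0, 60.0)
STANDARD_PULSE_DURATIONS_MS = (10, 20, 50, 100, 200, 500, 1000)
DEFAULT_RECOVERY_S = 30.0


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation.

    ``odors`` holds one panel name for a pulse, two for a pulse train.
    ``concentration`` is the valve duty in percent of full.
    """

    kind: str
    odors: tuple
    duration_ms: float
    concentration: float = 100.0
    frequency_hz: float | None = None
    recovery_s: float = DEFAULT_RECOVERY_S

    def __post_init__(self):
        object.__setattr__(self, "odors", tuple(self.odors))
        if self.kind == PULSE:
            if len(self.odors) != 1:
                raise ValueError("pulse trials take exactly one odor")
            if self.frequency_hz is not None:
                raise ValueError("pulse trials have no modulation frequency")
        elif self.kind in TRAIN_KINDS:
            if len(self.odors) != 2:
                raise ValueError("pulse-train trials take exactly two odors")
            if self.frequency_hz not in ALLOWED_FREQUENCIES:
                raise ValueError(
                    f"modulation frequency must be one of {ALLOWED_FREQUENCIES}")
        else:
            raise ValueError(f"unknown trial kind: {self.kind!r}")
        if self.duration_ms < 0:
            raise ValueError("duration must be non-negative")
        if not (0.0 < self.concentration <= 100.0):
            raise ValueError("concentration must be in (0, 100] percent")
        if self.recovery_s < 0:
            raise ValueError("recovery must be non-negative")

    @property
    def span_s(self) -> float:
        """Experiment-clock time occupied by this trial (stimulus + recovery)."""
        return self.duration_ms / 1000.0 + self.recovery_s


def build_standard_protocol(panel) -> list:
    """The full delivery inventory (1280 trials).

    Rows: 300 one-second full-concentration pulses split equally over the four
    odors and the two solvent vials (50 each; the two blank vials are
    indistinguishable downstream, so both map to the panel blank); 80 pulses
    per reduced concentration (20 per odor); 20 pulses per short duration
    (5 per odor); anticorrelated trains, 60 per frequency (10 per unordered
    odor pair); correlated trains, 30 per frequency (5 per pair).
    """
    odors = list(panel.odor_names)
    if len(odors) != 4:
        raise ValueError("standard protocol requires a four-odor panel")
    blank = panel.blank_name
    trials: list[Trial] = []
    for name in odors + [blank, blank]:
        trials += [Trial(PULSE, (name,), 1000, 100.0)] * 50
    for conc in (80.0, 60.0, 40.0, 20.0):
        for name in odors:
            trials += [Trial(PULSE, (name,), 1000, conc)] * 20
    for dur in (500, 200, 100, 50, 20, 10):
        for name in odors:
            trials += [Trial(PULSE, (name,), dur, 100.0)] * 5
    pairs = list(combinations(odors, 2))
    for freq in ALLOWED_FREQUENCIES:
        for pair in pairs:
            trials += [Trial(ANTICORR_TRAIN, pair, 1000, 100.0, freq)] * 10
    for freq in ALLOWED_FREQUENCIES:
        for pair in pairs:
            trials += [Trial(CORR_TRAIN, pair, 1000, 100.0, freq)] * 5
    return trials


@dataclass(frozen=True)
class RandomizedProtocol:
    trials: tuple
    start_times_s: np.ndarray
    p_uniform: float
    flagged: bool = False


def randomize_protocol(trials, seed: int, bin_s: float = 3600.0) -> RandomizedProtocol:
    """Permute the trial order and test odor-count uniformity over time bins.

    Start times accumulate each trial's stimulus span plus its recovery phase.
    The chi-square test compares per-bin odor occurrence counts (each trial
    contributes every odor it presents) against homogeneity; a protocol with
    fewer than two odor classes or a single bin is flagged with p = 1.0.
    """
    rng = np.random.default_rng(seed)
    trials = list(trials)
    order = rng.permutation(len(trials))
    ordered = [trials[i] for i in order]
    return _score_order(ordered, bin_s)


def _score_order(ordered, bin_s: float) -> RandomizedProtocol:
    spans = np.array([t.span_s for t in ordered])
    starts = np.concatenate(([0.0], np.cumsum(spans)[:-1]))
    classes = sorted({name for t in ordered for name in t.odors})
    n_bins = max(1, int(np.ceil((starts[-1] + 1e-9) / bin_s)))
    if len(classes) < 2 or n_bins < 2:
        return RandomizedProtocol(tuple(ordered), starts, 1.0, flagged=True)
    table = np.zeros((n_bins, len(classes)))
    col = {c: j for j, c in enumerate(classes)}
    for t, t0 in zip(ordered, starts):
        b = min(int(t0 // bin_s), n_bins - 1)
        for name in t.odors:
            table[b, col[name]] += 1
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return RandomizedProtocol(tuple(ordered), starts, 1.0, flagged=True)
    _, p, _, _ = stats.chi2_contingency(table)
    return RandomizedProtocol(tuple(ordered), starts, float(p))


def uniformity_pvalue(ordered, bin_s: float = 3600.0) -> RandomizedProtocol:
    """Score an externally supplied trial order (e.g. a deliberately blocked
    one) with the same chi-square statistic used after randomization."""
    return _score_order(list(ordered), bin_s)


def trial_to_record(trial: Trial) -> dict:
    return {
        "kind": trial.kind,
        "odors": list(trial.odors),
        "duration_ms": trial.duration_ms,
        "concentration": trial.concentration,
        "frequency_hz": trial.frequency_hz,
        "recovery_s": trial.recovery_s,
    }


def trial_from_record(rec: dict) -> Trial:
    return Trial(
        kind=rec["kind"],
        odors=tuple(rec["odors"]),
        duration_ms=rec["duration_ms"],
        concentration=rec.get("concentration", 100.0),
        frequency_hz=rec.get("frequency_hz"),
        recovery_s=rec.get("recovery_s", DEFAULT_RECOVERY_S),
    )
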