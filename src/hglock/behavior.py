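"""Trial scoring and behavioral metrics for the target-detection task.

Outcomes: a target with a press is a hit, a target without a press a miss, a
non-target with a press a false alarm, otherwise a correct reject.  A press
is attributed to the most recent stimulus onset (the events-table contract
already stores at most one press per row; a press occurring after the next
onset belongs to that later row).

Sensitivity is d' = Z(hit rate) - Z(false-alarm rate) with Z the standard
normal quantile function; extreme rates are clipped to
[1/(2N), 1 - 1/(2N)] (log-linear correction) before the quantile.

Hit trials with reaction time <= 550 ms are excluded from the neural
analysis so the post-stimulus (50-300 ms) and pre-behavior (250-0 ms before
the press) windows cannot overlap; the retained set is strictly RT > 550 ms.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import norm

from .dataio import (CORRECT_REJECT, FALSE_ALARM, HIT, MISS,
                     BehavioralSummary, TrialEvent)

log = logging.getLogger("hglock")


def score_trials(events: list[TrialEvent]) -> list[TrialEvent]:
    """Assign hit/miss/false-alarm/correct-reject outcomes in place."""
    prev_onset = -np.inf
    for e in events:
        if e.onset_s < prev_onset:
            raise ValueError("events must be sorted by onset")
        prev_onset = e.onset_s
        if e.is_target:
            e.outcome = HIT if e.press_s is not None else MISS
        else:
            e.outcome = FALSE_ALARM if e.press_s is not None else CORRECT_REJECT
    return events


def clipped_rate(count: int, n: int) -> float:
    """Proportion clipped into (0, 1) by the 1/(2N) correction."""
    if n <= 0:
        raise ValueError("rate undefined for zero trials")
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    return float(np.clip(count / n, lo, hi))


def d_prime(hit_rate: float, fa_rate: float) -> float:
    """Detection sensitivity from hit and false-alarm proportions in (0, 1)."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError("rates must lie strictly in (0, 1); clip first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def filter_fast_hits(events: list[TrialEvent], min_rt_ms: float = 550.0
                     ) -> list[TrialEvent]:
    """Hit trials retained for neural analysis: RT strictly above the floor."""
    return [e for e in events
            if e.outcome == HIT and e.rt_ms is not None and e.rt_ms > min_rt_ms]


def behavioral_summary(events: list[TrialEvent]) -> BehavioralSummary:
    outcomes = [e.outcome for e in events]
    if any(o is None for o in outcomes):
        raise ValueError("score_trials must run before summarizing")
    n_hits = outcomes.count(HIT)
    n_misses = outcomes.count(MISS)
    n_fas = outcomes.count(FALSE_ALARM)
    n_crs = outcomes.count(CORRECT_REJECT)
    n_targets = n_hits + n_misses
    n_nontargets = n_fas + n_crs
    rts = [e.rt_ms for e in events if e.outcome == HIT]
    dp = d_prime(clipped_rate(n_hits, n_targets),
                 clipped_rate(n_fas, n_nontargets)) \
        if n_targets and n_nontargets else float("nan")
    return BehavioralSummary(
        n_hits=n_hits, n_misses=n_misses, n_fas=n_fas, n_crs=n_crs,
        hit_rate=100.0 * n_hits / n_targets if n_targets else float("nan"),
        fa_rate=100.0 * n_fas / n_nontargets if n_nontargets else float("nan"),
        d_prime=dp,
        median_rt_ms=float(np.median(rts)) if rts else float("nan"))
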