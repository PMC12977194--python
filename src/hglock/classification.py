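"""Two-window significance classification of recording sites.

Per retained hit trial, ERBP is averaged over a post-stimulus window
(50-300 ms after stimulus onset) and a pre-behavior window (250-0 ms before
the button press).  Each window mean is tested against zero (one-sample
one-tailed t-test for an increase, alpha = 0.05, raw p-values — no
multiple-comparison correction at the site level, to limit false negatives).
The label follows from which windows are significant:

=============  ===========  ==========
p_post < a     p_pre < a    pattern
=============  ===========  ==========
yes            no           stimulus
no             yes          behavior
yes            yes          intermediate
no             no           none
=============  ===========  ==========

The identical retained trial set (hits with RT > 550 ms, artifact-free in
both alignments) feeds both tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ERBPMatrix
from .erbp import window_columns

log = logging.getLogger("hglock")

STIMULUS = "stimulus"
BEHAVIOR = "behavior"
INTERMEDIATE = "intermediate"
NONE = "none"
PATTERNS = (STIMULUS, BEHAVIOR, INTERMEDIATE, NONE)


@dataclass
class SiteClassification:
    site_id: str
    n_trials_used: int
    mean_post_db: float
    mean_pre_db: float
    p_post: float
    p_pre: float
    pattern: str


def window_means(erbp: ERBPMatrix, window_ms) -> np.ndarray:
    """Per-trial mean ERBP over a half-open [start, end) window."""
    if erbp.n_trials == 0:
        raise ValueError("no trials")
    cols = window_columns(erbp.times_ms, window_ms)
    return erbp.values[:, cols].mean(axis=1)


def one_tailed_increase_test(values: np.ndarray) -> float:
    """One-sample t-test p-value for H1: population mean > 0."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        log.warning("degenerate zero-variance window means")
        return 0.0 if values[0] > 0 else 1.0
    return float(stats.ttest_1samp(values, 0.0, alternative="greater").pvalue)


def classify_site(p_post: float, p_pre: float, alpha: float = 0.05) -> str:
    """Pattern label from the two raw window p-values (strict p < alpha)."""
    sig_post, sig_pre = p_post < alpha, p_pre < alpha
    if sig_post and sig_pre:
        return INTERMEDIATE
    if sig_post:
        return STIMULUS
    if sig_pre:
        return BEHAVIOR
    return NONE


def classify_from_matrices(stim_erbp: ERBPMatrix, press_erbp: ERBPMatrix,
                           post_window_ms=(50.0, 300.0),
                           pre_window_ms=(-250.0, 0.0),
                           alpha: float = 0.05) -> SiteClassification:
    """Classify one site from its stimulus- and press-aligned ERBP matrices.

    The two matrices must hold the same retained trials in the same order.
    """
    if not np.array_equal(stim_erbp.trial_index, press_erbp.trial_index):
        raise ValueError("stimulus- and press-aligned matrices must cover "
                         "the identical retained trial set")
    post = window_means(stim_erbp, post_window_ms)
    pre = window_means(press_erbp, pre_window_ms)
    p_post = one_tailed_increase_test(post)
    p_pre = one_tailed_increase_test(pre)
    return SiteClassification(
        site_id=stim_erbp.site_id, n_trials_used=stim_erbp.n_trials,
        mean_post_db=float(post.mean()), mean_pre_db=float(pre.mean()),
        p_post=p_post, p_pre=p_pre,
        pattern=classify_site(p_post, p_pre, alpha))
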