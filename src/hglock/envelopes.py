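"""Grand-average ERBP envelope time courses per ROI.

Each qualifying site is first averaged across its retained trials, then the
site means are averaged across sites (trials-then-sites order is fixed);
the band is a 95 % across-site confidence interval (t-interval by default,
bootstrap optional).  Stimulus-aligned envelopes cover -100..300 ms around
onset; press-aligned envelopes cover -400..200 ms around the button press.
ROIs contributing fewer than 10 qualifying sites are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ERBPMatrix
from .erbp import window_columns


@dataclass
class ROIEnvelope:
    roi: str
    alignment: str
    times_ms: np.ndarray
    mean_db: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_sites: int


def site_mean_trace(erbp: ERBPMatrix, window_ms) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial mean envelope of one site over a display window."""
    cols = window_columns(erbp.times_ms, window_ms)
    return erbp.times_ms[cols], erbp.values[:, cols].mean(axis=0)


def grand_average_envelope(site_traces: np.ndarray, times_ms: np.ndarray,
                           roi: str, alignment: str, min_sites: int = 10,
                           ci_method: str = "t",
                           n_boot: int = 2000, seed: int = 0
                           ) -> ROIEnvelope | None:
    """Across-site mean and 95 % CI; ``None`` when the ROI has too few sites.

    ``site_traces`` is sites x time, each row already a within-site trial
    average on the common ``times_ms`` grid.
    """
    site_traces = np.atleast_2d(np.asarray(site_traces, dtype=float))
    n_sites = site_traces.shape[0]
    if n_sites < min_sites:
        return None
    mean = site_traces.mean(axis=0)
    if ci_method == "t":
        sem = site_traces.std(axis=0, ddof=1) / np.sqrt(n_sites)
        half = stats.t.ppf(0.975, n_sites - 1) * sem
        lo, hi = mean - half, mean + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_sites, size=(n_boot, n_sites))
        boot = site_traces[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROIEnvelope(roi=roi, alignment=alignment, times_ms=times_ms,
                       mean_db=mean, ci95_low=lo, ci95_high=hi,
                       n_sites=n_sites)
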