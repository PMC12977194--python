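"""Single-trial power vs reaction-time correlation.

For each site with significant post-stimulus activation (stimulus or
intermediate pattern), Spearman's rho is computed between the per-trial mean
ERBP in the 50-300 ms post-stimulus window and the trial's RT.  Negative rho
means stronger early activation precedes faster responses.  ROI-level
distributions of rho (for ROIs contributing at least 10 such sites) are
tested against zero with two-tailed Wilcoxon signed-rank tests and BH-FDR
across the tested ROIs; zero-valued rhos are dropped (signed-rank
convention) and the exact null distribution is used for n <= 25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import INTERMEDIATE, STIMULUS
from .regional import bh_fdr

INCLUDED_PATTERNS = (STIMULUS, INTERMEDIATE)


@dataclass
class SiteRTCorrelation:
    site_id: str
    rho: float                   # nan when undefined (constant ranks)
    n_trials: int
    included: bool


@dataclass
class ROIRhoTest:
    roi: str
    n_sites: int
    median_rho: float
    p_raw: float
    p_fdr: float = float("nan")


def site_spearman(post_means, rts) -> float:
    """Spearman rank correlation with average-rank ties; nan if degenerate."""
    post_means = np.asarray(post_means, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if post_means.shape != rts.shape or post_means.size < 5:
        raise ValueError("need >= 5 paired trials in matching order")
    if np.ptp(post_means) == 0 or np.ptp(rts) == 0:
        return float("nan")
    return float(stats.spearmanr(post_means, rts).statistic)


def _wilcoxon_p(rhos: np.ndarray, exact_max_n: int = 25) -> float:
    nz = rhos[rhos != 0.0]
    if nz.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= exact_max_n and not has_ties) else "approx"
    return float(stats.wilcoxon(nz, alternative="two-sided",
                                method=method, zero_method="wilcox").pvalue)


def roi_rho_test(site_table: pd.DataFrame, min_sites: int = 10
                 ) -> list[ROIRhoTest]:
    """Per-ROI Wilcoxon signed-rank tests of the site rho distribution.

    ``site_table`` needs columns roi and rho (finite values only); ROIs with
    fewer than ``min_sites`` sites are omitted.  BH-FDR runs across the
    tested ROIs.
    """
    df = site_table.dropna(subset=["rho"])
    if not np.isfinite(df["rho"]).all():
        raise ValueError("rho values must be finite")
    results = []
    for roi, grp in sorted(df.groupby("roi"), key=lambda kv: kv[0]):
        rhos = grp["rho"].to_numpy()
        if rhos.size < min_sites:
            continue
        results.append(ROIRhoTest(roi=roi, n_sites=int(rhos.size),
                                  median_rho=float(np.median(rhos)),
                                  p_raw=_wilcoxon_p(rhos)))
    for res, q in zip(results, bh_fdr([r.p_raw for r in results])):
        res.p_fdr = float(q)
    return results
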