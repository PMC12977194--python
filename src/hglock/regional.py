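"""Regional prevalence, hemispheric asymmetry, and the stimulus/behavior index.

Site labels are aggregated per hemisphere at whole-brain, ROI-group or ROI
level.  Hemispheric prevalence differences use two-sided Fisher exact tests
on [pattern, other] x [L, R] tables with Benjamini-Hochberg FDR across the
family; the reported odds ratio puts left-hemisphere odds in the numerator.
Printed values in the source tables mix estimators, so both the sample
(cross-product) odds ratio and the conditional maximum-likelihood estimate
are emitted; the sample OR is primary.

The SB index summarizes the stimulus/behavior balance of an ROI:

    SB = (n_behav - n_stim) / (n_behav + n_stim),    SB in [-1, 1],

computed only for ROIs with at least 5 sites of either pattern drawn from at
least 2 participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio
from statsmodels.stats.multitest import multipletests

from .classification import BEHAVIOR, INTERMEDIATE, NONE, STIMULUS

_COUNT_COLS = {"stimulus": "n_stim", "behavior": "n_behav",
               "intermediate": "n_intermediate", "none": "n_none"}


@dataclass
class AsymmetryResult:
    scope: str
    pattern: str
    table: np.ndarray            # [[k_L, n_L-k_L], [k_R, n_R-k_R]]
    odds_ratio: float            # sample (cross-product), L odds on top
    odds_ratio_cmle: float
    p_raw: float
    p_fdr: float = float("nan")


@dataclass
class SBIndexRecord:
    roi: str
    hemisphere: str
    n_stim: int
    n_behav: int
    sb_index: float              # nan when ineligible/undefined
    eligible: bool
    n_total: int = 0
    n_participants: int = 0


def tabulate_prevalence(classifications: pd.DataFrame, site_meta: pd.DataFrame,
                        scope: str = "roi_group") -> pd.DataFrame:
    """Pattern counts and prevalence (%) per scope cell and hemisphere.

    ``classifications`` needs columns site_id/pattern, ``site_meta`` needs
    site_id/participant_id/hemisphere/roi/roi_group.  ``scope`` is one of
    'whole_brain', 'roi_group', 'roi'.
    """
    df = classifications.merge(site_meta, on="site_id", how="left")
    if df["roi"].isna().any() or df["hemisphere"].isna().any():
        missing = df.loc[df["roi"].isna(), "site_id"].tolist()
        raise ValueError(f"sites without metadata: {missing}")
    if scope == "whole_brain":
        df = df.assign(scope="whole_brain")
    elif scope in ("roi_group", "roi"):
        df = df.assign(scope=df[scope])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for (cell, hemi), grp in df.groupby(["scope", "hemisphere"]):
        row = {"scope": cell, "hemisphere": hemi, "n_total": len(grp)}
        for pattern in (STIMULUS, BEHAVIOR, INTERMEDIATE, NONE):
            sub = grp[grp["pattern"] == pattern]
            col = _COUNT_COLS[pattern]
            row[col] = len(sub)
            row[f"prevalence_pct_{pattern}"] = (
                100.0 * len(sub) / len(grp) if len(grp) else float("nan"))
            row[f"n_participants_{pattern}"] = sub["participant_id"].nunique()
        rows.append(row)
    return pd.DataFrame(rows)


def hemispheric_fisher(counts_l: tuple[int, int], counts_r: tuple[int, int],
                       scope: str = "", pattern: str = "") -> AsymmetryResult:
    """Two-sided Fisher exact test of pattern prevalence between hemispheres."""
    k_l, n_l = counts_l
    k_r, n_r = counts_r
    if k_l > n_l or k_r > n_r:
        raise ValueError("pattern count exceeds site count")
    table = np.array([[k_l, n_l - k_l], [k_r, n_r - k_r]], dtype=int)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return AsymmetryResult(scope, pattern, table, float("nan"),
                               float("nan"), 1.0)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else float("nan")
    else:
        sample_or = (a * d) / (b * c)
    cmle = float(_cmle_odds_ratio(table).statistic)
    return AsymmetryResult(scope, pattern, table, float(sample_or), cmle,
                           float(p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def asymmetry_analysis(prevalence: pd.DataFrame,
                       patterns=(STIMULUS, INTERMEDIATE, BEHAVIOR),
                       fdr_family: str = "all_groups") -> list[AsymmetryResult]:
    """Fisher tests for every scope cell x pattern, with BH-FDR.

    ``fdr_family='all_groups'`` corrects across all cells x patterns in one
    family; ``'per_pattern'`` corrects each pattern's cells separately.
    """
    by_cell = {}
    for _, row in prevalence.iterrows():
        by_cell.setdefault(row["scope"], {})[row["hemisphere"]] = row
    results = []
    for cell, hemis in sorted(by_cell.items()):
        if "L" not in hemis or "R" not in hemis:
            continue
        for pattern in patterns:
            col = _COUNT_COLS[pattern]
            res = hemispheric_fisher(
                (int(hemis["L"][col]), int(hemis["L"]["n_total"])),
                (int(hemis["R"][col]), int(hemis["R"]["n_total"])),
                scope=cell, pattern=pattern)
            results.append(res)
    if fdr_family == "all_groups":
        adj = bh_fdr([r.p_raw for r in results])
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
    elif fdr_family == "per_pattern":
        for pattern in patterns:
            sub = [r for r in results if r.pattern == pattern]
            for r, q in zip(sub, bh_fdr([r.p_raw for r in sub])):
                r.p_fdr = float(q)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return results


def sb_index(n_stim: int, n_behav: int) -> float:
    """(n_behav - n_stim) / (n_behav + n_stim); nan when both counts are 0."""
    if n_stim < 0 or n_behav < 0:
        raise ValueError("counts must be nonnegative")
    total = n_stim + n_behav
    if total == 0:
        return float("nan")
    return (n_behav - n_stim) / total


def sb_eligibility(site_records: pd.DataFrame, min_sites: int = 5,
                   min_participants: int = 2) -> bool:
    """Eligibility of one ROI x hemisphere cell for the SB index.

    ``site_records`` holds the cell's sites with columns pattern and
    participant_id; eligible iff at least ``min_sites`` sites carry either
    pattern and those sites span at least ``min_participants`` participants.
    """
    patt = site_records[site_records["pattern"].isin([STIMULUS, BEHAVIOR])]
    return (len(patt) >= min_sites
            and patt["participant_id"].nunique() >= min_participants)


def sb_index_table(classifications: pd.DataFrame, site_meta: pd.DataFrame,
                   min_sites: int = 5, min_participants: int = 2
                   ) -> list[SBIndexRecord]:
    """SB index per ROI x hemisphere with the eligibility rule applied."""
    df = classifications.merge(site_meta, on="site_id", how="left")
    records = []
    for (roi, hemi), grp in df.groupby(["roi", "hemisphere"]):
        n_stim = int((grp["pattern"] == STIMULUS).sum())
        n_behav = int((grp["pattern"] == BEHAVIOR).sum())
        eligible = sb_eligibility(grp, min_sites, min_participants)
        records.append(SBIndexRecord(
            roi=roi, hemisphere=hemi, n_stim=n_stim, n_behav=n_behav,
            sb_index=sb_index(n_stim, n_behav) if eligible else float("nan"),
            eligible=eligible, n_total=len(grp),
            n_participants=grp.loc[grp["pattern"].isin([STIMULUS, BEHAVIOR]),
                                   "participant_id"].nunique()))
    return records


def coord_asymmetry_test(z_left, z_right) -> tuple[float, float]:
    """Pooled-variance two-sample two-tailed t-test on z (dorsoventral) mm."""
    z_left = np.asarray(z_left, dtype=float)
    z_right = np.asarray(z_right, dtype=float)
    if z_left.size < 2 or z_right.size < 2:
        raise ValueError("need at least 2 coordinates per hemisphere")
    if np.ptp(z_left) == 0 and np.ptp(z_right) == 0 and z_left[0] == z_right[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(z_left, z_right, equal_var=True)
    return float(res.statistic), float(res.pvalue)
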