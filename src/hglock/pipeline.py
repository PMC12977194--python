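"""End-to-end orchestration: dataset -> per-site ERBP -> tables.

Stages (each writes CSV outputs and logs record counts):

1. preprocess  — per-site ERBP window means on retained hit trials
2. classify    — two-window t-tests, pattern labels
3. stats       — prevalence, hemispheric Fisher/FDR, SB indices, z-coordinate
                 asymmetry for sensorimotor cortex
4. rtcorr      — per-site Spearman rho vs RT, ROI-level Wilcoxon tests
5. envelopes   — grand-average ROI envelope time courses

The per-site front-end (downsample, band filter, Hilbert envelope, epoching,
artifact screen, baselining) runs once per site; all later stages consume
the resulting window means and site traces.  A manifest with config, seed
and per-stage row counts accompanies every results directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import erbp as _erbp
from .behavior import behavioral_summary, filter_fast_hits, score_trials
from .classification import (SiteClassification, classify_site,
                             one_tailed_increase_test)
from .dataio import AnalysisConfig, Dataset, SiteMeta, sites_dataframe
from .envelopes import grand_average_envelope
from .regional import (asymmetry_analysis, coord_asymmetry_test,
                       sb_index_table, tabulate_prevalence)
from .rtcorr import INCLUDED_PATTERNS, roi_rho_test, site_spearman

log = logging.getLogger("hglock")

STAGES = ("preprocess", "classify", "stats", "rtcorr", "envelopes")


@dataclass
class SiteResult:
    """Everything later stages need from one site's signal pass."""

    site: SiteMeta
    n_trials_used: int
    post_means_db: np.ndarray     # per retained trial
    pre_means_db: np.ndarray
    rts_ms: np.ndarray
    stim_trace_db: np.ndarray     # trial-averaged envelope, stimulus-aligned
    press_trace_db: np.ndarray
    stim_trace_times: np.ndarray
    press_trace_times: np.ndarray


def process_site(dataset, site: SiteMeta, cfg: AnalysisConfig,
                 taps: np.ndarray | None = None) -> SiteResult | None:
    """Run the signal front-end for one site.

    Returns ``None`` when fewer than 2 artifact-free slow-hit trials remain
    (the site is then unclassifiable and reported as such).
    """
    x, fs_raw = dataset.channel(site)
    from .dataio import Recording
    rec = Recording(np.atleast_2d(x), fs_raw, [site.site_id], "block")
    rec = _erbp.downsample(rec, cfg.target_fs)
    raw = rec.samples[0]
    if cfg.notch_denoise:
        raw = _erbp.notch_denoise(raw, cfg.target_fs)
    if taps is None:
        taps = _erbp.design_highgamma_fir(cfg.target_fs, cfg.hg_band_hz,
                                          cfg.fir_order)
    env, hg = _erbp.highgamma_envelope(raw, cfg.target_fs, taps=taps,
                                       return_filtered=True)
    stats = _erbp.BlockStats.from_signals(raw, hg)

    events = dataset.events_for(site.participant_id)
    if any(e.outcome is None for e in events):
        score_trials(events)
    retained = set(id(e) for e in filter_fast_hits(events, cfg.min_rt_ms))
    idx = [i for i, e in enumerate(events) if id(e) in retained]

    stim = _erbp.epoch(raw, hg, env, cfg.target_fs, events, "stimulus",
                       cfg.stim_epoch_ms, idx, site.site_id)
    press = _erbp.epoch(raw, hg, env, cfg.target_fs, events, "press",
                        cfg.press_epoch_ms, idx, site.site_id)
    common = np.intersect1d(stim.trial_index, press.trial_index)

    def _subset(ep, keep_idx):
        sel = np.isin(ep.trial_index, keep_idx)
        return _erbp.EpochSet(ep.raw[sel], ep.hg_filtered[sel],
                              ep.envelope[sel], ep.times_ms, ep.alignment,
                              ep.trial_index[sel], ep.site_id)

    stim, press = _subset(stim, common), _subset(press, common)
    keep = (_erbp.reject_artifacts(stim, stats, cfg.voltage_sd_thresh,
                                   cfg.hg_sd_thresh)
            & _erbp.reject_artifacts(press, stats, cfg.voltage_sd_thresh,
                                     cfg.hg_sd_thresh))
    kept_idx = stim.trial_index[keep]
    stim, press = _subset(stim, kept_idx), _subset(press, kept_idx)
    if stim.n_trials < 2:
        log.warning("site %s: only %d usable trials, skipped",
                    site.site_id, stim.n_trials)
        return None

    baseline = _erbp.stimulus_baseline_db(stim, cfg.baseline_window_ms)
    stim_erbp = _erbp.compute_erbp(stim, cfg.baseline_window_ms,
                                   baseline_mode=cfg.baseline_mode)
    press_erbp = _erbp.compute_erbp(press, cfg.baseline_window_ms,
                                    baseline_db=baseline,
                                    baseline_mode=cfg.baseline_mode)

    from .classification import window_means
    post = window_means(stim_erbp, cfg.post_window_ms)
    pre = window_means(press_erbp, cfg.pre_window_ms)
    rts = np.array([events[i].rt_ms for i in stim_erbp.trial_index])

    from .envelopes import site_mean_trace
    t_stim, stim_trace = site_mean_trace(stim_erbp, cfg.envelope_stim_window_ms)
    t_press, press_trace = site_mean_trace(press_erbp, cfg.envelope_press_window_ms)
    return SiteResult(site=site, n_trials_used=stim_erbp.n_trials,
                      post_means_db=post, pre_means_db=pre, rts_ms=rts,
                      stim_trace_db=stim_trace, press_trace_db=press_trace,
                      stim_trace_times=t_stim, press_trace_times=t_press)


def classify_results(results: list[SiteResult], cfg: AnalysisConfig
                     ) -> pd.DataFrame:
    rows = []
    for r in results:
        p_post = one_tailed_increase_test(r.post_means_db)
        p_pre = one_tailed_increase_test(r.pre_means_db)
        rows.append({
            "site_id": r.site.site_id, "n_trials_used": r.n_trials_used,
            "mean_post_db": float(r.post_means_db.mean()),
            "mean_pre_db": float(r.pre_means_db.mean()),
            "p_post": p_post, "p_pre": p_pre,
            "pattern": classify_site(p_post, p_pre, cfg.alpha_site)})
    return pd.DataFrame(rows)


def run_pipeline(dataset, out_dir, cfg: AnalysisConfig | None = None,
                 stages=STAGES) -> dict:
    """Execute the analysis stages and write the results directory.

    ``dataset`` is a :class:`hglock.dataio.Dataset`, a
    :class:`hglock.simulate.SyntheticDataset`, or a path to a dataset
    directory.  Returns the manifest dict (also written as manifest.json).
    """
    if isinstance(dataset, (str, Path)):
        dataset = Dataset(dataset)
    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "stages": {},
                "seed": cfg.rng_seed}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str)
        .encode()).hexdigest()[:16]

    taps = _erbp.design_highgamma_fir(cfg.target_fs, cfg.hg_band_hz,
                                      cfg.fir_order)
    results: list[SiteResult] = []
    skipped = []
    for site in dataset.sites:
        try:
            res = process_site(dataset, site, cfg, taps)
        except Exception as exc:
            raise RuntimeError(
                f"stage preprocess failed at site {site.site_id}") from exc
        if res is None:
            skipped.append(site.site_id)
        else:
            results.append(res)

    if "preprocess" in stages:
        trial_rows = []
        for r in results:
            for k in range(r.n_trials_used):
                trial_rows.append({
                    "site_id": r.site.site_id, "trial": k,
                    "post_mean_db": r.post_means_db[k],
                    "pre_mean_db": r.pre_means_db[k], "rt_ms": r.rts_ms[k]})
        pd.DataFrame(trial_rows).to_csv(out / "site_window_means.csv",
                                        index=False)
        behav = []
        for pid in sorted({s.participant_id for s in dataset.sites}):
            events = dataset.events_for(pid)
            if any(e.outcome is None for e in events):
                score_trials(events)
            summary = behavioral_summary(events)
            behav.append({"participant_id": pid,
                          **dataclasses.asdict(summary)})
        pd.DataFrame(behav).to_csv(out / "behavior_summary.csv", index=False)
        manifest["stages"]["preprocess"] = {
            "n_sites": len(results), "n_skipped": len(skipped),
            "skipped": skipped, "n_trial_rows": len(trial_rows)}
        log.info("preprocess: %d sites, %d skipped", len(results),
                 len(skipped))

    meta = sites_dataframe(dataset.sites)
    classifications = classify_results(results, cfg)
    if "classify" in stages:
        classifications.to_csv(out / "site_classification.csv", index=False)
        manifest["stages"]["classify"] = {
            "n_sites": len(classifications),
            "by_pattern": classifications["pattern"].value_counts().to_dict()}

    if "stats" in stages:
        prevalence = pd.concat([
            tabulate_prevalence(classifications, meta, "whole_brain"),
            tabulate_prevalence(classifications, meta, "roi_group")],
            ignore_index=True)
        prevalence.to_csv(out / "prevalence.csv", index=False)

        wb = prevalence[prevalence["scope"] == "whole_brain"]
        groups = prevalence[prevalence["scope"] != "whole_brain"]
        asym = (asymmetry_analysis(wb, fdr_family=cfg.fdr_family)
                + asymmetry_analysis(groups, fdr_family=cfg.fdr_family))
        asym_df = pd.DataFrame([{
            "scope": a.scope, "pattern": a.pattern,
            "k_L": a.table[0, 0], "n_L": a.table[0].sum(),
            "k_R": a.table[1, 0], "n_R": a.table[1].sum(),
            "odds_ratio": a.odds_ratio, "odds_ratio_cmle": a.odds_ratio_cmle,
            "p_raw": a.p_raw, "p_fdr": a.p_fdr} for a in asym])
        asym_df.to_csv(out / "asymmetry.csv", index=False)

        sb = sb_index_table(classifications, meta, cfg.sb_min_sites,
                            cfg.sb_min_participants)
        sb_df = pd.DataFrame([dataclasses.asdict(r) for r in sb])
        sb_df.to_csv(out / "sb_index.csv", index=False)

        sm = meta[meta["roi_group"] == "Sensorimotor"]
        coord = {"t": float("nan"), "p": float("nan")}
        if (sm["hemisphere"] == "L").sum() >= 2 and \
                (sm["hemisphere"] == "R").sum() >= 2:
            t, p = coord_asymmetry_test(
                sm.loc[sm["hemisphere"] == "L", "z_mni"],
                sm.loc[sm["hemisphere"] == "R", "z_mni"])
            coord = {"t": t, "p": p}
        with open(out / "coord_asymmetry.json", "w") as fh:
            json.dump(coord, fh)
        manifest["stages"]["stats"] = {
            "n_prevalence_rows": len(prevalence),
            "n_asymmetry_tests": len(asym_df), "n_sb_rows": len(sb_df)}

    if "rtcorr" in stages:
        included = set(classifications.loc[
            classifications["pattern"].isin(INCLUDED_PATTERNS), "site_id"])
        site_rows = []
        for r in results:
            inc = r.site.site_id in included
            rho = site_spearman(r.post_means_db, r.rts_ms) if inc else float("nan")
            site_rows.append({"site_id": r.site.site_id, "roi": r.site.roi,
                              "rho": rho, "n_trials": r.n_trials_used,
                              "included": inc})
        sites_df = pd.DataFrame(site_rows)
        sites_df.to_csv(out / "rt_correlation_sites.csv", index=False)
        roi_tests = roi_rho_test(sites_df[sites_df["included"]],
                                 cfg.roi_min_sites_rho)
        roi_df = pd.DataFrame([dataclasses.asdict(t) for t in roi_tests])
        roi_df.to_csv(out / "rt_correlation_rois.csv", index=False)
        manifest["stages"]["rtcorr"] = {
            "n_sites_included": int(sites_df["included"].sum()),
            "n_rois_tested": len(roi_df)}

    if "envelopes" in stages:
        env_rows = []
        by_pattern = dict(zip(classifications["site_id"],
                              classifications["pattern"]))
        for alignment, patterns, attr, tattr in (
                ("stimulus", ("stimulus", "intermediate"),
                 "stim_trace_db", "stim_trace_times"),
                ("press", ("behavior", "intermediate"),
                 "press_trace_db", "press_trace_times")):
            qual = [r for r in results
                    if by_pattern.get(r.site.site_id) in patterns]
            by_roi: dict[str, list[SiteResult]] = {}
            for r in qual:
                by_roi.setdefault(r.site.roi, []).append(r)
            for roi, rs in sorted(by_roi.items()):
                traces = np.array([getattr(r, attr) for r in rs])
                times = getattr(rs[0], tattr)
                env = grand_average_envelope(
                    traces, times, roi, alignment,
                    min_sites=cfg.roi_min_sites_envelope)
                if env is None:
                    continue
                for t, m, lo, hi in zip(env.times_ms, env.mean_db,
                                        env.ci95_low, env.ci95_high):
                    env_rows.append({"roi": roi, "alignment": alignment,
                                     "time_ms": t, "mean": m, "lo": lo,
                                     "hi": hi, "n_sites": env.n_sites})
        pd.DataFrame(env_rows).to_csv(out / "roi_envelopes.csv", index=False)
        manifest["stages"]["envelopes"] = {"n_rows": len(env_rows)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def waterfall_order(events) -> tuple[list[int], list[int]]:
    """Display order for waterfall plots: hits sorted by RT, then misses."""
    hits = sorted((i for i, e in enumerate(events) if e.outcome == "hit"),
                  key=lambda i: events[i].rt_ms)
    misses = [i for i, e in enumerate(events) if e.outcome == "miss"]
    return hits, misses


def render_waterfall(erbp_matrix, events, path, clim=(-10.0, 10.0)) -> Path:
    """Single-trial ERBP raster sorted by RT, misses below a separator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_events = [events[i] for i in erbp_matrix.trial_index]
    hits, misses = waterfall_order(row_events)
    if not hits:
        log.warning("waterfall: no hit trials, plotting misses only")
    order = hits + misses
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(erbp_matrix.values[order], aspect="auto", cmap="RdBu_r",
              vmin=clim[0], vmax=clim[1],
              extent=[erbp_matrix.times_ms[0], erbp_matrix.times_ms[-1],
                      len(order), 0])
    rts = [row_events[i].rt_ms for i in hits]
    ax.plot(rts, np.arange(len(hits)) + 0.5, "k.", ms=2)
    if misses:
        ax.axhline(len(hits), color="k", lw=1)
    ax.set_xlabel(f"time re {erbp_matrix.alignment} (ms)")
    ax.set_ylabel("trial (sorted by RT)")
    ax.set_title(erbp_matrix.site_id)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def render_report(results_dir, path=None) -> Path:
    """Markdown summary embedding the emitted tables."""
    results_dir = Path(results_dir)
    path = Path(path) if path else results_dir / "report.md"
    parts = ["# hglock analysis report\n"]
    with open(results_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    parts.append(f"config hash: `{manifest['config_hash']}`, "
                 f"seed: {manifest['seed']}\n")
    for name in ("behavior_summary", "site_classification", "prevalence",
                 "asymmetry", "sb_index", "rt_correlation_rois"):
        csv = results_dir / f"{name}.csv"
        if not csv.exists():
            continue
        try:
            df = pd.read_csv(csv)
        except pd.errors.EmptyDataError:
            continue
        parts.append(f"\n## {name}\n")
        parts.append(df.to_markdown(index=False, floatfmt=".3g")
                     if hasattr(df, "to_markdown") else df.to_string())
        parts.append("\n")
    path.write_text("".join(parts))
    return path
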