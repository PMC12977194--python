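"""The synthetic generator: trial structure, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from hglock.dataio import Dataset
from hglock.regional import sb_index, tabulate_prevalence
from hglock.rtcorr import site_spearman
from hglock.simulate import (SimulationConfig, SitePlanRow, SyntheticDataset,
                             expected_erbp_db, simulate_dataset,
                             simulate_trials)


class TestTrialStructure:
    def test_block_duration_tracks_isi_sum(self, rng):
        cfg = SimulationConfig(rng_seed=0, n_trials_per_block=140)
        events, truth = simulate_trials(cfg, rng)
        span = events[-1].onset_s - events[0].onset_s
        # 139 ISIs of N(2 s, 10 ms): 278 s give or take well under a second
        assert span == pytest.approx(278.0, abs=1.0)

    def test_zero_miss_rate_all_targets_hit(self, rng):
        cfg = SimulationConfig(rng_seed=0, miss_rate=0.0)
        events, _ = simulate_trials(cfg, rng)
        targets = [e for e in events if e.is_target]
        assert targets and all(e.outcome == "hit" for e in targets)

    def test_event_table_determinism(self):
        a = SyntheticDataset(SimulationConfig(rng_seed=9))
        b = SyntheticDataset(SimulationConfig(rng_seed=9))
        ea, eb = a.events_for("sub-01"), b.events_for("sub-01")
        assert [(e.onset_s, e.label, e.press_s) for e in ea] == \
               [(e.onset_s, e.label, e.press_s) for e in eb]

    def test_rt_median_near_configured(self, rng):
        cfg = SimulationConfig(rng_seed=0)
        from hglock.simulate import _draw_rt_ms
        draws = np.array([_draw_rt_ms(cfg, rng)[0] for _ in range(1000)])
        assert np.median(draws) == pytest.approx(cfg.rt_median_ms, rel=0.05)
        assert draws.min() >= cfg.rt_min_ms

    def test_fast_hit_fraction_plausible(self, rng):
        cfg = SimulationConfig(rng_seed=0)
        from hglock.simulate import _draw_rt_ms
        draws = np.array([_draw_rt_ms(cfg, rng)[0] for _ in range(4000)])
        fast = (draws < 550.0).mean()
        assert 0.005 < fast < 0.10   # a small minority, as in real task data


class TestCalibration:
    def test_expected_erbp_limits(self):
        assert expected_erbp_db(np.array([0.0]))[0] == 0.0
        # high-SNR limit: 10 log10(rho) plus the Rayleigh bias of the
        # mean-log noise baseline, (10/ln10)*gamma = 2.507 dB
        bias = 10 / np.log(10) * np.euler_gamma
        assert expected_erbp_db(np.array([1e6]))[0] == \
            pytest.approx(60.0 + bias, abs=0.01)
        # low-SNR limit: linear in rho (nats to dB)
        assert expected_erbp_db(np.array([1e-4]))[0] == \
            pytest.approx(10 / np.log(10) * 1e-4, rel=1e-3)

    def test_window_mean_hits_target_db(self):
        """Measured post-window ERBP matches the requested burst level."""
        from hglock.dataio import AnalysisConfig
        from hglock.pipeline import process_site
        measured = []
        for seed in (301, 302, 303, 304):
            plan = [SitePlanRow("sub-01", "L", "STGP", "stimulus",
                                post_burst_db=6.0, pre_burst_db=0.0)]
            cfg = SimulationConfig(rng_seed=seed, n_participants=1,
                                   site_plan=plan, artifact_rate=0.0)
            ds = SyntheticDataset(cfg)
            res = process_site(ds, ds.sites[0], AnalysisConfig())
            measured.append(res.post_means_db.mean())
        assert np.mean(measured) == pytest.approx(6.0, abs=0.5)

    def test_perfect_coupling_is_antimonotone_in_ground_truth(self):
        """rho_coupling -1 makes burst amplitude a strictly decreasing
        function of RT (checked on the noise-free ground-truth amplitudes)."""
        plan = [SitePlanRow("sub-01", "L", "STGP", "stimulus",
                            post_burst_db=6.0, pre_burst_db=0.0,
                            rho_coupling=-1.0)]
        cfg = SimulationConfig(rng_seed=21, n_participants=1, site_plan=plan)
        ds = SyntheticDataset(cfg)
        ds.channel(ds.sites[0])    # populates burst ground truth
        gt = ds.ground_truth["sites"][ds.sites[0].site_id]
        trials = ds.ground_truth["trials"]["sub-01"]
        amps = [b["post_amp_uv"] for b in gt["burst_amps"]]
        rts = [trials["rt_ms"][b["trial"]] for b in gt["burst_amps"]]
        assert site_spearman(amps, rts) == pytest.approx(-1.0)


class TestDatasets:
    def test_plan_validation(self):
        with pytest.raises(ValueError, match="empty"):
            SimulationConfig(site_plan=[])
        with pytest.raises(ValueError, match="rho_coupling"):
            SitePlanRow("p", "L", "STGP", "stimulus", rho_coupling=-2.0)
        plan = [SitePlanRow("p", "L", "NOT_A_ROI", "stimulus")]
        with pytest.raises(ValueError, match="valid labels"):
            SyntheticDataset(SimulationConfig(site_plan=plan))

    def test_channel_determinism(self, small_sim_config):
        a = SyntheticDataset(small_sim_config)
        b = SyntheticDataset(small_sim_config)
        xa, _ = a.channel(a.sites[0])
        xb, _ = b.channel(b.sites[0])
        np.testing.assert_array_equal(xa, xb)

    def test_disk_round_trip_matches_memory(self, small_sim_config,
                                            small_dataset_dir):
        mem = SyntheticDataset(small_sim_config)
        disk = Dataset(small_dataset_dir)
        assert [s.site_id for s in disk.sites] == \
               [s.site_id for s in mem.sites]
        x_mem, fs = mem.channel(mem.sites[3])
        x_disk, fs2 = disk.channel(disk.sites[3])
        assert fs == fs2
        # float32 storage quantization only
        np.testing.assert_allclose(x_disk, x_mem, rtol=2e-7, atol=1e-4)

    def test_emitted_files_reproducible(self, small_sim_config, tmp_path):
        da = simulate_dataset(small_sim_config, tmp_path / "a")
        db = simulate_dataset(small_sim_config, tmp_path / "b")
        for name in ("electrodes.tsv", "sub-01_events.tsv", "sub-01_ieeg.bin",
                     "ground_truth.json"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_artifact_trials_recorded(self):
        plan = [SitePlanRow("sub-01", "L", "OG", "none",
                            post_burst_db=0.0, pre_burst_db=0.0)]
        cfg = SimulationConfig(rng_seed=8, n_participants=1, site_plan=plan,
                               artifact_rate=0.5)
        ds = SyntheticDataset(cfg)
        x, fs = ds.channel(ds.sites[0])
        gt = ds.ground_truth["sites"][ds.sites[0].site_id]
        assert len(gt["artifact_trials"]) > 10
        # pulses really are large relative to the background
        assert np.abs(x).max() > 6 * cfg.noise_rms_uv


class TestPipelineAlgebra:
    def test_true_label_counts_flow_through_prevalence_and_sb(self,
                                                              small_dataset):
        """Replacing classification with the intended labels must reproduce
        the generator's own counts exactly."""
        sites = small_dataset.sites
        gt = small_dataset.ground_truth["sites"]
        cls = pd.DataFrame({
            "site_id": [s.site_id for s in sites],
            "pattern": [gt[s.site_id]["intended_pattern"] for s in sites]})
        from hglock.dataio import sites_dataframe
        meta = sites_dataframe(sites)
        prev = tabulate_prevalence(cls, meta, "roi")
        stgp = prev[prev["scope"] == "STGP"]
        assert stgp["n_stim"].sum() == sum(
            1 for s in sites if s.roi == "STGP"
            and gt[s.site_id]["intended_pattern"] == "stimulus")
        n_stim = int(prev["n_stim"].sum())
        n_behav = int(prev["n_behav"].sum())
        truth_stim = sum(1 for s in sites
                         if gt[s.site_id]["intended_pattern"] == "stimulus")
        truth_behav = sum(1 for s in sites
                          if gt[s.site_id]["intended_pattern"] == "behavior")
        assert (n_stim, n_behav) == (truth_stim, truth_behav)
        assert sb_index(n_stim, n_behav) == pytest.approx(
            (truth_behav - truth_stim) / (truth_behav + truth_stim))
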