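"""Synthetic-cohort generators, recovery properties, container round-trips, CLI."""

import numpy as np
import pytest

from tfs_assay import behavior as bhv
from tfs_assay.cohort import (
    CohortConfig,
    LatentSubject,
    end_to_end_recovery,
    render_behavior,
    render_cortical_eeg,
    render_ffr,
    sample_cohort,
)
from tfs_assay.staircase import PsychometricObserver


class TestSampling:
    def test_reproducible_under_seed(self):
        cfg = CohortConfig(n_subjects=8)
        _, t1 = sample_cohort(cfg, 42)
        _, t2 = sample_cohort(cfg, 42)
        assert t1.equals(t2)
        _, t3 = sample_cohort(cfg, 43)
        assert not t1.equals(t3)

    def test_zero_sds_collapse_to_means(self):
        cfg = CohortConfig(n_subjects=5, theta_b_sd=0.0, theta_m_sd=0.0, lapse_sd=0.0,
                           gain_log_sd=0.0, latency_sd=0.0, itc_mid_log_sd=0.0,
                           ffr_log_sd=0.0, alpha_sd=0.0)
        _, truth = sample_cohort(cfg, 0)
        for col in ("theta_b", "theta_m", "gain", "latency_shift"):
            assert truth[col].nunique() == 1
        assert truth["theta_b"].iloc[0] == cfg.theta_b_mean

    def test_preset_cohort_shape(self):
        cfg = CohortConfig(n_subjects=32)
        subjects, truth = sample_cohort(cfg, 1)
        assert len(subjects) == 32 and len(truth) == 32
        for col in ("theta_b", "theta_m", "lapse", "gain", "latency_shift",
                    "itc_log_midpoint", "ffr_neural", "ffr_preneural", "masking_alpha"):
            assert col in truth.columns

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2)


class TestBehaviorRendering:
    def subject(self, lapse=0.0, spread=3.0, theta=30.0):
        return LatentSubject("S", theta, 14.0, lapse, 1.0, 0.0, float(np.log(50)),
                             1.5, 0.05, 0.1, 0.8, psychometric_spread=spread)

    def test_lapse_free_tight_observer_recovers_midpoint(self, small_config):
        s = self.subject(lapse=0.0, spread=0.5)
        runs = render_behavior(s, "itd", small_config, seed=3)
        thr = bhv.aggregate_blocks([r.threshold_db for r in runs])
        assert thr == pytest.approx(s.theta_b, abs=2.0)

    def test_lapse_inflates_expected_threshold(self, small_config):
        means = {}
        for lam in (0.0, 0.2):
            thrs = []
            for seed in range(25):
                runs = render_behavior(self.subject(lapse=lam), "itd", small_config, seed=seed)
                thrs.append(bhv.aggregate_blocks([r.threshold_db for r in runs]))
            means[lam] = np.mean(thrs)
        assert means[0.2] > means[0.0] + 1.0

    def test_catch_trial_lapse_estimate_unbiased(self, small_config):
        lam = 0.10
        ests, ns = [], []
        for seed in range(30):
            runs = render_behavior(self.subject(lapse=lam), "itd", small_config, seed=seed)
            ests.append(bhv.compute_lapse_rate(runs))
            ns.append(sum(r.n_catch for r in runs))
        pooled_n = np.mean(ns)
        se = np.sqrt(lam * (1 - lam) / pooled_n) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(lam, abs=4 * se + 0.01)

    def test_fm_task_runs_both_ears(self, small_config):
        runs = render_behavior(self.subject(), "fm", small_config, seed=0)
        assert len(runs) == 2 * small_config.n_fm_blocks_per_ear


class TestCorticalRendering:
    def test_gain_raises_itc_scalars(self, default_subject):
        import dataclasses

        from tfs_assay.cortical import compute_itc, lowband_itc_timecourse

        scalars = {}
        for g in (1.0, 2.5):
            s = dataclasses.replace(default_subject, gain=g)
            vals = []
            for seed in (11, 12):
                ep = render_cortical_eeg(s, conditions=(540,), n_trials=120, seed=seed)
                m = compute_itc(ep, "Cz", freqs=np.arange(4.0, 21.0), label=540)
                vals.append(lowband_itc_timecourse(m)[1])
            scalars[g] = np.mean(vals)
        assert scalars[2.5] > scalars[1.0]

    def test_smallest_jump_sits_near_noise_floor(self, default_subject):
        from tfs_assay.cortical import compute_itc, lowband_itc_timecourse

        ep = render_cortical_eeg(default_subject, n_trials=400, seed=2)
        out = {}
        for cond in (20, 540):
            m = compute_itc(ep, "Cz", freqs=np.arange(4.0, 21.0), label=cond)
            out[cond] = lowband_itc_timecourse(m)[1]
        assert out[20] < 0.4 * out[540]

    def test_condition_labels_balanced(self, default_subject):
        ep = render_cortical_eeg(default_subject, n_trials=120, seed=0)
        _, counts = np.unique(ep.labels, return_counts=True)
        assert np.all(counts == 30)


class TestFfrRendering:
    def test_odd_trial_count_rejected(self, default_subject):
        with pytest.raises(ValueError):
            render_ffr(default_subject, n_trials=101, seed=0)

    def test_polarities_alternate(self, default_subject):
        ep = render_ffr(default_subject, n_trials=8, seed=0)
        assert list(ep.labels) == [1, -1, 1, -1, 1, -1, 1, -1]


class TestEndToEnd:
    def test_report_structure_and_confound(self):
        cfg = CohortConfig(n_subjects=12, n_itd_blocks=4)
        rec = end_to_end_recovery(cfg, seed=3, n_cortical_trials=160)
        rep = rec["regression"]
        assert rep.predictors == ["nonsensory_score", "eeg_latency", "eeg_slope"]
        assert rep.total_explained_pct + rep.unexplained_pct == pytest.approx(100.0, abs=1e-9)
        assert sum(rep.incremental_r2_pct) == pytest.approx(rep.total_explained_pct, abs=1e-9)
        # the anatomy-gain confound: raw 540-us ITC tracks gain
        assert rec["corr_itc540_gain"] > 0.3


class TestContainerRoundTrip:
    def test_exact_roundtrip(self, tmp_path, default_subject):
        from tfs_assay.io import load_epochs, save_epochs

        ep = render_cortical_eeg(default_subject, n_trials=16, seed=1)
        ep.rejected[3] = True
        path = tmp_path / "epochs.h5"
        save_epochs(ep, path)
        back = load_epochs(path)
        assert np.array_equal(back.data, ep.data)
        assert np.array_equal(back.rejected, ep.rejected)
        assert np.array_equal(back.labels, ep.labels)
        assert back.rate == ep.rate and back.tmin == ep.tmin
        assert back.ch_names == ep.ch_names

    def test_unicode_labels_preserved(self, tmp_path):
        from tfs_assay.eeg import EpochArray
        from tfs_assay.io import load_epochs, save_epochs

        ep = EpochArray(np.zeros((3, 2, 16)), 100.0, -0.05, ["Cz", "Fzé"],
                        labels=np.array(["condición", "β", "plain"]))
        path = tmp_path / "e.h5"
        save_epochs(ep, path)
        back = load_epochs(path)
        assert list(back.labels) == ["condición", "β", "plain"]
        assert back.ch_names == ["Cz", "Fzé"]

    def test_corrupt_file_raises(self, tmp_path):
        from tfs_assay.io import load_epochs

        path = tmp_path / "bad.h5"
        path.write_bytes(b"\x89HDF\r\n\x1a\nnot really")
        with pytest.raises(ValueError):
            load_epochs(path)


class TestCli:
    def test_synth_writes_wav_and_sidecar(self, tmp_path):
        from click.testing import CliRunner

        from tfs_assay.cli import main

        res = CliRunner().invoke(main, ["synth", "--paradigm", "itd_jump",
                                        "--jump-us", "180", "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "itd_jump.wav").exists()
        assert (tmp_path / "itd_jump.wav.json").exists()
        assert (tmp_path / "itd_jump_events.tsv").read_text().startswith("onset_s\tcode")

    def test_simulate_behavior_and_regress(self, tmp_path):
        import json

        import pandas as pd
        from click.testing import CliRunner

        from tfs_assay.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["simulate-behavior", "--task", "itd", "--n-blocks", "3",
                                   "--seed", "1", "--out", str(tmp_path / "beh")])
        assert res.exit_code == 0, res.output
        summary = json.loads((tmp_path / "beh" / "summary.json").read_text())
        assert len(summary["block_thresholds_db"]) == 3

        rng = np.random.default_rng(0)
        df = pd.DataFrame({"itd_threshold_db": rng.normal(30, 4, 20),
                           "itd_lapse_rate": rng.uniform(0, 0.2, 20),
                           "latency_ms": rng.normal(150, 15, 20),
                           "slope": rng.normal(0.4, 0.1, 20)})
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        res = runner.invoke(main, ["regress", "--cohort", str(csv),
                                   "--out", str(tmp_path / "reg.json")])
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "reg.json").read_text())
        assert report["explained_pct"] + report["unexplained_pct"] == pytest.approx(100.0)


class TestObserverIntegration:
    def test_latent_subject_builds_consistent_observers(self):
        s = LatentSubject("S", 28.0, 12.0, 0.1, 1.0, 0.0, float(np.log(50)), 1.5,
                          0.05, 0.1, 0.8)
        obs = s.itd_observer(seed=0)
        assert isinstance(obs, PsychometricObserver)
        assert obs.midpoint == 28.0 and obs.lapse == 0.1
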