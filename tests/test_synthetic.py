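"""Ground-truth generator: determinism, design, spikes, truth labels."""

import numpy as np
import pandas as pd
import pytest

from dkdprot import preprocess
from dkdprot.diffabund import RatioSentinel, differential_abundance
from dkdprot.synthetic import (
    Spike,
    SyntheticConfig,
    generate_dataset,
    recovery_config,
    study_design,
    study_mirror_config,
)


class TestStudyDesign:
    def test_group_sizes_match_experiment(self):
        d = study_design()
        sizes = {g: len(s) for g, s in d.groups.items()}
        assert sizes == {"WT2": 7, "INS2": 8, "WT4": 8, "INS4": 8, "dbdm": 5, "dbdb": 3}

    def test_total_and_uniqueness(self):
        d = study_design()
        samples = d.all_samples()
        assert len(samples) == 39
        assert len(set(samples)) == 39


class TestGenerateDataset:
    def test_same_seed_bit_identical(self):
        cfg = study_mirror_config(seed=5, n_proteins=200)
        t1, _ = generate_dataset(cfg)
        t2, _ = generate_dataset(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_different_seed_differs(self):
        a, _ = generate_dataset(SyntheticConfig(n_proteins=50, seed=1))
        b, _ = generate_dataset(SyntheticConfig(n_proteins=50, seed=2))
        assert not a.data.equals(b.data)

    def test_unknown_spike_accession_rejected(self):
        cfg = SyntheticConfig(
            n_proteins=10, spikes=(Spike("NOPE", ("INS2",), fold=2.0),)
        )
        with pytest.raises(ValueError, match="NOPE"):
            generate_dataset(cfg)

    def test_invalid_config_fields_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(detection_rate=0.0)
        with pytest.raises(ValueError):
            Spike("A", ("INS2",), fold=2.0, only_in=True)

    def test_only_in_group_spike_missing_elsewhere(self):
        cfg = SyntheticConfig(
            n_proteins=20,
            spikes=(Spike("SYN0000", ("WT2", "WT4"), only_in=True),),
            seed=3,
        )
        table, truth = generate_dataset(cfg)
        d = cfg.design
        wt_cols = list(d.samples("WT2")) + list(d.samples("WT4"))
        other = [s for s in table.sample_ids if s not in wt_cols]
        assert table.data.loc["SYN0000", other].isna().all()
        assert table.data.loc["SYN0000", wt_cols].notna().all()
        assert truth.status("SYN0000", "INS2", "WT2") == "down"

    def test_dropout_increases_missingness_at_low_abundance(self):
        cfg = SyntheticConfig(
            n_proteins=800, dropout_midpoint_log10=6.0, dropout_steepness=1.5, seed=4
        )
        table, _ = generate_dataset(cfg)
        frac = table.detected().mean(axis=1)
        raw = table.data.to_numpy()
        any_det = ~np.all(np.isnan(raw), axis=1)
        abundance = np.full(len(raw), np.nan)
        abundance[any_det] = np.log10(np.nanmean(raw[any_det], axis=1))
        lo = frac[np.nan_to_num(abundance, nan=-np.inf) < 5.5]
        hi = frac[abundance > 6.5]
        assert lo.mean() < hi.mean()


class TestTruthLabels:
    def test_spike_status_per_comparison(self):
        cfg = recovery_config(seed=0, n_proteins=120, n_up=2, n_down=2)
        _, truth = generate_dataset(cfg)
        assert truth.status("SYN0000", "INS2", "WT2") == "up"
        assert truth.status("SYN0002", "INS4", "WT4") == "down"
        assert truth.status("SYN0000", "WT4", "WT2") == "null"
        assert truth.status("SYN0099", "INS2", "WT2") == "null"

    def test_aging_confound_marks_aging_comparison(self):
        cfg = study_mirror_config(seed=0, n_proteins=100)
        _, truth = generate_dataset(cfg)
        assert len(truth.aging_confounded) == 4
        for acc in truth.aging_confounded:
            assert truth.status(acc, "WT4", "WT2") == "up"
            assert truth.status(acc, "INS4", "WT4") == "up"  # still disease-like


class TestFoldRecovery:
    def test_estimated_ratio_converges_to_spiked_fold_at_low_cv(self):
        """At 5% CV and full detection the estimated group-mean ratio of a
        fold-4 (and fold-0.25) spike lies within 5% of the truth."""
        # study-scale background: with few proteins the ppm closure itself
        # biases ratios (spiked mass shifts the per-sample totals)
        cfg = recovery_config(seed=9, n_proteins=2000, n_up=5, n_down=5, cv=0.05)
        table, truth = generate_dataset(cfg)
        norm = preprocess.normalize_ppm(table)
        d = cfg.design
        flt = preprocess.presence_filter(norm, d, groups=["INS2", "WT2"])
        recs = {r.accession: r for r in differential_abundance(flt, "INS2", "WT2", d)}
        for acc in truth.expected("up", "INS2", "WT2"):
            assert recs[acc].ratio == pytest.approx(4.0, rel=0.05)
        for acc in truth.expected("down", "INS2", "WT2"):
            assert recs[acc].ratio == pytest.approx(0.25, rel=0.05)

    def test_aging_confound_removal_sensitivity(self):
        """Spikes riding on an age effect (shared by WT4 and INS4) are
        candidates in both disease comparisons but are subtracted by the
        aging comparison with sensitivity >= 0.9 under full detection."""
        from dkdprot.consistency import aging_correction, consistent_across

        accs = [f"SYN{i:04d}" for i in range(10)]
        cfg = SyntheticConfig(
            n_proteins=500,
            spikes=tuple(Spike(a, ("INS2", "INS4"), fold=4.0) for a in accs),
            aging_spikes=tuple((a, 4.0) for a in accs[:4]),
            seed=12,
        )
        table, truth = generate_dataset(cfg)
        norm = preprocess.normalize_ppm(table)
        d = cfg.design

        def comp(case, ctrl):
            flt = preprocess.presence_filter(norm, d, groups=[case, ctrl])
            return differential_abundance(flt, case, ctrl, d)

        pre = consistent_across(comp("INS2", "WT2"), comp("INS4", "WT4"))
        post = aging_correction(pre, comp("WT4", "WT2"))
        assert truth.aging_confounded <= pre.accessions
        removed = truth.aging_confounded - post.accessions
        assert len(removed) / len(truth.aging_confounded) >= 0.9
        assert len(post.accessions & set(accs[4:])) >= 5  # clean spikes survive

    def test_only_in_control_spike_classified_down(self):
        cfg = SyntheticConfig(
            n_proteins=60,
            spikes=(Spike("SYN0001", ("WT2", "WT4"), only_in=True),),
            seed=6,
        )
        table, _ = generate_dataset(cfg)
        norm = preprocess.normalize_ppm(table)
        d = cfg.design
        flt = preprocess.presence_filter(norm, d, groups=["INS2", "WT2"])
        recs = {r.accession: r for r in differential_abundance(flt, "INS2", "WT2", d)}
        assert recs["SYN0001"].ratio is RatioSentinel.ONLY_IN_CONTROL
        assert recs["SYN0001"].classification == "down"
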