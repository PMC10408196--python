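import numpy as np
import pandas as pd
import pytest

import microresist as mr
from microresist import simulate as sim


class TestConfig:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(sigma_b2=-1), "sigma_b2"),
        (dict(sigma_w2=0), "sigma_w2"),
        (dict(depth=0), "depth"),
        (dict(responder_fraction=1.5), "responder_fraction"),
        (dict(timepoints=(3, 1)), "increasing"),
        (dict(timepoints=(5,)), "2 timepoints"),
        (dict(sigma_b2=float("nan")), "non-finite"),
        (dict(effect_size=float("inf")), "non-finite"),
    ])
    def test_invalid_configs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            mr.SimulationConfig(**kwargs)

    def test_true_rho_is_variance_ratio(self):
        assert mr.SimulationConfig(sigma_b2=1, sigma_w2=1).true_rho == 0.5
        assert mr.SimulationConfig(sigma_b2=0, sigma_w2=1).true_rho == 0.0


class TestControlCohort:
    def test_reproducible_bit_identical(self):
        cfg = mr.SimulationConfig(n_subjects=8, n_species=20, seed=5)
        a = mr.simulate_control_cohort(cfg)
        b = mr.simulate_control_cohort(cfg)
        pd.testing.assert_frame_equal(a.counts.data, b.counts.data)
        pd.testing.assert_frame_equal(a.metadata.frame, b.metadata.frame)
        assert a.tree_newick == b.tree_newick

    def test_column_sums_equal_depth(self, control_study):
        assert (control_study.counts.data.sum(axis=0)
                == control_study.config.depth).all()

    def test_compositional_closure_after_tss(self, control_study):
        rel = control_study.relative()
        assert np.allclose(rel.data.sum(axis=0), 1.0, atol=1e-9)

    def test_every_sample_in_metadata_exactly_once(self, control_study):
        meta_ids = control_study.metadata.sample_ids
        assert sorted(meta_ids) == sorted(control_study.counts.sample_ids)
        assert len(set(meta_ids)) == len(meta_ids)

    def test_truth_rho_recorded_per_feature(self):
        cfg = mr.SimulationConfig(n_subjects=5, n_species=12, sigma_b2=1,
                                  sigma_w2=1, seed=1)
        study = mr.simulate_control_cohort(cfg)
        assert (study.truth_rho == 0.5).all()
        assert len(study.truth_rho) == 12

    def test_zero_between_subject_variance(self):
        cfg = mr.SimulationConfig(n_subjects=6, n_species=15, sigma_b2=0.0,
                                  sigma_w2=0.5, seed=2)
        study = mr.simulate_control_cohort(cfg)
        assert (study.truth_rho == 0.0).all()

    def test_intervisit_correlation_tracks_truth(self):
        # generator's own Monte-Carlo oracle: higher rho -> higher observed
        # correlation of arcsine-root abundances (attenuated by softmax)
        out = {}
        for sb in (0.2, 3.0):
            cfg = mr.SimulationConfig(n_subjects=120, n_species=40, sigma_b2=sb,
                                      sigma_w2=1.0, seed=3)
            study = mr.simulate_control_cohort(cfg)
            rel = study.relative().data
            m = study.metadata.frame
            v1 = rel[m.loc[m.day == 0, "sample_id"]].to_numpy()
            v2 = rel[m.loc[m.day == 1, "sample_id"]].to_numpy()
            a1, a2 = np.arcsin(np.sqrt(v1)), np.arcsin(np.sqrt(v2))
            cors = [np.corrcoef(a1[j], a2[j])[0, 1] for j in range(40)]
            out[sb] = np.nanmean(cors)
        assert out[0.2] < 0.35
        assert out[3.0] > 0.55

    def test_tree_contains_every_species(self, control_study, study_dir):
        import skbio, io
        tree = skbio.TreeNode.read(io.StringIO(control_study.tree_newick),
                                   convert_underscores=False)
        leaves = {t.name for t in tree.tips()}
        terminals = set(control_study.relative().terminal_names())
        assert terminals <= leaves


class TestInterventionCohort:
    def test_zero_fraction_means_no_shift(self):
        cfg = mr.SimulationConfig(n_subjects=10, n_species=25, responder_fraction=0.0,
                                  n_informative=0, timepoints=(0, 14), seed=9)
        iv = mr.simulate_intervention_cohort(cfg, cohort_id="CTL")
        ctl = sim._simulate(cfg, "CTL", "control", None)
        pd.testing.assert_frame_equal(iv.counts.data, ctl.counts.data)
        assert not iv.responder_labels.any()

    def test_planted_fraction_matches_config(self, intervention_study):
        labels = intervention_study.responder_labels
        assert labels.sum() == round(0.5 * 60)

    def test_responders_move_more_than_nonresponders(self, intervention_study):
        from microresist import diversity as dv
        rel = intervention_study.relative()
        dm = dv.bray_curtis(rel).to_frame()
        meta = intervention_study.metadata
        move = {}
        for subj in meta.subjects:
            samples = meta.subject_samples(subj)
            move[subj] = dm.loc[samples.sample_id.iloc[0], samples.sample_id.iloc[1]]
        move = pd.Series(move)
        lab = intervention_study.responder_labels
        assert move[lab].mean() > move[~lab].mean() + 0.2

    def test_informative_species_separate_groups_at_baseline(self, intervention_study):
        rel = intervention_study.relative()
        meta = intervention_study.metadata.frame
        base = meta[meta.phase == "baseline"]
        lab = intervention_study.responder_labels
        fid = intervention_study.informative_features[0]  # positive offset
        vals = rel.data.loc[fid, base.sample_id]
        by_subject = pd.Series(vals.to_numpy(), index=base.subject_id.to_numpy())
        assert by_subject[lab].median() > by_subject[~lab].median()


class TestStratifiedFunctions:
    def test_unstratified_equals_sum_of_stratified(self, control_study):
        func = mr.simulate_stratified_functions(control_study)
        strat = func.stratified()
        for pwy in control_study.contribution_map:
            rows = [i for i in strat.index if i.startswith(pwy + "|")]
            assert np.allclose(strat.loc[rows].sum(axis=0), func.data.loc[pwy],
                               atol=1e-8)

    def test_columns_sum_to_one_million(self, control_study):
        func = mr.simulate_stratified_functions(control_study)
        unstr = func.unstratified()
        total = unstr.sum(axis=0) + func.data.loc["UNMAPPED"] + func.data.loc["UNINTEGRATED"]
        assert np.allclose(total, 1e6, rtol=1e-9)

    def test_single_contributor_proportional_to_species(self, control_study):
        study = control_study
        single = {p: m for p, m in study.contribution_map.items() if len(m) == 1}
        if not single:
            pytest.skip("no single-contributor pathway in this draw")
        pwy, [(sp, w)] = next(iter(single.items()))
        func = mr.simulate_stratified_functions(study)
        rel = study.relative().data.loc[sp]
        ratio = func.data.loc[pwy] / rel.replace(0, np.nan)
        # proportional up to the per-column CPM rescaling
        col_scale = ratio / ratio.mean()
        assert func.data.loc[pwy].corr(rel) > 0

    def test_two_to_one_weights_give_matching_rows(self):
        cfg = mr.SimulationConfig(n_subjects=4, n_species=10, n_pathways=2, seed=12)
        study = mr.simulate_control_cohort(cfg)
        sp = study.counts.feature_ids[:2]
        study.contribution_map = {"PWY-9999": [(sp[0], 2.0), (sp[1], 1.0)]}
        func = mr.simulate_stratified_functions(study)
        strat = func.stratified()
        rel = study.relative().data
        r0 = strat.iloc[0] / strat.iloc[1]
        expected = 2.0 * rel.loc[sp[0]] / rel.loc[sp[1]]
        assert np.allclose(r0, expected, rtol=1e-9)

    def test_negative_weight_rejected(self, control_study):
        study = mr.simulate_control_cohort(control_study.config)
        pwy = next(iter(study.contribution_map))
        sp, _ = study.contribution_map[pwy][0]
        study.contribution_map[pwy][0] = (sp, -1.0)
        with pytest.raises(ValueError, match="negative"):
            mr.simulate_stratified_functions(study)


class TestGenusAggregation:
    def test_genus_table_sums_species(self, control_study):
        rel = control_study.relative()
        gt = mr.genus_table(rel, control_study.genus_map)
        assert np.allclose(gt.data.sum(axis=0), 1.0, atol=1e-9)
        genus = control_study.genus_map[rel.feature_ids[0]]
        members = [f for f, g in control_study.genus_map.items() if g == genus]
        assert np.allclose(gt.data.loc[genus],
                           rel.data.loc[members].sum(axis=0), atol=1e-12)
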