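"""Generator-level properties: determinism, calibration, planted effects."""

import numpy as np
import pandas as pd
import pytest

import sleepsig as ss
from sleepsig.errors import InvalidArgumentError
from sleepsig.synthetic import (CouplingSpec, PHENOTYPES, _draw_covariates,
                                _draw_latent, default_task_design, n_edges)


class TestAtlas:
    def test_full_parcellation_has_180_regions_and_7_networks(self):
        atlas = ss.generate_atlas(180, seed=0)
        assert atlas.n_regions == 180
        assert len(set(atlas.network)) == 7

    def test_deterministic_for_fixed_seed(self):
        a = ss.generate_atlas(4, seed=1).to_frame()
        b = ss.generate_atlas(4, seed=1).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_centroids_are_mirror_symmetric_unit_vectors(self, atlas20):
        cl, cr = atlas20.centroids_left, atlas20.centroids_right
        assert np.allclose(cl[:, 0], -cr[:, 0])
        assert np.allclose(cl[:, 1:], cr[:, 1:])
        assert np.max(np.abs(np.linalg.norm(cl, axis=1) - 1)) < 1e-9

    def test_too_few_regions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.generate_atlas(3)


class TestPhenotypes:
    def test_deterministic_tables(self):
        a = ss.generate_phenotypes(100, seed=3, calibrate=False)
        b = ss.generate_phenotypes(100, seed=3, calibrate=False)
        pd.testing.assert_frame_equal(a, b)

    def test_ordinals_within_ranges_and_no_missing(self, cohort200):
        t = cohort200
        assert not t.isna().any().any()
        assert t["insomnia"].between(0, 3).all()
        assert t["dozing"].between(0, 3).all()
        assert t["phq2"].between(0, 6).all()
        assert (t["cognition"] >= 0).all()

    def test_identity_coupling_gives_independent_phenotypes(self):
        n = 5000
        t = ss.generate_phenotypes(n, CouplingSpec.null(), seed=5)
        r = np.corrcoef(t[list(PHENOTYPES)].to_numpy(float), rowvar=False)
        off = r[np.triu_indices(5, 1)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(n)

    def test_latent_layer_matches_requested_correlation(self):
        """Monte-Carlo oracle on the latent Gaussian layer itself."""
        target = ss.default_coupling().phenotype_corr
        rng = np.random.default_rng(7)
        cov = _draw_covariates(5000, rng)
        x = _draw_latent(5000, target, ss.default_coupling(), cov, rng)
        emp = np.corrcoef(x, rowvar=False)
        assert np.max(np.abs(emp - target)) < 0.05

    def test_non_positive_definite_matrix_rejected_with_eigenvalue(self):
        bad = np.full((5, 5), 0.9)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.9
        with pytest.raises(InvalidArgumentError, match="eigenvalue"):
            CouplingSpec(phenotype_corr=bad)

    def test_calibrated_partial_correlations_match_targets(self):
        """Realised covariate-adjusted partial correlations hit the printed
        targets within +/-0.01 at large n."""
        t = ss.generate_phenotypes(100_000, seed=1)
        pairs = ss.pairwise_partial_correlations(t)
        got = {(r.phenotype_a, r.phenotype_b): r.r
               for r in pairs.itertuples()}
        targets = {("sleep_bout_h", "insomnia"): -0.072,
                   ("sleep_bout_h", "dozing"): -0.11,
                   ("sleep_bout_h", "cognition"): 0.036,
                   ("insomnia", "dozing"): 0.081,
                   ("insomnia", "phq2"): 0.15}
        for pair, want in targets.items():
            assert abs(got[pair] - want) < 0.01, (pair, got[pair])

    def test_covariate_leakage_is_removed_by_adjustment(self):
        c = CouplingSpec(covariate_leakage={("age", "cognition"): -0.5})
        t = ss.generate_phenotypes(20_000, c, seed=9, calibrate=False)
        raw = np.corrcoef(t["age"], t["cognition"])[0, 1]
        res = ss.partial_correlation(
            t["cognition"].to_numpy(float), t["age"].to_numpy(float),
            covariates=t[["ses"]])
        assert raw < -0.25  # leakage visible marginally
        adj = ss.pairwise_partial_correlations(t)
        cogn = adj[(adj.phenotype_a == "dozing")
                   & (adj.phenotype_b == "cognition")]["r"].iloc[0]
        assert abs(cogn) < 0.03  # and absent after adjustment


class TestTaskData:
    def test_default_design_yields_60_balanced_samples(self):
        d = default_task_design()
        d.validate()
        assert d.n_samples == 60
        from sleepsig.synthetic import CATEGORY_CLASS
        classes = [CATEGORY_CLASS[c] for _, _, c in d.blocks]
        assert classes.count("face") == classes.count("shape") == 10
        assert d.tr_s * d.hemodynamic_delay_volumes == pytest.approx(3.675)

    def test_amplitude_floor_at_zero(self, atlas8):
        c = CouplingSpec(task_coupling={p: -5.0 for p in PHENOTYPES})
        t = ss.generate_phenotypes(50, c, seed=2, calibrate=False)
        a = ss.task_amplitudes(t, atlas8, c, seed=2)
        assert np.min(a) == 0.0

    def test_generated_arrays_deterministic_and_well_formed(self, atlas8):
        t = ss.generate_phenotypes(25, seed=4, calibrate=False)
        d1 = next(iter(ss.generate_task_data(t, atlas8, seed=4)))
        d2 = next(iter(ss.generate_task_data(t, atlas8, seed=4)))
        assert np.array_equal(d1.voxels_by_time, d2.voxels_by_time)
        assert d1.voxels_by_time.shape[1] == d1.design.n_volumes
        assert np.all(np.isfinite(d1.voxels_by_time))

    def test_decoding_accuracy_monotone_in_planted_amplitude(self, atlas8):
        """Mean accuracy over 50 seeds is non-decreasing in the base
        amplitude (three levels)."""
        means = []
        for a0 in (0.0, 0.12, 0.40):
            accs = []
            for seed in range(50):
                c = CouplingSpec.null()
                c = CouplingSpec(phenotype_corr=np.eye(5),
                                 task_coupling={p: 0.0 for p in PHENOTYPES},
                                 task_base_range=(a0, a0))
                t = ss.generate_phenotypes(21, c, seed=seed,
                                           calibrate=False)
                data = next(iter(ss.generate_task_data(
                    t, atlas8, coupling=c, seed=seed)))
                run = ss.preprocess_run(data, seed=seed)
                accs.append(ss.decode_region(run.samples, run.class_labels,
                                             seed=seed).accuracy)
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.9

    def test_positive_sleep_coupling_couples_accuracy_to_sleep(self, atlas8):
        t = ss.generate_phenotypes(200, seed=6)
        res = ss.decode_cohort(t, atlas8, seed=6)
        mean_acc = res.accuracy.to_numpy().mean(axis=1)
        r = np.corrcoef(mean_acc, t["sleep_bout_h"])[0, 1]
        assert r > 0


class TestRestData:
    def test_edge_count_matches_unique_pairs(self):
        assert n_edges(180) == 16_110
        assert n_edges(21) == 210

    def test_shapes_and_range(self, atlas8, cohort200):
        rest = ss.generate_rest_data(cohort200, atlas8, seed=11)
        assert rest.edges.shape == (200, n_edges(8))
        assert rest.ic_edges.shape == (200, 210)
        assert np.all(np.abs(rest.edges) < 1)

    def test_null_couplings_give_calibrated_edge_pvalues(self, atlas8):
        c = CouplingSpec.null()
        t = ss.generate_phenotypes(300, c, seed=12)
        rest = ss.generate_rest_data(t, atlas8, c, seed=12)
        m = ss.edge_associations(rest.edges, t, "phq2", n_nodes=8)
        frac = float((m["p"] < 0.05).mean())
        # binomial 99% bounds around 0.05 for 28 edges are wide; use a sane cap
        assert frac < 0.25

    def test_positive_global_coupling_recovered_in_sign(self, atlas8):
        zero = {p: 0.0 for p in PHENOTYPES}
        c = CouplingSpec(phenotype_corr=np.eye(5),
                         rest_global_coupling={**zero, "phq2": 0.1},
                         rest_edge_coupling=dict(zero))
        t = ss.generate_phenotypes(500, c, seed=13, calibrate=False)
        rest = ss.generate_rest_data(t, atlas8, c, seed=13)
        gmean = rest.edges.mean(axis=1)
        assoc = ss.global_mean_association_table(gmean, t, "rest")
        row = assoc[assoc.phenotype == "phq2"].iloc[0]
        assert row.beta > 0 and row.p < 0.01


class TestThickness:
    def test_output_dimensions(self, atlas8, cohort200):
        th = ss.generate_thickness(cohort200, atlas8, seed=3)
        assert th.shape == (200, 9)  # subject_id + 8 regions

    def test_null_coupling_yields_no_fdr_hits(self, atlas20):
        c = CouplingSpec.null()
        t = ss.generate_phenotypes(400, c, seed=14)
        th = ss.generate_thickness(t, atlas20, c, seed=14)
        m = ss.map_association(th.drop(columns="subject_id"), t, "phq2",
                               modality="anat")
        assert (m["p_adjusted"] < 0.05).sum() == 0

    def test_planted_single_region_effect_recovered(self, atlas20):
        zero = {p: 0.0 for p in PHENOTYPES}
        theta = np.zeros(20)
        theta[6] = 0.5 * 0.10  # half a noise sd on region 7
        c = CouplingSpec(phenotype_corr=np.eye(5),
                         thickness_coupling={**zero, "phq2": theta})
        t = ss.generate_phenotypes(2000, c, seed=15, calibrate=False)
        th = ss.generate_thickness(t, atlas20, c, seed=15)
        m = ss.map_association(th.drop(columns="subject_id"), t, "phq2",
                               modality="anat")
        hits = m.loc[m["p_adjusted"] < 0.05, "unit"].tolist()
        assert "region_007" in hits
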