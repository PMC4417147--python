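"""Cross-validation machinery, Kabsch superposition and ensemble queries."""

import numpy as np
import pytest

from chromens import (
    Conformation,
    EnsembleState,
    InferenceConfig,
    RestraintSet,
    SyntheticSpec,
    align_ensemble,
    contact_pairs,
    cross_validate,
    expected_distance,
    fit_distance_curve,
    generate_truth,
    kabsch_align,
    kfold_split,
    pearson_correlation,
    simulate_frequencies,
)
from chromens.validation import UndefinedCorrelationError

from conftest import random_chain


def restraint_set_of_size(m):
    iu, ju = np.triu_indices(30, k=1)
    d = np.linspace(1.0, 2.0, len(iu))
    return RestraintSet(iu[:m], ju[:m], 1.0 / d[:m], d[:m],
                        beta=1.0, alpha=1.0)


def uniform_ensemble(confs):
    k = len(confs)
    return EnsembleState(members=[(c, 1.0 / k) for c in confs],
                         log_likelihoods=np.zeros(k))


class TestPearson:
    def test_identity_gives_one(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_perfect_negative_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -2 * x + 3) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(50)
        x, y = rng.normal(0, 1, (2, 40))
        xm, ym = x - x.mean(), y - y.mean()
        oracle = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
        assert pearson_correlation(x, y) == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKFoldSplit:
    def test_exhaustive_partition_into_singletons(self):
        rs = restraint_set_of_size(10)
        folds = kfold_split(rs, 10, seed=0)
        assert sorted(np.bincount(folds)) == [1] * 10

    def test_seeded_determinism(self):
        rs = restraint_set_of_size(25)
        np.testing.assert_array_equal(kfold_split(rs, 5, seed=3),
                                      kfold_split(rs, 5, seed=3))

    def test_47_records_10_folds_sizes(self):
        rs = restraint_set_of_size(47)
        sizes = np.bincount(kfold_split(rs, 10, seed=1))
        assert set(sizes.tolist()) == {4, 5}
        assert sizes.sum() == 47

    def test_more_folds_than_records_rejected(self):
        rs = restraint_set_of_size(5)
        with pytest.raises(ValueError):
            kfold_split(rs, 6, seed=0)


class TestKabsch:
    def test_identity_gives_zero_rmsd(self):
        conf = random_chain(8, seed=60)
        _, rmsd = kabsch_align(conf, conf)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_exactly_recovered(self):
        from scipy.spatial.transform import Rotation

        conf = random_chain(8, seed=61)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = Conformation(conf.coords @ rot.T + np.array([5.0, -2.0, 1.0]))
        aligned, rmsd = kabsch_align(conf, moved)
        assert rmsd < 1e-8
        np.testing.assert_allclose(aligned.coords, conf.coords, atol=1e-7)

    def test_optimal_against_random_rotations(self):
        from scipy.spatial.transform import Rotation

        ref = random_chain(6, seed=62)
        mob = random_chain(6, seed=63)
        _, best = kabsch_align(ref, mob)
        rng = np.random.default_rng(64)
        centered = mob.coords - mob.coords.mean(axis=0)
        ref_centered = ref.coords - ref.coords.mean(axis=0)
        for _ in range(100):
            rot = Rotation.random(rng=rng).as_matrix()
            rmsd = np.sqrt(np.mean(np.sum(
                (centered @ rot.T - ref_centered) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_point_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_align(random_chain(5, seed=0), random_chain(6, seed=0))


class TestAlignEnsemble:
    def test_identity_on_singleton(self):
        conf = random_chain(6, seed=65)
        ens = uniform_ensemble([conf])
        out = align_ensemble(ens)
        np.testing.assert_array_equal(out.conformations[0].coords,
                                      conf.coords)

    def test_identical_members_have_zero_pairwise_rmsd(self):
        conf = random_chain(6, seed=66)
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(67)
        members = [conf]
        for _ in range(3):
            rot = Rotation.random(rng=rng).as_matrix()
            members.append(Conformation(conf.coords @ rot.T
                                        + rng.normal(0, 4, 3)))
        out = align_ensemble(uniform_ensemble(members))
        base = out.conformations[0].coords
        for other in out.conformations[1:]:
            assert np.sqrt(np.mean((other.coords - base) ** 2)) < 1e-7

    def test_reference_member_unchanged_and_order_preserved(self):
        rng = np.random.default_rng(68)
        confs = [random_chain(6, seed=70 + i) for i in range(4)]
        w = np.array([0.1, 0.5, 0.2, 0.2])
        lls = np.log(w)
        ens = EnsembleState(members=list(zip(confs, w)), log_likelihoods=lls)
        out = align_ensemble(ens)
        np.testing.assert_array_equal(out.conformations[1].coords,
                                      confs[1].coords)
        np.testing.assert_allclose(out.weights, w)

    def test_pairwise_rmsd_symmetric_in_common_frame(self):
        confs = [random_chain(7, seed=80 + i) for i in range(3)]
        out = align_ensemble(uniform_ensemble(confs))
        coords = [c.coords for c in out.conformations]
        for i in range(3):
            for j in range(3):
                rij = np.sqrt(np.mean((coords[i] - coords[j]) ** 2))
                rji = np.sqrt(np.mean((coords[j] - coords[i]) ** 2))
                assert rij == pytest.approx(rji, abs=1e-6)


class TestExpectedDistance:
    def test_same_position_is_zero(self, unit_model, eparams,
                                   straight_conformation):
        ens = uniform_ensemble([straight_conformation])
        assert expected_distance(ens, unit_model, eparams, 5000,
                                 5000) == pytest.approx(0.0)

    def test_cut_site_maps_to_endpoint(self, unit_model, eparams,
                                       straight_conformation):
        # cut site at 3900 bp is endpoint 1 at x=1; start of chain is x=0
        ens = uniform_ensemble([straight_conformation])
        d = expected_distance(ens, unit_model, eparams, 0, 3900)
        assert d == pytest.approx(1.0 * eparams.length_scale_nm)

    def test_weighted_mean_of_member_distances(self, unit_model, eparams):
        # two members with bp-pair distances 2 and 4 reduced units
        a = Conformation(np.column_stack([np.arange(11) * 1.0,
                                          np.zeros(11), np.zeros(11)]))
        b = Conformation(np.column_stack([np.arange(11) * 2.0,
                                          np.zeros(11), np.zeros(11)]))
        ens = EnsembleState(members=[(a, 0.5), (b, 0.5)],
                            log_likelihoods=np.zeros(2))
        d = expected_distance(ens, unit_model, eparams, 0, 2 * 3900)
        assert d == pytest.approx(0.5 * (2 + 4) * eparams.length_scale_nm)

    def test_outside_span_rejected(self, unit_model, eparams,
                                   straight_conformation):
        ens = uniform_ensemble([straight_conformation])
        with pytest.raises(ValueError):
            expected_distance(ens, unit_model, eparams, 0, 39001)


class TestContactPairs:
    def test_straight_chain_has_no_long_range_contacts(self, unit_model,
                                                       eparams,
                                                       straight_conformation):
        # separations of >= 5 segments are >= 150 nm apart on this chain
        ens = uniform_ensemble([straight_conformation])
        pairs, count = contact_pairs(ens, unit_model, eparams,
                                     dmin_nm=45, dmax_nm=100)
        assert count == 0 and pairs == []

    def test_hairpin_places_single_pair_in_window(self, unit_model, eparams):
        # a wide loop whose tail returns next to the head: fragment
        # midpoints 0 and 9 end up 2 reduced units (60 nm) apart while every
        # other >=5-separated pair stays well outside 45-100 nm
        xy = [(0, 0), (3, 0), (6, 0), (9, 0), (12, 0), (15, 0),
              (15, 12), (3, 12), (0, 8), (0, 2), (3, 2)]
        coords = np.array([[x, y, 0.0] for x, y in xy])
        ens = uniform_ensemble([Conformation(coords)])
        pairs, count = contact_pairs(ens, unit_model, eparams,
                                     min_sep_segments=5,
                                     dmin_nm=45, dmax_nm=100)
        assert count == 1
        i, j, d_nm = pairs[0]
        assert (i, j) == (0, 9)
        assert d_nm == pytest.approx(60.0)

    def test_invariant_under_rigid_motion(self, unit_model, eparams):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(90)
        confs = [random_chain(11, seed=91 + i) for i in range(3)]
        ens = uniform_ensemble(confs)
        pairs0, count0 = contact_pairs(ens, unit_model, eparams)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0, 10, 3)
        moved = uniform_ensemble([Conformation(c.coords @ rot.T + shift)
                                  for c in confs])
        pairs1, count1 = contact_pairs(moved, unit_model, eparams)
        assert count1 == count0
        assert [(i, j) for i, j, _ in pairs1] == [(i, j) for i, j, _ in pairs0]


class TestFitDistanceCurve:
    def test_recovers_generating_parameters_within_one_percent(self):
        from chromens.validation import fit_saturating_curve

        s = np.linspace(5_000, 200_000, 40)
        d_max, s0 = 300.0, 50_000.0
        d = d_max * (1 - np.exp(-s / s0))
        d_max_hat, s0_hat, resid = fit_saturating_curve(s, d)
        assert d_max_hat == pytest.approx(d_max, rel=0.01)
        assert s0_hat == pytest.approx(s0, rel=0.01)
        assert resid < 1e-6

    def test_fitted_curve_monotone_and_beats_constant(self, unit_model,
                                                      eparams):
        rng = np.random.default_rng(95)
        confs = [random_chain(11, seed=96 + i) for i in range(4)]
        ens = uniform_ensemble(confs)
        d_max_hat, s0_hat, resid = fit_distance_curve(ens, unit_model,
                                                      eparams)
        s = np.linspace(1, 5e5, 200)
        curve = d_max_hat * (1 - np.exp(-s / s0_hat))
        assert np.all(np.diff(curve) >= -1e-9)
        # nested-model comparison against the best constant fit
        w = ens.weights
        mean_d = np.zeros((unit_model.n, unit_model.n))
        for i, conf in enumerate(ens.conformations):
            mids = conf.segment_midpoints()
            diff = mids[:, None, :] - mids[None, :, :]
            mean_d += w[i] * np.linalg.norm(diff, axis=-1)
        mean_d *= eparams.length_scale_nm
        iu, ju = np.triu_indices(unit_model.n, k=1)
        const_resid = float(np.sqrt(np.mean(
            (mean_d[iu, ju] - mean_d[iu, ju].mean()) ** 2)))
        assert resid <= const_resid + 1e-9


@pytest.fixture(scope="module")
def small_noiseless(eparams):
    spec = SyntheticSpec(n_segments=10, noise_sigma=0.0, seed=17)
    model, truths = generate_truth(spec, eparams)
    fm = simulate_frequencies(model, truths, spec)
    return model, fm


class TestCrossValidateSmall:
    def test_every_restraint_in_exactly_one_test_fold(self, small_noiseless,
                                                      eparams):
        model, fm = small_noiseless
        cfg = InferenceConfig(k=3, seed=17, brownian_steps=800,
                              ascent_max_steps=1500, max_em_iter=8)
        report = cross_validate(fm, model, cfg, folds=5, eparams=eparams)
        counts = np.bincount(report.fold_assignments, minlength=5)
        assert counts.sum() == len(report.fold_assignments)
        assert np.all(counts >= 1)
        assert report.n_folds == 5
        assert np.max(counts) - np.min(counts) <= 1

    def test_5fold_and_10fold_agree(self, small_noiseless, eparams):
        model, fm = small_noiseless
        cfg = InferenceConfig(k=3, seed=18, brownian_steps=800,
                              ascent_max_steps=1500, max_em_iter=8)
        r5 = cross_validate(fm, model, cfg, folds=5, eparams=eparams)
        r10 = cross_validate(fm, model, cfg, folds=10, eparams=eparams)
        assert abs(r5.pooled_correlation - r10.pooled_correlation) < 0.1
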