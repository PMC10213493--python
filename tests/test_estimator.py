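import numpy as np
import pytest

from hapclean.emission import ModelParams, genotype_likelihoods, founder_emission_matrix
from hapclean.estimator import (
    call_genotypes,
    correct_dataset,
    estimate_chromosome,
    marginal_probabilities,
    merge_rounds,
    two_round_estimate,
    viterbi_pass,
)
from hapclean.evaluator import call_metrics
from hapclean.scheme import build_transition_model
from hapclean.simulator import SimConfig, simulate
from tests.oracles import exhaustive_joint_max, joint_logprob, random_tiny_instance


def _decode(log_pyx, log_lf, log_trans, log_pi, space, seed=0):
    return viterbi_pass(
        log_pyx, space.genotype_map, log_lf, log_trans, log_pi, np.random.default_rng(seed)
    )


class TestViterbiPass:
    def test_deep_unambiguous_reads_equal_exhaustive_argmax(self, f2_space):
        # 2 markers, 1 offspring, opposite-homozygote founders, deep reads:
        # offspring het at both markers; a single state sequence dominates
        params = ModelParams(2)
        oreads = np.array([[[15, 14]], [[16, 15]]])
        freads = np.array([[[20, 0], [0, 20]]] * 2)
        model = build_transition_model(f2_space.design, np.array([1, 2_000_000]), 0.04)
        pyx = genotype_likelihoods(oreads, params)
        lf = founder_emission_matrix(freads, f2_space.founder_classes, params)
        with np.errstate(divide="ignore"):
            log_pyx, log_lf = np.log(pyx), np.log(lf)
            log_trans = [np.log(t) for t in model.matrices]
            log_pi = np.log(model.initial)
        combo, h = _decode(log_pyx, log_lf, log_trans, log_pi, f2_space)
        got = joint_logprob(log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi, combo, h)
        want = exhaustive_joint_max(log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi)
        assert got == pytest.approx(want, abs=1e-9)
        assert (f2_space.genotype_map[combo[:, None], h] == 1).all()

    def test_returned_joint_never_exceeds_exhaustive_maximum(self, f2_space, rng):
        for t in range(30):
            log_pyx, log_lf, log_trans, log_pi = random_tiny_instance(rng, f2_space)
            combo, h = _decode(log_pyx, log_lf, log_trans, log_pi, f2_space, seed=t)
            got = joint_logprob(
                log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi, combo, h
            )
            want = exhaustive_joint_max(
                log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi
            )
            assert got <= want + 1e-9

    def test_single_marker_exact(self, f2_space, rng):
        for t in range(20):
            log_pyx, log_lf, log_trans, log_pi = random_tiny_instance(
                rng, f2_space, max_markers=1
            )
            combo, h = _decode(log_pyx, log_lf, log_trans, log_pi, f2_space, seed=t)
            got = joint_logprob(
                log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi, combo, h
            )
            want = exhaustive_joint_max(
                log_pyx, f2_space.genotype_map, log_lf, log_trans, log_pi
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_all_zero_reads_returns_admissible_sequence(self, f2_space):
        params = ModelParams(3)
        oreads = np.zeros((3, 2, 2), dtype=int)
        freads = np.zeros((3, 2, 2), dtype=int)
        model = build_transition_model(f2_space.design, np.array([1, 100, 200]), 0.04)
        pyx = genotype_likelihoods(oreads, params)
        lf = founder_emission_matrix(freads, f2_space.founder_classes, params)
        with np.errstate(divide="ignore"):
            combo, h = _decode(
                np.log(pyx), np.log(lf), [np.log(t) for t in model.matrices],
                np.log(model.initial), f2_space,
            )
        assert set(combo) <= {0, 1}
        assert ((h >= 0) & (h < 4)).all()


class TestTwoRoundEstimate:
    def test_merge_boundary_takes_first_half_from_reverse(self):
        fwd = np.array([10, 11, 12, 13])
        rev = np.array([20, 21, 22, 23])
        np.testing.assert_array_equal(merge_rounds(rev, fwd), [20, 21, 12, 13])
        # odd M: floor(5/2) = 2 markers from the reverse round
        np.testing.assert_array_equal(
            merge_rounds(np.arange(5) + 20, np.arange(5)), [20, 21, 2, 3, 4]
        )

    def test_agreeing_rounds_reproduce_forward(self, f2_space):
        cfg = SimConfig(n_offspring=8, n_markers=40, offspring_depth=20.0,
                        bias_fraction=0, mismap_fraction=0, seed=7)
        truth, ds = simulate(cfg)
        params = ModelParams(40)
        model = build_transition_model(f2_space.design, ds.pos, params.ed)
        pyx = genotype_likelihoods(ds.offspring_reads, params)
        lf = founder_emission_matrix(ds.founder_reads, f2_space.founder_classes, params)
        with np.errstate(divide="ignore"):
            log_pyx, log_lf = np.log(pyx), np.log(lf)
            log_trans = [np.log(t) for t in model.matrices]
            log_pi = np.log(model.initial)
        combo_f, haps_f = _decode(log_pyx, log_lf, log_trans, log_pi, f2_space)
        combo_m, haps_m = two_round_estimate(
            log_pyx, f2_space.genotype_map, log_lf, model, np.random.default_rng(0)
        )
        np.testing.assert_array_equal(combo_m, combo_f)
        np.testing.assert_array_equal(
            f2_space.genotype_map[combo_m[:, None], haps_m],
            f2_space.genotype_map[combo_f[:, None], haps_f],
        )


class TestMarginals:
    def test_posteriors_sum_to_one(self, f2_space, rng):
        cfg = SimConfig(n_offspring=5, n_markers=30, offspring_depth=1.0, seed=3)
        truth, ds = simulate(cfg)
        res = estimate_chromosome(
            ds.offspring_reads, ds.founder_reads, ds.pos, f2_space, ModelParams(30), rng
        )
        np.testing.assert_allclose(res.posteriors.sum(axis=2), 1.0, atol=1e-10)

    def test_deep_concordant_reads_certain(self, f2_space, rng):
        cfg = SimConfig(n_offspring=5, n_markers=30, offspring_depth=30.0,
                        bias_fraction=0, mismap_fraction=0, seed=4)
        truth, ds = simulate(cfg)
        res = estimate_chromosome(
            ds.offspring_reads, ds.founder_reads, ds.pos, f2_space, ModelParams(30), rng
        )
        ref_cells = truth.genotypes == 0
        assert (res.posteriors[..., 0][ref_cells] > 0.999).mean() > 0.95

    def test_single_marker_closed_form(self, f2_space):
        # one marker: posterior over h is emission * pi normalized
        params = ModelParams(1)
        oreads = np.array([[[3, 0]]])
        model = build_transition_model(f2_space.design, np.array([100]), params.ed)
        pyx = genotype_likelihoods(oreads, params)
        post = marginal_probabilities(pyx, f2_space.genotype_map, np.array([0]), model)
        e = pyx[0, 0, f2_space.genotype_map[0]] * model.initial
        e /= e.sum()
        want = np.array([e[f2_space.genotype_map[0] == x].sum() for x in range(3)])
        np.testing.assert_allclose(post[0, 0], want, atol=1e-12)


class TestCallGenotypes:
    def test_threshold_masks_low_posterior(self):
        vg = np.array([[1, 0]])
        post = np.zeros((1, 2, 3))
        post[0, 0, 1] = 0.95
        post[0, 1, 0] = 0.89
        called, marginal = call_genotypes(vg, post, 0.9)
        np.testing.assert_array_equal(called, [[1, -1]])
        np.testing.assert_allclose(marginal, [[0.95, 0.89]])

    def test_zero_threshold_masks_nothing(self):
        vg = np.array([[2, 1, 0]])
        post = np.full((1, 3, 3), 1 / 3)
        called, _ = call_genotypes(vg, post, 0.0)
        assert (called >= 0).all()


class TestSymmetryAndMonotonicity:
    def test_allele_swap_relabels_output(self, f2_design):
        cfg = SimConfig(n_offspring=10, n_markers=50, offspring_depth=6.0,
                        bias_fraction=0, mismap_fraction=0, seed=9)
        truth, ds = simulate(cfg)
        params = ModelParams(50)
        res = correct_dataset(ds, f2_design, params, np.random.default_rng(1))
        from dataclasses import replace

        swapped = replace(ds, reads=ds.reads[..., ::-1].copy())
        res_s = correct_dataset(swapped, f2_design, params, np.random.default_rng(1))
        ok = (res.genotypes >= 0) & (res_s.genotypes >= 0)
        np.testing.assert_array_equal(res.genotypes[ok], 2 - res_s.genotypes[ok])

    def test_correct_call_rate_nondecreasing_in_depth(self, f2_design):
        # unbiased data: averaged over seeds the call rate improves with depth
        means = []
        for depth in (0.5, 3.0, 20.0):
            rates = []
            for seed in range(8):
                cfg = SimConfig(n_offspring=20, n_markers=150, offspring_depth=depth,
                                bias_fraction=0, mismap_fraction=0, seed=100 + seed)
                truth, ds = simulate(cfg)
                res = correct_dataset(
                    ds, f2_design, ModelParams(150), np.random.default_rng(seed)
                )
                rates.append(call_metrics(res.genotypes, truth.genotypes).mean_correct)
            means.append(np.mean(rates))
        assert means[0] <= means[1] <= means[2]
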