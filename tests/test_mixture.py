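"""Per-locus mixture EM, genotype assignment, accuracy metrics, and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gras2qtl.errors import DataFormatError, NonEstimableError
from gras2qtl.mixture import (
    DepthMatrix,
    MixtureFit,
    assign_genotypes,
    call_markers,
    codominant_accuracy,
    collapse_to_dominant,
    consensus_filter,
    dominant_accuracy,
    fit_mixture_em,
    initialize_mixture,
    marker_set_from_calls,
    parental_consistency_filter,
    priority_merge,
)
from conftest import genotype_frame


def trimodal_counts(rng, n=150, mus=(2.0, 60.0, 120.0), sds=(1.0, 8.0, 11.0)):
    """Counts from a well-separated three-gamma mixture, weights 1:2:1."""
    comp = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
    shape = np.array(mus) ** 2 / np.array(sds) ** 2
    scale = np.array(sds) ** 2 / np.array(mus)
    return np.round(rng.gamma(shape[comp], scale[comp])), comp


class TestInitializeMixture:
    def test_weights_exact_quarter_half_quarter(self):
        rng = np.random.default_rng(0)
        x, _ = trimodal_counts(rng)
        for family in ("gamma", "normal"):
            init = initialize_mixture(x, family)
            assert init.weights.tolist() == [0.25, 0.50, 0.25]

    def test_normal_means_are_zero_q50_q75(self):
        rng = np.random.default_rng(1)
        x, _ = trimodal_counts(rng)
        init = initialize_mixture(x, "normal")
        assert init.means[0] == 0.0
        assert init.means[1] == pytest.approx(np.quantile(x, 0.5))
        assert init.means[2] == pytest.approx(np.quantile(x, 0.75))
        assert np.all(init.sds == np.std(x, ddof=1))

    def test_gamma_moment_matching_and_offsets(self):
        # engineered so q50 = 60 and q75 = 120 exactly
        x = np.array(
            [0.0] * 8 + [2.0, 5.0, 60.0, 60.0, 60.0, 80.0, 100.0, 120.0]
            + [120.0, 130.0, 140.0, 150.0, 160.0]
        )
        assert np.quantile(x, 0.5) == 60.0 and np.quantile(x, 0.75) == 120.0
        init = initialize_mixture(x, "gamma")
        sd = np.std(x, ddof=1)
        # component 3: target mean 120, target sd = sd/2
        assert init.pre_shape[2] == pytest.approx(120.0**2 / (sd / 2) ** 2)
        assert init.pre_scale[2] == pytest.approx((sd / 2) ** 2 / 120.0)
        # component 2: target mean 60, target sd = sd/2
        assert init.pre_shape[1] == pytest.approx(60.0**2 / (sd / 2) ** 2)
        assert np.allclose(init.shape, init.pre_shape + 1.0)
        assert np.allclose(init.scale, init.pre_scale + 0.5)

    def test_gamma_pre_initials_match_target_moments(self):
        # moment matching: for each nonzero component, alpha*theta equals the
        # target mean and alpha*theta^2 the target variance
        rng = np.random.default_rng(8)
        x, _ = trimodal_counts(rng)
        init = initialize_mixture(x, "gamma")
        targets_m = [init.q50, init.q75]
        targets_s = [init.sd_total / 2, init.sd_total / 2]
        for k, (m, s) in enumerate(zip(targets_m, targets_s), start=1):
            assert init.pre_shape[k] * init.pre_scale[k] == pytest.approx(m)
            assert init.pre_shape[k] * init.pre_scale[k] ** 2 == pytest.approx(s**2)

    def test_gamma_worked_example_q75_120_sd_45(self):
        # counts rescaled so that q75 = 120 and sd = 45 exactly: the third
        # component then targets (mean 120, sd 22.5), so pre-initials are
        # (28.44, 4.219) and the EM starting values (29.44, 4.719)
        rng = np.random.default_rng(9)
        x, _ = trimodal_counts(rng)
        x = x - np.mean(x)
        x = x * (45.0 / np.std(x, ddof=1))
        x = x + (120.0 - np.quantile(x, 0.75))
        init = initialize_mixture(x, "gamma")
        assert init.sd_total == pytest.approx(45.0)
        assert init.q75 == pytest.approx(120.0)
        assert init.pre_shape[2] == pytest.approx(28.44, abs=0.005)
        assert init.pre_scale[2] == pytest.approx(4.219, abs=0.001)
        assert init.shape[2] == pytest.approx(29.44, abs=0.005)
        assert init.scale[2] == pytest.approx(4.719, abs=0.001)

    def test_zero_mean_component_initials(self):
        rng = np.random.default_rng(2)
        x, _ = trimodal_counts(rng)
        init = initialize_mixture(x, "gamma")
        assert init.pre_shape[0] == 0.0 and init.pre_scale[0] == 0.0
        assert init.shape[0] == 1.0 and init.scale[0] == 0.5

    def test_too_few_counts_non_estimable(self):
        with pytest.raises(NonEstimableError):
            initialize_mixture(np.arange(19.0), "gamma")

    def test_constant_counts_non_estimable(self):
        with pytest.raises(NonEstimableError):
            initialize_mixture(np.full(150, 7.0), "normal")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            initialize_mixture(np.arange(30.0), "poisson")


class TestFitMixtureEM:
    @pytest.mark.parametrize("family", ["gamma", "normal"])
    def test_loglik_monotone_and_bounded_iterations(self, family):
        rng = np.random.default_rng(3)
        x, _ = trimodal_counts(rng)
        fit = fit_mixture_em(x, initialize_mixture(x, family))
        assert fit.converged
        assert fit.n_iter <= 5000
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-6)
        assert fit.loglik_trace[-1] >= fit.loglik_trace[0]

    @pytest.mark.parametrize("family", ["gamma", "normal"])
    def test_posterior_rows_sum_to_one(self, family):
        rng = np.random.default_rng(4)
        x, _ = trimodal_counts(rng)
        fit = fit_mixture_em(x, initialize_mixture(x, family))
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert fit.posteriors.shape == (len(x), 3)

    def test_component_means_recovered_within_15_pct(self):
        rng = np.random.default_rng(5)
        mus = (2.0, 60.0, 120.0)
        x, _ = trimodal_counts(rng, n=300, mus=mus)
        fit = fit_mixture_em(x, initialize_mixture(x, "gamma"))
        fitted = np.sort(fit.component_means)
        for m_hat, m in zip(fitted[1:], mus[1:]):
            assert abs(m_hat - m) / m < 0.15
        assert fitted[0] < 10.0

    def test_weights_recovered(self):
        rng = np.random.default_rng(6)
        x, _ = trimodal_counts(rng, n=600)
        fit = fit_mixture_em(x, initialize_mixture(x, "gamma"))
        w = fit.weights[fit.component_order]
        assert np.allclose(w, [0.25, 0.5, 0.25], atol=0.08)
        assert fit.weights.sum() == pytest.approx(1.0)

    @given(seed=st.integers(0, 50))
    def test_property_loglik_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        x, _ = trimodal_counts(rng, n=100)
        for family in ("gamma", "normal"):
            fit = fit_mixture_em(x, initialize_mixture(x, family))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-6)
            if fit.converged:
                assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)


def _toy_fit(posteriors, means=(2.0, 60.0, 120.0)):
    means = np.asarray(means, dtype=float)
    return MixtureFit(
        family="normal",
        weights=np.array([0.25, 0.5, 0.25]),
        params={"mean": means, "sd": np.ones(3)},
        loglik_trace=np.zeros(2),
        n_iter=2,
        converged=True,
        posteriors=np.asarray(posteriors, dtype=float),
    )


class TestAssignGenotypes:
    def test_certain_posterior_maps_by_component_mean(self):
        fit = _toy_fit([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        # source parent 1: dosage of its allele is the genotype code directly
        assert assign_genotypes(fit, 1).tolist() == [0, 1, 2]

    def test_source_parent_2_flips_dosage(self):
        fit = _toy_fit([[1, 0, 0], [0, 0, 1]])
        assert assign_genotypes(fit, 2).tolist() == [2, 0]

    def test_unsorted_component_means_reordered(self):
        fit = _toy_fit([[1, 0, 0], [0, 1, 0], [0, 0, 1]], means=(120.0, 2.0, 60.0))
        assert assign_genotypes(fit, 1).tolist() == [2, 0, 1]

    def test_posterior_tie_is_missing(self):
        fit = _toy_fit([[0.5, 0.5, 0.0], [0.2, 0.2, 0.6]])
        assert assign_genotypes(fit, 1).tolist() == [-1, 2]

    def test_non_converged_fit_raises(self):
        fit = _toy_fit([[1, 0, 0]])
        fit.converged = False
        fit.posteriors = None
        with pytest.raises(NonEstimableError):
            assign_genotypes(fit, 1)


class TestAccuracyMetrics:
    def test_identical_matrices_100_pct(self):
        calls = genotype_frame({"m1": "AAHHBB", "m2": "ABABHH"})
        per, mean = codominant_accuracy(calls, calls.copy())
        assert mean == 100.0
        assert (per == 100.0).all()

    def test_six_disagreements_of_120_is_95_pct(self):
        rng = np.random.default_rng(7)
        codes = rng.choice(list("AHB"), size=120)
        a = genotype_frame({"m1": "".join(codes)})
        flipped = codes.copy()
        for i in range(6):
            flipped[i] = {"A": "H", "H": "B", "B": "A"}[flipped[i]]
        b = genotype_frame({"m1": "".join(flipped)})
        _, mean = codominant_accuracy(a, b)
        assert mean == 95.0

    def test_missing_excluded_from_denominator(self):
        a = genotype_frame({"m1": "AAHH-B"})
        b = genotype_frame({"m1": "AAHHB-"})
        per, _ = codominant_accuracy(a, b)
        assert per.loc["m1"] == 100.0

    def test_no_overlap_raises(self):
        a = genotype_frame({"m1": "AHB"})
        b = genotype_frame({"m2": "AHB"})
        with pytest.raises(DataFormatError):
            codominant_accuracy(a, b)

    def test_collapse_to_dominant_by_source(self):
        calls = genotype_frame({"m1": "AHB-", "m2": "AHB-"})
        src = pd.Series([1, 2], index=["m1", "m2"])
        out = collapse_to_dominant(calls, src)
        assert out.loc["m1"].tolist() == ["P", "P", "A", "-"]
        assert out.loc["m2"].tolist() == ["A", "P", "P", "-"]

    def test_dominant_accuracy_perfect_on_truthful_collapse(self):
        calls = genotype_frame({"m1": "AAHHBB"})
        src = pd.Series([1], index=["m1"])
        dom = genotype_frame({"m1": "PPPPAA"})
        _, mean = dominant_accuracy(calls, dom, src)
        assert mean == 100.0


def _marker_set(rows, source_parent=None, info_extra=None):
    calls = genotype_frame(rows)
    sp = source_parent or {m: 1 for m in rows}
    ms = marker_set_from_calls(calls, "gamma", pd.Series(sp))
    if info_extra:
        for col, vals in info_extra.items():
            ms.info[col] = [vals[m] for m in ms.info.index]
    return ms


class TestFilters:
    def test_consensus_strictly_greater_than_threshold(self):
        ms = _marker_set({"m1": "AHB", "m2": "AHB"})
        ms.info["consensus_pct"] = [95.0, 95.1]
        out = consensus_filter(ms)
        assert list(out.calls.index) == ["m2"]
        assert out.filter_history[-1]["step"] == "consensus_filter"

    def test_consensus_recomputed_from_dominant(self):
        ms = _marker_set({"m1": "AAHHBB"})
        dom = genotype_frame({"m1": "PPPPAA"})  # perfect agreement
        out = consensus_filter(ms, dom)
        assert out.n_markers == 1
        assert out.info.loc["m1", "consensus_pct"] == 100.0

    def test_consensus_without_column_raises(self):
        ms = _marker_set({"m1": "AHB"})
        with pytest.raises(DataFormatError):
            consensus_filter(ms)

    @pytest.mark.parametrize(
        "p1, p2, kept", [(2, 0, True), (1, 0, False), (-1, 0, False), (2, 1, False)]
    )
    def test_parental_consistency(self, p1, p2, kept):
        ms = _marker_set(
            {"m1": "AHB"},
            info_extra={"parent1_call": {"m1": p1}, "parent2_call": {"m1": p2}},
        )
        out = parental_consistency_filter(ms)
        assert (out.n_markers == 1) is kept

    def test_priority_merge_prefers_earlier_sets(self):
        default = _marker_set({"m1": "AAA"})
        default.info["source"] = "default"
        gamma = _marker_set({"m1": "BBB", "m2": "HHH"})
        normal = _marker_set({"m2": "AAA", "m3": "BBB"})
        normal.info["source"] = "normal"
        merged = priority_merge(default, gamma, normal)
        assert merged.n_markers == 3
        assert merged.calls.loc["m1"].tolist() == ["A", "A", "A"]
        assert merged.calls.loc["m2"].tolist() == ["H", "H", "H"]
        assert merged.info.loc["m1", "source"] == "default"
        assert merged.info.loc["m3", "source"] == "normal"

    def test_priority_merge_idempotent_and_associative(self):
        a = _marker_set({"m1": "AAA", "m2": "HHH"})
        b = _marker_set({"m2": "BBB", "m3": "AAA"})
        c = _marker_set({"m3": "HHH"})
        once = priority_merge(a, b, c)
        nested = priority_merge(priority_merge(a, b), c)
        pd.testing.assert_frame_equal(once.calls, nested.calls)
        again = priority_merge(once)
        pd.testing.assert_frame_equal(once.calls, again.calls)

    def test_priority_merge_empty_raises(self):
        with pytest.raises(DataFormatError):
            priority_merge()


@pytest.fixture(scope="module")
def called(small_dataset):
    gamma, fits = call_markers(small_dataset.depths, "gamma")
    return gamma, fits


class TestCallMarkers:
    def test_accuracy_against_truth(self, called, small_dataset):
        gamma, _ = called
        _, acc = codominant_accuracy(gamma.calls, small_dataset.truth.genotypes)
        assert acc > 90.0

    def test_info_columns_and_history(self, called):
        gamma, _ = called
        for col in ("source", "converged", "n_iter", "source_parent",
                    "parent1_call", "parent2_call", "parental_ok"):
            assert col in gamma.info.columns
        assert gamma.info["converged"].all()
        assert gamma.filter_history[-1]["step"] == "em_convergence"

    def test_parents_called_as_opposite_homozygotes(self, called):
        gamma, _ = called
        assert gamma.info["parental_ok"].mean() > 0.9

    def test_constant_marker_dropped_not_crashing(self, small_dataset):
        d = small_dataset.depths
        counts = d.counts.copy()
        counts.loc["FLAT"] = 7
        dm = DepthMatrix(
            counts=counts,
            parent1_counts=pd.concat([d.parent1_counts, pd.Series({"FLAT": 7})]),
            parent2_counts=pd.concat([d.parent2_counts, pd.Series({"FLAT": 7})]),
            source_parent=pd.concat([d.source_parent, pd.Series({"FLAT": 1})]),
        )
        ms, fits = call_markers(dm, "gamma")
        assert "FLAT" not in ms.calls.index
        assert "FLAT" not in fits

    def test_depth_matrix_validation(self, small_dataset):
        d = small_dataset.depths
        with pytest.raises(DataFormatError):
            DepthMatrix(
                counts=d.counts,
                parent1_counts=d.parent1_counts.iloc[:-1],
                parent2_counts=d.parent2_counts,
                source_parent=d.source_parent,
            )
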