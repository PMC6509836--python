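import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import norm

from celltag_demux import (
    CellTagDemux,
    NormalizedTagMatrix,
    TagCountMatrix,
    TagDensity,
    agreement_kappa,
    classify,
    compute_proportions,
    expected_multiplet_percent,
    log_normalize,
    multiplet_checkpoint,
    select_tags,
)
from celltag_demux.demux import MULTIPLET, NON_DETERMINED, SINGLET

from .conftest import TAG_A, TAG_B


def make_matrix(counts, tags=None):
    counts = np.asarray(counts)
    tags = tags or [TAG_A, TAG_B][: counts.shape[1]]
    return TagCountMatrix(
        np.array([f"c{i}" for i in range(counts.shape[0])], dtype=object),
        np.array(tags, dtype=object),
        sp.csr_matrix(counts),
    )


def make_norm(values, zero_flag=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return NormalizedTagMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        tag_seqs=np.array([f"TAG{j}" for j in range(k)], dtype=object),
        zero_flag=np.zeros(n, bool) if zero_flag is None else np.asarray(zero_flag),
    )


def make_P(P, zero_flag=None, cell_ids=None):
    P = np.asarray(P, dtype=float)
    from celltag_demux import ProportionMatrix

    n, k = P.shape
    return ProportionMatrix(
        P=P,
        cell_ids=np.array(cell_ids or [f"c{i}" for i in range(n)], dtype=object),
        tag_seqs=np.array([f"TAG{j}" for j in range(k)], dtype=object),
        zero_flag=np.zeros(n, bool) if zero_flag is None else np.asarray(zero_flag),
    )


class TestSelectTags:
    def test_expected_tags_kept_in_given_order(self, small_matrix):
        out = select_tags(small_matrix, expected_tags=[TAG_B, TAG_A])
        assert list(out.tag_seqs) == [TAG_B, TAG_A]

    def test_top_k_equal_to_n_tags_is_identity(self, small_matrix):
        assert select_tags(small_matrix, top_k=2).equals(small_matrix)

    def test_top_k_ranks_by_cell_prevalence(self, rng):
        # 5 true tags present in 90% of cells, 50 noise tags in <1%
        n = 200
        true_tags = [f"{b*8}" for b in "ACGTA"][:4] + ["TTTTAAAA"]
        noise_tags = sorted(
            {"".join(rng.choice(list("ACGT"), 8)) for _ in range(80)} - set(true_tags)
        )[:50]
        counts = np.zeros((n, 5 + 50), dtype=int)
        for j in range(5):
            mask = rng.random(n) < 0.9
            counts[mask, j] = rng.integers(1, 20, mask.sum())
        for j in range(5, 55):
            mask = rng.random(n) < 0.01
            counts[mask, j] = 1
        m = make_matrix(counts, tags=true_tags + noise_tags)
        out = select_tags(m, top_k=5)
        assert sorted(out.tag_seqs) == sorted(true_tags)

    def test_absent_expected_tag_named_in_error(self, small_matrix):
        with pytest.raises(KeyError, match="AAAACCCC"):
            select_tags(small_matrix, expected_tags=["AAAACCCC"])

    def test_exactly_one_selector_required(self, small_matrix):
        with pytest.raises(ValueError):
            select_tags(small_matrix)
        with pytest.raises(ValueError):
            select_tags(small_matrix, expected_tags=[TAG_A], top_k=1)


class TestLogNormalize:
    def test_zero_count_row_is_flagged_and_zero(self):
        norm = log_normalize(make_matrix([[0, 0], [1, 0]]))
        assert norm.zero_flag[0] and not norm.zero_flag[1]
        np.testing.assert_array_equal(norm.values[0], [0.0, 0.0])

    def test_equal_counts_give_ln6_at_scale_10(self):
        norm = log_normalize(make_matrix([[5, 5]]), scale=10)
        np.testing.assert_allclose(norm.values[0], np.log(6.0), rtol=1e-12)

    def test_depth_invariance(self):
        a = log_normalize(make_matrix([[3, 9]]))
        b = log_normalize(make_matrix([[30, 90]]))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_zero_iff_zero_count(self):
        norm = log_normalize(make_matrix([[4, 0], [1, 1]]))
        assert norm.values[0, 1] == 0.0 and (norm.values[1] > 0).all()


class TestTagDensity:
    def test_point_mass_survival_is_step(self):
        d = TagDensity(np.full(10, 2.0))
        assert d.point_mass
        np.testing.assert_array_equal(
            d.survival(np.array([1.9, 2.0, 2.1])), [1.0, 1.0, 0.0]
        )

    def test_clamped_sampling_nonnegative_and_survival_one_at_zero(self, rng):
        d = TagDensity(np.array([0.0] * 50 + [2.0] * 50))
        draws = d.sample(rng, 5000)
        assert (draws >= 0).all()
        assert d.survival(np.array([0.0]))[0] == 1.0

    def test_survival_matches_normal_mixture(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        d = TagDensity(vals)
        x = 1.5
        expected = norm.sf((x - vals) / d.bandwidth).mean()
        np.testing.assert_allclose(d.survival(np.array([x]))[0], expected, rtol=1e-12)


class TestComputeProportions:
    def test_constant_column_saturates_at_one(self):
        P = compute_proportions(make_norm([[1.0], [1.0], [1.0]]), 100, 3, seed=0)
        np.testing.assert_array_equal(P.P, 1.0)

    def test_value_above_point_mass_gets_zero(self):
        d = TagDensity(np.full(5, 1.0))
        draws = d.sample(np.random.default_rng(0), 1000)
        assert (draws < 2.0).all()  # C above every draw -> P = 0

    def test_entries_bounded_and_monotone_in_value(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(100, 2))
        P = compute_proportions(make_norm(vals), 500, 10, seed=3)
        assert ((P.P >= 0) & (P.P <= 1)).all()
        for j in range(2):
            order = np.argsort(vals[:, j])
            diffs = np.diff(P.P[order, j])
            assert (diffs <= 1e-12).all()

    def test_seed_determinism(self):
        norm_m = make_norm(np.random.default_rng(0).gamma(2, 1, (50, 2)))
        P1 = compute_proportions(norm_m, 200, 5, seed=42)
        P2 = compute_proportions(norm_m, 200, 5, seed=42)
        np.testing.assert_array_equal(P1.P, P2.P)

    def test_sampled_proportions_approach_closed_form(self, rng):
        # small version of the survival-function oracle
        vals = np.concatenate([np.zeros(60), rng.normal(2.4, 0.1, 40)]).clip(min=0)
        norm_m = make_norm(vals[:, None])
        P = compute_proportions(norm_m, 1000, 50, seed=9)
        d = TagDensity(vals)
        exact = norm.sf((vals[:, None] - d.centers) / d.bandwidth).mean(axis=1)
        exact[vals <= 0] = 1.0
        assert np.abs(P.P[:, 0] - exact).max() <= 0.02


class TestClassify:
    def test_clear_gap_is_singlet(self):
        cls = classify(make_P([[0.01, 0.95]]))
        assert cls.category[0] == SINGLET and cls.tags[0] == ("TAG0",)

    def test_exact_tie_is_multiplet(self):
        cls = classify(make_P([[0.02, 0.02]]))
        assert cls.category[0] == MULTIPLET and set(cls.tags[0]) == {"TAG0", "TAG1"}

    def test_high_minimum_is_non_determined(self):
        cls = classify(make_P([[0.90, 0.95]]), nd_threshold=0.762)
        assert cls.category[0] == NON_DETERMINED

    def test_zero_flagged_cell_is_non_determined(self):
        cls = classify(make_P([[0.0, 0.5]], zero_flag=[True]))
        assert cls.category[0] == NON_DETERMINED

    def test_delta_zero_limits_multiplets_to_exact_ties(self):
        P = make_P([[0.1, 0.1], [0.1, 0.100001]])
        cls = classify(P, delta=0.0)
        assert cls.category[0] == MULTIPLET and cls.category[1] == SINGLET

    def test_delta_one_makes_all_determined_cells_full_multiplets(self):
        P = make_P([[0.1, 0.7], [0.9, 0.95]])
        cls = classify(P, delta=1.0)
        assert cls.category[0] == MULTIPLET and len(cls.tags[0]) == 2
        assert cls.category[1] == NON_DETERMINED

    def test_categories_partition_cells(self, rng):
        P = make_P(rng.random((200, 3)))
        counts = classify(P).summary()
        assert sum(counts.values()) == 200

    def test_empty_tag_set_rejected(self):
        with pytest.raises(ValueError):
            classify(make_P(np.empty((3, 0))))


class TestExpectedMultipletPercent:
    def test_matches_printed_calibration_at_4673_cells(self):
        assert round(expected_multiplet_percent(4673), 1) == 3.6

    def test_intercept_at_zero_cells(self):
        assert expected_multiplet_percent(0) == pytest.approx(0.0527214)

    def test_linear_evaluation_at_10000(self):
        assert expected_multiplet_percent(10_000) == pytest.approx(7.6417214)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            expected_multiplet_percent(-1)


class TestMultipletCheckpoint:
    def build(self, n_mult, n_cells, gaps):
        # multiplet rows have two equal-ish small entries; gap controlled
        rows = [[0.1, 0.1 + g] for g in gaps]
        rows += [[0.05, 0.9]] * (n_cells - n_mult)
        P = make_P(rows)
        cls = classify(P)
        assert (cls.category[:n_mult] == MULTIPLET).all()
        return cls, P

    def test_untriggered_checkpoint_returns_input(self):
        cls, P = self.build(2, 2000, [0.0, 0.01])
        # E(2000) = round(1.57% of 2000) = 31 >> 2 multiplets
        assert multiplet_checkpoint(cls, P, 2000) is cls

    def test_quantile_rule_retains_smallest_gaps(self):
        # n_cells = 500 -> expected % = 0.4322, E = round(2.16) = 2, keep 3 of 6
        gaps = [0.20, 0.00, 0.10, 0.15, 0.05, 0.23]
        cls, P = self.build(6, 500, gaps)
        out = multiplet_checkpoint(cls, P, 500)
        kept = [i for i in range(6) if out.category[i] == MULTIPLET]
        assert len(kept) == 3
        assert sorted(np.array(gaps)[kept]) == sorted(gaps)[:3]
        demoted = [i for i in range(6) if out.category[i] == SINGLET]
        assert all(out.tags[i] == ("TAG0",) for i in demoted)
        assert max(np.array(gaps)[kept]) <= min(np.array(gaps)[demoted])

    def test_zero_expected_demotes_every_multiplet(self):
        cls, P = self.build(3, 0, [0.0, 0.1, 0.2])
        out = multiplet_checkpoint(cls, P, 0)
        assert (out.category[:3] == SINGLET).all()


class TestAgreementKappa:
    def test_identical_vectors_give_one(self):
        assert agreement_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_constant_vs_balanced_gives_zero(self):
        a = ["x"] * 10 + ["y"] * 10
        b = ["x"] * 20
        assert agreement_kappa(a, b) == pytest.approx(0.0)

    def test_known_confusion_table_gives_040(self):
        # table [[20, 5], [10, 15]]: p_o = 0.70, p_e = 0.50 -> kappa = 0.40
        a = ["p"] * 25 + ["n"] * 25
        b = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        assert agreement_kappa(a, b) == pytest.approx(0.40)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_kappa(["a"], ["a", "b"])


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, small_sim_config):
        from celltag_demux import simulate_count_matrix

        matrix, _ = simulate_count_matrix(small_sim_config)
        res = CellTagDemux(matrix, top_k=2, n_samples=200, n_iter=5).fit(seed=0)
        counts = res.classification.summary()
        assert sum(counts.values()) == matrix.n_cells
        text = res.summary()
        assert "singlets" in text and "non-determined" in text
        df = res.to_frame()
        assert list(df.columns) == ["cell_id", "label", "tags", "min_p", "gap"]

    def test_from_dataframe_constructor(self, small_matrix):
        model = CellTagDemux.from_dataframe(small_matrix.to_dataframe(), top_k=2)
        assert model.matrix.equals(small_matrix)
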