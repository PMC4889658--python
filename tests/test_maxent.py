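"""Maximum-entropy splice-site model: fits, scoring, quartiles, serialization."""

import itertools

import numpy as np
import pytest

from genearch.maxent_splice import (
    FactorizedMaxEnt,
    MarginalConstraintSet,
    SpliceSiteModel,
    ZeroOrderModel,
    acceptor_fragment_layout,
    adjacent_pair_constraints,
    assign_quartiles,
    collect_training_windows,
    consecutive_fragment_layout,
    empirical_distribution,
    encode,
    full_constraints,
    load_model,
    save_model,
    singleton_constraints,
    train_factorized,
    train_maxent,
)

BASES = "ACGT"


def all_windows(k):
    return ["".join(w) for w in itertools.product(BASES, repeat=k)]


class TestConstraints:
    def test_uncovered_position_rejected(self):
        with pytest.raises(ValueError, match="every position"):
            MarginalConstraintSet(3, ((0,), (1,)))

    def test_duplicate_subset_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarginalConstraintSet(2, ((0,), (1,), (0,)))


class TestTrainMaxent:
    def test_fully_constrained_equals_pseudocounted_empirical(self):
        # Exhaustive k=3 check: constraining the full joint forces the fit
        # to the pseudocounted empirical distribution itself.
        rng = np.random.default_rng(0)
        windows = ["".join(rng.choice(list(BASES), 3)) for _ in range(200)]
        dist = train_maxent(windows, full_constraints(3), pseudocount=1.0, tol=1e-10)
        emp = empirical_distribution(windows, 3, 1.0)
        np.testing.assert_allclose(dist.probs, emp, atol=1e-12)

    def test_singleton_constraints_give_product_of_marginals(self):
        rng = np.random.default_rng(1)
        windows = ["".join(rng.choice(list(BASES), 2, p=[0.5, 0.2, 0.2, 0.1])) for _ in range(300)]
        dist = train_maxent(windows, singleton_constraints(2), pseudocount=0.5, tol=1e-12)
        emp = empirical_distribution(windows, 2, 0.5)
        expected = np.outer(emp.sum(axis=1), emp.sum(axis=0))
        np.testing.assert_allclose(dist.probs, expected, atol=1e-10)

    def test_pairwise_marginals_match_sample(self):
        # Windows from a pairwise-coupled source; fitted adjacent-pair
        # marginals must match the empirical ones within tol, verified by
        # exhaustive enumeration of the 64 outcomes.
        rng = np.random.default_rng(2)
        windows = []
        for _ in range(500):
            a = rng.choice(list(BASES))
            b = a if rng.random() < 0.6 else rng.choice(list(BASES))
            c = b if rng.random() < 0.6 else rng.choice(list(BASES))
            windows.append(a + b + c)
        tol = 1e-6
        dist = train_maxent(windows, adjacent_pair_constraints(3), tol=tol)
        emp = empirical_distribution(windows, 3, 1.0)
        for subset in ((0, 1), (1, 2), (0,), (1,), (2,)):
            axes = tuple(i for i in range(3) if i not in subset)
            np.testing.assert_allclose(
                dist.probs.sum(axis=axes), emp.sum(axis=axes), atol=tol * 5
            )

    def test_normalization(self):
        rng = np.random.default_rng(3)
        windows = ["".join(rng.choice(list(BASES), 4)) for _ in range(100)]
        dist = train_maxent(windows)
        assert abs(dist.probs.sum() - 1.0) < 1e-9

    def test_log_likelihood_nondecreasing(self):
        rng = np.random.default_rng(4)
        windows = []
        for _ in range(300):
            a = rng.choice(list(BASES), p=[0.6, 0.2, 0.1, 0.1])
            b = a if rng.random() < 0.7 else rng.choice(list(BASES))
            windows.append(a + b + rng.choice(list(BASES)))
        dist = train_maxent(windows, adjacent_pair_constraints(3), tol=1e-10)
        ll = np.array(dist.log_likelihood_path)
        assert np.all(np.diff(ll) > -1e-9)

    def test_duplication_scaling_invariance(self):
        # counts x c => same distribution (pseudocount scaled alike).
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list(BASES), 3)) for _ in range(50)]
        d1 = train_maxent(windows, adjacent_pair_constraints(3), pseudocount=1.0, tol=1e-10)
        d3 = train_maxent(windows * 3, adjacent_pair_constraints(3), pseudocount=3.0, tol=1e-10)
        np.testing.assert_allclose(d1.probs, d3.probs, atol=1e-8)

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list(BASES), 3)) for _ in range(80)]
        d1 = train_maxent(windows, tol=1e-10)
        d2 = train_maxent(windows[::-1], tol=1e-10)
        np.testing.assert_allclose(d1.probs, d2.probs, atol=1e-12)

    def test_inconsistent_widths_rejected(self):
        with pytest.raises(ValueError, match="widths"):
            train_maxent(["AAA", "AAAA"])

    def test_zero_probability_constraint_without_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            train_maxent(["AA", "AA"], singleton_constraints(2), pseudocount=0.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_maxent([])


class TestFactorized:
    def test_single_fragment_layout_equals_dense(self):
        rng = np.random.default_rng(7)
        windows = ["".join(rng.choice(list(BASES), 4)) for _ in range(150)]
        dense = train_maxent(windows, adjacent_pair_constraints(4), tol=1e-10)
        fact = train_factorized(windows, [(0, 1, 2, 3)], tol=1e-10)
        for w in all_windows(4):
            assert fact.log2prob(w) == pytest.approx(dense.log2prob(w), abs=1e-8)

    def test_disjoint_fragments_on_independent_data_equal_dense(self):
        # Data built as a full cross product factorizes exactly across the
        # cut; with pseudocount 0 the dense fit equals the fragment product.
        rng = np.random.default_rng(8)
        halves_a = ["".join(rng.choice(list(BASES), 3)) for _ in range(10)]
        halves_b = ["".join(rng.choice(list(BASES), 3)) for _ in range(10)]
        windows = [a + b for a in halves_a for b in halves_b]
        dense = train_maxent(windows, full_constraints(6), pseudocount=1e-12, tol=1e-12)
        fact = train_factorized(
            windows, [(0, 1, 2), (3, 4, 5)],
            constraints_factory=full_constraints, pseudocount=1e-12, tol=1e-12,
        )
        # compare on the data's support, where counts dominate the
        # (vanishing) pseudocount mass
        for w in [halves_a[0] + halves_b[0], halves_a[3] + halves_b[7], windows[42]]:
            assert fact.log2prob(w) == pytest.approx(dense.log2prob(w), abs=1e-6)

    def test_exact_normalization_over_exhaustive_windows(self):
        rng = np.random.default_rng(9)
        windows = ["".join(rng.choice(list(BASES), 6, p=[0.4, 0.3, 0.2, 0.1])) for _ in range(200)]
        fact = train_factorized(windows, consecutive_fragment_layout(range(6), width=4, overlap=2))
        total = sum(fact.prob(w) for w in all_windows(6))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_finite_logprob_for_training_windows(self):
        rng = np.random.default_rng(10)
        windows = ["".join(rng.choice(list(BASES), 8)) for _ in range(50)]
        fact = train_factorized(windows, consecutive_fragment_layout(range(8), 5, 2))
        assert all(np.isfinite(fact.log2prob(w)) for w in windows)

    def test_uncovered_layout_rejected(self):
        rng = np.random.default_rng(11)
        windows = ["".join(rng.choice(list(BASES), 6)) for _ in range(20)]
        with pytest.raises(ValueError, match="uncovered"):
            train_factorized(windows, [(0, 1, 2)])

    def test_acceptor_layout_covers_all_non_ag_positions(self):
        layout = acceptor_fragment_layout()
        covered = sorted({p for frag in layout for p in frag})
        assert covered == [p for p in range(23) if p not in (18, 19)]


class TestScoring:
    def test_identical_signal_and_background_score_zero(self):
        rng = np.random.default_rng(12)
        windows = ["".join(rng.choice(list(BASES), 3)) for _ in range(100)]
        dist = train_maxent(windows, tol=1e-10)
        model = SpliceSiteModel(site_kind="donor", signal=dist, background=dist)
        for w in ("AAA", "CGT", "TTT"):
            assert model.score(w) == pytest.approx(0.0, abs=1e-12)

    def test_single_position_closed_form(self):
        # signal P(A)=0.75 vs background P(A)=0.25 => score(A) = log2(3).
        signal = ZeroOrderModel(1, np.array([0.75, 0.25 / 3, 0.25 / 3, 0.25 / 3]))
        background = ZeroOrderModel(1, np.array([0.25, 0.25, 0.25, 0.25]))
        model = SpliceSiteModel(site_kind="donor", signal=signal, background=background)
        assert model.score("A") == pytest.approx(np.log2(3), abs=1e-12)

    def test_k3_scores_match_exhaustive_table(self):
        # Dual-route check: dense fits on listed counts vs hand-computed
        # log-ratios over the enumerated 64 outcomes.
        sig_windows = ["AAA"] * 6 + ["ACG"] * 3 + ["TTT"] * 1
        bg_windows = ["AAA"] * 2 + ["ACG"] * 2 + ["TTT"] * 2 + ["GGG"] * 4
        pc = 1.0
        model = SpliceSiteModel(
            site_kind="donor",
            signal=train_maxent(sig_windows, full_constraints(3), pc, tol=1e-12),
            background=train_maxent(bg_windows, full_constraints(3), pc, tol=1e-12),
        )
        cell = pc / 64
        for w in all_windows(3):
            ns = {"AAA": 6, "ACG": 3, "TTT": 1}.get(w, 0)
            nb = {"AAA": 2, "ACG": 2, "TTT": 2, "GGG": 4}.get(w, 0)
            expected = np.log2(((ns + cell) / (10 + pc)) / ((nb + cell) / (10 + pc)))
            assert model.score(w) == pytest.approx(expected, abs=1e-9)

    def test_n_in_window_is_undefined(self):
        dist = train_maxent(["AAA", "CCC"], tol=1e-8)
        model = SpliceSiteModel(site_kind="donor", signal=dist, background=dist)
        assert model.score("ANA") is None

    def test_width_mismatch_is_error(self):
        dist = train_maxent(["AAA", "CCC"], tol=1e-8)
        model = SpliceSiteModel(site_kind="donor", signal=dist, background=dist)
        with pytest.raises(ValueError):
            model.score("AAAA")

    def test_planted_strength_separation(self, small_synth, small_survey):
        # Sites drawn with higher planted sharpness must score higher on
        # average than low-sharpness sites (planted-strength recovery).
        syn, _ = small_synth
        idf = small_survey.intron_frame.dropna(subset=["donor_score"])
        merged = idf.merge(syn.truth.introns, on=["gene_id", "ordinal"], suffixes=("", "_t"))
        hi = merged[merged["donor_sharpness"] > merged["donor_sharpness"].median()]
        lo = merged[merged["donor_sharpness"] <= merged["donor_sharpness"].median()]
        assert hi["donor_score"].mean() > lo["donor_score"].mean()


class TestWindows:
    def test_donor_window_construction(self):
        from genearch.gene_model import IntronRecord

        rec = IntronRecord(
            gene_id="g", transcript_id="t", ordinal=1, pos_class="first",
            length=32, sequence="GTAAGT" + "C" * 24 + "AG", donor_dinuc="GT",
            acceptor_dinuc="AG", donor_window="CAGGTAAGT",
            acceptor_window="C" * 17 + "CAG" + "GGG",
        )
        assert collect_training_windows([rec], "donor") == ["CAGGTAAGT"]

    def test_window_with_n_excluded(self):
        from genearch.gene_model import IntronRecord

        rec = IntronRecord(
            gene_id="g", transcript_id="t", ordinal=1, pos_class="first",
            length=32, sequence="GT" + "C" * 28 + "AG", donor_dinuc="GT",
            acceptor_dinuc="AG", donor_window="CANGTAAGT", acceptor_window=None,
        )
        with pytest.raises(ValueError, match="no usable"):
            collect_training_windows([rec], "donor")

    def test_min_intron_admits_disjoint_windows(self):
        # 6 intronic donor nt + 20 intronic acceptor nt = 26 <= 32.
        from genearch.gene_model import ACCEPTOR_INTRONIC, DONOR_INTRONIC, MIN_INTRON_LEN

        assert DONOR_INTRONIC + ACCEPTOR_INTRONIC <= MIN_INTRON_LEN


class TestQuartiles:
    def test_percentile_arithmetic(self):
        q, labels = assign_quartiles(list(range(1, 9)))
        assert q.cuts == pytest.approx((2.75, 4.5, 6.25))
        assert labels.count("weak") == 2
        assert labels.count("strong") == 2

    def test_boundary_goes_to_lower_class(self):
        q, _ = assign_quartiles([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        assert q.label(q.cuts[0]) == "weak"
        assert q.label(q.cuts[0] + 1e-9) == "moderately weak"
        assert q.label(q.cuts[2]) == "moderately strong"

    def test_degenerate_scores_flagged(self):
        q, _ = assign_quartiles([5.0] * 10)
        assert q.degenerate

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([1.0, 2.0, 3.0])


class TestSerialization:
    def test_dense_roundtrip_and_byte_identity(self, tmp_path):
        rng = np.random.default_rng(13)
        windows = ["".join(rng.choice(list(BASES), 3)) for _ in range(60)]
        model = SpliceSiteModel(
            site_kind="donor",
            signal=train_maxent(windows, tol=1e-8),
            background=train_maxent(windows[::2], tol=1e-8),
        )
        p1, p2 = tmp_path / "m1.txt", tmp_path / "m2.txt"
        save_model(model, p1)
        loaded = load_model(p1)
        save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for w in ("AAA", "CGT"):
            assert loaded.score(w) == pytest.approx(model.score(w), abs=1e-12)

    def test_factorized_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        windows = ["".join(rng.choice(list(BASES), 6)) for _ in range(80)]
        layout = consecutive_fragment_layout(range(6), 4, 2)
        model = SpliceSiteModel(
            site_kind="acceptor",
            signal=train_factorized(windows, layout),
            background=train_factorized(windows[::2], layout),
        )
        p = tmp_path / "m.txt"
        save_model(model, p)
        loaded = load_model(p)
        for w in ("AAAAAA", "ACGTAC"):
            assert loaded.score(w) == pytest.approx(model.score(w), abs=1e-12)
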