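"""Worked examples and invariants of the four auxiliary evidence scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diadem import (
    Peptide,
    RTContext,
    SearchConfig,
    coelution_score,
    precursor_rank_score,
    rt_diff_score,
)
from diadem.edge_features import (
    binomial_tail_neglog,
    build_fragment_match_model,
    chance_match_probability,
    count_fragment_matches,
    fragment_pvalue_score,
    max_intensity_batch,
    pick_peaks,
    FragmentMatchModel,
)
from diadem.peptide_db import Precursor
from diadem.search_core import Edge

from conftest import make_cycle_run, make_spectrum


class TestPrecursorRank:
    def test_all_isotopes_on_top_peak_scores_zero(self):
        # one dominant peak; a huge tolerance lets all three isotope
        # queries match it, so every rank is 1
        ms1 = make_spectrum([500.0], [100.0], ms_level=1)
        assert precursor_rank_score(ms1, 500.0, 1, tolerance_ppm=5000.0) == 0.0

    def test_hand_computed_rank_product(self):
        # mono matches intensity 80 (rank 2), M+1 matches 60 (rank 3),
        # M+2 matches 20 (rank 5): w = -ln(2*3*5) = -ln 30
        ms1 = make_spectrum(
            [100.0, 200.0, 201.00335, 202.0067, 300.0],
            [100.0, 80.0, 60.0, 20.0, 40.0],
            ms_level=1,
        )
        w = precursor_rank_score(ms1, 200.0, 1, tolerance_ppm=10.0)
        assert w == pytest.approx(-np.log(30.0), abs=1e-6)

    def test_no_match_takes_worst_rank(self):
        ms1 = make_spectrum(
            [100.0, 200.0, 300.0, 400.0, 500.0], [5.0, 4.0, 3.0, 2.0, 1.0], ms_level=1
        )
        w = precursor_rank_score(ms1, 777.0, 1, tolerance_ppm=10.0)
        assert w == pytest.approx(-3 * np.log(5.0), abs=1e-6)

    def test_empty_ms1_degenerate_zero(self):
        ms1 = make_spectrum([], [], ms_level=1)
        assert precursor_rank_score(ms1, 500.0, 2, 10.0) == 0.0
        assert precursor_rank_score(None, 500.0, 2, 10.0) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_never_positive(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        ms1 = make_spectrum(
            np.sort(rng.uniform(300, 1500, n)), rng.uniform(1, 1000, n), ms_level=1
        )
        w = precursor_rank_score(ms1, float(rng.uniform(300, 1500)), 2, 10.0)
        assert w <= 0.0


class TestFragmentPValue:
    def test_binomial_tail_example(self):
        # P(X >= 2), X ~ Bin(3, 0.1): 3*0.01*0.9 + 0.001 = 0.028
        assert binomial_tail_neglog(3, 2, 0.1) == pytest.approx(-np.log(0.028), abs=1e-6)

    def test_zero_matches_scores_zero(self):
        assert binomial_tail_neglog(10, 0, 0.3) == 0.0

    def test_interval_union_geometry(self):
        p = chance_match_probability(np.array([100.0, 200.0]), tau_abs=0.5)
        assert p == pytest.approx(2.0 / 101.0, abs=1e-9)

    def test_overlapping_intervals_merged(self):
        # peaks 0.4 apart with tau 0.5: union is one interval, p = 1 capped
        p = chance_match_probability(np.array([100.0, 100.4]), tau_abs=0.5)
        assert p == pytest.approx(1.0)

    def test_few_picked_peaks_uninformative(self):
        spec = make_spectrum([500.0], [10.0])
        assert fragment_pvalue_score(spec, np.array([500.0])) == 0.0

    def test_empty_fragment_set_scores_zero(self):
        spec = make_spectrum([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
        assert fragment_pvalue_score(spec, np.array([])) == 0.0

    def test_monotone_in_matches(self):
        vals = [binomial_tail_neglog(20, k, 0.2) for k in range(21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force_enumeration(self):
        import math

        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 25))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            tail = sum(
                math.comb(n, j) * p ** j * (1 - p) ** (n - j) for j in range(k, n + 1)
            )
            assert binomial_tail_neglog(n, k, p) == pytest.approx(
                -math.log(tail), abs=1e-9
            )

    def test_peak_picking_keeps_top_per_segment(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 1100, 300))
        spec = make_spectrum(mz, rng.uniform(1, 100, 300))
        picked = pick_peaks(spec, n_segments=10, peaks_per_segment=10)
        assert picked.size == 100
        assert np.all(np.diff(picked) > 0)
        # the most intense peak overall is always picked
        assert mz[np.argmax(spec.intensity)] in picked

    def test_chance_probability_against_monte_carlo(self):
        rng = np.random.default_rng(7)
        picked = np.sort(rng.uniform(100, 1000, 30))
        tau = 0.5
        p = chance_match_probability(picked, tau_abs=tau)
        n_mc = 20000
        queries = rng.uniform(picked[0] - tau, picked[-1] + tau, n_mc)
        hits = np.zeros(n_mc, dtype=bool)
        for z in picked:
            hits |= np.abs(queries - z) <= tau
        estimate = hits.mean()
        se = np.sqrt(p * (1 - p) / n_mc)
        assert abs(estimate - p) <= 3 * se + 1e-12


class TestRTDiff:
    def test_hand_computed_difference(self):
        context = RTContext(
            observed=np.array([10.0, 20.0, 30.0, 40.0]),
            predicted=np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
        )
        w = rt_diff_score(20.0, 9.0, context)
        assert w == pytest.approx(-0.5, abs=1e-9)

    def test_both_at_maximum_rank(self):
        context = RTContext(
            observed=np.array([1.0, 2.0, 3.0]), predicted=np.array([10.0, 20.0])
        )
        assert rt_diff_score(3.0, 20.0, context) == 0.0

    def test_unpredictable_takes_fallback(self):
        context = RTContext(observed=np.array([1.0]), predicted=np.array([1.0]))
        assert rt_diff_score(1.0, None, context) == -0.5

    @given(
        st.floats(0, 100, allow_nan=False), st.floats(-50, 50, allow_nan=False)
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, t_obs, t_pred):
        context = RTContext(
            observed=np.arange(0.0, 100.0), predicted=np.arange(-50.0, 50.0)
        )
        w = rt_diff_score(t_obs, t_pred, context)
        assert -1.0 <= w <= 0.0


def coelution_setup(prec_profile, frag_profiles, frag_mzs=(300.0, 400.0, 500.0)):
    """Build a 5-cycle, 1-window run realizing the given elution profiles."""
    pep = Peptide("PEPTIDEK")
    prec = Precursor(pep, 2, False, 0)
    window = (prec.mz - 12.5, prec.mz + 12.5)
    spectra = []
    sid = 0
    for c in range(5):
        sid += 1
        mzs, ints = [], []
        if prec_profile[c] > 0:
            mzs, ints = [prec.mz], [prec_profile[c]]
        spectra.append(
            make_spectrum(mzs, ints, ms_level=1, cycle=c, scan_id=f"scan={sid}")
        )
        sid += 1
        fmzs, fints = [], []
        for mz, profile in zip(frag_mzs, frag_profiles):
            if profile[c] > 0:
                fmzs.append(mz)
                fints.append(profile[c])
        order = np.argsort(fmzs)
        spectra.append(
            make_spectrum(
                np.asarray(fmzs)[order] if fmzs else [],
                np.asarray(fints)[order] if fints else [],
                ms_level=2,
                cycle=c,
                window=window,
                scan_id=f"scan={sid}",
            )
        )
    from diadem import build_run

    run = build_run(spectra)
    edge = Edge(
        spectrum_pos=5,  # cycle 2's MS2 scan
        scan_id="scan=6",
        cycle=2,
        window_index=0,
        precursor=prec,
        fragment_mzs=np.asarray(frag_mzs, dtype=float),
        xcorr=1.0,
    )
    return run, edge


class TestCoelution:
    def test_identical_profiles_score_one(self):
        profile = [1.0, 2.0, 3.0, 2.0, 1.0]
        run, edge = coelution_setup(profile, [profile, profile, profile])
        assert coelution_score(run, edge) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_profiles_score_zero(self):
        run, edge = coelution_setup(
            [1.0, 0, 0, 0, 0],
            [[0, 1.0, 0, 0, 0], [0, 1.0, 0, 0, 0], [0, 1.0, 0, 0, 0]],
        )
        assert coelution_score(run, edge) == 0.0

    def test_top3_mean_hand_computed(self):
        prec = [0.0, 1.0, 1.0, 0.0, 0.0]
        f1 = [1.0, 1.0, 0.0, 0.0, 0.0]           # dot 0.5
        f2 = [0.0, 1.0, 1.0, 0.0, 0.0]           # dot 1.0
        x = np.sqrt(11.5)                        # dot 0.2
        f3 = [x, 1.0, 0.0, 0.0, 0.0]
        run, edge = coelution_setup(prec, [f1, f2, f3])
        expected = (1.0 + 0.5 + 0.2) / 3.0
        assert coelution_score(run, edge) == pytest.approx(expected, abs=1e-6)

    def test_zero_norm_precursor_scores_zero(self):
        run, edge = coelution_setup(
            [0.0] * 5, [[0, 1.0, 0, 0, 0], [0, 1.0, 0, 0, 0], [0, 1.0, 0, 0, 0]]
        )
        assert coelution_score(run, edge) == 0.0

    def test_fewer_than_three_fragments_averages_all(self):
        profile = [1.0, 2.0, 3.0, 2.0, 1.0]
        run, edge = coelution_setup(profile, [profile, profile], frag_mzs=(300.0, 400.0))
        edge.fragment_mzs = np.array([300.0, 400.0])
        assert coelution_score(run, edge) == pytest.approx(1.0, abs=1e-9)

    def test_bounded_unit_interval(self, small_sim):
        from diadem import build_graph, SearchConfig
        from diadem.peptide_db import generate_decoys, enumerate_precursors

        db = small_sim["database"][:50]
        pairs = generate_decoys(db, seed=0)
        precursors = enumerate_precursors(pairs, (2, 3))
        config = SearchConfig(charges=(2, 3), top_k=2)
        graph = build_graph(small_sim["run"], precursors, config)
        for edge in graph.edges[:100]:
            w = coelution_score(small_sim["run"], edge, config)
            assert 0.0 <= w <= 1.0 + 1e-12


class TestBatchLookup:
    def test_max_intensity_within_tolerance(self):
        mz = np.array([100.0, 100.0005, 200.0])
        inten = np.array([5.0, 7.0, 3.0])
        out = max_intensity_batch(mz, inten, np.array([100.0, 150.0, 200.0]), 10.0)
        np.testing.assert_allclose(out, [7.0, 0.0, 3.0])
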