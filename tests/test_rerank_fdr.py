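"""Rescoring protocol, precursor competition, q-values, entrapment harness."""

import numpy as np
import pytest

from diadem import (
    Peptide,
    ScoredPeptide,
    compute_qvalues,
    precursor_tdc,
    pseudo_target_evaluate,
    rerank,
    tdc_qvalues,
)
from diadem.peptide_db import Precursor
from diadem.rerank_fdr import count_accepted_targets, pair_folds
from diadem.search_core import Edge


def brute_force_qvalues(scores, is_decoy):
    """Oracle: evaluate the FDR at every threshold, take the suffix minimum."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    qvals = np.empty(scores.size)
    thresholds = np.unique(scores)
    fdr_at = {}
    for s in thresholds:
        accepted = scores >= s  # tau just below s
        d = int(np.sum(accepted & is_decoy))
        t = int(np.sum(accepted & ~is_decoy))
        fdr_at[s] = min(1.0, d / max(t, 1))
    for i, s in enumerate(scores):
        qvals[i] = min(fdr for thr, fdr in fdr_at.items() if thr <= s)
    return qvals


def make_edge(score_features, pair_id, decoy, charge=2, seq="ACDEFGK"):
    return Edge(
        spectrum_pos=0,
        scan_id="scan=1",
        cycle=0,
        window_index=0,
        precursor=Precursor(Peptide(seq), charge, decoy, pair_id),
        fragment_mzs=np.array([100.0]),
        xcorr=1.0,
        tailor=score_features.get("tailor", 1.0),
        delta_cn=score_features.get("delta_cn", 0.0),
        delta_lcn=score_features.get("delta_lcn", 0.0),
        w_p=score_features.get("w_p", -1.0),
        w_f=score_features.get("w_f", 1.0),
        w_r=score_features.get("w_r", -0.3),
        w_e=score_features.get("w_e", 0.5),
    )


class TestQValues:
    def test_hand_enumerated_example(self):
        scores = np.array([10.0, 8.0, 6.0, 9.0, 1.0])
        decoy = np.array([False, False, False, True, True])
        q = tdc_qvalues(scores, decoy)
        np.testing.assert_allclose(
            q[:3], [0.0, 1 / 3, 1 / 3], atol=1e-12
        )

    def test_no_decoys_all_zero(self):
        q = tdc_qvalues(np.array([3.0, 2.0, 1.0]), np.array([False] * 3))
        np.testing.assert_array_equal(q, 0.0)

    def test_all_decoys_above_targets_capped_at_one(self):
        scores = np.array([10.0, 9.0, 8.0, 3.0, 2.0, 1.0])
        decoy = np.array([True, True, True, False, False, False])
        q = tdc_qvalues(scores, decoy)
        np.testing.assert_array_equal(q[3:], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        scores = np.round(rng.normal(size=n), 2)  # ties likely
        decoy = rng.uniform(size=n) < 0.5
        np.testing.assert_array_equal(
            tdc_qvalues(scores, decoy), brute_force_qvalues(scores, decoy)
        )

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        decoy = rng.uniform(size=40) < 0.5
        perm = rng.permutation(40)
        q = tdc_qvalues(scores, decoy)
        q_perm = tdc_qvalues(scores[perm], decoy[perm])
        np.testing.assert_array_equal(q[perm], q_perm)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        decoy = rng.uniform(size=50) < 0.5
        q = tdc_qvalues(scores, decoy)
        order = np.argsort(-scores)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPrecursorTDC:
    def test_max_scoring_edge_wins(self):
        edges = [
            make_edge({}, 0, False),
            make_edge({}, 0, False),
            make_edge({}, 0, True),
        ]
        winners = precursor_tdc(edges, [3.1, 2.0, 2.5])
        assert len(winners) == 1
        assert winners[0].score == 3.1 and not winners[0].precursor.is_decoy

    def test_decoy_only_pair_yields_decoy(self):
        winners = precursor_tdc([make_edge({}, 1, True)], [0.5])
        assert winners[0].precursor.is_decoy

    def test_tie_breaks_toward_decoy(self):
        edges = [make_edge({}, 0, False), make_edge({}, 0, True)]
        winners = precursor_tdc(edges, [2.0, 2.0])
        assert winners[0].precursor.is_decoy

    def test_competes_across_charges(self):
        edges = [
            make_edge({}, 0, False, charge=2),
            make_edge({}, 0, False, charge=3),
            make_edge({}, 0, True, charge=2),
        ]
        winners = precursor_tdc(edges, [1.0, 5.0, 2.0])
        assert len(winners) == 1 and winners[0].precursor.charge == 3

    def test_compute_qvalues_sorted_and_monotone(self):
        rng = np.random.default_rng(0)
        peptides = [
            ScoredPeptide(i, Precursor(Peptide("ACDEFGK"), 2, bool(i % 2), i), "s", float(s))
            for i, s in enumerate(rng.normal(size=30))
        ]
        ranked = compute_qvalues(peptides)
        scores = [p.score for p in ranked]
        assert scores == sorted(scores, reverse=True)
        qs = [p.q_value for p in ranked]
        assert all(b >= a - 1e-15 for a, b in zip(qs, qs[1:]))


def synthetic_edges(rng, n_pairs=120, separation=3.0):
    """Target edges shifted up in the tailor feature by ``separation``."""
    edges = []
    for pid in range(n_pairs):
        base = rng.normal()
        for decoy in (False, True):
            shift = 0.0 if decoy else separation
            edges.append(
                make_edge(
                    {
                        "tailor": base + shift + rng.normal(scale=0.2),
                        "w_p": rng.normal(),
                        "w_f": rng.normal(),
                        "w_r": rng.normal(scale=0.1),
                        "w_e": rng.uniform(),
                    },
                    pid,
                    decoy,
                )
            )
    return edges


class TestRerank:
    def test_separable_feature_recovered(self):
        rng = np.random.default_rng(0)
        edges = synthetic_edges(rng, separation=5.0)
        scores, model = rerank(edges, seed=1)
        is_decoy = np.array([e.precursor.is_decoy for e in edges])
        # with a perfectly separating feature, nearly all targets accepted
        n = count_accepted_targets(scores, is_decoy, 0.01)
        assert n >= 0.95 * (~is_decoy).sum()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        edges = synthetic_edges(rng)
        s1, _ = rerank(edges, seed=7)
        s2, _ = rerank(edges, seed=7)
        np.testing.assert_array_equal(s1, s2)

    def test_pair_atomic_folds(self):
        rng = np.random.default_rng(1)
        pair_ids = rng.integers(0, 1000, size=5000)
        folds = pair_folds(pair_ids, 3, seed=3)
        for pid in np.unique(pair_ids):
            assert np.unique(folds[pair_ids == pid]).size == 1
        # all three folds populated
        assert np.unique(folds).size == 3

    def test_null_labels_accept_almost_nothing(self):
        accepted, winners = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            edges = []
            for pid in range(150):
                for decoy in (False, True):
                    edges.append(
                        make_edge(
                            {
                                "tailor": rng.normal(),
                                "w_p": rng.normal(),
                                "w_f": rng.normal(),
                                "w_r": rng.normal(),
                                "w_e": rng.normal(),
                            },
                            pid,
                            decoy,
                        )
                    )
            scores, _ = rerank(edges, seed=seed)
            ranked = compute_qvalues(precursor_tdc(edges, scores))
            winners += len(ranked)
            accepted += sum(
                1 for p in ranked if p.q_value <= 0.01 and not p.precursor.is_decoy
            )
        assert accepted / winners <= 0.02

    def test_no_positives_falls_back_flagged(self):
        # all targets and decoys identical: no separation, zero positives
        edges = []
        for pid in range(30):
            for decoy in (False, True):
                edges.append(make_edge({"tailor": 1.0}, pid, decoy))
        scores, model = rerank(edges, seed=0)
        assert scores.size == len(edges)
        assert model.flags  # fallback path taken


class TestPseudoTargets:
    def _peptides(self, n=40):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))
        out = []
        while len(out) < n:
            seq = "".join(rng.choice(alphabet, size=9)) + "K"
            if seq not in {p.sequence for p in out}:
                out.append(Peptide(seq))
        return out

    @staticmethod
    def perfect_pipeline(true_keys):
        def pipeline(peptides):
            results = []
            for i, pep in enumerate(peptides):
                score = 100.0 - i if pep.key() in true_keys else -float(i)
                results.append(
                    ScoredPeptide(i, Precursor(pep, 2, False, i), "s", score, q_value=0.0)
                )
            return results

        return pipeline

    def test_perfect_separation_gives_zero_pseudo_q(self):
        peptides = self._peptides()
        true_keys = {p.key() for p in peptides}
        frame = pseudo_target_evaluate(peptides, 11, self.perfect_pipeline(true_keys))
        real = frame[~frame.is_pseudo]
        assert (real.pseudo_q == 0.0).all()

    def test_output_bounded_by_input_pairs(self):
        peptides = self._peptides()
        frame = pseudo_target_evaluate(
            peptides, 11, self.perfect_pipeline({p.key() for p in peptides})
        )
        assert len(frame) <= 2 * len(peptides)

    def test_random_ranking_accepts_about_one_percent(self):
        peptides = self._peptides(n=150)
        accepted = []
        for seed in range(10):
            rng = np.random.default_rng(seed)

            def pipeline(peps, rng=rng):
                return [
                    ScoredPeptide(
                        i, Precursor(p, 2, False, i), "s", float(rng.normal()), q_value=0.5
                    )
                    for i, p in enumerate(peps)
                ]

            frame = pseudo_target_evaluate(peptides, 1000 + seed, pipeline)
            accepted.append((frame.pseudo_q <= 0.01).sum() / len(frame))
        assert np.mean(accepted) <= 0.03

    def test_pseudo_decoys_avoid_target_collisions(self):
        peptides = self._peptides()
        target_seqs = {p.sequence for p in peptides}
        seen = []

        def capture(peps):
            seen.extend(peps)
            return []

        pseudo_target_evaluate(peptides, 5, capture)
        pseudo = seen[len(peptides):]
        assert pseudo and all(p.sequence not in target_seqs for p in pseudo)
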