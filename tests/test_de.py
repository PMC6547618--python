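import numpy as np
import pandas as pd
import pytest

from mirpair.containers import PairedCountMatrix, PatientPair
from mirpair.de import (
    DEConfig,
    bh_fdr,
    consensus_select,
    consistency_filter,
    moderated_t_test,
    per_pair_logfc,
    run_de_tests,
    select_de_features,
)
from mirpair.normalize import log_cpm
from mirpair.simulate import SimCountParams, simulate_paired_counts


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """O(m^2) literal step-up: q_i = min over {j: p_j >= p_i} of m p_j / rank_j."""
    m = len(p)
    ranks = np.argsort(np.argsort(p, kind="stable"), kind="stable") + 1
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0
        )
    return q


class TestPerPairLogfc:
    def test_hand_differences(self, tiny_counts):
        expr = log_cpm(tiny_counts)
        diffs = per_pair_logfc(expr, tiny_counts.manifest)
        v = expr.values
        for pat, t, n in (("P1", "P1T", "P1N"), ("P2", "P2T", "P2N")):
            assert np.allclose(diffs[pat], v[t] - v[n])

    def test_equal_samples_give_zero(self):
        df = pd.DataFrame({"a": [5, 7], "b": [5, 7], "c": [1, 2], "d": [3, 4]},
                          index=["f1", "f2"], dtype=float)
        from mirpair.containers import ExpressionMatrix
        expr = ExpressionMatrix(df)
        diffs = per_pair_logfc(expr, [PatientPair("P1", "a", "b")])
        assert (diffs["P1"] == 0).all()

    def test_missing_sample_names_patient(self, tiny_counts):
        expr = log_cpm(tiny_counts)
        with pytest.raises(ValueError, match="P9"):
            per_pair_logfc(expr, [PatientPair("P9", "nope", "P1N")])


class TestBhFdr:
    def test_hand_step_up_cases(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_fdr([0.05]), [0.05])
        assert np.allclose(bh_fdr([0.005, 0.1]), [0.01, 0.1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            if rng.uniform() < 0.3:  # exercise ties
                p = np.round(p, 1)
            assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestStatistics:
    def test_all_zero_feature_gives_p_one(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(rng.normal(size=(30, 10)))
        d.iloc[0] = 0.0
        p = moderated_t_test(d)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_requires_three_pairs(self):
        counts = pd.DataFrame(
            {"aT": [5, 5], "aN": [5, 5], "bT": [5, 5], "bN": [5, 5]},
            index=["f1", "f2"],
        )
        pcm = PairedCountMatrix(
            counts, [PatientPair("a", "aT", "aN"), PatientPair("b", "bT", "bN")]
        )
        with pytest.raises(ValueError):
            run_de_tests(pcm, log_cpm(pcm))

    def test_planted_signal_found_by_all_methods(self):
        params = SimCountParams(
            n_features=300, n_pairs=48, frac_de=0.1, logfc_range=(2.0, 2.0), seed=21
        )
        pcm, truth = simulate_paired_counts(params)
        pvals = run_de_tests(pcm, log_cpm(pcm))
        planted = sorted(truth.de_feature_ids)
        for m in ("p_modt", "p_wilcoxon", "p_nbwald"):
            q = pd.Series(bh_fdr(pvals[m].to_numpy()), index=pvals.index)
            assert (q[planted] < 1e-5).mean() >= 0.90, m


def _records(q_triplets):
    df = pd.DataFrame(
        q_triplets, columns=["q_modt", "q_wilcoxon", "q_nbwald"]
    )
    df["feature_id"] = [f"f{i}" for i in range(len(df))]
    return df


class TestConsensus:
    def test_threshold_rules(self):
        cfg = DEConfig()
        rec = _records([(1e-6, 1e-6, 1e-6), (1e-6, 1e-6, 1e-4)])
        got = consensus_select(rec, cfg)
        assert got.tolist() == [True, False]

    def test_equals_intersection_oracle(self, rng):
        cfg = DEConfig(fdr_threshold=0.05)
        q = rng.uniform(0, 0.2, size=(100, 3))
        rec = _records(list(map(tuple, q)))
        got = consensus_select(rec, cfg)
        sets = [set(np.where(q[:, j] <= 0.05)[0]) for j in range(3)]
        expected = sets[0] & sets[1] & sets[2]
        assert set(np.where(got)[0]) == expected


class TestConsistencyFilter:
    def _apply(self, diffs_rows, cfg, avg_logcpm=10.0):
        diffs = pd.DataFrame(
            diffs_rows,
            index=[f"f{i}" for i in range(len(diffs_rows))],
            columns=[f"P{j}" for j in range(len(diffs_rows[0]))],
        )
        rec = pd.DataFrame(
            {
                "feature_id": diffs.index,
                "avg_logcpm": avg_logcpm,
                "avg_logfc": diffs.mean(axis=1),
                "consensus": True,
            },
            index=diffs.index,
        )
        return consistency_filter(rec, diffs, cfg)

    def test_strict_majority_at_48_pairs(self):
        cfg = DEConfig()  # direction 0.80 strict, fold 0.70
        # 39 concordant of 48 passes (39 > 38.4); 38 fails
        row39 = [1.5] * 39 + [-1.5] * 9
        row38 = [1.5] * 38 + [-1.5] * 10
        out = self._apply([row39, row38], cfg)
        assert out["called"].tolist() == [True, False]
        assert out.loc[out.index[0], "direction"] == "up"

    def test_ten_pair_hand_count(self):
        cfg = DEConfig()
        row = [1.5] * 9 + [-0.2]
        out = self._apply([row], cfg)
        assert out["n_concordant"].iloc[0] == 9 and out["n_twofold"].iloc[0] == 9
        assert bool(out["called"].iloc[0]) and out["direction"].iloc[0] == "up"

    def test_logcpm_gate_in_mirna_mode(self):
        cfg = DEConfig()
        out = self._apply([[2.0] * 10], cfg, avg_logcpm=2.9)
        assert not out["called"].iloc[0]
        out_ok = self._apply([[2.0] * 10], cfg, avg_logcpm=3.0)
        assert bool(out_ok["called"].iloc[0])

    def test_exact_zero_counts_against_both_criteria(self):
        cfg = DEConfig(direction_frac=0.80, fold_frac=0.70)
        # 10 pairs: 8 positive, 2 exactly zero -> 8 > 8? no -> fails (a)
        out = self._apply([[1.5] * 8 + [0.0, 0.0]], cfg)
        assert not out["called"].iloc[0]

    def test_equals_naive_oracle(self, rng):
        cfg = DEConfig(min_avg_logcpm=0.0)
        diffs_rows = rng.normal(0, 1.5, size=(60, 12)).tolist()
        out = self._apply(diffs_rows, cfg)
        thresh = np.log2(cfg.fold_threshold)
        for i, row in enumerate(diffs_rows):
            row = np.array(row)
            n_conc = max((row > 0).sum(), (row < 0).sum())
            n_two = (np.abs(row) >= thresh).sum()
            expect = (
                n_conc > cfg.direction_frac * 12
                and n_two >= cfg.fold_frac * 12
                and (row > 0).sum() != (row < 0).sum()
            )
            assert bool(out["called"].iloc[i]) == expect


@pytest.fixture(scope="module")
def planted_run():
    params = SimCountParams(
        n_features=800, n_pairs=24, frac_de=0.05, logfc_range=(2.0, 3.0), seed=31
    )
    return simulate_paired_counts(params)


class TestSelectDeFeatures:

    def test_label_flip_negates_direction_keeps_calls(self, planted_run):
        pcm, _ = planted_run
        feats = select_de_features(pcm, DEConfig.mirna())
        flipped = PairedCountMatrix(
            pcm.counts,
            [PatientPair(p.patient_id, p.normal_sample, p.tumor_sample)
             for p in pcm.manifest],
        )
        feats_f = select_de_features(flipped, DEConfig.mirna())
        assert set(feats.called_ids()) == set(feats_f.called_ids())
        for fid, d in feats.directions().items():
            assert feats_f.directions()[fid] == ("down" if d == "up" else "up")
        merged = feats.records.merge(feats_f.records, on="feature_id")
        assert np.allclose(merged["avg_logfc_x"], -merged["avg_logfc_y"], atol=1e-9)

    def test_patient_permutation_invariance(self, planted_run):
        pcm, _ = planted_run
        feats = select_de_features(pcm, DEConfig.mirna())
        perm = PairedCountMatrix(pcm.counts, list(reversed(pcm.manifest)))
        feats_p = select_de_features(perm, DEConfig.mirna())
        assert feats.called_ids() == feats_p.called_ids()
        a = feats.records.drop(columns=["p_nbwald", "q_nbwald"])
        b = feats_p.records.drop(columns=["p_nbwald", "q_nbwald"])
        pd.testing.assert_frame_equal(a, b)

    def test_relaxing_thresholds_never_shrinks_calls(self, planted_run):
        pcm, _ = planted_run
        strict = set(select_de_features(pcm, DEConfig.mirna()).called_ids())
        for relaxed_cfg in (
            DEConfig.mirna(fdr_threshold=1e-3),
            DEConfig.mirna(min_avg_logcpm=0.0),
            DEConfig.mirna(direction_frac=0.6, fold_frac=0.5),
        ):
            relaxed = set(select_de_features(pcm, relaxed_cfg).called_ids())
            assert strict <= relaxed

    def test_step_counts_monotone(self, planted_run):
        pcm, _ = planted_run
        feats = select_de_features(pcm, DEConfig.mirna())
        sc = feats.step_counts
        assert sc["input"] >= sc["prefilter"] >= sc["consensus"] >= sc["called"]
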