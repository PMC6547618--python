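import numpy as np
import pandas as pd
import pytest

from mirpair.containers import TargetMap, TargetRelation
from mirpair.simulate import (
    simulate_repression_data,
    simulate_sequence_universe,
    simulate_site_features,
)
from mirpair.targets import (
    MLRModel,
    SeedSite,
    compute_site_features,
    fit_mlr_coefficients,
    merge_target_maps,
    mlr_score,
    predict_targets,
    reverse_complement,
    scan_seed_sites,
    seed_pairing_stability,
)

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"  # positions 2-8 = GAGGUAG


def scan_oracle(mirna: str, utr: str) -> list[tuple[int, str]]:
    """Exhaustive per-offset pattern check with 8mer > 7mer-m8 > 7mer-A1 priority."""
    mirna = mirna.replace("T", "U")
    utr = utr.replace("T", "U")
    seed7 = reverse_complement(mirna[1:8])
    seed6 = reverse_complement(mirna[1:7])
    eight = seed7 + "A"
    hits: list[tuple[int, str]] = []
    covered_8mer: set[int] = set()
    for s in range(len(utr) - 7):
        if utr[s : s + 8] == eight:
            hits.append((s, "8mer"))
            covered_8mer.add(s)
    for s in range(len(utr) - 6):
        if utr[s : s + 7] == seed7 and s not in covered_8mer:
            hits.append((s, "7mer-m8"))
        elif utr[s : s + 7] == seed6 + "A" and utr[s : s + 8] != eight and (s - 1) not in covered_8mer:
            hits.append((s, "7mer-A1"))
    return sorted(hits)


class TestScanner:
    def test_let7a_8mer_hand_case(self):
        sites = scan_seed_sites(LET7A, "GG" + "CUACCUCA" + "GG")
        assert [(s.start, s.site_type) for s in sites] == [(2, "8mer")]

    def test_let7a_7mer_m8_without_terminal_a(self):
        sites = scan_seed_sites(LET7A, "GG" + "CUACCUCG" + "GG")
        assert [(s.start, s.site_type) for s in sites] == [(2, "7mer-m8")]

    def test_let7a_7mer_a1(self):
        sites = scan_seed_sites(LET7A, "GG" + "UACCUCA" + "GG")
        assert [(s.start, s.site_type) for s in sites] == [(2, "7mer-A1")]

    def test_no_c_utr_has_no_let7a_sites(self):
        assert scan_seed_sites(LET7A, "AGU" * 40) == []

    def test_t_normalized_to_u(self):
        sites = scan_seed_sites(LET7A.replace("U", "T"), "GGCTACCTCAGG")
        assert [(s.start, s.site_type) for s in sites] == [(2, "8mer")]

    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError):
            scan_seed_sites(LET7A, "ACGUXACGU")

    def test_matches_exhaustive_oracle_on_random_pairs(self, rng):
        alphabet = np.array(list("ACGU"))
        for _ in range(100):
            mirna = "".join(rng.choice(alphabet, size=int(rng.integers(20, 24))))
            # AU-rich UTRs raise the chance of real matches in short sequences
            utr = "".join(
                rng.choice(alphabet, size=int(rng.integers(50, 400)),
                           p=[0.3, 0.2, 0.2, 0.3])
            )
            got = [(s.start, s.site_type) for s in scan_seed_sites(mirna, utr)]
            assert sorted(got) == scan_oracle(mirna, utr)

    def test_one_type_per_locus(self, rng):
        alphabet = np.array(list("ACGU"))
        mirna = "".join(rng.choice(alphabet, size=21))
        utr = "".join(rng.choice(alphabet, size=5000))
        sites = scan_seed_sites(mirna, utr)
        starts = [s.start for s in sites]
        assert len(starts) == len(set(starts))

    def test_background_rate_matches_binomial_expectation(self, rng):
        # P(7mer-m8 at an offset) = 4^-7 on uniform sequence
        mirna = "UGAGGUAGUAGGUUGUAUAG"
        n_utrs, length = 2000, 500
        alphabet = np.array(list("ACGU"))
        total = 0
        for _ in range(n_utrs):
            utr = "".join(rng.choice(alphabet, size=length))
            total += sum(
                1 for s in scan_seed_sites(mirna, utr) if s.site_type == "7mer-m8"
            )
        positions = n_utrs * (length - 6)
        expect = positions * 4.0**-7 * (3 / 4)  # trailing base must not be A
        sd = np.sqrt(expect)
        assert abs(total - expect) < 3 * sd


class TestSiteFeatures:
    def test_au_saturated_flanks(self):
        utr = "U" * 30 + "CUACCUCA" + "A" * 30
        site = scan_seed_sites(LET7A, utr)[0]
        site = compute_site_features(site, utr, {"u": utr}, LET7A, flank=30)
        assert site.au_content == 1.0

    def test_utr_length_feature_is_log10(self):
        utr = ("G" * 496 + "CUACCUCA" + "G" * 496)
        assert len(utr) == 1000
        site = scan_seed_sites(LET7A, utr)[0]
        site = compute_site_features(site, utr, {"u": utr}, LET7A)
        assert site.utr_len_feature == pytest.approx(3.0)

    def test_target_site_abundance_counts_all_utrs(self):
        # exactly 9 occurrences of CUACCUC across the utrome -> log10(10) = 1
        hit_utr = "G" * 10 + "CUACCUC" + "G" * 10
        utrome = {f"u{i}": hit_utr for i in range(9)}
        main = "G" * 40 + "CUACCUCA" + "G" * 40
        utrome["main"] = main.replace("CUACCUCA", "GGGGGGGG")  # no extra hits
        site = SeedSite("let7a", "main", 40, "8mer")
        site2 = compute_site_features(site, main, utrome, LET7A)
        # main's own site was blanked in the utrome copy, so count stays 9
        assert site2.ta_feature == pytest.approx(1.0)

    def test_sps_is_negative_and_additive(self):
        sps = seed_pairing_stability(LET7A)
        assert sps < 0
        # GC-rich seed pairs more stably than AU-rich seed
        au_mirna = "UAUAUAUAUAUAUAUAUAUAU"
        gc_mirna = "UGCGCGCGCGCGCGCGCGCGC"
        assert seed_pairing_stability(gc_mirna) < seed_pairing_stability(au_mirna)

    def test_negative_flank_rejected(self):
        utr = "G" * 30 + "CUACCUCA" + "G" * 30
        site = scan_seed_sites(LET7A, utr)[0]
        with pytest.raises(ValueError):
            compute_site_features(site, utr, {"u": utr}, LET7A, flank=-1)


class TestMlrScoring:
    def test_constant_model(self):
        site = simulate_site_features(1, seed=0)[0]
        model = MLRModel(intercept=-0.5, coefficients=(0, 0, 0, 0))
        assert mlr_score(site, model) == pytest.approx(-0.5)

    def test_hand_arithmetic(self):
        site = SeedSite("m", "u", 0, "7mer-m8",
                        au_content=1.0, utr_len_feature=3.0,
                        ta_feature=1.0, sps_feature=-9.0)
        model = MLRModel(intercept=0.0, coefficients=(-0.4, 0.05, 0.1, 0.02))
        assert mlr_score(site, model) == pytest.approx(-0.4 + 0.15 + 0.1 - 0.18)
        assert mlr_score(site, model) == pytest.approx(-0.33)

    @pytest.mark.parametrize("score,is_target", [(-0.31, True), (-0.29, False)])
    def test_threshold_classification_boundary(self, score, is_target):
        # one site scoring exactly `score` under an intercept-only model
        utr = "G" * 30 + "CUACCUCA" + "G" * 30
        model = MLRModel(intercept=score, coefficients=(0, 0, 0, 0),
                         score_threshold=-0.3)
        tm = predict_targets({"let7a": LET7A}, {"u": utr}, model)
        assert (("let7a", "u") in tm.keys()) == is_target

    def test_noiseless_fit_recovers_exactly(self):
        sites = simulate_site_features(100, seed=1)
        df, _ = simulate_repression_data(sites, -0.2, [-0.4, 0.05, 0.1, 0.02], 0.0, seed=2)
        m = fit_mlr_coefficients(df)
        assert np.allclose(m.coefficients, (-0.4, 0.05, 0.1, 0.02), atol=1e-8)
        assert m.intercept == pytest.approx(-0.2, abs=1e-8)

    def test_noisy_fit_recovers_within_tolerance(self):
        sites = simulate_site_features(500, seed=3)
        df, _ = simulate_repression_data(sites, -0.2, [-0.4, 0.05, 0.1, 0.02], 0.1, seed=4)
        m = fit_mlr_coefficients(df)
        assert np.all(np.abs(np.array(m.coefficients) - (-0.4, 0.05, 0.1, 0.02)) < 0.05)

    def test_constant_feature_is_singular(self):
        sites = simulate_site_features(50, seed=5)
        for s in sites:
            s.ta_feature = 1.0
        df, _ = simulate_repression_data(sites, 0.0, [1, 1, 1, 1], 0.1, seed=6)
        with pytest.raises(ValueError, match="singular"):
            fit_mlr_coefficients(df)

    def test_too_few_rows_rejected(self):
        sites = simulate_site_features(10, seed=7)
        df, _ = simulate_repression_data(sites, 0.0, [1, 1, 1, 1], 0.1, seed=8)
        with pytest.raises(ValueError):
            fit_mlr_coefficients(df)


@pytest.fixture(scope="module")
def universe():
    return simulate_sequence_universe(6, 40, sites_per_utr={0: 0.3, 1: 0.7}, seed=17)


class TestPredictTargets:

    def test_empty_inputs_give_empty_map(self):
        assert len(predict_targets({}, {}, MLRModel())) == 0

    def test_utr_without_sites_yields_no_relation(self):
        tm = predict_targets({"m": LET7A}, {"u": "G" * 100}, MLRModel(score_threshold=1e9))
        assert len(tm) == 0

    def test_planted_strong_site_is_predicted(self, universe):
        mirnas, utrs, truth = universe
        # a permissive threshold must include every planted (miRNA, UTR)
        tm = predict_targets(mirnas, utrs, MLRModel(score_threshold=1e9))
        keys = tm.keys()
        for mid, uid, _, _ in truth.planted_sites:
            assert (mid, uid) in keys

    def test_threshold_monotonicity(self, universe):
        mirnas, utrs, _ = universe
        strict = predict_targets(mirnas, utrs, MLRModel(score_threshold=-0.3)).keys()
        loose = predict_targets(mirnas, utrs, MLRModel(score_threshold=0.0)).keys()
        assert strict <= loose


def _tm(rels):
    tm = TargetMap()
    for r in rels:
        tm.add(TargetRelation(*r))
    return tm


class TestMergeTargetMaps:
    def test_support_and_validated_rules(self):
        validated = _tm([("m1", "g1", "validated")])
        preds = [
            _tm([("m2", "g2", "p"), ("m3", "g3", "p")]),
            _tm([("m2", "g2", "p"), ("m3", "g3", "p")]),
            _tm([("m2", "g2", "p")]),
        ]
        out = merge_target_maps([validated], preds, min_support=3)
        keys = out.keys()
        assert ("m1", "g1") in keys          # validated always kept
        assert ("m2", "g2") in keys          # 3 programs
        assert ("m3", "g3") not in keys      # only 2 programs

    def test_targetscan_score_rule(self):
        ts = _tm([("m1", "g1", "ts", 0.3), ("m2", "g2", "ts", 0.1)])
        out = merge_target_maps([], [], ts, ts_threshold=0.2)
        assert out.keys() == {("m1", "g1")}
        inv = merge_target_maps([], [], ts, ts_threshold=0.2, ts_comparison="lt")
        assert inv.keys() == {("m2", "g2")}

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            merge_target_maps([], [], min_support=0)

    def test_equals_set_comprehension_oracle(self, rng):
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(15)]
        def random_map(tag, with_scores=False):
            rels = []
            for _ in range(30):
                score = float(rng.uniform(-0.5, 0.5)) if with_scores else None
                rels.append(
                    TargetRelation(str(rng.choice(mirnas)), str(rng.choice(genes)), tag, score)
                )
            return _tm([(r.mirna_id, r.gene_id, r.provenance, r.score) for r in rels])
        validated = [random_map("validated") for _ in range(2)]
        preds = [random_map(f"p{i}") for i in range(5)]
        ts = random_map("ts", with_scores=True)
        out = merge_target_maps(validated, preds, ts, min_support=3, ts_threshold=0.2)

        expected = set()
        for v in validated:
            expected |= v.keys()
        support = {}
        for p in preds:
            for k in p.keys():
                support[k] = support.get(k, 0) + 1
        expected |= {k for k, n in support.items() if n >= 3}
        expected |= {r.key for r in ts.relations if r.score is not None and r.score > 0.2}
        assert out.keys() == expected
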