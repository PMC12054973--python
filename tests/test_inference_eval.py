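import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from funcmatch.data_io import FunctionTerm
from funcmatch.encoders import EncoderSpec, encode_sequence, encode_text
from funcmatch.inference_eval import (
    ECNumber,
    average_precision,
    concordance,
    ec_description,
    ec_to_term,
    evaluate,
    predict_pair,
    predict_scores,
    prevalence_baseline_ap,
    similarity_baseline,
)
from funcmatch.model_core import ModelConfig, build_model

from .conftest import make_dataset


def brute_force_ap(scores, labels):
    """Mean precision at each positive's rank, counted with explicit loops."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    precisions = []
    hits = 0
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


class TestAveragePrecision:
    def test_worked_example(self):
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_pair(self):
        assert average_precision([0.13], [1]) == 1.0

    def test_no_positive_is_undefined(self):
        with pytest.raises(ValueError):
            average_precision([0.5, 0.4], [0, 0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            scores = rng.random(n)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() == 0:
                labels[int(rng.integers(n))] = 1
            assert average_precision(scores, labels) == pytest.approx(
                brute_force_ap(list(scores), list(labels)), abs=1e-9
            )

    def test_matches_sklearn_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 50
            scores = rng.permutation(n) / n  # distinct scores, no tie ambiguity
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_ties_broken_by_input_order(self):
        # same score everywhere: ranking is the input order
        assert average_precision([0.5, 0.5, 0.5], [1, 0, 0]) == 1.0
        assert average_precision([0.5, 0.5, 0.5], [0, 0, 1]) == pytest.approx(1 / 3)


class TestEvaluate:
    @pytest.fixture
    def terms(self):
        return {
            "T1": FunctionTerm("T1", "molecular_function", "one"),
            "T2": FunctionTerm("T2", "biological_process", "two"),
        }

    def test_macro_is_mean_of_per_term_aps(self, terms):
        ds = make_dataset({"p1": {"T1"}, "p2": {"T2"}}, terms, split="test")
        scores = {  # T1 perfectly ranked (AP 1), T2 ranked worst (AP 0.5)
            ("p1", "T1"): 0.9, ("p2", "T1"): 0.1,
            ("p1", "T2"): 0.9, ("p2", "T2"): 0.1,
        }
        report = evaluate(scores, ds)
        assert report.per_term_ap["T1"] == 1.0
        assert report.per_term_ap["T2"] == 0.5
        assert report.map_macro == pytest.approx(0.75)

    def test_terms_without_positives_skipped_and_counted(self, terms):
        ds = make_dataset({"p1": {"T1"}, "p2": {"T1"}}, terms, split="test")
        scores = {(p, t): 0.5 for p in ("p1", "p2") for t in terms}
        report = evaluate(scores, ds)
        assert report.n_terms_skipped == 1
        assert "T2" not in report.per_term_ap

    def test_micro_pools_all_pairs(self, terms):
        ds = make_dataset({"p1": {"T1", "T2"}, "p2": set()}, terms, split="test")
        scores = {
            ("p1", "T1"): 0.9, ("p1", "T2"): 0.8,
            ("p2", "T1"): 0.1, ("p2", "T2"): 0.2,
        }
        assert evaluate(scores, ds).map_micro == 1.0

    def test_missing_pair_raises_coverage_error(self, terms):
        ds = make_dataset({"p1": {"T1"}}, terms, split="test")
        with pytest.raises(ValueError, match="missing"):
            evaluate({("p1", "T1"): 0.5}, ds)

    def test_per_group_breakdown(self, terms):
        ds = make_dataset({"p1": {"T1"}, "p2": {"T2"}}, terms, split="test")
        scores = {(p, t): 0.5 for p in ("p1", "p2") for t in terms}
        grouping = {t: term.namespace for t, term in terms.items()}
        report = evaluate(scores, ds, grouping)
        assert set(report.per_group) == {"molecular_function", "biological_process"}

    def test_macro_invariant_to_term_relabeling(self, terms):
        ds = make_dataset({"p1": {"T1"}, "p2": {"T2"}}, terms, split="test")
        rng = np.random.default_rng(0)
        scores = {(p, t): float(rng.random()) for p in ("p1", "p2") for t in terms}
        renamed_terms = {
            "Z9": FunctionTerm("Z9", "molecular_function", "one"),
            "A0": FunctionTerm("A0", "biological_process", "two"),
        }
        mapping = {"T1": "Z9", "T2": "A0"}
        ds2 = make_dataset({"p1": {"Z9"}, "p2": {"A0"}}, renamed_terms, split="test")
        scores2 = {(p, mapping[t]): s for (p, t), s in scores.items()}
        assert evaluate(scores2, ds2).map_macro == evaluate(scores, ds).map_macro

    def test_random_scores_track_prevalence(self):
        # micro mAP of uninformative scores concentrates near positive
        # prevalence on a 50-sequence x 10-term fixture (AP of a random
        # ranking has a small positive finite-sample bias, hence the
        # distribution-scale tolerance)
        terms10 = {
            f"T{i}": FunctionTerm(f"T{i}", "molecular_function", f"t{i}")
            for i in range(10)
        }
        rng = np.random.default_rng(3)
        annot = {
            f"p{i}": {t for t in terms10 if rng.random() < 0.3} for i in range(50)
        }
        annot["p0"] = {"T0"}
        ds = make_dataset(annot, terms10, split="test")
        n_pos = sum(len(a) for a in annot.values())
        prevalence = n_pos / (50 * 10)
        micros = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            scores = {(p, t): float(r.random()) for p in annot for t in terms10}
            micros.append(evaluate(scores, ds).map_micro)
        assert abs(np.mean(micros) - prevalence) < 3 * np.std(micros)
        assert abs(np.mean(micros) - prevalence) < 0.03


class TestPredictPair:
    @pytest.fixture
    def setup(self):
        seq_spec = EncoderSpec("toy_sequence", 64, {"k": 3, "seed": 0})
        text_spec = EncoderSpec("toy_text", 32, {"seed": 0})
        model = build_model(ModelConfig(d=8, seed=0), 64, 32)
        return model, seq_spec, text_spec

    def test_equal_descriptions_equal_single_score(self, setup):
        model, seq_spec, text_spec = setup
        term = FunctionTerm("T", "molecular_function", "kinase activity")
        p = predict_pair(model, "MKVLLAGH", term, seq_spec, text_spec)
        single = float(model.score_batch(
            encode_sequence("MKVLLAGH", seq_spec),
            encode_text("kinase activity", text_spec))[0])
        assert p == single

    def test_distinct_descriptions_average(self, setup):
        model, seq_spec, text_spec = setup
        term = FunctionTerm("T", "molecular_function", "kinase", "transfers phosphate")
        seq_emb = encode_sequence("MKVLLAGH", seq_spec)
        p_short = float(model.score_batch(seq_emb, encode_text("kinase", text_spec))[0])
        p_long = float(model.score_batch(
            seq_emb, encode_text("transfers phosphate", text_spec))[0])
        ensembled = predict_pair(model, "MKVLLAGH", term, seq_spec, text_spec)
        assert ensembled == pytest.approx(0.5 * (p_short + p_long), abs=1e-15)
        assert 0.0 <= ensembled <= 1.0

    def test_symmetric_in_descriptions(self, setup):
        model, seq_spec, text_spec = setup
        a = FunctionTerm("T", "molecular_function", "alpha text", "beta text")
        b = FunctionTerm("T", "molecular_function", "beta text", "alpha text")
        assert predict_pair(model, "MKV", a, seq_spec, text_spec) == pytest.approx(
            predict_pair(model, "MKV", b, seq_spec, text_spec), abs=1e-15
        )

    def test_grid_matches_pairwise(self, setup, tiny_world):
        model_, seq_spec, text_spec = setup
        proteins = tiny_world[0].proteins[:4]
        terms = dict(list(tiny_world[0].terms.items())[:3])
        grid = predict_scores(model_, proteins, terms, seq_spec, text_spec)
        for rec in proteins:
            for tid, term in terms.items():
                assert grid[(rec.seq_id, tid)] == pytest.approx(
                    predict_pair(model_, rec.sequence, term, seq_spec, text_spec),
                    abs=1e-12,
                )


class TestECNumbers:
    def test_description_concatenation(self):
        ec = ECNumber("1.2.3.4", ["w", "x", "y", "z"])
        assert ec_description(ec) == "w, x, y, z"
        assert ec_description(ec).count(",") == 3

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            ECNumber("1.2.3.4", ["w", "x", "y"])
        with pytest.raises(ValueError):
            ECNumber("1.2.3", ["w", "x", "y", "z"])

    def test_term_wrapper_uses_single_description(self):
        term = ec_to_term(ECNumber("1.2.3.4", ["a", "b", "c", "d"]))
        assert term.short_desc == term.long_desc == "a, b, c, d"
        assert term.namespace == "ec_class"

    def test_top_class(self):
        assert ECNumber("3.1.1.1", ["a", "b", "c", "d"]).top_class == "3"


class TestSimilarityBaseline:
    @pytest.fixture
    def text_spec(self):
        return EncoderSpec("toy_text", 128, {"seed": 0})

    def test_identical_description_maps_to_that_term(self, text_spec):
        iv = {
            "T1": FunctionTerm("T1", "molecular_function", "kinase activity"),
            "T2": FunctionTerm("T2", "molecular_function", "transporter activity"),
        }
        oov = {"Z1": FunctionTerm("Z1", "molecular_function", "kinase activity")}
        iv_scores = {("p1", "T1"): 0.8, ("p1", "T2"): 0.3}
        out = similarity_baseline(oov, iv, iv_scores, text_spec)
        assert out == {("p1", "Z1"): 0.8}

    def test_argmax_matches_brute_force_scan(self, text_spec):
        rng = np.random.default_rng(0)
        iv = {
            f"T{i}": FunctionTerm(f"T{i}", "molecular_function",
                                  f"motif-{i} and motif-{i+1} activity")
            for i in range(3)
        }
        oov = {"Z1": FunctionTerm("Z1", "molecular_function", "motif-2 dependent role")}
        iv_scores = {(f"p{j}", f"T{i}"): float(rng.random())
                     for j in range(4) for i in range(3)}
        out = similarity_baseline(oov, iv, iv_scores, text_spec)

        def emb(term):
            e = encode_text(term.short_desc, text_spec)
            if term.long_desc != term.short_desc:
                e = 0.5 * (e + encode_text(term.long_desc, text_spec))
            return e

        z = emb(oov["Z1"])
        sims = {
            t: float(emb(iv[t]) @ z / (np.linalg.norm(emb(iv[t])) * np.linalg.norm(z)))
            for t in iv
        }
        best = max(sorted(sims), key=lambda t: sims[t])
        for j in range(4):
            assert out[(f"p{j}", "Z1")] == iv_scores[(f"p{j}", best)]

    def test_propagated_scores_are_a_selection_of_iv_scores(self, text_spec, tiny_world):
        tr, _, _, zs, _ = tiny_world
        rng = np.random.default_rng(1)
        iv_scores = {(r.seq_id, t): float(rng.random())
                     for r in zs.proteins for t in tr.terms}
        out = similarity_baseline(zs.terms, tr.terms, iv_scores, text_spec)
        per_seq_iv = {r.seq_id: {iv_scores[(r.seq_id, t)] for t in tr.terms}
                      for r in zs.proteins}
        for (sid, _), score in out.items():
            assert score in per_seq_iv[sid]

    def test_empty_iv_catalog_rejected(self, text_spec):
        with pytest.raises(ValueError):
            similarity_baseline({}, {}, {}, text_spec)


class TestConcordance:
    def test_jaccard_values(self):
        emb = {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 0.0]),
               "c": np.array([0.0, 1.0])}
        ann = {"a": {"T1"}, "b": {"T1", "T2"}, "c": {"T3"}}
        cosines, jaccards, _ = concordance(emb, ann)
        # pairs in sorted-id order: (a,b), (a,c), (b,c)
        np.testing.assert_allclose(jaccards, [0.5, 0.0, 0.0])
        np.testing.assert_allclose(cosines, [1.0, 0.0, 0.0])

    def test_identical_sets_have_jaccard_one(self):
        emb = {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 0.5])}
        _, jaccards, _ = concordance(emb, {"a": {"T1"}, "b": {"T1"}})
        assert jaccards[0] == 1.0

    def test_pearson_r_sign(self):
        rng = np.random.default_rng(0)
        emb, ann = {}, {}
        for i in range(12):
            group = i % 2
            emb[f"s{i}"] = np.array([1.0, 0.0]) + 0.05 * rng.normal(size=2) \
                if group == 0 else np.array([0.0, 1.0]) + 0.05 * rng.normal(size=2)
            ann[f"s{i}"] = {"T1"} if group == 0 else {"T2"}
        _, _, r = concordance(emb, ann)
        assert r > 0.9

    def test_zero_norm_embedding_rejected(self):
        with pytest.raises(ValueError):
            concordance({"a": np.zeros(2), "b": np.ones(2)},
                        {"a": {"T1"}, "b": {"T1"}})

    def test_empty_annotation_set_rejected(self):
        with pytest.raises(ValueError):
            concordance({"a": np.ones(2), "b": np.ones(2)},
                        {"a": set(), "b": {"T1"}})


class TestPrevalenceBaseline:
    def test_mean_prevalence(self):
        terms = {
            "T1": FunctionTerm("T1", "molecular_function", "one"),
            "T2": FunctionTerm("T2", "molecular_function", "two"),
        }
        ds = make_dataset({"p1": {"T1"}, "p2": {"T1", "T2"}}, terms, split="test")
        # T1 prevalence 1.0, T2 prevalence 0.5
        assert prevalence_baseline_ap(ds) == pytest.approx(0.75)
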