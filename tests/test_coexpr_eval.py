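import io
import itertools

import numpy as np
import pytest

import geonorm as gn
from geonorm.coexpr_eval import EvalResult

from conftest import make_matrix


def annotations(mapping):
    return gn.GOAnnotationSet({g: set(c) for g, c in mapping.items()})


class TestTopCorrelated:
    def _matrix(self, rows, gene_ids=None):
        return make_matrix(np.asarray(rows, dtype=float), gene_ids=gene_ids)

    def test_exact_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 10)
        rows = [base, base.copy(), rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)]
        m = self._matrix(rows)
        assert gn.top_correlated(m, 1, k=1) == [2]

    def test_anticorrelated_ranks_last(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 1, 12)
        rows = [base, -base, base + rng.normal(0, 0.1, 12), rng.uniform(0, 1, 12)]
        m = self._matrix(rows)
        assert gn.top_correlated(m, 1, k=3)[-1] == 2  # gene 2 = -base

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 100, (5, 8))
        m = self._matrix(values)
        for qi, query in enumerate(m.gene_ids):
            corrs = []
            for gi, gene in enumerate(m.gene_ids):
                if gene == query:
                    continue
                r = np.corrcoef(values[qi], values[gi])[0, 1]
                corrs.append((-r, gene))
            expected = [g for _, g in sorted(corrs)]
            assert gn.top_correlated(m, int(query), k=4) == expected

    def test_ties_broken_by_ascending_entrez_id(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        rows = [base, base * 2, base * 3]  # both candidates have r = 1
        m = self._matrix(rows, gene_ids=[5, 12, 30])
        assert gn.top_correlated(m, 5, k=2) == [12, 30]

    def test_insufficient_overlap_rejected(self):
        values = np.full((3, 5), np.nan)
        values[0, :2] = [1.0, 2.0]
        values[1] = np.arange(5.0)
        values[2] = np.arange(5.0) * 2
        m = self._matrix(values)
        with pytest.raises(ValueError, match="candidates"):
            gn.top_correlated(m, 1, k=2)


class TestPredictCategories:
    def test_unanimous_category_predicted(self):
        ann = annotations({i: {"X"} for i in range(1, 21)})
        assert gn.predict_categories(99, list(range(1, 21)), ann) == {"X"}

    def test_single_vote_below_threshold(self):
        ann = annotations({1: {"X"}, 2: {"Y"}, 3: {"Y"}})
        assert gn.predict_categories(99, [1, 2, 3], ann, m=2) == {"Y"}

    def test_union_mode_m1(self):
        ann = annotations({1: {"X"}, 2: {"Y"}})
        assert gn.predict_categories(99, [1, 2], ann, m=1) == {"X", "Y"}

    def test_query_annotations_never_consulted(self):
        ann = annotations({99: {"SELF"}, 1: {"A"}, 2: {"A"}})
        assert gn.predict_categories(99, [1, 2], ann) == {"A"}


class TestEvalResult:
    def test_direct_substitution(self):
        r = EvalResult(tp=1, fp=1, fn=1)
        assert r.precision == 0.5 and r.recall == 0.5 and r.f_measure == 0.5

    def test_perfect_predictions(self):
        r = EvalResult(tp=10, fp=0, fn=0)
        assert r.f_measure == 1.0

    def test_zero_denominators_defined_as_zero(self):
        r = EvalResult(tp=0, fp=0, fn=0)
        assert r.precision == 0.0 and r.recall == 0.0 and r.f_measure == 0.0

    def test_harmonic_mean_formula_on_random_counts(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, fp, fn = (int(x) for x in rng.integers(0, 30, 3))
            r = EvalResult(tp=tp, fp=fp, fn=fn)
            p = tp / (tp + fp) if tp + fp else 0.0
            q = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * q / (p + q) if p + q else 0.0
            assert r.f_measure == pytest.approx(f)


class TestEvaluate:
    def test_confusion_counts_match_brute_force(self):
        # hand-built matrix: two tight pairs plus independent noise genes
        rng = np.random.default_rng(8)
        base1, base2 = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        rows = [
            base1,
            base1 + rng.normal(0, 0.01, 12),
            base2,
            base2 + rng.normal(0, 0.01, 12),
            rng.uniform(0, 1, 12),
            rng.uniform(0, 1, 12),
        ]
        m = make_matrix(np.asarray(rows))
        ann = annotations(
            {1: {"A"}, 2: {"A"}, 3: {"B"}, 4: {"B"}, 5: {"C"}, 6: {"D"}}
        )
        k, vote = 2, 1
        result = gn.evaluate(m, ann, k=k, m=vote)
        tp = fp = fn = 0
        for gene in m.gene_ids:
            neighbors = gn.top_correlated(m, int(gene), k=k)
            predicted = set(
                itertools.chain.from_iterable(
                    ann.gene_to_categories[n] for n in neighbors
                )
            )
            annotated = ann.gene_to_categories[int(gene)]
            tp += len(predicted & annotated)
            fp += len(predicted - annotated)
            fn += len(annotated - predicted)
        assert (result.tp, result.fp, result.fn) == (tp, fp, fn)

    def test_planted_modules_recovered_after_normalization(self, corpus_builder):
        # 5 datasets x 10 experiments, 3 modules of 25 genes at correlation 0.8
        spec = gn.SimSpec(
            seed=0, n_genes=100, expressed_fraction=0.8,
            n_datasets=5, samples_per_dataset=10,
        )
        _, _, normalized, _, truth = corpus_builder(spec)
        result = gn.evaluate(normalized, truth)
        assert result.f_measure > 0.5

    def test_zero_module_strength_no_better_than_permuted_truth(self, corpus_builder):
        spec = gn.SimSpec(
            seed=1, n_genes=300, n_datasets=5, samples_per_dataset=10,
            module_correlation=0.0,
        )
        _, _, normalized, _, truth = corpus_builder(spec)
        f_null = gn.evaluate(normalized, truth).f_measure
        # chance baseline: same matrix, category labels shuffled across genes
        rng = np.random.default_rng(0)
        genes = sorted(truth.gene_to_categories)
        cats = [truth.gene_to_categories[g] for g in genes]
        f_perm = []
        for _ in range(3):
            shuffled = list(cats)
            rng.shuffle(shuffled)
            perm = gn.GOAnnotationSet(dict(zip(genes, shuffled)))
            f_perm.append(gn.evaluate(normalized, perm).f_measure)
        assert f_null <= max(f_perm) + 0.05

    def test_strong_modules_beat_chance(self, corpus_builder):
        spec = gn.SimSpec(seed=2, n_genes=300, n_datasets=5, samples_per_dataset=10)
        _, _, normalized, _, truth = corpus_builder(spec)
        f_signal = gn.evaluate(normalized, truth).f_measure
        spec0 = gn.SimSpec(
            seed=2, n_genes=300, n_datasets=5, samples_per_dataset=10,
            module_correlation=0.0,
        )
        _, _, normalized0, _, truth0 = corpus_builder(spec0)
        f_null = gn.evaluate(normalized0, truth0).f_measure
        assert f_signal > 2 * f_null

    def test_requires_two_annotated_genes(self):
        m = make_matrix(np.random.default_rng(0).uniform(0, 1, (4, 5)))
        with pytest.raises(ValueError, match="annotated"):
            gn.evaluate(m, annotations({1: {"A"}}))


class TestAnnotationIO:
    def test_tsv_roundtrip(self, tmp_path):
        ann = annotations({7: {"GO:1", "GO:2"}, 3: {"GO:9"}})
        path = str(tmp_path / "ann.tsv")
        ann.to_tsv(path)
        back = gn.GOAnnotationSet.from_tsv(path)
        assert back.gene_to_categories == ann.gene_to_categories

    def test_empty_category_set_rejected(self):
        with pytest.raises(ValueError):
            gn.GOAnnotationSet({5: set()})
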