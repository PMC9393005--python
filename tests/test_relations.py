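"""Candidate extraction, dependency paths, splits, metrics, baselines."""

import itertools
import math
from collections import deque

import numpy as np
import pytest

from bryolat.corpus import AnnotatedDocument, Sentence, Span, Token
from bryolat.relations import (
    Candidate,
    ConfusionCounts,
    compute_metrics,
    evaluate,
    extract_candidates,
    path_tokens_with_fallback,
    random_baseline,
    shortest_dependency_path,
    split_by_publication,
)


class TestExtractCandidates:
    def test_worked_sentence_four_candidates(self, worked_doc):
        doc, gold = worked_doc
        cands, report = extract_candidates(doc)
        assert len(cands) == 4
        assert report["n_unresolved_dropped"] == 0
        names = {(c.resolved_taxon, c.location_span.surface) for c in cands}
        assert names == {
            ("Beania intermedia", "Tasmania"),
            ("Beania intermedia", "New Zealand"),
            ("Beania cookae", "Tasmania"),
            ("Beania cookae", "New Zealand"),
        }

    def test_taxa_only_no_candidates(self):
        s = Sentence("d", 0, [Token(0, "Beania"), Token(1, "here")], [(-1, 1, "root"), (1, 0, "nsubj")])
        doc = AnnotatedDocument("d", [s])
        doc.add_spans([Span(0, 0, 1, "TAXON", "Beania")])
        cands, _ = extract_candidates(doc)
        assert cands == []

    def test_per_sentence_product(self):
        def mksent(i, n):
            return Sentence("d", i, [Token(j, f"w{j}") for j in range(n)], [(-1, 0, "root")])

        doc = AnnotatedDocument("d", [mksent(0, 6), mksent(1, 4)])
        doc.add_spans(
            [
                Span(0, 0, 1, "TAXON", "Aa bb"),
                Span(0, 1, 2, "TAXON", "Cc dd"),
                Span(0, 2, 3, "LOCATION", "X"),
                Span(1, 0, 1, "TAXON", "Ee ff"),
                Span(1, 1, 2, "LOCATION", "Y"),
            ]
        )
        cands, _ = extract_candidates(doc)
        assert len(cands) == 2 + 1

    def test_unresolved_abbreviation_dropped_and_counted(self):
        s = Sentence("d", 0, [Token(0, "B."), Token(1, "alba"), Token(2, "here")], [(-1, 2, "root")])
        doc = AnnotatedDocument("d", [s])
        doc.add_spans(
            [Span(0, 0, 2, "TAXON", "B. alba"), Span(0, 2, 3, "LOCATION", "here")]
        )
        cands, report = extract_candidates(doc)
        assert cands == [] and report["n_unresolved_dropped"] == 1


def bfs_oracle(edges, src, dst):
    adj = {}
    for h, d, _ in edges:
        if h < 0:
            continue
        adj.setdefault(h, set()).add(d)
        adj.setdefault(d, set()).add(h)
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist.get(dst)


class TestDependencyPaths:
    def _sentence(self, n, edges):
        return Sentence("d", 0, [Token(i, f"t{i}") for i in range(n)], edges)

    def test_adjacent_tokens_one_edge(self):
        s = self._sentence(2, [(-1, 0, "root"), (0, 1, "obj")])
        path = shortest_dependency_path(s, Span(0, 0, 1, "TAXON", "t0"), Span(0, 1, 2, "LOCATION", "t1"))
        assert path == [0, 1]

    def test_chain(self):
        s = self._sentence(3, [(-1, 1, "root"), (1, 0, "a"), (1, 2, "b")])
        path = shortest_dependency_path(s, Span(0, 0, 1, "TAXON", "t0"), Span(0, 2, 3, "LOCATION", "t2"))
        assert path == [0, 1, 2]

    def test_matches_bfs_oracle_on_constructed_tree(self):
        edges = [(-1, 3, "root"), (3, 1, "a"), (1, 0, "b"), (1, 2, "c"),
                 (3, 5, "d"), (5, 4, "e"), (5, 6, "f")]
        s = self._sentence(7, edges)
        for a, b in itertools.combinations(range(7), 2):
            path = shortest_dependency_path(
                s, Span(0, a, a + 1, "TAXON", f"t{a}"), Span(0, b, b + 1, "LOCATION", f"t{b}")
            )
            assert len(path) - 1 == bfs_oracle(edges, a, b)
            assert path[0] == a and path[-1] == b

    def test_path_symmetry(self, worked_doc):
        doc, _ = worked_doc
        s = doc.sentences[1]
        spans = doc.spans_in(1)
        for a, b in itertools.combinations(spans, 2):
            assert shortest_dependency_path(s, a, b) == shortest_dependency_path(s, b, a)[::-1]

    def test_disconnected_fallback_flagged(self):
        s = self._sentence(4, [(0, 1, "a"), (2, 3, "b")])  # two components
        tokens, flagged = path_tokens_with_fallback(
            s, Span(0, 0, 1, "TAXON", "t0"), Span(0, 3, 4, "LOCATION", "t3")
        )
        assert flagged and tokens == ["t1", "t2"]


def exhaustive_best_split(counts, ratios):
    """Minimal total deviation over all 3^n assignments of docs to splits."""
    docs = list(counts)
    total = sum(counts.values())
    best = math.inf
    for assign in itertools.product(range(3), repeat=len(docs)):
        fills = [0, 0, 0]
        for d, a in zip(docs, assign):
            fills[a] += counts[d]
        if 0 in [sum(1 for a in assign if a == k) for k in range(3)]:
            continue
        dev = sum(abs(f / total - r) for f, r in zip(fills, ratios))
        best = min(best, dev)
    return best


class TestSplitByPublication:
    def _items(self, sizes):
        class It:
            def __init__(self, d):
                self.doc_id = d

        return [It(f"doc{i}") for i, n in enumerate(sizes) for _ in range(n)]

    def test_even_docs_8_1_1(self):
        items = self._items([10] * 10)
        split = split_by_publication(items, seed=0)
        assert sorted(map(len, (split.train, split.val, split.test))) == [1, 1, 8]
        assert len(split.train) == 8

    def test_disjointness_invariant(self, corpus_bundle):
        split = split_by_publication(corpus_bundle.gold, seed=1)
        assert not (split.train & split.val)
        assert not (split.train & split.test)
        assert not (split.val & split.test)

    def test_proportions_near_targets(self, corpus_bundle):
        split = split_by_publication(corpus_bundle.gold, seed=1)
        counts = {"train": 0, "val": 0, "test": 0}
        for lc in corpus_bundle.gold:
            counts[split.split_of(lc.candidate.doc_id)] += 1
        total = sum(counts.values())
        for name, target in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
            assert abs(counts[name] / total - target) < 0.10

    def test_greedy_near_exhaustive_optimum_on_skewed_sizes(self):
        sizes = [100, 1, 1, 1, 50, 30, 2, 2]
        counts = {f"doc{i}": n for i, n in enumerate(sizes)}
        items = self._items(sizes)
        split = split_by_publication(items, seed=0)
        total = sum(sizes)
        fills = {k: 0 for k in ("train", "val", "test")}
        for d, n in counts.items():
            fills[split.split_of(d)] += n
        dev = sum(
            abs(fills[k] / total - r)
            for k, r in zip(("train", "val", "test"), (0.8, 0.1, 0.1))
        )
        best = exhaustive_best_split(counts, (0.8, 0.1, 0.1))
        assert dev <= best + 0.35  # greedy is near-optimal, never absurd

    def test_too_few_publications(self):
        with pytest.raises(ValueError):
            split_by_publication(self._items([5, 5]), seed=0)

    def test_deterministic_given_seed(self, corpus_bundle):
        a = split_by_publication(corpus_bundle.gold, seed=7)
        b = split_by_publication(corpus_bundle.gold, seed=7)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)


class TestMetrics:
    def test_hand_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.fpr == pytest.approx(0.2)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)
        assert m.fpr == 0

    def test_undefined_fpr_is_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1))
        assert math.isnan(m.fpr)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRandomBaseline:
    def test_sixty_forty_accuracy(self):
        assert random_baseline(0.6, 0.6).accuracy == pytest.approx(0.52)

    def test_fpr_independent_of_label_balance(self):
        for p_label in (0.1, 0.5, 0.9):
            assert random_baseline(p_label, 0.789).fpr == pytest.approx(0.789)

    def test_never_predict_positive(self):
        m = random_baseline(0.6, 0.0)
        assert m.recall == 0 and m.fpr == 0

    def test_monte_carlo_convergence(self):
        """Simulated random classifier matches the closed forms."""
        rng = np.random.default_rng(11)
        n = 100_000
        p_label, p_pred = 0.6, 0.3
        labels = rng.random(n) < p_label
        preds = rng.random(n) < p_pred
        counts = ConfusionCounts(
            tp=int((labels & preds).sum()),
            fp=int((~labels & preds).sum()),
            tn=int((~labels & ~preds).sum()),
            fn=int((labels & ~preds).sum()),
        )
        emp = compute_metrics(counts)
        exp = random_baseline(p_label, p_pred)
        se = 3 / math.sqrt(n)
        for attr in ("accuracy", "precision", "recall", "fpr"):
            assert abs(getattr(emp, attr) - getattr(exp, attr)) < 3 * se


class _FixedModel:
    """Predicts a fixed probability for everything."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, items):
        return np.tile([1 - self.p, self.p], (len(items), 1))


class _Item:
    def __init__(self, label, doc_id="d0"):
        self.label = label
        self.doc_id = doc_id


class TestEvaluate:
    def test_all_positive_predictor_on_unbalanced_set(self):
        items = [_Item(1)] * 6 + [_Item(0)] * 4
        counts, m = evaluate(_FixedModel(0.9), items)
        assert m.accuracy == pytest.approx(0.6)
        assert m.fpr == pytest.approx(1.0)

    def test_threshold_above_one_yields_zero_recall(self):
        items = [_Item(1)] * 3 + [_Item(0)] * 2
        _, m = evaluate(_FixedModel(0.99), items, threshold=1.0 + 1e-9)
        assert m.recall == 0

    def test_train_test_leak_refused(self):
        from bryolat.relations import SplitAssignment

        split = SplitAssignment(train={"d0"}, val={"d1"}, test={"d2"})
        with pytest.raises(ValueError, match="leak"):
            evaluate(_FixedModel(0.5), [_Item(1, "d0")], split=split)
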