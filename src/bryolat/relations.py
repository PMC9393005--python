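"""Species-location candidate relations and their evaluation machinery.

A candidate is one (taxon span, location span) pair co-occurring in a
sentence; the relation classifier decides whether the sentence asserts
that the species occurs at the location.  This module builds candidates
(Cartesian product per sentence, with genus de-abbreviation), extracts
the shortest dependency path between the two spans, splits labeled data
into train/validation/test grouped by publication, and computes the
standard confusion-matrix metrics plus closed-form random-classifier
baselines.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import AnnotatedDocument, Sentence, Span, UNRESOLVED, deabbreviate_genus

__all__ = [
    "Candidate",
    "LabeledCandidate",
    "ConfusionCounts",
    "Metrics",
    "SplitAssignment",
    "NoPathError",
    "extract_candidates",
    "shortest_dependency_path",
    "path_tokens_with_fallback",
    "split_by_publication",
    "compute_metrics",
    "random_baseline",
    "evaluate",
    "NOT_DEFINED",
]

NOT_DEFINED = float("nan")

_ABBREV_PREFIXES = tuple(f"{c}." for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass(frozen=True)
class Candidate:
    doc_id: str
    sent_index: int
    taxon_span: Span
    location_span: Span
    resolved_taxon: str

    def __post_init__(self) -> None:
        if self.taxon_span.sent_index != self.location_span.sent_index:
            raise ValueError("candidate spans must lie in the same sentence")


@dataclass(frozen=True)
class LabeledCandidate:
    candidate: Candidate
    label: int  # 1 positive, 0 negative
    annotator_id: str = "gold"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be binary")


def extract_candidates(
    doc: AnnotatedDocument, lookback: int = 14
) -> tuple[list[Candidate], dict]:
    """Per-sentence Cartesian product of taxon and location spans.

    Abbreviated genera are resolved against prior mentions; candidates
    whose genus stays UNRESOLVED are dropped and tallied in the report.
    """
    out: list[Candidate] = []
    n_unresolved = 0
    for sent in doc.sentences:
        taxa = doc.spans_in(sent.sent_index, "TAXON")
        locs = doc.spans_in(sent.sent_index, "LOCATION")
        for tsp in taxa:
            name = tsp.surface
            if name.startswith(_ABBREV_PREFIXES):
                genus = deabbreviate_genus(doc, tsp, lookback=lookback)
                if genus is UNRESOLVED or genus == UNRESOLVED:
                    n_unresolved += len(locs)
                    continue
                name = f"{genus} {name.split(' ', 1)[1]}" if " " in name else genus
            for lsp in locs:
                out.append(
                    Candidate(
                        doc_id=doc.doc_id,
                        sent_index=sent.sent_index,
                        taxon_span=tsp,
                        location_span=lsp,
                        resolved_taxon=name,
                    )
                )
    report = {"n_candidates": len(out), "n_unresolved_dropped": n_unresolved}
    return out, report


class NoPathError(Exception):
    """The dependency graph does not connect the two spans."""


def _span_head(sentence: Sentence, span: Span) -> int:
    """Span token whose governor lies outside the span (lowest index wins)."""
    inside = set(range(span.start, span.end))
    governor = {d: h for h, d, _ in sentence.dep_edges}
    heads = [i for i in inside if governor.get(i, -1) not in inside]
    return min(heads) if heads else span.start


def _bfs_path(adj: Mapping[int, list[int]], src: int, dst: int) -> list[int]:
    """Lexicographically-smallest shortest path by token index."""
    if src == dst:
        return [src]
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if dst not in dist:
        raise NoPathError(f"no dependency path between tokens {src} and {dst}")
    # walk forward from src, at each layer taking the smallest-index
    # neighbor that still lies on some shortest path to dst
    rdist = {dst: 0}
    q = deque([dst])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in rdist:
                rdist[v] = rdist[u] + 1
                q.append(v)
    total = dist[dst]
    path = [src]
    cur = src
    while cur != dst:
        nxt = min(
            v
            for v in adj.get(cur, ())
            if rdist.get(v, math.inf) == total - dist[cur] - 1 and dist[v] == dist[cur] + 1
        )
        path.append(nxt)
        cur = nxt
    return path


def shortest_dependency_path(
    sentence: Sentence, span_a: Span, span_b: Span
) -> list[int]:
    """Token indices on the shortest undirected dependency path.

    Endpoints are the span heads (the span token not governed from within
    its own span).  Among equal-length paths the lexicographically
    smallest token-index sequence, oriented from the lower-index head,
    wins; the a->b and b->a paths are exact reverses of each other.
    """
    adj: dict[int, list[int]] = {}
    for h, d, _ in sentence.dep_edges:
        if h < 0:
            continue
        adj.setdefault(h, []).append(d)
        adj.setdefault(d, []).append(h)
    for k in adj:
        adj[k] = sorted(set(adj[k]))
    ha, hb = _span_head(sentence, span_a), _span_head(sentence, span_b)
    lo, hi = (ha, hb) if ha <= hb else (hb, ha)
    canonical = _bfs_path(adj, lo, hi)
    return canonical if ha <= hb else canonical[::-1]


def path_tokens_with_fallback(
    sentence: Sentence, span_a: Span, span_b: Span
) -> tuple[list[str], bool]:
    """Surface tokens along the dependency path, or the inter-span surface.

    Returns (tokens, used_fallback).  When the graph is disconnected the
    fallback is the token stretch between the two spans, flagged so the
    candidate remains classifiable.
    """
    try:
        idxs = shortest_dependency_path(sentence, span_a, span_b)
        return [sentence.tokens[i].text for i in idxs], False
    except NoPathError:
        lo = min(span_a.end, span_b.end)
        hi = max(span_a.start, span_b.start)
        return [t.text for t in sentence.tokens[lo:hi]], True


@dataclass
class SplitAssignment:
    """Publication-grouped train/validation/test assignment."""

    train: set[str]
    val: set[str]
    test: set[str]

    def split_of(self, doc_id: str) -> str:
        for name in ("train", "val", "test"):
            if doc_id in getattr(self, name):
                return name
        raise KeyError(doc_id)

    def partition(self, items: Sequence) -> tuple[list, list, list]:
        out = {"train": [], "val": [], "test": []}
        for it in items:
            out[self.split_of(_doc_id_of(it))].append(it)
        return out["train"], out["val"], out["test"]


def _doc_id_of(item) -> str:
    if hasattr(item, "doc_id"):
        return item.doc_id
    return item.candidate.doc_id


def split_by_publication(
    items: Sequence, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitAssignment:
    """Assign whole publications to train/val/test near target proportions.

    All items from one publication land in exactly one split, so similar
    sentences from the same publication never leak across the boundary.
    Publications are taken largest-first (ties in seeded random order)
    and each goes to the split with the largest remaining deficit
    relative to its target share — a greedy pass that keeps candidate
    proportions close to the targets.
    """
    if not math.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    counts: dict[str, int] = {}
    for it in items:
        d = _doc_id_of(it)
        counts[d] = counts.get(d, 0) + 1
    if len(counts) < 3:
        raise ValueError("need at least 3 publications to form three disjoint splits")
    rng = np.random.default_rng(seed)
    docs = list(counts)
    rng.shuffle(docs)
    docs.sort(key=lambda d: -counts[d])  # stable: ties stay in shuffled order
    total = sum(counts.values())
    buckets: dict[str, set[str]] = {"train": set(), "val": set(), "test": set()}
    filled = {"train": 0, "val": 0, "test": 0}
    targets = dict(zip(("train", "val", "test"), ratios))
    order = ("train", "val", "test")
    for d in docs:
        deficits = {k: targets[k] - filled[k] / total for k in order}
        best = max(order, key=lambda k: deficits[k])
        buckets[best].add(d)
        filled[best] += counts[d]
    # every split must be non-empty; steal the smallest doc if needed
    for k in order:
        if not buckets[k]:
            donor = max(order, key=lambda j: len(buckets[j]))
            d = min(buckets[donor], key=lambda x: counts[x])
            buckets[donor].discard(d)
            buckets[k].add(d)
    return SplitAssignment(train=buckets["train"], val=buckets["val"], test=buckets["test"])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, precision, recall, FPR, F1; undefined ratios are NaN.

    A metric whose denominator is zero is reported as NOT_DEFINED (NaN),
    never silently as 0.
    """

    accuracy: float
    precision: float
    recall: float
    fpr: float
    f1: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else NOT_DEFINED


def compute_metrics(c: ConfusionCounts) -> Metrics:
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = NOT_DEFINED
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        fpr=_ratio(c.fp, c.fp + c.tn),
        f1=f1,
    )


def random_baseline(p_label: float, p_pred: float) -> Metrics:
    """Expected metrics of a label-independent Bernoulli(p_pred) predictor.

    Against Bernoulli(p_label) labels:
        accuracy  = p_label * p_pred + (1 - p_label) * (1 - p_pred)
        recall    = p_pred
        fpr       = p_pred
        precision = p_label
    e.g. a coin as unbalanced as a 60%-positive label set has expected
    accuracy 0.6^2 + 0.4^2 = 0.52, and a coin matching a recall of 0.789
    has the same expected false positive rate, 0.789.
    """
    if not (0 <= p_label <= 1 and 0 <= p_pred <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    accuracy = p_label * p_pred + (1 - p_label) * (1 - p_pred)
    precision = p_label if p_pred > 0 else NOT_DEFINED
    recall = p_pred
    fpr = p_pred
    if math.isnan(precision) or precision + recall == 0:
        f1 = NOT_DEFINED
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, fpr=fpr, f1=f1)


def evaluate(
    model,
    test: Sequence,
    threshold: float = 0.5,
    split: SplitAssignment | None = None,
) -> tuple[ConfusionCounts, Metrics]:
    """Score a trained classifier on held-out labeled examples.

    ``model`` must expose ``predict_proba(examples) -> (n, 2) array`` of
    class probabilities; an example is positive when the positive-class
    probability is >= threshold.  If a SplitAssignment is given, any test
    publication also present in train is a refusal error.
    """
    if split is not None:
        leaked = {_doc_id_of(it) for it in test} & split.train
        if leaked:
            raise ValueError(f"test publications leak into train: {sorted(leaked)[:5]}")
    probs = model.predict_proba(test)
    tp = fp = tn = fn = 0
    for item, p in zip(test, probs):
        pred = 1 if p[1] >= threshold else 0
        label = item.label
        if pred == 1 and label == 1:
            tp += 1
        elif pred == 1 and label == 0:
            fp += 1
        elif pred == 0 and label == 0:
            tn += 1
        else:
            fn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, compute_metrics(counts)
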