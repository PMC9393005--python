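"""Annotated-document model: tokens, dependency edges, entity spans.

Documents arrive pre-annotated (tokenized, sentence-split, dependency
parsed, location entities tagged) in CoNLL-U files with a JSON sidecar of
entity spans — this package consumes linguistic annotation, it does not
produce it.  What it does add is taxon tagging from a name lexicon and
genus de-abbreviation ("B. intermedia" -> "Beania intermedia") using
prior full genus mentions.

All span coordinates are 0-based, half-open [start, end) token indices
within a sentence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "Sentence",
    "Span",
    "AnnotatedDocument",
    "TaxonLexicon",
    "UNRESOLVED",
    "read_annotated_document",
    "write_annotated_document",
    "tag_taxa",
    "deabbreviate_genus",
]


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    ne_tag: str = "O"  # LOCATION | TAXON | O


@dataclass
class Sentence:
    doc_id: str
    sent_index: int
    tokens: list[Token]
    # (head_index, dependent_index, relation); head -1 marks the root
    dep_edges: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ValueError(f"token indices not consecutive in sentence {self.sent_index}")
        n = len(self.tokens)
        for h, d, _ in self.dep_edges:
            if not (-1 <= h < n) or not (0 <= d < n):
                raise ValueError(f"dependency edge ({h},{d}) out of range (n={n})")

    def __len__(self) -> int:
        return len(self.tokens)

    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)


@dataclass(frozen=True)
class Span:
    sent_index: int
    start: int  # inclusive
    end: int  # exclusive
    kind: str  # TAXON | LOCATION
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class AnnotatedDocument:
    doc_id: str
    sentences: list[Sentence]
    spans: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sentences):
            if s.sent_index != i:
                raise ValueError("sentence indices must be 0..n-1 in order")
        for sp in self.spans:
            self._check_span(sp)

    def _check_span(self, sp: Span) -> None:
        if sp.sent_index >= len(self.sentences):
            raise ValueError(f"span references missing sentence {sp.sent_index}")
        if sp.end > len(self.sentences[sp.sent_index]):
            raise ValueError(f"span [{sp.start},{sp.end}) exceeds sentence length")

    def spans_in(self, sent_index: int, kind: str | None = None) -> list[Span]:
        return [
            sp
            for sp in self.spans
            if sp.sent_index == sent_index and (kind is None or sp.kind == kind)
        ]

    def add_spans(self, spans: Iterable[Span]) -> None:
        for sp in spans:
            self._check_span(sp)
            self.spans.append(sp)


class ConlluParseError(ValueError):
    pass


def write_annotated_document(
    doc: AnnotatedDocument, conllu_path: str | Path, spans_path: str | Path
) -> None:
    """Serialize one document to CoNLL-U plus a JSON span sidecar."""
    lines: list[str] = [f"# newdoc id = {doc.doc_id}"]
    for sent in doc.sentences:
        heads = {d: h for h, d, _ in sent.dep_edges}
        rels = {d: r for h, d, r in sent.dep_edges}
        lines.append(f"# sent_id = {doc.doc_id}-{sent.sent_index}")
        lines.append(f"# text = {sent.text()}")
        for tok in sent.tokens:
            head = heads.get(tok.index, -1)
            rel = rels.get(tok.index, "root" if head == -1 else "dep")
            misc = f"NE={tok.ne_tag}" if tok.ne_tag != "O" else "_"
            lines.append(
                "\t".join(
                    [
                        str(tok.index + 1),
                        tok.text,
                        "_",  # lemma
                        "_",  # upos
                        "_",  # xpos
                        "_",  # feats
                        str(head + 1),  # CoNLL-U heads are 1-based, 0 = root
                        rel,
                        "_",
                        misc,
                    ]
                )
            )
        lines.append("")
    Path(conllu_path).write_text("\n".join(lines) + "\n")
    payload = [
        {"sent_index": s.sent_index, "start": s.start, "end": s.end, "kind": s.kind}
        for s in doc.spans
    ]
    Path(spans_path).write_text(json.dumps(payload, indent=1))


def read_annotated_document(
    conllu_path: str | Path, spans_path: str | Path | None = None
) -> AnnotatedDocument:
    """Read one document from a CoNLL-U file (plus optional span sidecar).

    Exactly one document per file: a second ``# newdoc`` directive is an
    error.  Malformed token lines raise with their line number.
    """
    conllu_path = Path(conllu_path)
    doc_id = conllu_path.stem
    sentences: list[Sentence] = []
    cur_tokens: list[Token] = []
    cur_edges: list[tuple[int, int, str]] = []
    seen_newdoc = False

    def flush() -> None:
        nonlocal cur_tokens, cur_edges
        if cur_tokens:
            sentences.append(
                Sentence(doc_id, len(sentences), cur_tokens, cur_edges)
            )
            cur_tokens, cur_edges = [], []

    for lineno, raw in enumerate(conllu_path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*newdoc\b(?:\s*id\s*=\s*(\S+))?", line)
            if m:
                if seen_newdoc:
                    raise ConlluParseError(
                        f"{conllu_path}:{lineno}: second document in file (one per file)"
                    )
                seen_newdoc = True
                if m.group(1):
                    doc_id = m.group(1)
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(
                f"{conllu_path}:{lineno}: expected 10 tab-separated fields, got {len(cols)}"
            )
        if "-" in cols[0] or "." in cols[0]:  # multiword / empty nodes unsupported
            continue
        try:
            idx = int(cols[0]) - 1
            head = int(cols[6]) - 1
        except ValueError as exc:
            raise ConlluParseError(f"{conllu_path}:{lineno}: non-integer index: {exc}")
        ne = "O"
        for item in cols[9].split("|"):
            if item.startswith("NE="):
                ne = item[3:]
        cur_tokens.append(Token(index=idx, text=cols[1], ne_tag=ne))
        cur_edges.append((head, idx, cols[7]))
    flush()

    doc = AnnotatedDocument(doc_id=doc_id, sentences=sentences)
    if spans_path is not None:
        payload = json.loads(Path(spans_path).read_text())
        spans = []
        for item in payload:
            si, a, b = item["sent_index"], item["start"], item["end"]
            if si >= len(sentences) or b > len(sentences[si]):
                raise ValueError(f"span {item} out of range for {conllu_path}")
            surface = " ".join(t.text for t in sentences[si].tokens[a:b])
            spans.append(Span(si, a, b, item["kind"], surface))
        doc.add_spans(spans)
    return doc


@dataclass
class TaxonLexicon:
    """Known genus names and binomials, the basis of taxon tagging rules."""

    genera: set[str]
    binomials: set[str] = field(default_factory=set)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "TaxonLexicon":
        genera, binomials = set(), set()
        for name in names:
            parts = name.split()
            genera.add(parts[0])
            if len(parts) >= 2:
                binomials.add(f"{parts[0]} {parts[1]}")
        return cls(genera=genera, binomials=binomials)


_ABBREV_RE = re.compile(r"^[A-Z]\.$")
_EPITHET_TOKEN = re.compile(r"^[a-z][a-z-]{2,}$")
# function words that a naive "Genus + lowercase token" rule would wrongly
# swallow as species epithets
_EPITHET_STOPWORDS = frozenset(
    "the and was were has have this that with from into are not also but "
    "species genus here there where which occurs occur found".split()
)


def _is_epithet_token(text: str) -> bool:
    return bool(_EPITHET_TOKEN.match(text)) and text not in _EPITHET_STOPWORDS


def tag_taxa(sentence: Sentence, lexicon: TaxonLexicon) -> list[Span]:
    """Rule-based taxon tagging: maximal non-overlapping spans, left to right.

    Rules, longest match first at each position:
      (i)  "Genus epithet" with Genus in the lexicon;
      (ii) abbreviated "G. epithet" (single capital + period);
      (iii) bare Genus in the lexicon.
    A match never extends over a third token (no trinomials unless the
    lexicon is extended to sanction them).
    """
    spans: list[Span] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        t = toks[i].text
        nxt = toks[i + 1].text if i + 1 < len(toks) else None
        two = nxt is not None and _is_epithet_token(nxt)
        if t in lexicon.genera and two:
            spans.append(Span(sentence.sent_index, i, i + 2, "TAXON", f"{t} {nxt}"))
            i += 2
        elif _ABBREV_RE.match(t) and two:
            spans.append(Span(sentence.sent_index, i, i + 2, "TAXON", f"{t} {nxt}"))
            i += 2
        elif t in lexicon.genera:
            spans.append(Span(sentence.sent_index, i, i + 1, "TAXON", t))
            i += 1
        else:
            i += 1
    return spans


#: Sentinel returned when no matching genus occurs in the lookback window.
UNRESOLVED = "UNRESOLVED"


def _span_genus(doc: AnnotatedDocument, sp: Span) -> str | None:
    """First token of a TAXON span when it is a full (unabbreviated) genus."""
    first = doc.sentences[sp.sent_index].tokens[sp.start].text
    if _ABBREV_RE.match(first):
        return None
    return first


def deabbreviate_genus(doc: AnnotatedDocument, span: Span, lookback: int = 14) -> str:
    """Resolve an abbreviated genus ("B.") from prior taxon mentions.

    Scans TAXON spans before the abbreviation — first earlier spans in the
    same sentence, then the previous ``lookback`` sentences in reverse
    order, most recent mention first — and returns the first full genus
    starting with the same capital letter, or UNRESOLVED.  The result
    depends only on the document prefix up to the span.
    """
    first_tok = doc.sentences[span.sent_index].tokens[span.start].text
    if not _ABBREV_RE.match(first_tok):
        raise ValueError(f"span {span.surface!r} is not an abbreviated genus")
    letter = first_tok[0]

    def candidates(sent_index: int, before: int | None):
        sps = [
            sp
            for sp in doc.spans_in(sent_index, kind="TAXON")
            if before is None or sp.end <= before
        ]
        return sorted(sps, key=lambda s: s.start, reverse=True)

    for sp in candidates(span.sent_index, span.start):
        g = _span_genus(doc, sp)
        if g and g[0] == letter:
            return g
    lo = max(0, span.sent_index - lookback)
    for si in range(span.sent_index - 1, lo - 1, -1):
        for sp in candidates(si, None):
            g = _span_genus(doc, sp)
            if g and g[0] == letter:
                return g
    return UNRESOLVED
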