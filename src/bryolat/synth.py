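"""Synthetic inputs for the whole pipeline.

Everything the pipeline consumes can be generated here with a known
ground truth: gazetteers with controlled bounding-box sizes, simulated
point occurrences drawn from a specified latitudinal richness profile
with per-unit detection probability, bounding-box ("text-mined"-style)
records derived from those points, synonym tables, land masks, and
template-based annotated corpora with gold species-location relation
labels.  All generators are deterministic functions of their
configuration and seed.

What the generators emulate — and what they do not — is documented in
the package methods note: the corpora are templated, not natural
language; species ranges are latitudinally contiguous rectangles
spanning all longitudes; sampling effort is uniform within a band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedDocument, Sentence, Span, Token
from .geo import BandGrid, GeoBox, Gazetteer, GeocodeResult, box_area_fraction, LandMask
from .harmonize import CleanRecord, SynonymTable
from .relations import Candidate, LabeledCandidate

__all__ = [
    "RichnessProfile",
    "SimulationConfig",
    "SentenceTemplate",
    "CorpusBundle",
    "LocationLabel",
    "EmptyGazetteerError",
    "UnmappableRecordError",
    "TemplateConfigError",
    "make_gazetteer",
    "bimodal_profile",
    "uniform_profile",
    "simulate_occurrences",
    "true_band_richness",
    "boxify_records",
    "generate_corpus",
    "worked_example_document",
    "DEFAULT_TEMPLATES",
    "make_synonym_table",
    "make_land_mask",
    "write_darwin_core_csv",
]


# ---------------------------------------------------------------------------
# Profiles


@dataclass(frozen=True)
class RichnessProfile:
    """True species richness per latitudinal band."""

    band_edges: tuple[float, ...]
    true_richness: tuple[int, ...]
    shape_name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.true_richness) != len(self.band_edges) - 1:
            raise ValueError("need one richness value per band")
        if any(c < 0 for c in self.true_richness):
            raise ValueError("richness counts must be non-negative")
        if any(b <= a for a, b in zip(self.band_edges, self.band_edges[1:])):
            raise ValueError("band edges must be strictly ascending")

    @property
    def n_bands(self) -> int:
        return len(self.true_richness)

    @property
    def total(self) -> int:
        return int(sum(self.true_richness))


def uniform_profile(n_species_per_band: int, n_bands: int = 36) -> RichnessProfile:
    edges = tuple(np.linspace(-90.0, 90.0, n_bands + 1))
    return RichnessProfile(edges, tuple([n_species_per_band] * n_bands), "uniform")


def bimodal_profile(n_species: int = 200, n_bands: int = 36) -> RichnessProfile:
    """Twin temperate richness peaks near +/-40 degrees with a tropical dip.

    Mimics the shape of a bimodal marine latitudinal diversity gradient:
    two Gaussian bumps centred at -40 and +40 (sd 15 degrees) over a
    small uniform floor, scaled so the per-band counts sum to n_species.
    """
    edges = np.linspace(-90.0, 90.0, n_bands + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    dens = (
        np.exp(-0.5 * ((mids - 40.0) / 15.0) ** 2)
        + np.exp(-0.5 * ((mids + 40.0) / 15.0) ** 2)
        + 0.05
    )
    counts = np.floor(dens / dens.sum() * n_species).astype(int)
    # distribute the rounding remainder to the densest bands
    for i in np.argsort(-dens)[: n_species - counts.sum()]:
        counts[i] += 1
    return RichnessProfile(tuple(edges), tuple(int(c) for c in counts), "bimodal")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 200
    range_width_deg: float = 15.0
    detection_prob: float = 0.3
    units_visited_per_band: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in [0, 1]")
        if self.n_species < 0 or self.units_visited_per_band < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# Gazetteer


class EmptyGazetteerError(ValueError):
    pass


#: Author surnames that a generic NER model mistakes for place names.
_AUTHOR_LOOKALIKES = ("Hincks", "Busk", "Waters")

_PLACE_POOL = (
    "New Zealand", "Tasmania", "Japan", "Madeira", "Azores", "Patagonia",
    "Queensland", "Bass Strait", "Port Phillip Bay", "Fort Pierce Inlet",
    "Oslo Fjord", "Shetland Islands", "Celebes", "Naples", "Plymouth Sound",
    "Chatham Islands", "Falkland Islands", "Cape Verde", "Tierra del Fuego",
    "Spitsbergen", "Galapagos Islands", "Okinawa", "Adriatic Coast",
    "Bay of Biscay", "Cook Strait", "Torres Strait", "Kerguelen Islands",
    "Aleutian Islands", "Gulf of Maine", "Coral Sea",
)

_OVERSIZED_POOL = (
    "Mediterranean Sea", "North Atlantic", "South Pacific", "Indian Ocean",
    "Southern Ocean", "Caribbean Region", "North Sea Region",
)


def make_gazetteer(
    n_names: int, oversized_fraction: float, seed: int = 0
) -> Gazetteer:
    """Gazetteer with a controlled share of oversized bounding boxes.

    Exactly ``round(n_names * oversized_fraction)`` entries cover more
    than 2% of the Earth's surface; the rest are small coastal boxes.
    At least one entry is an author-surname lookalike flagged
    ``non_location`` (when any non-oversized slot exists), so verifier
    training data always contains both classes.
    """
    if n_names == 0:
        raise EmptyGazetteerError("cannot build an empty gazetteer")
    if not (0.0 <= oversized_fraction <= 1.0):
        raise ValueError("oversized_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_over = round(n_names * oversized_fraction)
    n_small = n_names - n_over
    entries: list[GeocodeResult] = []

    def small_box() -> GeoBox:
        clat = rng.uniform(-65.0, 65.0)
        clon = rng.uniform(-170.0, 170.0)
        dlat = rng.uniform(0.5, 2.0)
        dlon = rng.uniform(0.5, 3.0)
        return GeoBox(clat - dlat, clat + dlat, clon - dlon, clon + dlon)

    def oversized_box() -> GeoBox:
        # lat span centred near the equator keeps sin() spread large
        clat = rng.uniform(-20.0, 20.0)
        half = rng.uniform(25.0, 40.0)
        clon = rng.uniform(-100.0, 100.0)
        wlon = rng.uniform(40.0, 70.0)
        b = GeoBox(clat - half, clat + half, clon - wlon, clon + wlon)
        assert box_area_fraction(b) > 0.02
        return b

    n_lookalike = min(len(_AUTHOR_LOOKALIKES), max(n_small, 0)) or min(
        len(_AUTHOR_LOOKALIKES), n_names
    )
    names_small = list(_PLACE_POOL)
    names_over = list(_OVERSIZED_POOL)
    for k in range(max(0, n_small - n_lookalike) - len(names_small)):
        names_small.append(f"Station {k + 1}")
    for k in range(n_over - len(names_over)):
        names_over.append(f"Open Region {k + 1}")

    made_small = 0
    for i in range(n_small):
        if i < n_lookalike:
            name = _AUTHOR_LOOKALIKES[i]
            flag = True
        else:
            name = names_small[i - n_lookalike]
            flag = False
        box = small_box()
        entries.append(
            GeocodeResult(
                name=name,
                box=box,
                centroid_lat=(box.min_lat + box.max_lat) / 2,
                centroid_lon=(box.min_lon + box.max_lon) / 2,
                non_location=flag,
            )
        )
        made_small += 1
    for i in range(n_over):
        name = names_over[i]
        flag = made_small == 0 and i == 0  # all-oversized edge case still gets a lookalike
        if flag:
            name = _AUTHOR_LOOKALIKES[0]
        box = oversized_box()
        entries.append(
            GeocodeResult(
                name=name,
                box=box,
                centroid_lat=(box.min_lat + box.max_lat) / 2,
                centroid_lon=(box.min_lon + box.max_lon) / 2,
                non_location=flag,
            )
        )
    return Gazetteer(entries)


# ---------------------------------------------------------------------------
# Occurrence simulation


def _sim_epithet(i: int) -> str:
    """Letters-only epithet for simulated species (parseable as a binomial)."""
    digits = []
    i += 1
    while i:
        digits.append(chr(ord("a") + i % 26))
        i //= 26
    return "sim" + "".join(reversed(digits))


def _default_grid(profile: RichnessProfile) -> BandGrid:
    return BandGrid(
        scheme="equal_angle",
        band_edges=np.array(profile.band_edges),
        lon_unit_deg=5.0,
    )


def simulate_occurrences(
    profile: RichnessProfile,
    cfg: SimulationConfig,
    grid: BandGrid | None = None,
) -> tuple[list[CleanRecord], dict[str, tuple[float, float]]]:
    """Simulate point occurrences from a known latitudinal richness profile.

    Each species receives a latitudinally contiguous range (all
    longitudes included) of width ``range_width_deg``.  When
    ``cfg.n_species`` equals the profile total and the range width fits
    inside one band, each band is allocated exactly its profile count and
    ranges are placed entirely within their home band, so complete
    sampling reproduces the profile exactly; otherwise home bands are
    drawn multinomially with probabilities proportional to the profile
    and recovery is judged against the returned truth map.

    Sampling: in every band a fixed set of visited (retained) units is
    drawn; each species present in the band is recorded in each visited
    unit with probability ``detection_prob``, as a point uniform in the
    range-band overlap and the unit's longitude interval.

    Returns (records, truth) where truth maps species name to its
    (lat_lo, lat_hi) range.
    """
    if grid is None:
        grid = _default_grid(profile)
    elif len(grid.band_edges) != len(profile.band_edges) or not np.allclose(
        grid.band_edges, profile.band_edges
    ):
        raise ValueError("profile band edges do not align with the grid")
    rng = np.random.default_rng(cfg.seed)
    edges = np.asarray(profile.band_edges)
    widths = np.diff(edges)
    counts = np.asarray(profile.true_richness)
    w = cfg.range_width_deg

    exact = cfg.n_species == profile.total and w <= widths.min() + 1e-9
    if exact:
        homes = np.repeat(np.arange(profile.n_bands), counts)
    else:
        probs = counts / counts.sum() if counts.sum() else np.full(len(counts), 1 / len(counts))
        homes = rng.choice(profile.n_bands, size=cfg.n_species, p=probs)

    truth: dict[str, tuple[float, float]] = {}
    for i, b in enumerate(homes):
        name = f"Simulatella {_sim_epithet(i)}"
        if exact:
            lo_c = edges[b] + w / 2.0
            hi_c = edges[b + 1] - w / 2.0
            center = rng.uniform(lo_c, hi_c) if hi_c > lo_c else (edges[b] + edges[b + 1]) / 2
        else:
            center = rng.uniform(edges[b], edges[b + 1])
        lo = max(center - w / 2.0, -90.0)
        hi = min(center + w / 2.0, 90.0)
        truth[name] = (lo, hi)

    # fixed per-band sampling effort, shared by all species
    visited: list[np.ndarray] = []
    for b in range(grid.n_bands):
        units = np.flatnonzero(grid.retained[b])
        k = min(cfg.units_visited_per_band, len(units))
        visited.append(rng.choice(units, size=k, replace=False) if k else np.array([], int))

    records: list[CleanRecord] = []
    if cfg.detection_prob == 0.0:
        return records, truth
    for name, (lo, hi) in truth.items():
        for b in range(grid.n_bands):
            blo, bhi = edges[b], edges[b + 1]
            olo, ohi = max(lo, blo), min(hi, bhi)
            if ohi <= olo:
                continue
            for u in visited[b]:
                if rng.random() >= cfg.detection_prob:
                    continue
                lat = rng.uniform(olo, ohi)
                ulo, uhi = grid.lon_unit_interval(int(u))
                lon = rng.uniform(ulo, uhi)
                records.append(
                    CleanRecord(name=name, geometry=(lat, lon), source="DB",
                                provenance=f"sim:{name}:{b}:{u}")
                )
    return records, truth


def true_band_richness(
    truth: dict[str, tuple[float, float]], grid: BandGrid
) -> np.ndarray:
    """Species per band whose true range overlaps the band with positive measure."""
    edges = grid.band_edges
    counts = np.zeros(grid.n_bands, dtype=int)
    for lo, hi in truth.values():
        for b in range(grid.n_bands):
            if min(hi, edges[b + 1]) > max(lo, edges[b]):
                counts[b] += 1
    return counts


class UnmappableRecordError(ValueError):
    def __init__(self, points):
        self.points = list(points)
        super().__init__(f"{len(self.points)} point(s) lie in no gazetteer box: "
                         f"{self.points[:5]}")


def boxify_records(
    occurrences: Sequence[CleanRecord], gazetteer: Gazetteer, seed: int = 0,
    strict: bool = True,
) -> list[CleanRecord]:
    """Replace each point with its smallest enclosing gazetteer box.

    Emulates the spatial imprecision of text-mined records: a point
    observation becomes the named place containing it.  Boxes are closed
    (edge points are inside); area ties break on the lexicographically
    smallest name, so the mapping is deterministic and the seed is kept
    only for interface symmetry with the other generators.

    With ``strict`` (default) a point covered by no box raises
    :class:`UnmappableRecordError` listing the offending points; with
    ``strict=False`` such points are silently skipped (a point nobody
    named is a point the literature never mentions).
    """
    entries = sorted(gazetteer, key=lambda e: e.name)
    out: list[CleanRecord] = []
    orphans = []
    for rec in occurrences:
        lat, lon = rec.geometry
        best: GeocodeResult | None = None
        best_area = math.inf
        for e in entries:
            if e.box.contains(lat, lon):
                a = box_area_fraction(e.box)
                if a < best_area:
                    best, best_area = e, a
        if best is None:
            orphans.append((lat, lon))
            continue
        out.append(
            CleanRecord(
                name=rec.name,
                geometry=best.box,
                source="TMO",
                provenance=rec.provenance,
                location_name=best.name,
            )
        )
    if orphans and strict:
        raise UnmappableRecordError(orphans)
    return out


# ---------------------------------------------------------------------------
# Corpus templates


class TemplateConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SentenceTemplate:
    """A sentence skeleton with a stored dependency parse.

    ``items`` mixes literal tokens with slot markers "TAXON", "LOCATION"
    and "LOOKALIKE" (a non-location name the upstream NER mis-tags as
    LOCATION).  ``deps`` are (head_item, dep_item, relation) over item
    positions, head -1 for the root.  Multi-token fillers keep the
    slot's head on their first token; the rest attach with "flat".
    ``positive_pairs`` lists (taxon_ordinal, location_ordinal) pairs the
    sentence asserts; every other taxon-location pair in the sentence is
    a gold negative.
    """

    name: str
    kind: str  # positive | negative | abbreviated | author_lookalike
    items: tuple
    deps: tuple
    positive_pairs: tuple = ()

    def slots(self, which: str) -> int:
        return sum(1 for it in self.items if it == which)


DEFAULT_TEMPLATES: tuple[SentenceTemplate, ...] = (
    SentenceTemplate(
        name="collected-from",
        kind="positive",
        # TAXON was collected from LOCATION .
        items=("TAXON", "was", "collected", "from", "LOCATION", "."),
        deps=((-1, 2, "root"), (2, 0, "nsubj:pass"), (2, 1, "aux:pass"),
              (4, 3, "case"), (2, 4, "obl"), (2, 5, "punct")),
        positive_pairs=((0, 0),),
    ),
    SentenceTemplate(
        name="occurs-in",
        kind="positive",
        # TAXON occurs in LOCATION .
        items=("TAXON", "occurs", "in", "LOCATION", "."),
        deps=((-1, 1, "root"), (1, 0, "nsubj"), (3, 2, "case"),
              (1, 3, "obl"), (1, 4, "punct")),
        positive_pairs=((0, 0),),
    ),
    SentenceTemplate(
        name="report-no-mention",
        kind="negative",
        # The report from LOCATION does not mention TAXON .
        items=("The", "report", "from", "LOCATION", "does", "not", "mention",
               "TAXON", "."),
        deps=((-1, 6, "root"), (1, 0, "det"), (6, 1, "nsubj"), (3, 2, "case"),
              (1, 3, "nmod"), (6, 4, "aux"), (6, 5, "advmod"), (6, 7, "obj"),
              (6, 8, "punct")),
        positive_pairs=(),
    ),
    SentenceTemplate(
        name="abbrev-collected",
        kind="abbreviated",
        # ABBR_TAXON was collected from LOCATION .  (context sentence with
        # the full genus is inserted just before by the generator)
        items=("ABBR_TAXON", "was", "collected", "from", "LOCATION", "."),
        deps=((-1, 2, "root"), (2, 0, "nsubj:pass"), (2, 1, "aux:pass"),
              (4, 3, "case"), (2, 4, "obl"), (2, 5, "punct")),
        positive_pairs=((0, 0),),
    ),
    SentenceTemplate(
        name="described-by-author",
        kind="author_lookalike",
        # TAXON was described by LOOKALIKE in 1881 .
        items=("TAXON", "was", "described", "by", "LOOKALIKE", "in", "1881", "."),
        deps=((-1, 2, "root"), (2, 0, "nsubj:pass"), (2, 1, "aux:pass"),
              (4, 3, "case"), (2, 4, "obl"), (6, 5, "case"), (2, 6, "obl"),
              (2, 7, "punct")),
        positive_pairs=(),
    ),
)


@dataclass(frozen=True)
class LocationLabel:
    """One verifier training example: a tagged location span and its truth."""

    doc_id: str
    sent_index: int
    sentence_tokens: tuple[str, ...]
    span: tuple[int, int]
    label: int  # 1 = real location, 0 = lookalike false positive


@dataclass
class CorpusBundle:
    documents: list[AnnotatedDocument]
    gold: list[LabeledCandidate]
    location_examples: list[LocationLabel]


def _context_sentence(doc_id: str, sent_index: int, genus: str) -> tuple[Sentence, Span]:
    tokens = ["The", "genus", genus, "is", "widespread", "."]
    deps = [(-1, 4, "root"), (2, 0, "det"), (2, 1, "compound"), (4, 2, "nsubj"),
            (4, 3, "cop"), (4, 5, "punct")]
    sent = Sentence(doc_id, sent_index, [Token(i, t) for i, t in enumerate(tokens)], deps)
    return sent, Span(sent_index, 2, 3, "TAXON", genus)


def _expand_template(
    tpl: SentenceTemplate,
    doc_id: str,
    sent_index: int,
    taxon_fillers: list[str],
    location_fillers: list[str],
):
    """Instantiate a template: returns (Sentence, spans, pair_labels).

    ``pair_labels`` maps (taxon_ordinal, location_ordinal) to 0/1.
    """
    tokens: list[Token] = []
    edges: list[tuple[int, int, str]] = []
    item_pos: list[int] = []  # first-token position of each item
    spans: list[Span] = []
    t_i = l_i = 0
    for it in tpl.items:
        pos = len(tokens)
        item_pos.append(pos)
        if it in ("TAXON", "ABBR_TAXON"):
            surface = taxon_fillers[t_i]
            t_i += 1
            parts = surface.split()
            for j, p in enumerate(parts):
                tokens.append(Token(pos + j, p, "TAXON"))
                if j > 0:
                    edges.append((pos, pos + j, "flat"))
            spans.append(Span(sent_index, pos, pos + len(parts), "TAXON", surface))
        elif it in ("LOCATION", "LOOKALIKE"):
            surface = location_fillers[l_i]
            l_i += 1
            parts = surface.split()
            for j, p in enumerate(parts):
                tokens.append(Token(pos + j, p, "LOCATION"))
                if j > 0:
                    edges.append((pos, pos + j, "flat"))
            spans.append(Span(sent_index, pos, pos + len(parts), "LOCATION", surface))
        else:
            tokens.append(Token(pos, it))
    for h, d, r in tpl.deps:
        edges.append((item_pos[h] if h >= 0 else -1, item_pos[d], r))
    sent = Sentence(doc_id, sent_index, tokens, edges)
    n_tax = tpl.slots("TAXON") + tpl.slots("ABBR_TAXON")
    n_loc = tpl.slots("LOCATION") + tpl.slots("LOOKALIKE")
    labels = {
        (a, b): (1 if (a, b) in tpl.positive_pairs else 0)
        for a in range(n_tax)
        for b in range(n_loc)
    }
    return sent, spans, labels


def generate_corpus(
    taxa: Sequence[str],
    gazetteer: Gazetteer,
    n_docs: int,
    templates: Sequence[SentenceTemplate] = DEFAULT_TEMPLATES,
    seed: int = 0,
    sentences_per_doc: tuple[int, int] = (4, 8),
) -> CorpusBundle:
    """Generate annotated documents with gold relation labels.

    Each document draws a run of sentences from the template classes.
    Abbreviated-genus sentences are immediately preceded by a context
    sentence carrying the full genus, so de-abbreviation always has a
    target within the 14-sentence lookback.  Gold labels are positive
    exactly where the template asserts presence; every location span
    yields a verifier example labeled by whether the filler is a real
    place or an author lookalike.
    """
    kinds = {t.kind for t in templates}
    for needed in ("positive", "negative", "abbreviated", "author_lookalike"):
        if needed not in kinds:
            raise TemplateConfigError(f"template set lacks a {needed!r} template")
    real_locs = sorted(e.name for e in gazetteer if not e.non_location)
    lookalikes = sorted(e.name for e in gazetteer if e.non_location)
    if not real_locs or not lookalikes:
        raise TemplateConfigError("gazetteer must supply real locations and lookalikes")
    rng = np.random.default_rng(seed)
    taxa = sorted(taxa)
    docs: list[AnnotatedDocument] = []
    gold: list[LabeledCandidate] = []
    loc_examples: list[LocationLabel] = []
    by_kind: dict[str, list[SentenceTemplate]] = {}
    for t in templates:
        by_kind.setdefault(t.kind, []).append(t)

    for d in range(n_docs):
        doc_id = f"doc{d:03d}"
        n_sent = int(rng.integers(sentences_per_doc[0], sentences_per_doc[1] + 1))
        sentences: list[Sentence] = []
        spans: list[Span] = []
        doc_gold: list[tuple[Span, Span, int, str]] = []
        # one sentence of each class per doc, then random draws
        plan = ["positive", "negative", "abbreviated", "author_lookalike"]
        while len(plan) < n_sent:
            plan.append(str(rng.choice(["positive", "negative", "abbreviated",
                                        "author_lookalike"])))
        rng.shuffle(plan)
        for kind in plan:
            tpl = by_kind[kind][int(rng.integers(len(by_kind[kind])))]
            binom = taxa[int(rng.integers(len(taxa)))]
            genus, epithet = binom.split()[0], binom.split()[1]
            if kind == "abbreviated":
                ctx_sent, ctx_span = _context_sentence(doc_id, len(sentences), genus)
                sentences.append(ctx_sent)
                spans.append(ctx_span)
                taxon_surface = f"{genus[0]}. {epithet}"
            else:
                taxon_surface = binom
            n_loc_slots = tpl.slots("LOCATION") + tpl.slots("LOOKALIKE")
            loc_fill = []
            loc_truth = []
            for it in tpl.items:
                if it == "LOCATION":
                    loc_fill.append(real_locs[int(rng.integers(len(real_locs)))])
                    loc_truth.append(1)
                elif it == "LOOKALIKE":
                    loc_fill.append(lookalikes[int(rng.integers(len(lookalikes)))])
                    loc_truth.append(0)
            si = len(sentences)
            sent, new_spans, pair_labels = _expand_template(
                tpl, doc_id, si, [taxon_surface], loc_fill
            )
            sentences.append(sent)
            spans.extend(new_spans)
            t_spans = [s for s in new_spans if s.kind == "TAXON"]
            l_spans = [s for s in new_spans if s.kind == "LOCATION"]
            for (a, b), lab in pair_labels.items():
                doc_gold.append((t_spans[a], l_spans[b], lab, binom))
            toks = tuple(t.text for t in sent.tokens)
            for ls, truth in zip(l_spans, loc_truth):
                loc_examples.append(
                    LocationLabel(doc_id, si, toks, (ls.start, ls.end), truth)
                )
        doc = AnnotatedDocument(doc_id=doc_id, sentences=sentences)
        doc.add_spans(spans)
        docs.append(doc)
        for tsp, lsp, lab, binom in doc_gold:
            cand = Candidate(
                doc_id=doc_id,
                sent_index=tsp.sent_index,
                taxon_span=tsp,
                location_span=lsp,
                resolved_taxon=binom,
            )
            gold.append(LabeledCandidate(candidate=cand, label=lab))
    return CorpusBundle(documents=docs, gold=gold, location_examples=loc_examples)


def worked_example_document() -> tuple[AnnotatedDocument, list[LabeledCandidate]]:
    """A two-sentence document exercising de-abbreviation and candidates.

    Sentence 0 introduces the full genus Beania; sentence 1 mentions two
    abbreviated species and two locations, asserting presence only for
    the first species: 4 candidates, 2 positive, 2 negative, and "B."
    must resolve to "Beania" through the sentence lookback.
    """
    doc_id = "worked-example"
    s0_tokens = ["Beania", "magellanica", "is", "a", "well", "known", "species", "."]
    s0_deps = [(-1, 6, "root"), (0, 1, "flat"), (6, 0, "nsubj"), (6, 2, "cop"),
               (6, 3, "det"), (5, 4, "advmod"), (6, 5, "amod"), (6, 7, "punct")]
    s0 = Sentence(doc_id, 0, [Token(i, t, "TAXON" if i < 2 else "O")
                              for i, t in enumerate(s0_tokens)], s0_deps)

    s1_tokens = ["The", "avicularia", "resemble", "those", "seen", "in", "B.",
                 "intermedia", "(", "Hincks", ",", "1881b", ")", ",", "from",
                 "Tasmania", "and", "New", "Zealand", ",", "but", "this",
                 "species", "is", "only", "just", "over", "half", "the", "size",
                 "of", "B.", "cookae", "."]
    s1_deps = [
        (1, 0, "det"), (2, 1, "nsubj"), (-1, 2, "root"), (2, 3, "obj"),
        (3, 4, "acl"), (6, 5, "case"), (4, 6, "obl"), (6, 7, "flat"),
        (9, 8, "punct"), (6, 9, "parataxis"), (9, 10, "punct"),
        (9, 11, "nummod"), (9, 12, "punct"), (6, 13, "punct"),
        (15, 14, "case"), (6, 15, "nmod"), (17, 16, "cc"), (15, 17, "conj"),
        (17, 18, "flat"), (2, 19, "punct"), (29, 20, "cc"), (22, 21, "det"),
        (29, 22, "nsubj"), (29, 23, "cop"), (27, 24, "advmod"),
        (27, 25, "advmod"), (27, 26, "advmod"), (29, 27, "nummod"),
        (29, 28, "det"), (2, 29, "conj"), (31, 30, "case"), (29, 31, "nmod"),
        (31, 32, "flat"), (2, 33, "punct"),
    ]
    ne = {6: "TAXON", 7: "TAXON", 15: "LOCATION", 17: "LOCATION",
          18: "LOCATION", 31: "TAXON", 32: "TAXON"}
    s1 = Sentence(doc_id, 1, [Token(i, t, ne.get(i, "O"))
                              for i, t in enumerate(s1_tokens)], s1_deps)
    doc = AnnotatedDocument(doc_id=doc_id, sentences=[s0, s1])
    doc.add_spans([
        Span(0, 0, 2, "TAXON", "Beania magellanica"),
        Span(1, 6, 8, "TAXON", "B. intermedia"),
        Span(1, 31, 33, "TAXON", "B. cookae"),
        Span(1, 15, 16, "LOCATION", "Tasmania"),
        Span(1, 17, 19, "LOCATION", "New Zealand"),
    ])
    ti = doc.spans[1]
    tc = doc.spans[2]
    tas = doc.spans[3]
    nz = doc.spans[4]
    gold = [
        LabeledCandidate(Candidate(doc_id, 1, ti, tas, "Beania intermedia"), 1),
        LabeledCandidate(Candidate(doc_id, 1, ti, nz, "Beania intermedia"), 1),
        LabeledCandidate(Candidate(doc_id, 1, tc, tas, "Beania cookae"), 0),
        LabeledCandidate(Candidate(doc_id, 1, tc, nz, "Beania cookae"), 0),
    ]
    return doc, gold


# ---------------------------------------------------------------------------
# Taxonomy and land-mask fixtures


_GENUS_POOL = (
    "Beania", "Microporella", "Bugula", "Membranipora", "Schizoporella",
    "Celleporella", "Chaperiopsis", "Escharella", "Fenestrulina", "Hippothoa",
    "Smittina", "Tubulipora", "Watersipora", "Adeonella", "Caberea",
)

_EPITHET_POOL = (
    "intermedia", "ciliata", "neritina", "membranacea", "unicornis",
    "hyalina", "magellanica", "immersa", "flagellum", "reticulata",
    "australis", "pacifica", "borealis", "gracilis", "plana", "cookae",
)


def species_pool(n: int, seed: int = 0) -> list[str]:
    """Deterministic list of plausible binomials."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        g = _GENUS_POOL[int(rng.integers(len(_GENUS_POOL)))]
        e = _EPITHET_POOL[int(rng.integers(len(_EPITHET_POOL)))]
        name = f"{g} {e}"
        if name not in seen:
            seen.add(name)
            out.append(name)
        if len(seen) >= len(_GENUS_POOL) * len(_EPITHET_POOL):
            break
    return out


def make_synonym_table(
    accepted: Sequence[str], n_synonyms: int = 5, chain_depth: int = 1, seed: int = 0
) -> SynonymTable:
    """Synonym table over the accepted species with invented old names.

    Synthesizes ``n_synonyms`` unaccepted binomials mapping to accepted
    ones; ``chain_depth`` > 1 builds chains a -> b -> c that must resolve
    to a fixpoint.
    """
    rng = np.random.default_rng(seed)
    accepted = list(accepted)
    genera = {name.split()[0] for name in accepted}
    synonyms: dict[str, str] = {}
    for i in range(n_synonyms):
        target = accepted[int(rng.integers(len(accepted)))]
        prev = target
        for depth in range(chain_depth):
            old = f"{target.split()[0]} obsoleta{i}{depth}"
            synonyms[old] = prev
            prev = old
    return SynonymTable(
        synonyms=synonyms,
        accepted_genera=set(genera),
        accepted_species=set(accepted),
    )


def make_land_mask(
    grid: BandGrid, land_fraction: float = 0.0, seed: int = 0
) -> LandMask:
    """Random land mask: each cell is land with the given probability."""
    rng = np.random.default_rng(seed)
    land = rng.random((grid.n_bands, grid.n_lon_units)) < land_fraction
    return LandMask(land=land)


def write_darwin_core_csv(
    records: Sequence[CleanRecord],
    path: str | Path,
    qualifier_fraction: float = 0.0,
    synonym_table: SynonymTable | None = None,
    synonym_fraction: float = 0.0,
    bad_coord_fraction: float = 0.0,
    seed: int = 0,
) -> None:
    """Write point records as a Darwin-Core-style CSV, optionally dirtied.

    A fraction of rows gets a cf. qualifier inserted, is renamed to an
    unaccepted synonym, or receives out-of-range coordinates — the noise
    the cleaning rules must handle.
    """
    rng = np.random.default_rng(seed)
    reverse: dict[str, list[str]] = {}
    if synonym_table:
        for old, new in synonym_table.synonyms.items():
            reverse.setdefault(new, []).append(old)
    rows = []
    for rec in records:
        lat, lon = rec.geometry
        name = rec.name
        u = rng.random()
        if u < qualifier_fraction:
            g, e = name.split()[0], name.split()[1]
            name = f"{g} cf. {e}"
        elif u < qualifier_fraction + synonym_fraction and name in reverse:
            name = reverse[name][0]
        if rng.random() < bad_coord_fraction:
            lat = 123.4
        rows.append({"scientificName": name, "decimalLatitude": lat,
                     "decimalLongitude": lon, "source": rec.source})
    pd.DataFrame(rows).to_csv(path, index=False)
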