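"""Taxonomic harmonization of occurrence records.

Cleaning rules applied to both database-style (point) and text-mined
(bounding-box) records:

* open-nomenclature qualifiers (cf., aff.) are stripped — uncertainty is
  disregarded, so "Microporella cf. ciliata" becomes "Microporella
  ciliata";
* records without a species epithet are dropped;
* records whose genus is not on the accepted-genera list are dropped;
* names are mapped through a synonym table to their accepted binomial
  (iterated to a fixpoint), and names that never reach an accepted
  binomial are dropped.

Every dropped row carries a machine-readable reason code so that input
rows are conserved: each row ends up either cleaned or in the drop
report, exactly once.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geo import GeoBox, Gazetteer, GeocodeResult, geocode, filter_oversized

__all__ = [
    "TaxonName",
    "SynonymTable",
    "CleanRecord",
    "DropReason",
    "DropReport",
    "OverlapStats",
    "MISSING",
    "parse_taxon_name",
    "resolve_name",
    "clean_db_records",
    "build_tmo_records",
    "merge_sources",
]

#: Sentinel for an absent species epithet.
MISSING = None

_QUALIFIERS = {"cf", "cf.", "aff", "aff."}


class DropReason(enum.Enum):
    NO_EPITHET = "NO_EPITHET"
    GENUS_UNACCEPTED = "GENUS_UNACCEPTED"
    NAME_UNKNOWN = "NAME_UNKNOWN"
    COORD_INVALID = "COORD_INVALID"
    GEOCODE_NOT_FOUND = "GEOCODE_NOT_FOUND"
    BOX_OVERSIZED = "BOX_OVERSIZED"
    UNPARSEABLE = "UNPARSEABLE"


@dataclass(frozen=True)
class TaxonName:
    genus: str
    epithet: str | None
    qualifier: str = "none"  # none | cf | aff

    @property
    def canonical(self) -> str | None:
        """Qualifier-free "Genus epithet"; None when the epithet is missing."""
        if self.epithet is MISSING:
            return None
        return f"{self.genus} {self.epithet}"


class TaxonNameError(ValueError):
    pass


_GENUS_RE = re.compile(r"^[A-Z][a-zA-Z-]+$")
_EPITHET_RE = re.compile(r"^[a-z][a-z-]+$")


def parse_taxon_name(raw: str) -> TaxonName:
    """Parse a scientific-name string into genus/epithet/qualifier.

    Qualifier tokens (cf./aff., case-insensitive, optional period) between
    genus and epithet are detected and recorded but stripped from the
    canonical form.  Trinomials are truncated to the binomial.
    """
    if not raw or not raw.strip():
        raise TaxonNameError("empty taxon name")
    tokens = raw.split()
    head = tokens[0]
    if not _GENUS_RE.match(head):
        raise TaxonNameError(f"unparseable taxon name: {raw!r}")
    genus = head[0].upper() + head[1:].lower()
    qualifier = "none"
    epithet: str | None = MISSING
    for tok in tokens[1:]:
        low = tok.lower()
        if low in _QUALIFIERS:
            qualifier = low.rstrip(".")
            continue
        if _EPITHET_RE.match(low):
            epithet = low
            break
        # author strings, years, parenthesized names: stop scanning
        break
    return TaxonName(genus=genus, epithet=epithet, qualifier=qualifier)


@dataclass
class SynonymTable:
    """Unaccepted-to-accepted binomial map plus accepted-name lists."""

    synonyms: dict[str, str]
    accepted_genera: set[str]
    accepted_species: set[str]
    max_depth: int = 10

    def __post_init__(self) -> None:
        bad = [t for t in self.synonyms.values() if t not in self.accepted_species
               and t not in self.synonyms]
        if bad:
            raise ValueError(f"synonym targets neither accepted nor mapped: {bad[:5]}")

    @classmethod
    def from_files(
        cls, synonyms_csv: str | Path, genera_txt: str | Path, species_txt: str | Path
    ) -> "SynonymTable":
        df = pd.read_csv(synonyms_csv)
        syn = dict(zip(df["unaccepted"], df["accepted"]))
        genera = {l.strip() for l in Path(genera_txt).read_text().splitlines() if l.strip()}
        species = {l.strip() for l in Path(species_txt).read_text().splitlines() if l.strip()}
        return cls(synonyms=syn, accepted_genera=genera, accepted_species=species)

    def to_files(
        self, synonyms_csv: str | Path, genera_txt: str | Path, species_txt: str | Path
    ) -> None:
        pd.DataFrame(
            {"unaccepted": list(self.synonyms), "accepted": list(self.synonyms.values())}
        ).to_csv(synonyms_csv, index=False)
        Path(genera_txt).write_text("\n".join(sorted(self.accepted_genera)) + "\n")
        Path(species_txt).write_text("\n".join(sorted(self.accepted_species)) + "\n")


def resolve_name(name: TaxonName, table: SynonymTable):
    """Map a parsed name to its accepted binomial, or a DropReason.

    Resolution order: epithet present -> genus accepted -> synonym map
    iterated to fixpoint -> membership in the accepted-species list.
    """
    if name.epithet is MISSING:
        return DropReason.NO_EPITHET
    if name.genus not in table.accepted_genera:
        return DropReason.GENUS_UNACCEPTED
    current = name.canonical
    for _ in range(table.max_depth):
        nxt = table.synonyms.get(current)
        if nxt is None or nxt == current:
            break
        current = nxt
    else:
        raise ValueError(f"synonym chain exceeds depth {table.max_depth}: {name.canonical}")
    if current not in table.accepted_species:
        return DropReason.NAME_UNKNOWN
    return current


@dataclass(frozen=True)
class CleanRecord:
    """One cleaned occurrence: accepted binomial + geometry + provenance."""

    name: str
    geometry: object  # (lat, lon) tuple or GeoBox
    source: str  # DB | TMO
    provenance: str = ""
    location_name: str = ""


@dataclass
class DropReport:
    """Rows removed during cleaning, with one reason code per row."""

    rows: list[tuple[str, DropReason]] = field(default_factory=list)

    def add(self, ident: str, reason: DropReason) -> None:
        self.rows.append((ident, reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rows:
            out[reason.value] = out.get(reason.value, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(i, r.value) for i, r in self.rows], columns=["row", "reason"]
        ).to_csv(path, index=False)


REQUIRED_DB_COLUMNS = ("scientificName", "decimalLatitude", "decimalLongitude")


def clean_db_records(
    csv_path: str | Path, table: SynonymTable
) -> tuple[list[CleanRecord], DropReport]:
    """Clean a Darwin-Core-style occurrence CSV into point records.

    Rows survive if the name parses, resolves to an accepted binomial,
    and the coordinates are in range.  Duplicate rows are kept here —
    deduplication happens at the incidence level, where it cannot
    inflate richness.
    """
    df = pd.read_csv(csv_path, dtype={"scientificName": str})
    missing = [c for c in REQUIRED_DB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing required columns: {missing}")
    kept: list[CleanRecord] = []
    report = DropReport()
    for idx, row in df.iterrows():
        rid = f"row{idx}"
        try:
            parsed = parse_taxon_name(str(row["scientificName"]))
        except TaxonNameError:
            report.add(rid, DropReason.UNPARSEABLE)
            continue
        resolved = resolve_name(parsed, table)
        if isinstance(resolved, DropReason):
            report.add(rid, resolved)
            continue
        try:
            lat = float(row["decimalLatitude"])
            lon = float(row["decimalLongitude"])
        except (TypeError, ValueError):
            report.add(rid, DropReason.COORD_INVALID)
            continue
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            report.add(rid, DropReason.COORD_INVALID)
            continue
        kept.append(CleanRecord(name=resolved, geometry=(lat, lon), source="DB", provenance=rid))
    return kept, report


def build_tmo_records(
    positive_candidates: Iterable,
    gazetteer: Gazetteer,
    table: SynonymTable,
    max_box_fraction: float = 0.02,
) -> tuple[list[CleanRecord], DropReport]:
    """Turn classified-positive species-location candidates into records.

    Each candidate supplies ``resolved_taxon`` (a binomial string) and the
    location surface form; the location is geocoded against the gazetteer
    and oversized bounding boxes are removed.
    """
    report = DropReport()
    staged: list[CleanRecord] = []
    cache: dict[str, GeocodeResult | None] = {}
    for cand in positive_candidates:
        ident = f"{cand.doc_id}:{cand.location_span.surface}:{cand.resolved_taxon}"
        parsed = parse_taxon_name(cand.resolved_taxon)
        resolved = resolve_name(parsed, table)
        if isinstance(resolved, DropReason):
            report.add(ident, resolved)
            continue
        hit = geocode(cand.location_span.surface, gazetteer, cache)
        if hit is None:
            report.add(ident, DropReason.GEOCODE_NOT_FOUND)
            continue
        staged.append(
            CleanRecord(
                name=resolved,
                geometry=hit.box,
                source="TMO",
                provenance=cand.doc_id,
                location_name=hit.name,
            )
        )
    kept, oversized = filter_oversized(staged, max_fraction=max_box_fraction)
    for rec in oversized:
        report.add(f"{rec.provenance}:{rec.location_name}:{rec.name}", DropReason.BOX_OVERSIZED)
    return kept, report


@dataclass(frozen=True)
class OverlapStats:
    """Species-set overlap between the two sources (inclusion-exclusion exact)."""

    n_db: int
    n_tmo: int
    n_common: int
    n_union: int

    @property
    def share_common(self) -> float:
        return self.n_common / self.n_union if self.n_union else 0.0

    @property
    def share_db_only(self) -> float:
        return (self.n_db - self.n_common) / self.n_union if self.n_union else 0.0

    @property
    def share_tmo_in_db(self) -> float:
        """Fraction of TMO species also present in DB."""
        return self.n_common / self.n_tmo if self.n_tmo else 0.0

    def as_dict(self) -> dict:
        return {
            "n_db": self.n_db,
            "n_tmo": self.n_tmo,
            "n_common": self.n_common,
            "n_union": self.n_union,
            "share_common": self.share_common,
            "share_db_only": self.share_db_only,
            "share_tmo_in_db": self.share_tmo_in_db,
        }


def merge_sources(
    db: Sequence[CleanRecord], tmo: Sequence[CleanRecord]
) -> tuple[list[CleanRecord], OverlapStats]:
    """Concatenate cleaned sources and tally species-set overlap."""
    s_db = {r.name for r in db}
    s_tmo = {r.name for r in tmo}
    stats = OverlapStats(
        n_db=len(s_db),
        n_tmo=len(s_tmo),
        n_common=len(s_db & s_tmo),
        n_union=len(s_db | s_tmo),
    )
    return list(db) + list(tmo), stats


def records_to_csv(records: Sequence[CleanRecord], path: str | Path) -> None:
    """Write cleaned records as CSV (boxes serialized as four corner columns)."""
    rows = []
    for r in records:
        if isinstance(r.geometry, GeoBox):
            rows.append(
                dict(name=r.name, source=r.source, provenance=r.provenance,
                     location_name=r.location_name, kind="box",
                     min_lat=r.geometry.min_lat, max_lat=r.geometry.max_lat,
                     min_lon=r.geometry.min_lon, max_lon=r.geometry.max_lon)
            )
        else:
            lat, lon = r.geometry
            rows.append(
                dict(name=r.name, source=r.source, provenance=r.provenance,
                     location_name=r.location_name, kind="point",
                     min_lat=lat, max_lat=lat, min_lon=lon, max_lon=lon)
            )
    pd.DataFrame(rows).to_csv(path, index=False)
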