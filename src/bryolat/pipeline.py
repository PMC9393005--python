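"""End-to-end pipeline: synthesize -> mine -> clean -> estimate.

Each stage reads its inputs from the run directory and writes its
outputs back there, so stages can be run separately or re-run; the run
manifest records per-stage record counts (input, kept, dropped by
reason) and the output file list.  The manifest is deterministic for a
fixed (config, seed): timestamps go to the log, never the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import geo, harmonize, nn, relations, richness, synth
from .corpus import read_annotated_document

logger = logging.getLogger("bryolat")

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # synthetic-data stage
    n_taxa: int = 12
    n_docs: int = 24
    gazetteer_size: int = 20
    oversized_fraction: float = 0.1
    n_species: int = 200
    range_width_deg: float = 15.0
    detection_prob: float = 0.3
    units_visited_per_band: int = 4
    tmo_sample_fraction: float = 0.25
    qualifier_fraction: float = 0.05
    synonym_fraction: float = 0.05
    bad_coord_fraction: float = 0.02
    land_fraction: float = 0.0
    # grid / filtering
    grid_schemes: tuple[str, ...] = ("equal_angle", "equal_area")
    n_bands: int = 36
    lon_unit_deg: float = 5.0
    max_box_fraction: float = 0.02
    lookback: int = 14
    # classifiers
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    embedding_dim: int = 300
    recurrent_hidden: int = 64
    dropout: float = 0.2
    epochs: int = 50
    decision_threshold: float = 0.5
    # optional basin polygons: {name: [[lon, lat], ...]}
    basins: dict[str, list] = field(default_factory=dict)

    def model_config(self, seed: int) -> nn.ModelConfig:
        return nn.ModelConfig(
            embedding_dim=self.embedding_dim,
            recurrent_hidden=self.recurrent_hidden,
            dropout=self.dropout,
            epochs=self.epochs,
            seed=seed,
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_RANGES = {
    "oversized_fraction": (0.0, 1.0),
    "detection_prob": (0.0, 1.0),
    "tmo_sample_fraction": (0.0, 1.0),
    "qualifier_fraction": (0.0, 1.0),
    "synonym_fraction": (0.0, 1.0),
    "bad_coord_fraction": (0.0, 1.0),
    "land_fraction": (0.0, 1.0),
    "max_box_fraction": (0.0, 1.0),
    "dropout": (0.0, 0.999),
    "decision_threshold": (0.0, 1.0),
}
_POSITIVE = (
    "n_taxa", "n_docs", "gazetteer_size", "n_species", "n_bands",
    "lon_unit_deg", "embedding_dim", "recurrent_hidden", "epochs", "lookback",
)


def validate_config(path_or_mapping) -> PipelineConfig:
    """Load + validate a YAML/JSON config; raises with every violation listed."""
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
    else:
        raw = dict(path_or_mapping)
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    for k in sorted(unknown):
        errors.append(f"{k}: unknown configuration field")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.grid_schemes, str):
        cfg.grid_schemes = (cfg.grid_schemes,)
    cfg.grid_schemes = tuple(cfg.grid_schemes)
    cfg.split_ratios = tuple(cfg.split_ratios)
    for name, (lo, hi) in _RANGES.items():
        v = getattr(cfg, name)
        if not (lo <= v <= hi):
            errors.append(f"{name}: {v} outside [{lo}, {hi}]")
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            errors.append(f"{name}: must be positive")
    for s in cfg.grid_schemes:
        if s not in ("equal_angle", "equal_area"):
            errors.append(f"grid_schemes: unknown scheme {s!r}")
    if abs(sum(cfg.split_ratios) - 1.0) > 1e-9 or len(cfg.split_ratios) != 3:
        errors.append("split_ratios: need three ratios summing to 1")
    if abs(360.0 / cfg.lon_unit_deg - round(360.0 / cfg.lon_unit_deg)) > 1e-9:
        errors.append("lon_unit_deg: must divide 360")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = dict(sorted(counts.items()))

    def add_output(self, path: Path, base: Path) -> None:
        self.outputs.append(str(path.relative_to(base)))

    def save(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "stages": self.stages,
            "outputs": sorted(self.outputs),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _subseed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _stage_synth(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> dict:
    """Generate every pipeline input with known ground truth."""
    gaz = synth.make_gazetteer(
        cfg.gazetteer_size, cfg.oversized_fraction, seed=_subseed(cfg.seed, "gaz")
    )
    gaz.to_json(out / "gazetteer.json")
    taxa = synth.species_pool(cfg.n_taxa, seed=_subseed(cfg.seed, "taxa"))
    bundle = synth.generate_corpus(
        taxa, gaz, n_docs=cfg.n_docs, seed=_subseed(cfg.seed, "corpus")
    )
    corpus_dir = out / "corpus"
    corpus_dir.mkdir(exist_ok=True)
    from .corpus import write_annotated_document

    for doc in bundle.documents:
        write_annotated_document(
            doc, corpus_dir / f"{doc.doc_id}.conllu", corpus_dir / f"{doc.doc_id}.spans.json"
        )
    profile = synth.bimodal_profile(cfg.n_species, cfg.n_bands)
    sim = synth.SimulationConfig(
        n_species=cfg.n_species,
        range_width_deg=cfg.range_width_deg,
        detection_prob=cfg.detection_prob,
        units_visited_per_band=cfg.units_visited_per_band,
        seed=_subseed(cfg.seed, "sim"),
    )
    records, truth = synth.simulate_occurrences(profile, sim)
    table = synth.make_synonym_table(
        sorted(set(taxa) | set(truth)), n_synonyms=6, chain_depth=2,
        seed=_subseed(cfg.seed, "syn"),
    )
    table.to_files(out / "synonyms.csv", out / "accepted_genera.txt", out / "accepted_species.txt")
    rng = np.random.default_rng(_subseed(cfg.seed, "routing"))
    mask = rng.random(len(records)) < cfg.tmo_sample_fraction
    db_records = [r for r, m in zip(records, mask) if not m]
    tmo_source = [r for r, m in zip(records, mask) if m]
    synth.write_darwin_core_csv(
        db_records, out / "occurrences.csv",
        qualifier_fraction=cfg.qualifier_fraction,
        synonym_table=table, synonym_fraction=cfg.synonym_fraction,
        bad_coord_fraction=cfg.bad_coord_fraction,
        seed=_subseed(cfg.seed, "dirty"),
    )
    grid = geo.make_band_grid("equal_angle", cfg.n_bands, cfg.lon_unit_deg)
    land = synth.make_land_mask(grid, cfg.land_fraction, seed=_subseed(cfg.seed, "land"))
    pd.DataFrame(land.land.astype(int)).to_csv(out / "land_mask.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps({k: list(v) for k, v in sorted(truth.items())}, indent=0)
    )
    gold_rows = [
        {
            "doc_id": lc.candidate.doc_id,
            "sent_index": lc.candidate.sent_index,
            "taxon_span": [lc.candidate.taxon_span.start, lc.candidate.taxon_span.end],
            "location_span": [lc.candidate.location_span.start, lc.candidate.location_span.end],
            "resolved_taxon": lc.candidate.resolved_taxon,
            "label": lc.label,
        }
        for lc in bundle.gold
    ]
    (out / "gold.jsonl").write_text("\n".join(json.dumps(r) for r in gold_rows) + "\n")
    for f in ("gazetteer.json", "synonyms.csv", "accepted_genera.txt",
              "accepted_species.txt", "occurrences.csv", "land_mask.csv",
              "truth.json", "gold.jsonl"):
        manifest.add_output(out / f, out)
    manifest.record(
        "synth",
        documents=len(bundle.documents),
        gold_candidates=len(bundle.gold),
        db_rows=len(db_records),
        tmo_source_points=len(tmo_source),
        gazetteer_entries=len(gaz),
    )
    return {
        "bundle": bundle,
        "gazetteer": gaz,
        "table": table,
        "tmo_source": tmo_source,
        "land": land,
        "profile": profile,
        "truth": truth,
    }


def _stage_mine(cfg: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    """Train/apply the verifier and relation classifier; emit positives."""
    bundle = state["bundle"]
    docs = {d.doc_id: d for d in bundle.documents}
    split = relations.split_by_publication(
        bundle.gold, ratios=cfg.split_ratios, seed=_subseed(cfg.seed, "split")
    )
    rel_ex = nn.relation_examples(bundle.gold, docs)
    ver_ex = nn.verifier_examples(bundle.location_examples)
    vocab = sorted({t for e in rel_ex + ver_ex for t in e.tokens})
    emb = nn.synthetic_embeddings(vocab, dim=cfg.embedding_dim,
                                  seed=_subseed(cfg.seed, "emb"))
    ver_tr, ver_va, ver_te = split.partition(ver_ex)
    verifier = nn.train_verifier(
        ver_tr, ver_va, cfg.model_config(_subseed(cfg.seed, "ver")), emb
    )
    _, ver_metrics = relations.evaluate(verifier, ver_te, cfg.decision_threshold, split)
    rel_tr, rel_va, rel_te = split.partition(rel_ex)
    classifier = nn.train_relation_classifier(
        rel_tr, rel_va, cfg.model_config(_subseed(cfg.seed, "rel")), emb
    )
    _, rel_metrics = relations.evaluate(classifier, rel_te, cfg.decision_threshold, split)

    # apply both models to every candidate in the corpus
    verified = [
        lab for lab, keep in zip(
            bundle.location_examples, verifier.predict(ver_ex, cfg.decision_threshold)
        ) if keep
    ]
    ok_locs = {(lab.doc_id, lab.sent_index, lab.span) for lab in verified}
    candidates = [lc.candidate for lc in bundle.gold]
    keep_mask = [
        (
            c.doc_id,
            c.sent_index,
            (c.location_span.start, c.location_span.end),
        ) in ok_locs
        for c in candidates
    ]
    probs = classifier.predict_proba(rel_ex)
    positives = [
        c
        for c, ok, p in zip(candidates, keep_mask, probs)
        if ok and p[1] >= cfg.decision_threshold
    ]
    rows = [
        {
            "doc_id": c.doc_id,
            "sent_index": c.sent_index,
            "resolved_taxon": c.resolved_taxon,
            "location": c.location_span.surface,
        }
        for c in positives
    ]
    (out / "positives.jsonl").write_text("\n".join(json.dumps(r) for r in rows) + "\n")
    metrics = {
        "verifier": dataclasses.asdict(ver_metrics),
        "relation": dataclasses.asdict(rel_metrics),
        "verifier_best_val_f1": verifier.best_val_f1,
        "relation_best_val_f1": classifier.best_val_f1,
    }
    (out / "classifier_metrics.json").write_text(json.dumps(metrics, indent=1))
    manifest.add_output(out / "positives.jsonl", out)
    manifest.add_output(out / "classifier_metrics.json", out)
    manifest.record(
        "mine",
        candidates=len(candidates),
        verified_locations=len(verified),
        predicted_positive=len(positives),
    )
    state["positives"] = positives


def _stage_clean(cfg: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    table = state["table"]
    db_records, db_report = harmonize.clean_db_records(out / "occurrences.csv", table)
    tmo_text, tmo_report = harmonize.build_tmo_records(
        state["positives"], state["gazetteer"], table, cfg.max_box_fraction
    )
    # simulated occurrences routed through the text channel: map points to
    # named-place boxes, then apply the same area filter
    boxed = synth.boxify_records(
        state["tmo_source"], state["gazetteer"], seed=_subseed(cfg.seed, "boxify"),
        strict=False,
    )
    boxed_kept, boxed_removed = geo.filter_oversized(boxed, cfg.max_box_fraction)
    tmo_records = tmo_text + boxed_kept
    merged, overlap = harmonize.merge_sources(db_records, tmo_records)
    harmonize.records_to_csv(db_records, out / "clean_db.csv")
    harmonize.records_to_csv(tmo_records, out / "clean_tmo.csv")
    db_report.to_csv(out / "drops_db.csv")
    tmo_report.to_csv(out / "drops_tmo.csv")
    (out / "overlap.json").write_text(json.dumps(overlap.as_dict(), indent=1))
    for f in ("clean_db.csv", "clean_tmo.csv", "drops_db.csv", "drops_tmo.csv",
              "overlap.json"):
        manifest.add_output(out / f, out)
    manifest.record(
        "clean",
        db_kept=len(db_records),
        db_dropped=len(db_report),
        tmo_kept=len(tmo_records),
        tmo_dropped=len(tmo_report) + len(boxed_removed),
        species_db=overlap.n_db,
        species_tmo=overlap.n_tmo,
        species_union=overlap.n_union,
    )
    state["db_records"] = db_records
    state["tmo_records"] = tmo_records
    state["merged"] = merged


def _stage_estimate(cfg: PipelineConfig, out: Path, state: dict, manifest: RunManifest) -> None:
    land = state["land"]
    sources = {
        "DB": state["db_records"],
        "TMO": state["tmo_records"],
        "combined": state["merged"],
    }
    n_profiles = 0
    for scheme in cfg.grid_schemes:
        grid = geo.make_band_grid(scheme, cfg.n_bands, cfg.lon_unit_deg)
        grid = geo.apply_land_mask(grid, land)
        for source, recs in sources.items():
            for estimator in ("observed", "chao2", "jackknife1", "range_through"):
                df = richness.richness_profile(recs, grid, estimator)
                df.insert(0, "source", source)
                name = f"profile_{scheme}_{source}_{estimator}.csv"
                df.to_csv(out / name, index=False)
                manifest.add_output(out / name, out)
                n_profiles += 1
            counts = geo.heatmap_counts(recs, grid)
            hname = f"heatmap_{scheme}_{source}.csv"
            pd.DataFrame(counts).to_csv(out / hname, index=False)
            manifest.add_output(out / hname, out)
        for basin, ring in cfg.basins.items():
            subset = geo.region_filter(sources["combined"], [ring])
            df = richness.richness_profile(subset, grid, "range_through")
            df.insert(0, "source", f"combined:{basin}")
            name = f"profile_{scheme}_basin_{basin}.csv"
            df.to_csv(out / name, index=False)
            manifest.add_output(out / name, out)
    manifest.record("estimate", profiles=n_profiles, basins=len(cfg.basins))


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order and return the saved manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash())
    state = _stage_synth(cfg, out, manifest)
    _stage_mine(cfg, out, state, manifest)
    _stage_clean(cfg, out, state, manifest)
    _stage_estimate(cfg, out, state, manifest)
    manifest.save(out / "manifest.json")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
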