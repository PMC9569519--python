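"""End-to-end pipeline: curate -> split -> normalize -> train -> predict ->
filter -> rank, with a manifest of every artifact written.

The upstream sequencing stages (variant calling, HLA typing, binding and
TAP prediction, expression quantification) are represented by the feature
table's input contract: one row per (peptide, allele) candidate with
``ic50_nm``, ``tap`` and ``tpm`` columns.  Any producer of that table plugs
in here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cnn import ModelConfig, alphabet_hash, predict, save_model, train
from .curation import DEFAULT_SPLIT_FRACTIONS, assign_splits, curate_dataframe
from .dataset import build_encoded_dataset
from .alphabet import DEFAULT_ALPHABET, PseudoSequenceTable
from .io import read_table, write_table
from .ranking import (candidates_from_frame, filter_candidates, rank_candidates,
                      rejects_frame)

logger = logging.getLogger(__name__)

STAGES = ("curate", "split", "normalize", "train", "predict", "filter", "rank")


class PipelineConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run; one seed drives all stages."""

    assays_path: str
    features_path: str
    pseudo_path: str
    out_dir: str
    seed: int = 0
    split_fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS
    column_map: dict = field(default_factory=dict)
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("model"), dict):
            data["model"] = ModelConfig(**data["model"])
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("assays_path", "features_path", "pseudo_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineConfigError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk).

    Each stage's outputs are written before the next stage starts, so a
    failure leaves partial results in place; the manifest lists every file
    with its SHA-256 and the stage that produced it.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][p.name] = {"sha256": _sha256(p), "stage": stage}
        logger.info("stage %s complete (%d file(s))", stage, len(paths))

    model_cfg = dataclasses.replace(config.model, seed=config.seed)

    # curate
    assays = read_table(config.assays_path, schema="assays")
    curated = curate_dataframe(assays, config.column_map)
    curated_path = out / "curated.tsv"
    write_table(curated.rows, curated_path)
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(curated.provenance, indent=2))
    record("curate", curated_path, prov_path)

    # split
    curated = assign_splits(curated, config.split_fractions, seed=config.seed)
    split_path = out / "curated_splits.tsv"
    write_table(curated.rows, split_path)
    record("split", split_path)

    # normalize (+ encode)
    features = read_table(config.features_path, schema="features")
    pseudo = PseudoSequenceTable.from_file(config.pseudo_path)
    encoded = build_encoded_dataset(curated.rows, features, pseudo)
    norm_path = out / "normalization.json"
    norm_path.write_text(json.dumps(
        {k: {"x_min": c.x_min, "x_max": c.x_max, "transform": c.transform}
         for k, c in encoded.norm_constants.items()}, indent=2))
    record("normalize", norm_path)

    # train
    checksum = alphabet_hash(DEFAULT_ALPHABET, pseudo)
    model = train(encoded.arrays, model_cfg, encoded.norm_constants, checksum)
    model_path = out / "model.npz"
    save_model(model, model_path)
    record("train", model_path)

    # predict (every curated pair, regardless of split)
    scores = predict(model, encoded.arrays, alphabet_checksum=checksum)
    scored = encoded.table.copy()
    scored["immunogenicity"] = scores
    scored = scored.rename(columns={"ic50_nm": "ic50"})
    scored_path = out / "scored.tsv"
    write_table(scored, scored_path)
    record("predict", scored_path)

    # filter
    rejects: list = []
    kept = filter_candidates(candidates_from_frame(scored), rejects)
    rejects_path = out / "rejects.tsv"
    write_table(rejects_frame(rejects), rejects_path)
    record("filter", rejects_path)

    # rank
    ranked = rank_candidates(kept)
    ranked_path = out / "ranked.tsv"
    write_table(ranked, ranked_path)
    record("rank", ranked_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
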