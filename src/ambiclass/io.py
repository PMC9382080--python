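"""Readers, writers and the end-to-end pipeline runner.

Tabular interchange is TSV with a header row; nested artifacts (metrics,
rule sets, model cards, configs) are JSON.  Positions are 1-based and
inclusive everywhere, matching UniProt/PDB author numbering.  Every file
written here carries provenance comment lines (tool version, seed,
config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

import ambiclass
from ambiclass.classify import (
    MODEL_CONFIGS,
    ModelConfig,
    evaluate_classifier,
    feature_importance,
    split_dataset,
    train_classifier,
)
from ambiclass.rules import induce_rules, surrogate_fidelity

logger = logging.getLogger(__name__)

#: Raw label alphabet each pipeline mode expects.
MODE_LABELS = {
    "disprot_codnas": {"O", "T", "D"},
    "foldswitch": {"S", "C"},
    "combined": {"order", "ambiguous", "disorder"},
}


def read_fasta(path) -> dict[str, str]:
    """Ordered id -> sequence mapping; duplicate ids are rejected."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_pdb_ca(path) -> dict[str, np.ndarray]:
    """Per-chain Cα coordinates from a PDB file.

    For alternate locations the first-listed conformer is kept; residues
    without a Cα atom are logged as gaps.  Files without any ATOM Cα
    records are rejected.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    chains: dict[str, np.ndarray] = {}
    model = structure[0]
    for chain in model:
        coords = []
        for residue in chain:
            if residue.het_flag != "A":
                continue
            ca = None
            for atom in residue:
                if atom.name == "CA":
                    ca = atom  # first listed altloc wins
                    break
            if ca is None:
                logger.warning(
                    "%s chain %s residue %s has no CA atom (gap)",
                    path, chain.name, residue.seqid.num,
                )
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if coords:
            chains[chain.name] = np.asarray(coords, dtype=float)
    if not chains:
        raise ValueError(f"no ATOM Cα records found in {path}")
    return chains


def _provenance_lines(seed=None, config_hash=None) -> list[str]:
    parts = [f"# ambiclass {ambiclass.__version__}", "# positions are 1-based"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    return parts


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    """TSV writer with provenance comment header."""
    with open(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(payload: dict, path, seed=None, config_hash=None) -> None:
    meta = {"tool": f"ambiclass {ambiclass.__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config_hash is not None:
        meta["config_hash"] = config_hash
    with open(path, "w") as fh:
        json.dump({"provenance": meta, **payload}, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "combined"
    seed: int = 42
    model: ModelConfig | None = None
    rule_seed: int | None = None
    prune_error_tolerance: float = 0.5
    min_coverage: int = 2
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "model": None if self.model is None else vars(self.model).copy(),
            "prune_error_tolerance": self.prune_error_tolerance,
            "min_coverage": self.min_coverage,
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(table: pd.DataFrame, config: RunConfig) -> dict:
    """Full analysis on a labeled feature table.

    Splits (stratified; 10% test for the disprot_codnas and foldswitch
    modes, 30% for combined), trains the preset forest, evaluates,
    reports impurity importances, induces the rule surrogate on the
    forest's training-set predictions, and scores its fidelity on the
    held-out predictions.  Writes metrics/rules/importance JSON when
    ``config.out_dir`` is set and returns the result bundle.
    """
    if config.mode not in MODE_LABELS:
        raise ValueError(f"unknown mode {config.mode!r}")
    observed = set(map(str, table["label"].unique()))
    expected = MODE_LABELS[config.mode]
    if not observed <= expected:
        raise ValueError(
            f"labels {sorted(observed - expected)} are inconsistent with mode "
            f"{config.mode!r} (expected subset of {sorted(expected)})"
        )
    if len(observed) < 2:
        raise ValueError(
            f"mode {config.mode!r} needs at least two classes, found {sorted(observed)}"
        )
    model_config = config.model
    if model_config is None:
        preset = MODEL_CONFIGS[config.mode]
        model_config = ModelConfig(**{**vars(preset), "seed": config.seed})

    train, test = split_dataset(table, model_config.test_fraction, seed=config.seed)
    model = train_classifier(train, model_config)
    metrics = evaluate_classifier(model, test)
    importance = feature_importance(model)

    surrogate_labels = model.predict(train)
    rule_seed = config.seed if config.rule_seed is None else config.rule_seed
    ruleset = induce_rules(
        train,
        surrogate_labels,
        min_coverage=config.min_coverage,
        prune_error_tolerance=config.prune_error_tolerance,
        seed=rule_seed,
    )
    fidelity = surrogate_fidelity(ruleset, model.predict(test), test)

    bundle = {
        "mode": config.mode,
        "seed": config.seed,
        "n_train": len(train),
        "n_test": len(test),
        "model_card": model.model_card_,
        "metrics": metrics.to_dict(),
        "metrics_table": metrics.rounded().to_dict(orient="records"),
        "importance": importance,
        "n_rules": len(ruleset.rules),
        "surrogate_fidelity": fidelity,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = config.config_hash()
        write_json({"metrics": bundle["metrics"],
                    "metrics_table": bundle["metrics_table"]},
                   out / "metrics.json", seed=config.seed, config_hash=h)
        write_json({"importance": importance}, out / "importance.json",
                   seed=config.seed, config_hash=h)
        write_json({"model_card": model.model_card_}, out / "model_card.json",
                   seed=config.seed, config_hash=h)
        (out / "rules.json").write_text(ruleset.to_json() + "\n")
        (out / "rules.txt").write_text(ruleset.to_text() + "\n")
        write_json({"surrogate_fidelity": fidelity}, out / "fidelity.json",
                   seed=config.seed, config_hash=h)
        cm = pd.DataFrame(metrics.confusion, index=metrics.classes,
                          columns=metrics.classes)
        write_table(cm.reset_index(names="true_class"), out / "confusion.tsv",
                    seed=config.seed, config_hash=h)
    return bundle
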