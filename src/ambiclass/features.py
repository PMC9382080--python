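"""The seven-feature per-residue vector and its providers.

Every residue is described by seven sequence-predicted biophysical
scores: backbone dynamics, side-chain dynamics, helix / sheet / coil
conformational propensity, early folding propensity and disorder.  All
are unitless; backbone-dynamics scores above 0.8 indicate a well-folded
(rigid) backbone, 0.69-0.80 a context-dependent one and below 0.69 a
flexible one, and disorder scores live in [0, 1].

Feature tables are plain :class:`pandas.DataFrame` objects with columns
``protein_id, position, aa`` plus the seven feature columns.  Providers
produce them: a file-backed provider replays a precomputed TSV, the
synthetic provider draws reproducible scores for testing, and an
optional adapter can call the external b2bTools predictor suite when it
is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Order of the seven biophysical feature columns in every feature table.
FEATURE_COLUMNS = [
    "backbone",
    "sidechain",
    "helix",
    "sheet",
    "coil",
    "earlyfold",
    "disorder",
]

ID_COLUMNS = ["protein_id", "position", "aa"]

#: Upstream sequence predictors require at least 20 residues.
MIN_SEQUENCE_LENGTH = 20

FLEXIBLE = "flexible"
CONTEXT_DEPENDENT = "context_dependent"
RIGID = "rigid"

#: Backbone-dynamics band boundaries: the context-dependent band is the
#: closed interval [0.69, 0.80]; below is flexible, above rigid.
BAND_LOW = 0.69
BAND_HIGH = 0.80


def band_backbone(score: float) -> str:
    """Band a backbone-dynamics score into flexible / context-dependent / rigid."""
    if not np.isfinite(score):
        raise ValueError(f"backbone score must be finite, got {score!r}")
    if score < BAND_LOW:
        return FLEXIBLE
    if score <= BAND_HIGH:
        return CONTEXT_DEPENDENT
    return RIGID


class SyntheticFeatureProvider:
    """Seeded random feature provider for self-contained pipelines.

    Draws each feature uniformly from a plausible score range; the same
    (seed, sequence) pair always yields the same table.  Intended for
    plumbing tests -- class-structured features come from
    :mod:`ambiclass.synthetic`.
    """

    name = "synthetic"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def predict(self, protein_id: str, sequence: str) -> pd.DataFrame:
        # per-protein child seed so tables are independent of call order
        child = np.random.SeedSequence([self.seed, abs(hash(protein_id)) % (2**31)])
        rng = np.random.default_rng(child)
        n = len(sequence)
        data = {"protein_id": protein_id, "position": np.arange(1, n + 1), "aa": list(sequence)}
        for col in FEATURE_COLUMNS:
            hi = 1.0 if col == "disorder" else 1.2
            data[col] = rng.uniform(0.0, hi, size=n)
        return pd.DataFrame(data)


class FileFeatureProvider:
    """Replays per-residue features from a precomputed feature table."""

    name = "file"

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ID_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self._table = table

    def predict(self, protein_id: str, sequence: str) -> pd.DataFrame:
        sub = self._table[self._table["protein_id"] == protein_id]
        if sub.empty:
            raise KeyError(f"no features stored for protein {protein_id!r}")
        sub = sub.sort_values("position").reset_index(drop=True)
        if len(sub) != len(sequence):
            raise ValueError(
                f"{protein_id}: stored feature rows ({len(sub)}) do not match "
                f"sequence length ({len(sequence)})"
            )
        return sub[ID_COLUMNS + FEATURE_COLUMNS].copy()


class B2bToolsProvider:
    """Adapter for the external b2bTools predictor suite (optional).

    Maps the suite's per-residue outputs (DynaMine backbone and side-chain
    dynamics, conformational propensities, EFoldMine early folding,
    DisoMine disorder) onto the seven-feature contract.  Only usable when
    the ``b2bTools`` package is installed; the rest of the pipeline never
    requires it.
    """

    name = "b2btools"

    def __init__(self):
        try:
            from b2bTools import SingleSeq  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the b2bTools predictor suite is not installed; use the file or "
                "synthetic provider instead"
            ) from exc
        self._single_seq = SingleSeq  # pragma: no cover

    def predict(self, protein_id: str, sequence: str) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError(
            "call through b2bTools on a system where it is installed"
        )


def featurize(sequence: str, provider, protein_id: str = "query") -> pd.DataFrame:
    """Predict the seven-feature table for one sequence.

    Sequences shorter than 20 residues are rejected (the minimum length the
    upstream predictors accept).  The returned table carries the provider
    name in ``df.attrs["provider"]`` as provenance.
    """
    if len(sequence) < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"{protein_id}: sequence length {len(sequence)} is below the "
            f"minimum of {MIN_SEQUENCE_LENGTH} residues"
        )
    try:
        table = provider.predict(protein_id, sequence)
    except Exception as exc:
        raise RuntimeError(f"feature provider failed for {protein_id!r}: {exc}") from exc
    table = table.reset_index(drop=True)
    _check_complete(table, protein_id, len(sequence))
    table.attrs["provider"] = getattr(provider, "name", type(provider).__name__)
    return table


def _check_complete(table: pd.DataFrame, protein_id: str, n: int) -> None:
    if len(table) != n:
        raise ValueError(f"{protein_id}: provider returned {len(table)} rows for {n} residues")
    positions = table["position"].to_numpy()
    if not np.array_equal(positions, np.arange(1, n + 1)):
        raise ValueError(f"{protein_id}: positions are not 1..{n} in order")
    bad = validate_feature_table(table)
    if bad:
        raise ValueError(f"{protein_id}: non-finite feature values at {bad[:5]}")


@dataclass(frozen=True)
class FeatureIssue:
    protein_id: str
    position: int
    column: str


def validate_feature_table(table: pd.DataFrame) -> list[FeatureIssue]:
    """List residues with missing or non-finite feature components.

    A clean table yields an empty report.  Disorder scores outside [0, 1]
    are also flagged; the other propensity scores are only checked for
    finiteness since their valid range is predictor-dependent.
    """
    if table.empty:
        logger.warning("validating an empty feature table")
        return []
    issues: list[FeatureIssue] = []
    for col in FEATURE_COLUMNS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if col == "disorder":
            bad |= (values < 0).to_numpy() | (values > 1).to_numpy()
        for _, row in table.loc[bad].iterrows():
            issues.append(FeatureIssue(str(row["protein_id"]), int(row["position"]), col))
    return issues


def drop_incomplete(table: pd.DataFrame) -> pd.DataFrame:
    """Drop (and log) residues with any missing feature; never impute."""
    issues = validate_feature_table(table)
    if not issues:
        return table
    bad_keys = {(i.protein_id, i.position) for i in issues}
    logger.info("dropping %d residues with incomplete features", len(bad_keys))
    mask = [
        (str(p), int(pos)) not in bad_keys
        for p, pos in zip(table["protein_id"], table["position"])
    ]
    return table.loc[mask].reset_index(drop=True)
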