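"""Class-normalized context analyses: PTMs, mutations and pLDDT.

Conformational-class assignments only become interpretable against
external context.  This module consolidates post-translational
modification (PTM) sites across evidence databases, filters missense
mutation sets, and computes class-size-normalized enrichment tables, as
well as pLDDT-versus-feature stratifications of the kind used to relate
sequence-predicted backbone dynamics to structure-prediction confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PTM_TYPES = (
    "phosphorylation",
    "acetylation",
    "methylation",
    "ubiquitination",
    "sumoylation",
    "multiple",
)

CLASSES = ("order", "ambiguous", "disorder")


@dataclass
class EnrichmentTable:
    """Class x category counts with class-size-normalized fractions.

    ``fractions = counts / denominators`` row-wise; the denominators (the
    number of residues assigned to each class) are recorded so the
    normalization is always reconstructible.  ``extra_normalization``
    records any additional column scaling (e.g. the somatic/germline
    count ratio).
    """

    counts: pd.DataFrame
    denominators: dict[str, int]
    fractions: pd.DataFrame = field(init=False)
    unassigned: int = 0
    extra_normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fractions = self.counts.astype(float).copy()
        for cls in fractions.index:
            denom = self.denominators.get(cls, 0)
            if denom > 0:
                fractions.loc[cls] = fractions.loc[cls] / denom
            else:
                fractions.loc[cls] = np.nan
                logger.warning("class %r has zero residues; fractions undefined", cls)
        for col, factor in self.extra_normalization.items():
            fractions[col] = fractions[col] / factor
        self.fractions = fractions


def consolidate_ptms(raw: pd.DataFrame, sequence_lengths: dict[str, int] | None = None,
                     min_evidence: int = 2) -> pd.DataFrame:
    """Consolidate raw PTM records into reliable sites.

    Per (protein, position, type) the evidence databases are unioned
    across input records; types supported by fewer than ``min_evidence``
    distinct databases are dropped.  If more than one type survives at a
    position, the site is reported once with type ``"multiple"`` (a
    single-evidence type can never contribute to "multiple").  Sites
    beyond the supplied sequence length are dropped and logged.

    ``raw`` needs columns ``protein_id, position, ptm_type, source``.
    """
    required = {"protein_id", "position", "ptm_type", "source"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"PTM table missing columns: {sorted(missing)}")
    if raw.empty:
        return pd.DataFrame(columns=["protein_id", "position", "ptm_type", "evidence"])
    work = raw.copy()
    if sequence_lengths is not None:
        def in_range(row):
            length = sequence_lengths.get(row["protein_id"])
            return length is None or 1 <= row["position"] <= length
        keep = work.apply(in_range, axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d PTM records beyond sequence bounds", n_dropped)
        work = work[keep]
    grouped = (
        work.groupby(["protein_id", "position", "ptm_type"])["source"]
        .agg(lambda s: frozenset(s))
        .reset_index(name="evidence")
    )
    grouped = grouped[grouped["evidence"].map(len) >= min_evidence]
    records = []
    for (protein, position), sub in grouped.groupby(["protein_id", "position"]):
        if len(sub) == 1:
            row = sub.iloc[0]
            records.append((protein, position, row["ptm_type"], row["evidence"]))
        else:
            evidence = frozenset().union(*sub["evidence"])
            records.append((protein, position, "multiple", evidence))
    return pd.DataFrame(records, columns=["protein_id", "position", "ptm_type", "evidence"])


def _resolve_classes(df: pd.DataFrame, class_map: dict) -> pd.Series:
    keys = list(zip(df["protein_id"], df["position"]))
    return pd.Series([class_map.get(k) for k in keys], index=df.index, dtype=object)


def ptm_enrichment(sites: pd.DataFrame, class_map: dict, class_totals: dict[str, int],
                   ) -> EnrichmentTable:
    """Count PTM sites per (class, type), normalized by class size.

    ``class_map`` maps ``(protein_id, position)`` to a conformational
    class; sites at residues without an assignment are counted as
    unassigned and reported separately.  Counts are site-level: a residue
    carrying several consolidated records contributes each of them.
    """
    classes = [c for c in CLASSES if c in class_totals] or list(class_totals)
    for cls in classes:
        if cls not in class_totals:
            raise ValueError(f"class_totals missing entry for {cls!r}")
    types = [t for t in PTM_TYPES if sites.empty or t in set(sites.get("ptm_type", []))]
    counts = pd.DataFrame(0, index=classes, columns=types or list(PTM_TYPES), dtype=int)
    unassigned = 0
    if not sites.empty:
        assigned = _resolve_classes(sites, class_map)
        unassigned = int(assigned.isna().sum())
        for cls, sub in sites.groupby(assigned):
            if cls in counts.index:
                for ptm_type, n in sub["ptm_type"].value_counts().items():
                    counts.loc[cls, ptm_type] = int(n)
    return EnrichmentTable(counts=counts, denominators=dict(class_totals),
                           unassigned=unassigned)


def filter_mutation_proteins(muts: pd.DataFrame):
    """Keep proteins that carry at least one deleterious AND one benign mutation.

    Returns ``(filtered, summary)`` where the summary reports retained
    protein and per-category mutation counts.
    """
    required = {"protein_id", "pathogenicity"}
    missing = required - set(muts.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    if muts.empty:
        return muts.copy(), {"n_proteins": 0, "n_mutations": 0,
                             "n_deleterious": 0, "n_benign": 0}
    has_both = (
        muts.groupby("protein_id")["pathogenicity"]
        .agg(lambda s: {"deleterious", "benign"} <= set(s))
    )
    keep = has_both[has_both].index
    filtered = muts[muts["protein_id"].isin(keep)].reset_index(drop=True)
    summary = {
        "n_proteins": int(len(keep)),
        "n_mutations": int(len(filtered)),
        "n_deleterious": int((filtered["pathogenicity"] == "deleterious").sum()),
        "n_benign": int((filtered["pathogenicity"] == "benign").sum()),
    }
    return filtered, summary


def mutation_enrichment(muts: pd.DataFrame, class_map: dict,
                        class_totals: dict[str, int],
                        mode: str = "pathogenicity") -> EnrichmentTable:
    """Mutation counts per class, normalized by class residue totals.

    ``mode="pathogenicity"`` tabulates deleterious/benign counts divided
    by the class totals.  ``mode="origin"`` tabulates somatic/germline
    counts the same way, then additionally divides the somatic column by
    the global somatic/germline count ratio so the two columns are
    directly comparable.
    """
    if mode not in ("pathogenicity", "origin"):
        raise ValueError(f"invalid mode {mode!r}")
    column = mode
    categories = (
        ["deleterious", "benign"] if mode == "pathogenicity" else ["somatic", "germline"]
    )
    classes = [c for c in CLASSES if c in class_totals] or list(class_totals)
    counts = pd.DataFrame(0, index=classes, columns=categories, dtype=int)
    unassigned = 0
    if not muts.empty:
        assigned = _resolve_classes(muts, class_map)
        unassigned = int(assigned.isna().sum())
        for cls, sub in muts.groupby(assigned):
            if cls in counts.index:
                for cat, n in sub[column].value_counts().items():
                    if cat in counts.columns:
                        counts.loc[cls, cat] = int(n)
    extra = {}
    if mode == "origin":
        n_somatic = int((muts[column] == "somatic").sum()) if not muts.empty else 0
        n_germline = int((muts[column] == "germline").sum()) if not muts.empty else 0
        if n_germline > 0 and n_somatic > 0:
            extra["somatic"] = n_somatic / n_germline
    return EnrichmentTable(counts=counts, denominators=dict(class_totals),
                           unassigned=unassigned, extra_normalization=extra)


@dataclass
class HistogramGrid:
    """2D (pLDDT x feature score) count grid for one secondary-structure state."""

    counts: np.ndarray
    plddt_edges: np.ndarray
    feature_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def plddt_feature_histogram(records: pd.DataFrame, feature: str = "backbone",
                            plddt_bin: float = 2.5, feature_bin: float = 0.02,
                            feature_range: tuple[float, float] = (0.0, 1.2),
                            ) -> dict[str, HistogramGrid]:
    """Per-secondary-structure 2D histograms of pLDDT against a feature score.

    ``records`` needs columns ``plddt``, ``ss3`` (helix/strand/coil) and the
    feature column.  Rows with pLDDT outside [0, 100] are rejected and
    logged; grid totals partition the accepted rows by secondary structure.
    """
    for col in ("plddt", "ss3", feature):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    plddt_edges = np.arange(0.0, 100.0 + plddt_bin, plddt_bin)
    lo, hi = feature_range
    feature_edges = np.arange(lo, hi + feature_bin, feature_bin)
    out_of_range = (records["plddt"] < 0) | (records["plddt"] > 100)
    if out_of_range.any():
        logger.warning("rejected %d rows with pLDDT outside [0, 100]",
                       int(out_of_range.sum()))
    accepted = records[~out_of_range]
    grids = {}
    for ss in ("helix", "strand", "coil"):
        sub = accepted[accepted["ss3"] == ss]
        counts, _, _ = np.histogram2d(
            np.clip(sub["plddt"].to_numpy(dtype=float), 0, plddt_edges[-1] - 1e-9),
            np.clip(sub[feature].to_numpy(dtype=float), lo, feature_edges[-1] - 1e-9),
            bins=[plddt_edges, feature_edges],
        )
        grids[ss] = HistogramGrid(counts.astype(int), plddt_edges, feature_edges)
    return grids


def class_context_summary(records: pd.DataFrame, value_columns=("plddt",),
                          class_column: str = "label") -> dict:
    """Per-class distributions of pLDDT (and optionally feature) values.

    For each class and value column, returns the count, mean and the
    25/50/75% quantiles -- the summary behind plots relating class
    assignments to structure-prediction confidence.
    """
    out: dict[str, dict] = {}
    for cls, sub in records.groupby(class_column):
        entry = {}
        for col in value_columns:
            v = sub[col].to_numpy(dtype=float)
            entry[col] = {
                "n": int(len(v)),
                "mean": float(np.mean(v)) if len(v) else np.nan,
                "q25": float(np.percentile(v, 25)) if len(v) else np.nan,
                "q50": float(np.percentile(v, 50)) if len(v) else np.nan,
                "q75": float(np.percentile(v, 75)) if len(v) else np.nan,
            }
        out[str(cls)] = entry
    return out
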