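"""Published benchmark summaries of the residue datasets and models.

The classification scheme implemented here was characterized on curated
residue datasets (DisProt folding-upon-binding regions, CoDNaS rigid
conformer clusters, and a manually curated fold-switch structure-pair
set).  Reproducing those datasets requires large external downloads, but
the published per-class counts and scores are internally redundant --
per-dataset class counts determine the merged-set sizes, and each F1 is
the harmonic mean of its precision and recall -- so they serve as
arithmetic consistency checks on the bookkeeping and metric code.

Only printed summary numbers live here; nothing in this module feeds the
classifiers.
"""

from __future__ import annotations

from ambiclass.classify import round_half_up
from ambiclass.labeling import MERGE_MAP

#: Per-dataset, per-raw-label residue counts and reported test scores of
#: the published forest models: (dataset, raw_label, n, precision, recall, f1).
BENCHMARK_METRICS = [
    ("disprot_codnas", "O", 11_947, 0.72, 0.84, 0.78),
    ("disprot_codnas", "T", 9_409, 0.65, 0.60, 0.62),
    ("disprot_codnas", "D", 4_232, 0.72, 0.50, 0.59),
    ("foldswitch", "S", 3_751, 0.79, 0.96, 0.87),
    ("foldswitch", "C", 1_341, 0.72, 0.26, 0.38),
    ("combined", "order", 15_698, 0.72, 0.86, 0.78),
    ("combined", "ambiguous", 10_750, 0.62, 0.53, 0.57),
    ("combined", "disorder", 4_232, 0.72, 0.46, 0.56),
]

#: Reported sizes of the canonical missense-mutation analysis
#: (proteins with >= 1 deleterious and >= 1 benign mutation) and of the
#: somatic-vs-germline deleterious comparison.
MUTATION_SET_COUNTS = {
    "canonical": {"deleterious": 4_690, "benign": 4_605, "n_proteins": 1_115},
    "somatic_germline": {"somatic": 2_145, "germline": 1_020, "n_proteins": 173},
}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def check_f1_consistency(ndigits: int = 2) -> list[dict]:
    """Recompute every benchmark F1 from its precision/recall.

    Returns one entry per benchmark row with the recomputed (rounded)
    harmonic mean and its deviation from the printed F1.
    """
    out = []
    for dataset, label, n, precision, recall, f1 in BENCHMARK_METRICS:
        recomputed = round_half_up(f1_from_precision_recall(precision, recall), ndigits)
        out.append(
            {
                "dataset": dataset,
                "label": label,
                "n": n,
                "printed_f1": f1,
                "recomputed_f1": recomputed,
                "abs_deviation": abs(recomputed - f1),
            }
        )
    return out


def merged_class_sizes() -> dict[str, int]:
    """Merged order/ambiguous/disorder pool sizes from the per-dataset counts.

    Applies the raw-label merge (O, S -> order; T, C -> ambiguous;
    D -> disorder) to the benchmark counts of the two source datasets.
    """
    sizes = {"order": 0, "ambiguous": 0, "disorder": 0}
    for dataset, label, n, *_ in BENCHMARK_METRICS:
        if dataset == "combined":
            continue
        sizes[MERGE_MAP[label]] += n
    return sizes


def training_pool_total() -> int:
    """Total residues available to the three-class folding-upon-binding model."""
    return sum(n for ds, _, n, *_ in BENCHMARK_METRICS if ds == "disprot_codnas")


def canonical_mutation_total() -> int:
    """Total missense mutations in the canonical pathogenicity analysis."""
    counts = MUTATION_SET_COUNTS["canonical"]
    return counts["deleterious"] + counts["benign"]
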