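"""Residue-level conformational labels.

Three labeling primitives feed the classification datasets:

* fold-switch labels from paired secondary-structure annotations of two
  experimentally solved conformers of the same sequence (same ``S`` /
  converted ``C`` / excluded coil-coil positions),
* a rigidity check on conformer sets, where a protein region counts as
  rigid when every pair of conformers superposes within 2 A RMSD,
* the merge of the raw five-label scheme (O, T, D, S, C) into the three
  conformational classes order / ambiguous / disorder.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

HELIX = "helix"
STRAND = "strand"
COIL = "coil"
SS3_STATES = (HELIX, STRAND, COIL)

#: Strict 8-state -> 3-state simplification: only H is helix and only E is
#: strand; 3-10/pi helices, bridges, turns and bends all collapse to coil.
SS8_TO_SS3_STRICT = {
    "H": HELIX,
    "G": COIL,
    "I": COIL,
    "E": STRAND,
    "B": COIL,
    "T": COIL,
    "S": COIL,
    "-": COIL,
}

#: Extended dialect: 3-10 (G) and pi (I) helices count as helix, isolated
#: beta-bridges (B) as strand.  Kept as an optional mapping for users whose
#: upstream annotations follow the broader DSSP grouping.
SS8_TO_SS3_EXTENDED = {
    "H": HELIX,
    "G": HELIX,
    "I": HELIX,
    "E": STRAND,
    "B": STRAND,
    "T": COIL,
    "S": COIL,
    "-": COIL,
}

RAW_LABELS = ("O", "T", "D", "S", "C", "excluded")
MERGED_CLASSES = ("order", "ambiguous", "disorder")

#: O (rigid conformer clusters) and S (stable secondary structure across a
#: fold switch) are comparably defined and merge to "order"; T (folding upon
#: binding) and C (secondary-structure conversion) both undergo conformational
#: rearrangement and merge to "ambiguous"; D stays "disorder".
MERGE_MAP = {
    "O": "order",
    "S": "order",
    "T": "ambiguous",
    "C": "ambiguous",
    "D": "disorder",
    "excluded": "none",
}

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def simplify_ss(state: str, dialect: str = "strict") -> str:
    """Map an 8-state secondary-structure code to helix / strand / coil.

    Parameters
    ----------
    state:
        Single 8-state DSSP code, one of ``H G I E B T S -``.
    dialect:
        ``"strict"`` (only H -> helix, only E -> strand, default) or
        ``"extended"`` (G, I -> helix; B -> strand).
    """
    mapping = {"strict": SS8_TO_SS3_STRICT, "extended": SS8_TO_SS3_EXTENDED}
    try:
        table = mapping[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'strict' or 'extended'")
    try:
        return table[state]
    except KeyError:
        raise ValueError(f"unknown 8-state secondary-structure code {state!r}")


def pair_label(a: str, b: str) -> str:
    """Fold-switch label for a residue seen in two conformers.

    Residues that stay helix or stay strand in both conformers are ``"S"``
    (same); residues that stay coil in both are ``"excluded"`` (likely
    disordered, dropped from the analysis); every other combination --
    including transitions to or from coil -- is ``"C"`` (converted).
    """
    for state in (a, b):
        if state not in SS3_STATES:
            raise ValueError(f"invalid 3-state secondary structure {state!r}")
    if a == b:
        return "excluded" if a == COIL else "S"
    return "C"


@dataclass(frozen=True)
class StructurePair:
    """Two secondary-structure annotations of the same protein sequence.

    The two conformers must share an identical sequence: small sequence
    variations can themselves change topology, so no alignment between
    non-identical sequences is attempted.
    """

    protein_id: str
    sequence: str
    ss_a: Sequence[str]
    ss_b: Sequence[str]

    def __post_init__(self) -> None:
        if len(self.ss_a) != len(self.sequence) or len(self.ss_b) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: annotation lengths "
                f"({len(self.ss_a)}, {len(self.ss_b)}) do not match sequence "
                f"length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its raw label and merged conformational class."""

    protein_id: str
    position: int  # 1-based
    amino_acid: str
    source: str
    raw_label: str
    merged_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.raw_label not in RAW_LABELS:
            raise ValueError(f"invalid raw label {self.raw_label!r}")
        expected = MERGE_MAP[self.raw_label]
        if self.merged_class == "":
            object.__setattr__(self, "merged_class", expected)
        elif self.merged_class != expected:
            raise ValueError(
                f"merged_class {self.merged_class!r} inconsistent with raw "
                f"label {self.raw_label!r} (expected {expected!r})"
            )


@dataclass(frozen=True)
class PairLabelCounts:
    n_same: int
    n_converted: int
    n_excluded: int


def label_structure_pair(pair: StructurePair, source: str = "foldswitch"):
    """Label every residue of a conformer pair as S / C / excluded.

    Returns ``(records, counts)`` where ``counts`` holds the number of
    same, converted and excluded positions (summing to the length).
    """
    records = []
    counter = Counter()
    for i, (aa, sa, sb) in enumerate(zip(pair.sequence, pair.ss_a, pair.ss_b)):
        raw = pair_label(sa, sb)
        counter[raw] += 1
        records.append(
            ResidueRecord(
                protein_id=pair.protein_id,
                position=i + 1,
                amino_acid=aa,
                source=source,
                raw_label=raw,
            )
        )
    counts = PairLabelCounts(counter["S"], counter["C"], counter["excluded"])
    return records, counts


def merge_label(raw: str) -> str:
    """Merge a raw label into order / ambiguous / disorder / none."""
    try:
        return MERGE_MAP[raw]
    except KeyError:
        raise ValueError(f"invalid raw label {raw!r}")


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimal least-squares RMSD between two point sets (A).

    Both sets are centered and the optimal proper rotation is found by the
    Kabsch procedure, so the result is invariant under rigid motion of
    either argument and symmetric in them.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): {p.shape} vs {q.shape}")
    if p.shape[0] < 1:
        raise ValueError("empty coordinate sets")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("coordinates must be finite")
    n = p.shape[0]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # align_vectors restricts to proper rotations (det +1) and returns the
    # root-sum-square deviation after optimal superposition; collinear sets
    # have a non-unique optimal rotation but a well-defined minimal RMSD
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Optimal rotation is not uniquely")
        _, rssd = Rotation.align_vectors(pc, qc)
    return float(rssd / np.sqrt(n))


def is_rigid(conformers: Sequence[np.ndarray], threshold: float = 2.0):
    """Max-pairwise-RMSD rigidity check over a conformer set.

    A set is rigid when every unordered pair of conformers superposes
    within ``threshold`` A (inclusive).  A single conformer is trivially
    rigid with max RMSD 0.

    Returns ``(max_pairwise_rmsd, rigid)``.
    """
    conformers = [np.asarray(c, dtype=float) for c in conformers]
    if len(conformers) == 0:
        raise ValueError("empty conformer set")
    shapes = {c.shape for c in conformers}
    if len(shapes) > 1:
        raise ValueError(f"conformers have differing atom counts: {sorted(shapes)}")
    worst = 0.0
    for i in range(len(conformers)):
        for j in range(i + 1, len(conformers)):
            worst = max(worst, kabsch_rmsd(conformers[i], conformers[j]))
    return worst, worst <= threshold


def aa_fractions(records: Iterable[ResidueRecord], by: str = "raw_label"):
    """Per-label amino-acid composition.

    Returns ``{label: (fractions, n)}`` where ``fractions`` maps each of the
    20 standard one-letter codes to its fraction within the label group
    (summing to 1); an empty group is flagged with ``n == 0`` and all-zero
    fractions.
    """
    if by not in ("raw_label", "merged_class"):
        raise ValueError(f"invalid grouping {by!r}")
    groups: dict[str, Counter] = {}
    for rec in records:
        if rec.amino_acid not in AMINO_ACIDS:
            raise ValueError(
                f"invalid amino-acid code {rec.amino_acid!r} at "
                f"{rec.protein_id}:{rec.position}"
            )
        groups.setdefault(getattr(rec, by), Counter())[rec.amino_acid] += 1
    out = {}
    for label, counter in groups.items():
        total = sum(counter.values())
        fractions = {aa: (counter[aa] / total if total else 0.0) for aa in AMINO_ACIDS}
        out[label] = (fractions, total)
    return out
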