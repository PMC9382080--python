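"""Synthetic inputs with controlled statistical structure.

Every input the pipeline consumes can be generated here: labeled
feature tables with class-conditional score distributions, planted-rule
datasets for the rule learner, secondary-structure pairs with a
controlled switching fraction, Cα conformer sets with controlled RMSD,
pLDDT tables correlated with backbone rigidity, and PTM/mutation tables
with controlled per-class rates.  All draws are reproducible from one
seed; each table consumes its own child seed (fixed offsets), so adding
a table never perturbs existing draws.

The default class-conditional feature distributions place the three
classes in the qualitative bands the backbone-dynamics convention
defines (order rigid and confidently predicted, disorder flexible,
ambiguous in between); they are configurable plumbing, not measured
values.  Class priors default to the composition of the merged
order/ambiguous/disorder residue pool (roughly 0.51 / 0.35 / 0.14).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from scipy.spatial.transform import Rotation

from ambiclass.features import FEATURE_COLUMNS
from ambiclass.labeling import AMINO_ACIDS, COIL, HELIX, STRAND, StructurePair
from ambiclass.rules import RuleSet

# child-seed offsets per table kind
_OFFSETS = {"features": 1, "rules": 2, "pairs": 3, "conformers": 4, "context": 5}

#: (mean, sd) per class and feature; scores truncated to [0, 1.2]
#: except disorder, truncated to [0, 1].
DEFAULT_FEATURE_PARAMS = {
    "order": {
        "backbone": (0.85, 0.05),
        "sidechain": (0.70, 0.08),
        "helix": (0.40, 0.10),
        "sheet": (0.30, 0.10),
        "coil": (0.25, 0.08),
        "earlyfold": (0.25, 0.08),
        "disorder": (0.05, 0.05),
    },
    "ambiguous": {
        "backbone": (0.76, 0.06),
        "sidechain": (0.60, 0.08),
        "helix": (0.35, 0.10),
        "sheet": (0.25, 0.10),
        "coil": (0.40, 0.10),
        "earlyfold": (0.15, 0.07),
        "disorder": (0.45, 0.10),
    },
    "disorder": {
        "backbone": (0.65, 0.06),
        "sidechain": (0.50, 0.08),
        "helix": (0.25, 0.10),
        "sheet": (0.15, 0.08),
        "coil": (0.60, 0.10),
        "earlyfold": (0.08, 0.05),
        "disorder": (0.85, 0.08),
    },
}

DEFAULT_PTM_RATES = {
    "phosphorylation": {"order": 0.020, "ambiguous": 0.050, "disorder": 0.030},
    "acetylation": {"order": 0.010, "ambiguous": 0.008, "disorder": 0.005},
    "methylation": {"order": 0.005, "ambiguous": 0.005, "disorder": 0.005},
    "ubiquitination": {"order": 0.015, "ambiguous": 0.008, "disorder": 0.004},
    "sumoylation": {"order": 0.004, "ambiguous": 0.002, "disorder": 0.001},
}

DEFAULT_MUTATION_RATES = {
    "deleterious": {"order": 0.030, "ambiguous": 0.025, "disorder": 0.008},
    "benign": {"order": 0.010, "ambiguous": 0.020, "disorder": 0.025},
}

PTM_SOURCES = ("scop3p", "swissprot", "dbptm", "psp")

#: secondary-structure state probabilities (helix, strand, coil) per class,
#: used for the pLDDT table's DSSP-style annotation
DEFAULT_SS3_PROBS = {
    "order": (0.45, 0.35, 0.20),
    "ambiguous": (0.30, 0.20, 0.50),
    "disorder": (0.05, 0.05, 0.90),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 42
    n_proteins: int = 30
    min_length: int = 20
    max_length: int = 120
    class_priors: dict = field(
        default_factory=lambda: {"order": 0.512, "ambiguous": 0.350, "disorder": 0.138}
    )
    feature_params: dict = field(default_factory=lambda: DEFAULT_FEATURE_PARAMS)
    plddt_intercept: float = -122.5
    plddt_slope: float = 250.0
    plddt_noise_sd: float = 8.0
    ptm_rates: dict = field(default_factory=lambda: DEFAULT_PTM_RATES)
    mutation_rates: dict = field(default_factory=lambda: DEFAULT_MUTATION_RATES)
    switch_fraction: float = 0.3
    conformer_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.class_priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class priors must sum to 1, got {total}")
        if self.min_length < 20:
            raise ValueError("minimum protein length is 20 residues")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must be in [0, 1]")
        for cls, params in self.feature_params.items():
            for feat, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {cls}/{feat}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _child_rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _OFFSETS[kind]]))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_class_features(cfg: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Labeled per-residue feature table with class-conditional distributions.

    Residue classes are drawn iid from the class priors; each feature is a
    truncated normal with the class's configured mean and sd.  Returns a
    DataFrame with ``protein_id, position, aa``, the seven features, and a
    ``label`` column.
    """
    seed = cfg.seed if seed is None else seed
    rng = _child_rng(seed, "features")
    classes = list(cfg.class_priors)
    priors = np.array([cfg.class_priors[c] for c in classes])
    frames = []
    for k in range(cfg.n_proteins):
        n = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        labels = rng.choice(classes, size=n, p=priors)
        data = {
            "protein_id": f"SYN{k:04d}",
            "position": np.arange(1, n + 1),
            "aa": rng.choice(list(AMINO_ACIDS), size=n),
        }
        cols = {col: np.empty(n) for col in FEATURE_COLUMNS}
        for cls in classes:
            mask = labels == cls
            m = int(mask.sum())
            if m == 0:
                continue
            for col in FEATURE_COLUMNS:
                mean, sd = cfg.feature_params[cls][col]
                hi = 1.0 if col == "disorder" else 1.2
                cols[col][mask] = _truncated_normal(rng, mean, sd, 0.0, hi, m)
        data.update(cols)
        data["label"] = labels
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def gen_planted_rule_dataset(
    rules: RuleSet,
    n: int,
    noise_rate: float = 0.0,
    seed: int = 0,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Feature rows labeled by a planted rule list, with optional label noise.

    Features are uniform on a grid of step ``grid_step`` over [0, 1], so a
    planted threshold always falls on a grid point and midpoint-based
    learners can recover it to within half a grid step.  Labels are the
    rule-list application, flipped to a different class with probability
    ``noise_rate``.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    rng = _child_rng(seed, "rules")
    n_levels = int(round(1.0 / grid_step)) + 1
    data = {
        col: rng.integers(0, n_levels, size=n) * grid_step for col in FEATURE_COLUMNS
    }
    table = pd.DataFrame(data)
    labels = rules.apply(table)
    class_pool = sorted({r.consequent for r in rules.rules} | {rules.default_class})
    if noise_rate > 0 and len(class_pool) > 1:
        flip = rng.random(n) < noise_rate
        for i in np.nonzero(flip)[0]:
            others = [c for c in class_pool if c != labels[i]]
            labels[i] = others[rng.integers(0, len(others))]
    table["label"] = labels
    return table


def gen_structure_pair(
    length: int,
    switch_fraction: float,
    seed: int = 0,
    protein_id: str = "SYNPAIR",
) -> StructurePair:
    """A conformer pair whose non-coil positions switch at a controlled rate.

    The first annotation is drawn as helix/strand/coil segments; in the
    second, each non-coil position is switched to one of the two other
    states with probability ``switch_fraction``.  Coil positions are left
    untouched, so they are excluded coil-coil pairs.
    """
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValueError("switch_fraction must be in [0, 1]")
    rng = _child_rng(seed, "pairs")
    states = [HELIX, STRAND, COIL]
    ss_a: list[str] = []
    while len(ss_a) < length:
        state = states[rng.choice(3, p=[0.35, 0.25, 0.40])]
        ss_a.extend([state] * int(rng.integers(3, 13)))
    ss_a = ss_a[:length]
    ss_b = list(ss_a)
    for i, s in enumerate(ss_a):
        if s != COIL and rng.random() < switch_fraction:
            others = [t for t in states if t != s]
            ss_b[i] = others[rng.integers(0, 2)]
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return StructurePair(protein_id, sequence, tuple(ss_a), tuple(ss_b))


def gen_conformers(
    n_atoms: int,
    n_conformers: int,
    noise_sd: float,
    seed: int = 0,
) -> list[np.ndarray]:
    """Cα conformer sets: rigid motions of a random coil plus isotropic noise.

    The base chain is a random walk with 3.8 A steps (consecutive Cα
    spacing); each conformer is the base plus Gaussian displacement of sd
    ``noise_sd`` A, then randomly rotated and translated.  With zero noise
    all conformers are congruent (max pairwise RMSD 0).
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    if n_conformers < 1:
        raise ValueError("need at least one conformer")
    rng = _child_rng(seed, "conformers")
    steps = rng.normal(size=(n_atoms - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    base = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    conformers = []
    for _ in range(n_conformers):
        coords = base + rng.normal(scale=noise_sd, size=base.shape)
        rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, size=3))
        coords = rot.apply(coords) + rng.uniform(-10, 10, size=3)
        conformers.append(coords)
    return conformers


def gen_context_tables(cfg: SyntheticConfig, features: pd.DataFrame,
                       seed: int | None = None):
    """pLDDT, raw-PTM and mutation tables consistent with class assignments.

    * pLDDT is a linear function of the backbone score
      (``clip(a + b * backbone + noise, 0, 100)``), so higher predicted
      rigidity means higher structure-prediction confidence.
    * PTM records are drawn per residue at the class- and type-specific
      rates; each planted site is emitted once per evidence database (2-3
      databases), so consolidation keeps it.
    * Mutations are drawn per residue at class-specific deleterious and
      benign rates; deleterious records are mostly somatic, benign mostly
      germline.

    Returns ``(plddt_table, ptm_table, mutation_table)``.
    """
    seed = cfg.seed if seed is None else seed
    rng = _child_rng(seed, "context")
    n = len(features)
    labels = features["label"].to_numpy()

    plddt = np.clip(
        cfg.plddt_intercept
        + cfg.plddt_slope * features["backbone"].to_numpy()
        + rng.normal(scale=cfg.plddt_noise_sd, size=n),
        0.0,
        100.0,
    )
    ss3 = np.empty(n, dtype=object)
    for cls, probs in DEFAULT_SS3_PROBS.items():
        mask = labels == cls
        m = int(mask.sum())
        if m:
            ss3[mask] = rng.choice([HELIX, STRAND, COIL], size=m, p=probs)
    plddt_table = pd.DataFrame(
        {
            "protein_id": features["protein_id"],
            "position": features["position"],
            "plddt": plddt,
            "ss3": ss3,
        }
    )

    ptm_records = []
    for ptm_type, rates in cfg.ptm_rates.items():
        rate = np.array([rates.get(cls, 0.0) for cls in labels])
        hits = np.nonzero(rng.random(n) < rate)[0]
        for i in hits:
            n_sources = 2 + int(rng.random() < 0.3)
            sources = rng.choice(PTM_SOURCES, size=n_sources, replace=False)
            for src in sources:
                ptm_records.append(
                    (
                        features["protein_id"].iat[i],
                        int(features["position"].iat[i]),
                        features["aa"].iat[i],
                        ptm_type,
                        src,
                    )
                )
    ptm_table = pd.DataFrame(
        ptm_records, columns=["protein_id", "position", "aa", "ptm_type", "source"]
    )

    mut_records = []
    for pathogenicity, rates in cfg.mutation_rates.items():
        rate = np.array([rates.get(cls, 0.0) for cls in labels])
        hits = np.nonzero(rng.random(n) < rate)[0]
        p_somatic = 0.67 if pathogenicity == "deleterious" else 0.10
        for i in hits:
            ref = features["aa"].iat[i]
            alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
            origin = "somatic" if rng.random() < p_somatic else "germline"
            mut_records.append(
                (
                    features["protein_id"].iat[i],
                    int(features["position"].iat[i]),
                    ref,
                    alt,
                    pathogenicity,
                    origin,
                )
            )
    mutation_table = pd.DataFrame(
        mut_records,
        columns=["protein_id", "position", "ref", "alt", "pathogenicity", "origin"],
    )
    return plddt_table, ptm_table, mutation_table


@dataclass
class SyntheticDataset:
    """The full fixture bundle one config generates."""

    config: SyntheticConfig
    features: pd.DataFrame
    plddt: pd.DataFrame
    ptms: pd.DataFrame
    mutations: pd.DataFrame

    @property
    def sequences(self) -> dict[str, str]:
        return {
            str(pid): "".join(sub.sort_values("position")["aa"])
            for pid, sub in self.features.groupby("protein_id")
        }


def simulate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete input bundle for one configuration."""
    features = gen_class_features(cfg)
    plddt, ptms, mutations = gen_context_tables(cfg, features)
    return SyntheticDataset(cfg, features, plddt, ptms, mutations)
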