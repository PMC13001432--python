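"""Synthetic structure libraries, bioassay worlds and QSAR datasets with known rules.

Structures come from a seeded scaffold + substituent grammar (alkanes,
cyclohexane, benzene, pyridine decorated with nitro, halogen, hydroxyl,
amino, methyl groups), so every generated SMILES parses and substructure
rules carry real signal. Bioassay worlds plant informative assays whose
outcome is a substructure match (optionally flipped with a noise
probability) among background assays with a fixed hit rate, with entries
withheld at a missing rate; the full ground truth is retained for recovery
tests. QSAR datasets plant one structural rule with label-flip (binary) or
additive Gaussian (continuous) noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset import QSARDataset, Task
from .store import (
    BioactivityRecord,
    BioassayDatabase,
    CompoundRegistry,
    Outcome,
    merge_with_registry,
)

__all__ = [
    "RULES",
    "WorldSpec",
    "InformativeAssay",
    "WorldTruth",
    "generate_chemical_library",
    "generate_bioassay_world",
    "generate_qsar_dataset",
]

#: Named substructure rules available for planting (name -> SMARTS).
RULES: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "halogen": "[F,Cl,Br,I]",
    "hydroxyl": "[OX2H]",
    "amino": "[NX3;H2]",
    "aromatic": "a",
}

_SUBSTITUENTS = ["[N+](=O)[O-]", "Cl", "F", "Br", "O", "N", "C"]

_MONO_TEMPLATES = [
    "c1ccc({a})cc1",
    "c1ccnc({a})c1",
    "C1CCC({a})CC1",
    "CCC({a})CC",
    "CC({a})C",
    "CCCCC{a}",
]

_DI_TEMPLATES = [
    "c1cc({a})ccc1{b}",
    "c1c({a})cccc1{b}",
    "c1cc({a})cnc1{b}",
    "C1CC({a})CCC1{b}",
    "CC({a})CCC({b})C",
    "C({a})CCC{b}",
    "CC({a})CC({b})C",
]

_TRI_TEMPLATES = [
    "c1c({a})cc({b})cc1{c}",
    "CC({a})CC({b})CC({c})C",
    "c1c({a})cnc({b})c1{c}",
]


def _enumerate_library() -> list[str]:
    """Deterministically enumerate the grammar, canonicalized and deduplicated."""
    seen: set[str] = set()
    out: list[str] = []

    def emit(smiles: str) -> None:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)

    for t in _MONO_TEMPLATES:
        for a in _SUBSTITUENTS:
            emit(t.format(a=a))
    for t in _DI_TEMPLATES:
        for a, b in itertools.product(_SUBSTITUENTS, repeat=2):
            emit(t.format(a=a, b=b))
    for t in _TRI_TEMPLATES:
        for a, b, c in itertools.product(_SUBSTITUENTS, repeat=3):
            emit(t.format(a=a, b=b, c=c))
    return out


_LIBRARY_CACHE: list[str] | None = None


def _library() -> list[str]:
    global _LIBRARY_CACHE
    if _LIBRARY_CACHE is None:
        _LIBRARY_CACHE = _enumerate_library()
    return _LIBRARY_CACHE


def generate_chemical_library(n: int, seed: int) -> list[str]:
    """n distinct, parseable SMILES drawn without replacement from the grammar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lib = _library()
    if n > len(lib):
        raise ValueError(
            f"grammar enumerates only {len(lib)} distinct structures (requested {n}); "
            "extend the template/substituent grammar"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), size=n, replace=False)
    return [lib[i] for i in idx]


def matches_rule(smiles: str, rule: str) -> bool:
    """Does the structure contain the named (or SMARTS) substructure rule?"""
    patt = Chem.MolFromSmarts(RULES.get(rule, rule))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or patt is None:
        raise ValueError(f"bad structure or rule: {smiles!r}, {rule!r}")
    return mol.HasSubstructMatch(patt)


@dataclass(frozen=True)
class InformativeAssay:
    aid: str
    rule: str
    noise_rate: float = 0.0


@dataclass
class WorldSpec:
    """Generation spec for a sparse synthetic bioassay world."""

    n_chemicals: int = 100
    n_assays: int = 10
    informative_assays: list[InformativeAssay] = field(default_factory=list)
    background_active_rate: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.background_active_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for a in self.informative_assays:
            if not 0.0 <= a.noise_rate <= 1.0:
                raise ValueError("noise_rate must lie in [0, 1]")
        if self.n_chemicals < 1 or self.n_assays < 1:
            raise ValueError("world must have at least one chemical and one assay")
        if len(self.informative_assays) > self.n_assays:
            raise ValueError("more informative assays than assays")


@dataclass
class WorldTruth:
    """Complete ground truth behind a generated world (no missing entries)."""

    chemicals: list[str]  # cids
    assays: list[str]  # aids
    structures: dict[str, str]  # cid -> SMILES
    truth: np.ndarray  # {1, -1}, chemicals x assays, before withholding
    rules: dict[str, str]  # aid -> rule, informative assays only
    observed: np.ndarray  # bool mask, True where a record was emitted

    @property
    def overall_labels(self) -> np.ndarray:
        """1 iff truly active in at least one assay."""
        return (self.truth == 1).any(axis=1).astype(int)


def generate_bioassay_world(spec: WorldSpec) -> tuple[BioassayDatabase, WorldTruth]:
    """Generate a sparse bioassay database plus its complete ground truth.

    Informative assays label each chemical by substructure match, flipped
    with probability ``noise_rate``; background assays are active with
    probability ``background_active_rate``. Each (chemical, assay) cell is
    withheld (no record) with probability ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    smiles = generate_chemical_library(spec.n_chemicals, spec.seed)
    cids = [f"C{i + 1:05d}" for i in range(spec.n_chemicals)]
    structures = dict(zip(cids, smiles))

    width = max(3, len(str(spec.n_assays)))
    info_aids = [a.aid for a in spec.informative_assays]
    n_background = spec.n_assays - len(info_aids)
    aids = info_aids + [f"A{i + 1:0{width}d}" for i in range(n_background)]
    if len(set(aids)) != len(aids):
        raise ValueError("informative assay aids collide with background aids")
    rules = {a.aid: a.rule for a in spec.informative_assays}

    truth = np.empty((spec.n_chemicals, spec.n_assays), dtype=np.int8)
    for j, aid in enumerate(aids):
        if aid in rules:
            base = np.array(
                [1 if matches_rule(s, rules[aid]) else -1 for s in smiles], dtype=np.int8
            )
            noise = next(a.noise_rate for a in spec.informative_assays if a.aid == aid)
            flip = rng.random(spec.n_chemicals) < noise
            truth[:, j] = np.where(flip, -base, base)
        else:
            hit = rng.random(spec.n_chemicals) < spec.background_active_rate
            truth[:, j] = np.where(hit, 1, -1)

    observed = rng.random(truth.shape) >= spec.missing_rate

    registry = CompoundRegistry()
    for cid, s in structures.items():
        mol = Chem.MolFromSmiles(s)
        registry.add(cid, Chem.MolToInchi(mol), Chem.MolToInchiKey(mol),
                     Chem.MolToSmiles(mol))

    records = [
        BioactivityRecord(
            cids[i], aids[j],
            Outcome.ACTIVE if truth[i, j] == 1 else Outcome.INACTIVE,
        )
        for i in range(spec.n_chemicals)
        for j in range(spec.n_assays)
        if observed[i, j]
    ]
    db, _ = merge_with_registry(records, registry)
    return db, WorldTruth(cids, aids, structures, truth, rules, observed)


def generate_qsar_dataset(
    n: int,
    rule: str = "nitro",
    noise_rate: float = 0.0,
    task: Task | str = Task.BINARY,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> tuple[QSARDataset, pd.DataFrame]:
    """Generate a QSAR dataset with one planted structural rule.

    Binary: label = rule match XOR a noise flip of probability ``noise_rate``;
    class balance (on the noiseless rule) is enforced within ±10% of n/2 by
    stratified sampling. Continuous: activity = heavy-atom count + 3·(rule
    match) + Gaussian noise of sd ``noise_sd``.

    Returns (dataset, truth table with the noiseless rule evaluation).
    """
    task = Task(task) if isinstance(task, str) else task
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = np.random.default_rng(seed)
    lib = _library()
    match_mask = [matches_rule(s, rule) for s in lib]
    pos_pool = [s for s, m in zip(lib, match_mask) if m]
    neg_pool = [s for s, m in zip(lib, match_mask) if not m]
    n_pos = n // 2
    n_neg = n - n_pos
    if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
        raise ValueError(
            f"grammar cannot balance rule {rule!r}: {len(pos_pool)} matching / "
            f"{len(neg_pool)} non-matching structures available"
        )
    pos = [pos_pool[i] for i in rng.choice(len(pos_pool), n_pos, replace=False)]
    neg = [neg_pool[i] for i in rng.choice(len(neg_pool), n_neg, replace=False)]
    smiles = pos + neg
    rule_truth = np.array([True] * n_pos + [False] * n_neg)
    order = rng.permutation(n)
    smiles = [smiles[i] for i in order]
    rule_truth = rule_truth[order]

    ids = [f"S{i + 1:05d}" for i in range(n)]
    if task is Task.BINARY:
        flips = rng.random(n) < noise_rate
        labels = rule_truth.astype(int) ^ flips.astype(int)
        activity = labels.astype(int)
    else:
        heavy = np.array([Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in smiles])
        activity = heavy + 3.0 * rule_truth + rng.normal(0.0, noise_sd, size=n)

    records = pd.DataFrame({"id": ids, "smiles": smiles, "activity": activity})
    truth = pd.DataFrame({"id": ids, "smiles": smiles, "rule_match": rule_truth})
    ds = QSARDataset(f"synthetic_{rule}_{task.value}", records, task)
    return ds, truth
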