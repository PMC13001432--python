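"""Molecular featurization: circular fingerprints and 2D physicochemical descriptors.

ECFP6/FCFP6 are Morgan fingerprints of radius 3 (diameter 6) hashed to 2048
bits; FCFP uses pharmacophoric feature invariants instead of atomic ones.
The physicochemical set is a fixed, documented list of standard 2D
descriptors so feature matrices are reproducible across machines.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

N_BITS = 2048
RADIUS = 3

#: Fixed 2D descriptor list for the "physchem" scheme (order is part of the contract).
PHYSCHEM_DESCRIPTORS: tuple[str, ...] = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHAcceptors",
    "NumHDonors",
    "NumRotatableBonds",
    "NumAromaticRings",
    "HeavyAtomCount",
    "FractionCSP3",
    "RingCount",
    "NumHeteroatoms",
    "MolMR",
    "BalabanJ",
    "BertzCT",
    "Chi0",
    "Chi1",
    "HallKierAlpha",
    "LabuteASA",
    "MaxPartialCharge",
    "MinPartialCharge",
)


def mol_from_structure(structure: str):
    """Parse a SMILES or InChI string; returns None on failure."""
    if structure is None:
        return None
    structure = str(structure).strip()
    if not structure:
        return None
    if structure.startswith("InChI="):
        return Chem.MolFromInchi(structure)
    return Chem.MolFromSmiles(structure)


def _morgan_generator(feature_based: bool):
    if feature_based:
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=RADIUS, fpSize=N_BITS, atomInvariantsGenerator=inv
        )
    return rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


def fingerprint(structure: str, *, feature_based: bool = False) -> np.ndarray | None:
    """2048-bit radius-3 circular fingerprint (uint8 0/1); None if unparseable."""
    mol = mol_from_structure(structure)
    if mol is None:
        return None
    gen = _morgan_generator(feature_based)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def fingerprint_matrix(
    structures, *, feature_based: bool = False
) -> tuple[np.ndarray, list[int]]:
    """Stack fingerprints for a structure list.

    Returns (matrix, kept_indices); unparseable structures are skipped and
    absent from ``kept_indices``.
    """
    gen = _morgan_generator(feature_based)
    rows, kept = [], []
    for i, s in enumerate(structures):
        mol = mol_from_structure(s)
        if mol is None:
            continue
        rows.append(gen.GetFingerprintAsNumPy(mol).astype(np.uint8))
        kept.append(i)
    if not rows:
        return np.zeros((0, N_BITS), dtype=np.uint8), []
    return np.vstack(rows), kept


def physchem_vector(structure: str) -> np.ndarray | None:
    mol = mol_from_structure(structure)
    if mol is None:
        return None
    vals = []
    for name in PHYSCHEM_DESCRIPTORS:
        fn = getattr(Descriptors, name)
        try:
            v = fn(mol)
        except Exception:
            v = float("nan")
        vals.append(v)
    vec = np.asarray(vals, dtype=float)
    # rare descriptor failures (e.g. partial charges on odd atoms) become 0
    vec[~np.isfinite(vec)] = 0.0
    return vec


def physchem_matrix(structures) -> tuple[np.ndarray, list[int]]:
    rows, kept = [], []
    for i, s in enumerate(structures):
        v = physchem_vector(s)
        if v is None:
            continue
        rows.append(v)
        kept.append(i)
    if not rows:
        return np.zeros((0, len(PHYSCHEM_DESCRIPTORS))), []
    return np.vstack(rows), kept
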