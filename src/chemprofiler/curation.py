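"""Structure flagging, standardization and duplicate resolution.

Standardization follows the ChEMBL-style curation procedure on top of RDKit:
sanitize/normalize (kekulization, hydrogen removal, SMIRKS-based functional
group normalization), strip salt/solvent fragments down to the largest
organic parent, and neutralize charges where chemically sensible. Flagging
reports — without fixing — invalid or ambiguous stereochemistry, valence
problems, illegal bond/kekulization states, and undesirable fragments
(salts, solvents, metals). Duplicates are grouped by the InChIKey of the
standardized parent and resolved by a user-chosen policy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

from .dataset import QSARDataset, Task

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "IssueCode",
    "StructureIssue",
    "CuratedRecord",
    "DuplicatePolicy",
    "CurationReport",
    "flag_structure",
    "standardize_structure",
    "curate_dataset",
]

# metals flagged as undesirable; the common organic-subset elements are allowed
_ORGANIC_SUBSET = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}


class IssueCode(enum.Enum):
    INVALID_STEREO = "invalid_stereo"
    BAD_VALENCE = "bad_valence"
    ILLEGAL_BOND = "illegal_bond"
    UNDESIRABLE_FRAGMENT = "undesirable_fragment"
    PARSE_FAILURE = "parse_failure"


@dataclass(frozen=True)
class StructureIssue:
    code: IssueCode
    detail: str = ""


@dataclass
class CuratedRecord:
    original_smiles: str
    standardized_smiles: str
    standardized_inchikey: str
    issues: list[StructureIssue] = field(default_factory=list)
    activity: float | None = None
    record_id: str | None = None


class DuplicatePolicy(enum.Enum):
    HIGHEST = "highest"
    LOWEST = "lowest"
    AVERAGE = "average"
    REMOVE = "remove"


@dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    n_merged: int = 0
    n_removed: int = 0
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)


class CurationError(ValueError):
    pass


def flag_structure(smiles: str) -> list[StructureIssue]:
    """Report structural problems without altering the structure.

    A parse failure short-circuits every other check. Clean structures
    return an empty list.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return [StructureIssue(IssueCode.PARSE_FAILURE, f"unparseable SMILES: {smiles!r}")]

    issues: list[StructureIssue] = []
    problems = Chem.DetectChemistryProblems(mol)
    for p in problems:
        t = p.GetType()
        if t == "AtomValenceException":
            issues.append(StructureIssue(IssueCode.BAD_VALENCE, p.Message()))
        elif t in ("AtomKekulizeException", "KekulizeException"):
            issues.append(StructureIssue(IssueCode.ILLEGAL_BOND, p.Message()))
        else:
            issues.append(StructureIssue(IssueCode.PARSE_FAILURE, p.Message()))
    if problems:
        return issues

    Chem.SanitizeMol(mol)

    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        issues.append(
            StructureIssue(IssueCode.UNDESIRABLE_FRAGMENT,
                           f"{len(frags)} fragments (possible salt/solvent)")
        )
    metals = sorted({a.GetSymbol() for a in mol.GetAtoms()
                     if a.GetAtomicNum() not in _ORGANIC_SUBSET and a.GetAtomicNum() > 1})
    if metals:
        issues.append(
            StructureIssue(IssueCode.UNDESIRABLE_FRAGMENT,
                           f"metal/non-organic atoms: {', '.join(metals)}")
        )

    undefined = [
        idx for idx, code in
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
        if code == "?"
    ]
    if undefined:
        issues.append(
            StructureIssue(IssueCode.INVALID_STEREO,
                           f"unassigned stereocenters at atoms {undefined}")
        )
    for bond in mol.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREOANY:
            issues.append(
                StructureIssue(IssueCode.INVALID_STEREO,
                               f"ambiguous double-bond stereo at bond {bond.GetIdx()}"))
            break
    return issues


def standardize_structure(smiles: str, activity: float | None = None) -> CuratedRecord:
    """Standardize one structure to its neutral parent form.

    Pipeline: sanitize + normalize, keep the largest organic fragment
    (dropping salts/solvents), neutralize charges, emit canonical SMILES and
    the standardized InChIKey. Raises :class:`CurationError` on unparseable
    input. The result is a fixed point: re-standardizing it is a no-op.
    """
    issues = flag_structure(smiles)
    fatal = {IssueCode.PARSE_FAILURE, IssueCode.BAD_VALENCE, IssueCode.ILLEGAL_BOND}
    if any(i.code in fatal for i in issues):
        raise CurationError(f"cannot standardize {smiles!r}: {issues[0].detail}")

    mol = Chem.MolFromSmiles(smiles)
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    std_smiles = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    return CuratedRecord(
        original_smiles=smiles,
        standardized_smiles=std_smiles,
        standardized_inchikey=inchikey,
        issues=issues,
        activity=activity,
    )


def curate_dataset(
    ds: QSARDataset,
    policy: DuplicatePolicy = DuplicatePolicy.AVERAGE,
    rename: bool = True,
) -> tuple[QSARDataset, CurationReport, list[CuratedRecord]]:
    """Standardize every structure and resolve duplicates by standardized InChIKey.

    Policies: keep the highest or lowest activity, average activities, or
    remove duplicated structures entirely. Averaging a binary dataset is
    only allowed when the duplicate group is unanimous (the mean of
    disagreeing 0/1 labels is not a label); such a conflict raises.
    Unparseable structures are dropped and counted as failures. The curated
    dataset is named ``<name>_curated`` unless ``rename`` is False.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    report = CurationReport(n_input=len(ds))
    curated: list[CuratedRecord] = []
    for row in ds.records.itertuples(index=False):
        try:
            rec = standardize_structure(row.smiles, activity=float(row.activity))
        except CurationError as exc:
            report.n_failed += 1
            report.failures.append(str(exc))
            continue
        rec.record_id = str(row.id)
        curated.append(rec)

    groups: dict[str, list[CuratedRecord]] = {}
    for rec in curated:
        groups.setdefault(rec.standardized_inchikey, []).append(rec)

    out_rows = []
    for key in sorted(groups):
        group = groups[key]
        if len(group) == 1:
            rec = group[0]
            out_rows.append((rec.record_id, rec.standardized_smiles, rec.activity))
            report.n_kept += 1
            continue
        activities = [r.activity for r in group]
        if policy is DuplicatePolicy.REMOVE:
            report.n_removed += len(group)
            continue
        if policy is DuplicatePolicy.AVERAGE:
            if ds.task is Task.BINARY and len(set(activities)) > 1:
                raise CurationError(
                    f"average policy on conflicting binary labels for group {key}"
                )
            resolved = sum(activities) / len(activities)
        elif policy is DuplicatePolicy.HIGHEST:
            resolved = max(activities)
        else:
            resolved = min(activities)
        rec = group[0]
        out_rows.append((rec.record_id, rec.standardized_smiles, resolved))
        report.n_kept += 1
        report.n_merged += len(group) - 1

    records = pd.DataFrame(out_rows, columns=["id", "smiles", "activity"])
    name = f"{ds.name}_curated" if rename else ds.name
    return QSARDataset(name, records, ds.task), report, curated
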