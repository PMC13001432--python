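"""Chemical–bioassay outcome records: loading, merging, deduplication and queries.

The store mirrors how large public screening databases export bioactivity:
one row per (compound, assay) observation with a five-state outcome, plus a
separate compound-to-structure mapping (InChI / InChIKey, optionally SMILES).
Records are merged on compound id, entries without a usable InChI are dropped,
and conflicting outcomes for the same (compound, assay) pair are resolved in
favour of the more active call.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Outcome",
    "BioactivityRecord",
    "CompoundRegistry",
    "BioassayDatabase",
    "AssayOutcomeCounts",
    "LoadReport",
    "load_records",
    "load_registry",
    "merge_with_registry",
    "resolve_outcome_conflicts",
    "query_by_chemicals",
    "query_by_assay",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class Outcome(enum.Enum):
    """Five-state assay outcome; ordering encodes conflict-resolution precedence.

    ``active`` wins over everything; ``probe`` (an active chemical probe) is
    grouped with actives downstream; the remaining states rank
    inactive > inconclusive > unspecified.
    """

    ACTIVE = "active"
    PROBE = "probe"
    INACTIVE = "inactive"
    INCONCLUSIVE = "inconclusive"
    UNSPECIFIED = "unspecified"

    @classmethod
    def parse(cls, token: str) -> "Outcome":
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValueError(f"unknown outcome token: {token!r}") from None

    @property
    def precedence(self) -> int:
        order = [Outcome.UNSPECIFIED, Outcome.INCONCLUSIVE, Outcome.INACTIVE,
                 Outcome.PROBE, Outcome.ACTIVE]
        return order.index(self)

    @property
    def is_active(self) -> bool:
        """Active or probe — encoded +1 in bioprofiles."""
        return self in (Outcome.ACTIVE, Outcome.PROBE)

    @property
    def encoded(self) -> int:
        """Bioprofile encoding: 1 active/probe, -1 inactive, 0 otherwise."""
        if self.is_active:
            return 1
        if self is Outcome.INACTIVE:
            return -1
        return 0


@dataclass(frozen=True)
class BioactivityRecord:
    """One (compound, assay, outcome) observation."""

    cid: str
    aid: str
    outcome: Outcome

    def __post_init__(self):
        if not str(self.cid) or not str(self.aid):
            raise ValueError("cid and aid must be non-empty")
        object.__setattr__(self, "cid", str(self.cid))
        object.__setattr__(self, "aid", str(self.aid))


@dataclass
class RegistryEntry:
    inchi: str
    inchikey: str
    smiles: str | None = None


class CompoundRegistry:
    """Compound id → structure identifiers (InChI, InChIKey, optional SMILES)."""

    def __init__(self, entries: Mapping[str, RegistryEntry] | None = None):
        self._entries: dict[str, RegistryEntry] = dict(entries or {})
        self._by_inchikey: dict[str, str] = {
            e.inchikey: cid for cid, e in self._entries.items() if e.inchikey
        }

    def add(self, cid: str, inchi: str, inchikey: str, smiles: str | None = None) -> None:
        cid = str(cid)
        if cid in self._entries:
            raise ValueError(f"duplicate cid in registry: {cid}")
        entry = RegistryEntry(inchi=inchi, inchikey=inchikey, smiles=smiles)
        self._entries[cid] = entry
        if inchikey:
            self._by_inchikey[inchikey] = cid

    def __contains__(self, cid) -> bool:
        return str(cid) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, cid) -> RegistryEntry | None:
        return self._entries.get(str(cid))

    def cid_for_inchikey(self, inchikey: str) -> str | None:
        return self._by_inchikey.get(inchikey)

    def cids(self) -> list[str]:
        return list(self._entries)

    def has_valid_inchi(self, cid) -> bool:
        """Valid = non-empty and carrying the standard ``InChI=`` prefix."""
        e = self.get(cid)
        return e is not None and bool(e.inchi) and e.inchi.startswith("InChI=")

    def structure_for(self, cid) -> str | None:
        """Preferred structure string for featurization: SMILES if present, else InChI."""
        e = self.get(cid)
        if e is None:
            return None
        return e.smiles if e.smiles else e.inchi

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cid": cid, "inchi": e.inchi, "inchikey": e.inchikey,
             "smiles": e.smiles or ""}
            for cid, e in self._entries.items()
        ]
        return pd.DataFrame(rows, columns=["cid", "inchi", "inchikey", "smiles"])


@dataclass
class AssayOutcomeCounts:
    """Per-assay tallies; actives include probes, inconclusive includes unspecified."""

    aid: str
    active: int
    inactive: int
    inconclusive: int

    @property
    def total(self) -> int:
        return self.active + self.inactive + self.inconclusive


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_rejected: int = 0
    errors: list[str] = field(default_factory=list)


class BioassayDatabase:
    """Deduplicated records (unique (cid, aid)) joined to a compound registry."""

    def __init__(self, records: Sequence[BioactivityRecord], registry: CompoundRegistry):
        for r in records:
            if r.cid not in registry:
                raise ValueError(f"record cid {r.cid} missing from registry")
        self.records: list[BioactivityRecord] = list(records)
        self.registry = registry
        self._by_cid: dict[str, list[BioactivityRecord]] = {}
        self._by_aid: dict[str, list[BioactivityRecord]] = {}
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.cid, r.aid)
            if key in seen:
                raise ValueError(f"duplicate (cid, aid) pair: {key}")
            seen.add(key)
            self._by_cid.setdefault(r.cid, []).append(r)
            self._by_aid.setdefault(r.aid, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def aids(self) -> list[str]:
        return sorted(self._by_aid)

    @property
    def cids(self) -> list[str]:
        return sorted(self._by_cid)

    def records_for_cid(self, cid) -> list[BioactivityRecord]:
        return list(self._by_cid.get(str(cid), []))

    def records_for_aid(self, aid) -> list[BioactivityRecord]:
        return list(self._by_aid.get(str(aid), []))

    def save(self, path: str | Path) -> None:
        """Persist as a directory of two plain CSVs (records + mapping)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rec = pd.DataFrame(
            [{"cid": r.cid, "aid": r.aid, "outcome": r.outcome.value} for r in self.records]
        )
        rec.to_csv(path / "bioactivities.csv", index=False)
        self.registry.to_frame().to_csv(path / "mapping.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BioassayDatabase":
        path = Path(path)
        records, _ = load_records(path / "bioactivities.csv")
        registry = load_registry(path / "mapping.csv")
        return cls(records, registry)


def load_records(source, *, strict: bool = False) -> tuple[list[BioactivityRecord], LoadReport]:
    """Read (cid, aid, outcome) rows from a CSV/TSV path or file-like stream.

    Column matching is case-insensitive. Malformed rows are counted and
    reported in the :class:`LoadReport`; with ``strict=True`` the first bad
    row raises instead.
    """
    df = _read_table(source)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("cid", "aid", "outcome") if c not in cols]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    records: list[BioactivityRecord] = []
    report = LoadReport()
    for i, vals in enumerate(df.to_dict("records")):
        try:
            rec = BioactivityRecord(
                cid=_clean(vals[cols["cid"]]),
                aid=_clean(vals[cols["aid"]]),
                outcome=Outcome.parse(vals[cols["outcome"]]),
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i}: {exc}") from exc
            report.n_rejected += 1
            report.errors.append(f"row {i}: {exc}")
            continue
        records.append(rec)
        report.n_loaded += 1
    return records, report


def load_registry(source) -> CompoundRegistry:
    """Read a (cid, inchi, inchikey[, smiles]) mapping table."""
    df = _read_table(source)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("cid", "inchi", "inchikey") if c not in cols]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    reg = CompoundRegistry()
    for vals in df.to_dict("records"):
        smiles = _clean(vals.get(cols.get("smiles", ""), "")) if "smiles" in cols else None
        reg.add(
            _clean(vals[cols["cid"]]),
            _clean(vals[cols["inchi"]]),
            _clean(vals[cols["inchikey"]]),
            smiles or None,
        )
    return reg


def registry_from_structures(structures: Mapping[str, str]) -> CompoundRegistry:
    """Build a registry from cid → SMILES, deriving InChI/InChIKey with RDKit."""
    from rdkit import Chem

    reg = CompoundRegistry()
    for cid, smiles in structures.items():
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for cid {cid}: {smiles!r}")
        reg.add(cid, Chem.MolToInchi(mol), Chem.MolToInchiKey(mol),
                Chem.MolToSmiles(mol))
    return reg


def resolve_outcome_conflicts(records: Iterable[BioactivityRecord]) -> list[BioactivityRecord]:
    """Collapse duplicate (cid, aid) pairs, keeping the most active outcome.

    Precedence: active > probe > inactive > inconclusive > unspecified.
    Idempotent and invariant under input permutation; output sorted by
    (cid, aid) for determinism.
    """
    best: dict[tuple[str, str], BioactivityRecord] = {}
    for r in records:
        key = (r.cid, r.aid)
        cur = best.get(key)
        if cur is None or r.outcome.precedence > cur.outcome.precedence:
            best[key] = r
    return [best[k] for k in sorted(best)]


def merge_with_registry(
    records: Sequence[BioactivityRecord], registry: CompoundRegistry
) -> tuple[BioassayDatabase, int]:
    """Join records to the registry, dropping compounds without a valid InChI.

    Returns the database and the number of (post-deduplication) records
    dropped because their compound was absent or carried a missing/incomplete
    InChI string.
    """
    deduped = resolve_outcome_conflicts(records)
    kept = [r for r in deduped if registry.has_valid_inchi(r.cid)]
    n_dropped = len(deduped) - len(kept)
    return BioassayDatabase(kept, registry), n_dropped


def query_by_chemicals(
    db: BioassayDatabase, keys: Sequence[str]
) -> tuple[list[BioactivityRecord], list[str]]:
    """Fetch all records for compounds named by cid or InChIKey.

    Returns (records, unmatched keys). Raises on an empty key list.
    """
    if not keys:
        raise ValueError("empty key list")
    out: list[BioactivityRecord] = []
    unmatched: list[str] = []
    for key in keys:
        key = str(key)
        cid = key if key in db.registry else db.registry.cid_for_inchikey(key)
        if cid is None:
            unmatched.append(key)
            continue
        out.extend(db.records_for_cid(cid))
    return out, unmatched


def query_by_assay(db: BioassayDatabase, aid) -> tuple[AssayOutcomeCounts, list[BioactivityRecord]]:
    """Outcome tallies and records for one assay; active includes probe."""
    aid = str(aid)
    recs = db.records_for_aid(aid)
    if not recs:
        raise KeyError(f"assay not found: {aid}")
    active = sum(1 for r in recs if r.outcome.is_active)
    inactive = sum(1 for r in recs if r.outcome is Outcome.INACTIVE)
    inconclusive = len(recs) - active - inactive
    return AssayOutcomeCounts(aid, active, inactive, inconclusive), recs


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    sep = None
    if isinstance(source, (str, Path)) and str(source).endswith((".tsv", ".tsv.gz")):
        sep = "\t"
    return pd.read_csv(source, sep=sep if sep else ",", dtype=str,
                       comment="#", keep_default_na=False, engine="python" if sep else "c")


def _clean(value) -> str:
    return str(value).strip()
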