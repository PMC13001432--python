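"""The QSAR dataset container shared by curation and modeling."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class Task(enum.Enum):
    BINARY = "binary"
    CONTINUOUS = "continuous"


@dataclass
class QSARDataset:
    """Named set of (id, smiles, activity) records for one modeling task.

    Binary activities are coded 1 = active/toxic, 0 = inactive/non-toxic.
    """

    name: str
    records: pd.DataFrame  # columns: id, smiles, activity
    task: Task

    def __post_init__(self):
        req = {"id", "smiles", "activity"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        self.records = self.records.reset_index(drop=True)
        ids = self.records["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate record ids: {list(dups)}")
        if self.task is Task.BINARY:
            vals = set(pd.unique(self.records["activity"]))
            if not vals <= {0, 1, 0.0, 1.0}:
                raise ValueError("binary activities must be 0 or 1")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        task: Task | str,
        smiles_col: str | None = None,
        activity_col: str = "activity",
        id_col: str | None = None,
        name: str | None = None,
    ) -> "QSARDataset":
        """Load from CSV with user-named columns.

        The SMILES column is auto-detected by case-insensitive exact match on
        "smiles" when not named explicitly.
        """
        df = pd.read_csv(path, comment="#")
        if smiles_col is None:
            matches = [c for c in df.columns if c.lower() == "smiles"]
            if not matches:
                raise ValueError('no column named "SMILES"; specify smiles_col')
            smiles_col = matches[0]
        for col in (smiles_col, activity_col):
            if col not in df.columns:
                raise ValueError(f"column not found: {col}")
        ids = df[id_col] if id_col and id_col in df.columns else pd.Series(
            [f"rec{i}" for i in range(len(df))]
        )
        records = pd.DataFrame(
            {"id": ids.astype(str).values,
             "smiles": df[smiles_col].astype(str).values,
             "activity": pd.to_numeric(df[activity_col]).values}
        )
        return cls(name or Path(path).stem, records,
                   Task(task) if isinstance(task, str) else task)

    def to_csv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.records.to_csv(fh, index=False)
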