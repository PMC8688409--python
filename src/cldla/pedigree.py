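"""Pedigree container shared by the simulator, the I/O layer and phasing.

A pedigree is a table of individuals with optional sire/dam links, sex,
an X-genotype class (the five classes of an X-linked null allele:
wild-type male, affected/hemizygous male, wild-type female, carrier
female, homozygous-null female) and a generation index.  Founders have
unknown parents; parent links must be acyclic and sex-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "WT_MALE",
    "AFFECTED_MALE",
    "WT_FEMALE",
    "CARRIER_FEMALE",
    "NULL_FEMALE",
    "X_CLASSES",
    "UNKNOWN",
]

UNKNOWN = "0"

WT_MALE = "wt_male"            # DMD^Y/+
AFFECTED_MALE = "affected_male"  # DMD^Y/-
WT_FEMALE = "wt_female"        # DMD^+/+
CARRIER_FEMALE = "carrier_female"  # DMD^+/-
NULL_FEMALE = "null_female"    # DMD^-/-

X_CLASSES = (WT_MALE, AFFECTED_MALE, WT_FEMALE, CARRIER_FEMALE, NULL_FEMALE)

_MALE_CLASSES = {WT_MALE, AFFECTED_MALE}
_FEMALE_CLASSES = {WT_FEMALE, CARRIER_FEMALE, NULL_FEMALE}


@dataclass
class Pedigree:
    """Table of (id, sire, dam, sex, xclass, generation) records.

    ``sire``/``dam`` use the sentinel ``"0"`` for unknown (founder)
    parents; ``sex`` is ``"M"``/``"F"``; ``xclass`` may be ``None`` when
    genotype classes have not been assigned yet.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "sex", "generation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        if "xclass" not in self.table.columns:
            self.table = self.table.assign(xclass=None)
        tab = self.table
        ids = tab["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        known = set(ids)
        gen = dict(zip(ids, tab["generation"]))
        sex = dict(zip(ids, tab["sex"]))
        for _, row in tab.iterrows():
            for parent, want_sex in ((str(row["sire"]), "M"), (str(row["dam"]), "F")):
                if parent == UNKNOWN:
                    continue
                if parent not in known:
                    raise ValueError(
                        f"parent {parent!r} of {row['id']!r} is not a pedigree record")
                if sex[parent] != want_sex:
                    raise ValueError(
                        f"parent {parent!r} of {row['id']!r} has sex {sex[parent]!r}, "
                        f"expected {want_sex!r}")
                if gen[parent] >= row["generation"]:
                    raise ValueError(
                        f"generation of parent {parent!r} must precede {row['id']!r}")
            xc = row.get("xclass")
            if xc is not None and not (isinstance(xc, float) and np.isnan(xc)):
                if xc not in X_CLASSES:
                    raise ValueError(f"unknown X-genotype class {xc!r}")
                if row["sex"] == "M" and xc not in _MALE_CLASSES:
                    raise ValueError(f"male {row['id']!r} has female class {xc!r}")
                if row["sex"] == "F" and xc not in _FEMALE_CLASSES:
                    raise ValueError(f"female {row['id']!r} has male class {xc!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.table["id"]]

    def __len__(self) -> int:
        return len(self.table)

    def row(self, ind_id: str) -> pd.Series:
        hit = self.table[self.table["id"] == ind_id]
        if hit.empty:
            raise KeyError(ind_id)
        return hit.iloc[0]

    def founders(self) -> list[str]:
        tab = self.table
        mask = (tab["sire"].astype(str) == UNKNOWN) & (tab["dam"].astype(str) == UNKNOWN)
        return [str(i) for i in tab.loc[mask, "id"]]

    def cases(self) -> list[str]:
        """Affected (hemizygous-null) males — the phenotyped individuals."""
        tab = self.table
        return [str(i) for i in tab.loc[tab["xclass"] == AFFECTED_MALE, "id"]]

    def trios(self) -> list[tuple[str, str, str]]:
        """(sire, dam, case) triples with both parents on record."""
        out = []
        for _, row in self.table.iterrows():
            if row["xclass"] != AFFECTED_MALE:
                continue
            s, d = str(row["sire"]), str(row["dam"])
            if s != UNKNOWN and d != UNKNOWN:
                out.append((s, d, str(row["id"])))
        return out

    def in_order(self) -> pd.DataFrame:
        """Records sorted so parents always precede offspring."""
        return self.table.sort_values(["generation", "id"], kind="stable")

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in X_CLASSES}
        for xc in self.table["xclass"]:
            if xc in counts:
                counts[xc] += 1
        return counts
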