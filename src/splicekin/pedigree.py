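"""Pedigree container with TSV I/O.

The TSV schema is ``animal  sire  dam  sex  family`` with ``.`` for a missing
parent; any animal with at least one missing parent is treated as a founder.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PedRecord", "Pedigree", "read_pedigree", "write_pedigree"]

PED_COLUMNS = ["animal", "sire", "dam", "sex", "family"]


@dataclass(frozen=True)
class PedRecord:
    animal: str
    sire: str | None
    dam: str | None
    sex: str  # 'M' or 'F'
    family: str

    @property
    def is_founder(self) -> bool:
        return self.sire is None or self.dam is None


class Pedigree:
    """An acyclic family graph; animals are kept in topological order."""

    def __init__(self, records):
        self.records: list[PedRecord] = list(records)
        self._by_id = {r.animal: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate animal ids in pedigree")
        for r in self.records:
            for p in (r.sire, r.dam):
                if p is not None and p not in self._by_id:
                    raise ValueError(f"parent {p!r} of {r.animal!r} not in pedigree")
        self.records = self._toposort(self.records)

    @staticmethod
    def _toposort(records) -> list[PedRecord]:
        placed: dict[str, int] = {}
        out: list[PedRecord] = []
        pending = list(records)
        while pending:
            progressed = False
            rest = []
            for r in pending:
                if all(p is None or p in placed for p in (r.sire, r.dam)):
                    placed[r.animal] = len(out)
                    out.append(r)
                    progressed = True
                else:
                    rest.append(r)
            if not progressed:
                raise ValueError("pedigree contains a cycle")
            pending = rest
        return out

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def __contains__(self, animal: str) -> bool:
        return animal in self._by_id

    def __getitem__(self, animal: str) -> PedRecord:
        return self._by_id[animal]

    @property
    def animals(self) -> list[str]:
        return [r.animal for r in self.records]

    @property
    def founders(self) -> list[str]:
        return [r.animal for r in self.records if r.is_founder]

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for r in self.records:
            fams.setdefault(r.family, []).append(r.animal)
        return fams

    def family(self, name: str) -> "Pedigree":
        return Pedigree([r for r in self.records if r.family == name])

    def children(self, animal: str) -> list[str]:
        return [r.animal for r in self.records if animal in (r.sire, r.dam)]


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [
            (r.animal, r.sire or ".", r.dam or ".", r.sex, r.family)
            for r in ped
        ],
        columns=PED_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree TSV missing columns: {sorted(missing)}")
    recs = [
        PedRecord(
            row.animal,
            None if row.sire in (".", "", None) else row.sire,
            None if row.dam in (".", "", None) else row.dam,
            row.sex,
            row.family,
        )
        for row in df.itertuples()
    ]
    return Pedigree(recs)
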