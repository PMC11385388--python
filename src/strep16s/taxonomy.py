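"""Nomenclature validation and rank-hierarchy consistency checks.

Species-level labels are validated against an LPSN-style table of names
with standing in nomenclature (valid names, synonyms and their correct
names).  Each record's full rank hierarchy is separately classified into
one of four consistency categories relative to the expected lineage of
the focal genus:

* ``consistent`` - every present rank up to genus matches the expected
  lineage, and the species binomial names the focal genus;
* ``foreign_lineage`` - a rank above genus names a different lineage
  while the species binomial still names the focal genus (e.g. a
  *Streptomyces* species filed under *Bacillus*);
* ``genus_species_conflict`` - ranks up to genus match, but the species
  binomial belongs to a different genus;
* ``ambiguous_missing`` - no usable information above species level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd


class NameStatus(str, Enum):
    VALID_CURRENT = "valid_current"
    SYNONYM = "synonym"
    UNCLASSIFIED = "unclassified"
    TYPO = "typo"
    NOT_FOUND = "not_found"


class HierarchyClass(str, Enum):
    CONSISTENT = "consistent"
    FOREIGN_LINEAGE = "foreign_lineage"
    GENUS_SPECIES_CONFLICT = "genus_species_conflict"
    AMBIGUOUS_MISSING = "ambiguous_missing"


@dataclass
class NameValidation:
    status: NameStatus
    resolved_name: str = ""


@dataclass
class NomenclatureTable:
    """LPSN-style rows of (name, status, correct_name).

    Valid rows resolve to themselves; synonym rows carry a distinct
    non-empty correct_name.
    """

    valid: dict[str, str] = field(default_factory=dict)     # name -> name
    synonyms: dict[str, str] = field(default_factory=dict)  # name -> correct name

    @classmethod
    def from_csv(cls, path: str | Path) -> "NomenclatureTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NomenclatureTable":
        table = cls()
        for row in df.itertuples(index=False):
            name = row.name.strip()
            status = row.status.strip().lower()
            correct = row.correct_name.strip()
            if status == "valid":
                table.valid[name] = name
            elif status == "synonym":
                if not correct or correct == name:
                    raise ValueError(f"synonym row {name!r} needs a distinct correct_name")
                table.synonyms[name] = correct
        return table

    def all_names(self) -> list[str]:
        return list(self.valid) + list(self.synonyms)

    def resolve(self, name: str) -> str | None:
        if name in self.valid:
            return name
        return self.synonyms.get(name)


def levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Plain edit distance with an optional early-exit cap."""
    if a == b:
        return 0
    if cap is not None and abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        best = i
        for j, cb in enumerate(b, start=1):
            cost = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            cur.append(cost)
            best = min(best, cost)
        if cap is not None and best > cap:
            return cap + 1
        prev = cur
    return prev[-1]


def _is_unclassified(name: str, focal_genus: str) -> bool:
    if not name or name.lower() == "unclassified":
        return True
    toks = name.split()
    return len(toks) >= 2 and toks[0] == focal_genus and toks[1] in ("sp.", "sp")


def validate_species_name(
    name: str,
    table: NomenclatureTable,
    max_edit_distance: int = 2,
    focal_genus: str = "Streptomyces",
) -> NameValidation:
    """Validate a species label against the nomenclature table.

    Exact valid match -> valid_current; exact synonym -> synonym resolved
    to its correct name; '<genus> sp.' or empty -> unclassified; a unique
    table name within ``max_edit_distance`` -> typo (resolved); otherwise
    not_found.  Ties between equally near typo candidates demote to
    not_found.
    """
    name = " ".join(name.split())
    if _is_unclassified(name, focal_genus):
        return NameValidation(NameStatus.UNCLASSIFIED)
    if name in table.valid:
        return NameValidation(NameStatus.VALID_CURRENT, name)
    if name in table.synonyms:
        return NameValidation(NameStatus.SYNONYM, table.synonyms[name])
    best_d = max_edit_distance + 1
    best: list[str] = []
    for cand in table.all_names():
        d = levenshtein(name, cand, cap=max_edit_distance)
        if d < best_d:
            best_d, best = d, [cand]
        elif d == best_d:
            best.append(cand)
    if best_d <= max_edit_distance and len(best) == 1:
        return NameValidation(NameStatus.TYPO, table.resolve(best[0]) or best[0])
    return NameValidation(NameStatus.NOT_FOUND)


@dataclass(frozen=True)
class ExpectedLineage:
    """Reference lineage (kingdom..genus) for the focal genus, with an
    alias map absorbing rank-name drift (e.g. Actinomycetota vs
    Actinobacteriota)."""

    ranks: tuple[str, ...] = (
        "Bacteria",
        "Actinobacteriota",
        "Actinobacteria",
        "Streptomycetales",
        "Streptomycetaceae",
        "Streptomyces",
    )
    aliases: tuple[tuple[str, str], ...] = (("Actinomycetota", "Actinobacteriota"),)

    @property
    def genus(self) -> str:
        return self.ranks[-1]

    def canonical(self, rank_name: str) -> str:
        name = " ".join(rank_name.split())
        for alias, target in self.aliases:
            if name.lower() == alias.lower():
                return target
        return name


def classify_hierarchy(taxonomy: list[str], expected: ExpectedLineage | None = None) -> HierarchyClass:
    """Classify one record's rank list against the expected lineage.

    ``taxonomy`` is ordered kingdom..species; comparison ignores case and
    surrounding whitespace, and applies the lineage's alias map.
    """
    exp = expected or ExpectedLineage()
    higher = [exp.canonical(r) for r in taxonomy[:-1]]
    species = " ".join(taxonomy[-1].split()) if taxonomy else ""
    if not any(higher):
        return HierarchyClass.AMBIGUOUS_MISSING
    mismatch = False
    for got, want in zip(higher, exp.ranks):
        if got and got.lower() != want.lower():
            mismatch = True
            break
    species_genus = species.split()[0] if species else ""
    if mismatch:
        return HierarchyClass.FOREIGN_LINEAGE
    if species_genus and species_genus.lower() != exp.genus.lower():
        return HierarchyClass.GENUS_SPECIES_CONFLICT
    return HierarchyClass.CONSISTENT


def read_names_table(path: str | Path) -> dict[str, int]:
    """Read a names.dmp-style TSV of (taxid, name) into a name -> taxid map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxid", "name"], dtype=str)
    return {row.name.strip(): int(row.taxid) for row in df.itertuples(index=False)}


def assign_taxid(name: str, names_table: dict[str, int], table: NomenclatureTable | None = None) -> int | None:
    """taxID for a (possibly synonym/typo) name after nomenclature resolution."""
    resolved = name
    if table is not None:
        resolved = table.resolve(name) or name
    return names_table.get(resolved)


def validate_records(
    records,
    table: NomenclatureTable,
    names_table: dict[str, int] | None = None,
    expected: ExpectedLineage | None = None,
    max_edit_distance: int = 2,
) -> pd.DataFrame:
    """Per-record validation table: name status, resolved name, taxid and
    hierarchy class, one row per input record."""
    exp = expected or ExpectedLineage()
    rows = []
    for rec in records:
        val = validate_species_name(rec.species, table, max_edit_distance, exp.genus)
        taxid = None
        if names_table is not None and val.resolved_name:
            taxid = names_table.get(val.resolved_name)
        rows.append(
            {
                "id": rec.id,
                "species_label": rec.species,
                "status": val.status.value,
                "resolved_name": val.resolved_name,
                "taxid": taxid,
                "hierarchy_class": classify_hierarchy(rec.taxonomy, exp).value,
            }
        )
    return pd.DataFrame(rows)
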