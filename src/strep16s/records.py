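"""Sequence records and FASTA input/output for the 16S reference databases.

A 16S reference record couples a nucleotide sequence with the taxonomy
string its source database assigned to it.  The public 16S databases use
two header layouts:

* silva / RDP / NCBI style: ``>id<space>Rank1;Rank2;...;Genus species``
  (the taxonomy travels in the FASTA description), and
* Greengenes style: bare ``>id`` headers plus a sidecar two-column TSV
  mapping id to a ``k__Bacteria; p__...; s__species`` string.

Both are normalised into :class:`SequenceRecord`, whose ``taxonomy`` is an
ordered kingdom-to-species list of plain rank names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

SOURCE_DBS = ("silva", "greengenes", "rdp", "ncbi", "synthetic")

#: Greengenes rank prefixes in kingdom-to-species order.
_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class SequenceRecord:
    """One 16S sequence with provenance and its database taxonomy string.

    ``taxonomy`` is ordered kingdom -> species; entries may be empty
    strings when the source database left a rank blank.
    """

    id: str
    seq: str
    source_db: str = "synthetic"
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def species(self) -> str:
        """Species-level label (last taxonomy rank), or '' if absent."""
        return self.taxonomy[-1].strip() if self.taxonomy else ""


def _parse_semicolon_taxonomy(description: str) -> list[str]:
    return [rank.strip() for rank in description.split(";")] if description else []


def read_fasta(
    path: str | Path,
    dialect: str = "silva",
    taxonomy_tsv: str | Path | None = None,
    source_db: str | None = None,
) -> list[SequenceRecord]:
    """Read a 16S FASTA in one of the supported header dialects.

    ``silva``, ``rdp`` and ``ncbi`` all carry a ``;``-separated lineage in
    the description (RDP's leading ``Root;`` is stripped).  ``gg`` takes
    bare ids plus ``taxonomy_tsv`` with Greengenes ``k__...`` strings.
    """
    if dialect not in ("silva", "gg", "rdp", "ncbi"):
        raise ValueError(f"unknown dialect {dialect!r}")
    db = source_db or {"gg": "greengenes"}.get(dialect, dialect)

    gg_taxonomy: dict[str, list[str]] = {}
    if dialect == "gg":
        if taxonomy_tsv is None:
            raise ValueError("Greengenes dialect requires taxonomy_tsv")
        for line in Path(taxonomy_tsv).read_text().splitlines():
            if not line.strip():
                continue
            rec_id, _, tax = line.partition("\t")
            ranks = []
            for chunk in tax.split(";"):
                chunk = chunk.strip()
                for pref in _GG_PREFIXES:
                    if chunk.startswith(pref):
                        chunk = chunk[len(pref):]
                        break
                ranks.append(chunk.strip())
            gg_taxonomy[rec_id.strip()] = ranks

    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if dialect == "gg":
            taxonomy = list(gg_taxonomy.get(rec.id, []))
        else:
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            if dialect == "rdp" and desc.startswith("Root;"):
                desc = desc[len("Root;"):]
            taxonomy = _parse_semicolon_taxonomy(desc)
        out.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), source_db=db, taxonomy=taxonomy))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records silva-style (taxonomy joined by ';' in the description)."""
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id, description=";".join(r.taxonomy))
        for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def iter_unique_ids(records: Iterable[SequenceRecord]) -> Iterator[str]:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
        yield r.id
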