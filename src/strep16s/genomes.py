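"""Extraction and profiling of 16S rRNA loci from annotated genomes.

A genome assembly contributes to the congruence analysis only if every
16S copy it carries is full length and free of ambiguity symbols -
partial or ambiguous copies would inflate apparent intragenomic
diversity.  Copies are compared as exact strings (after base
standardisation); no alignment-based collapsing happens here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
import warnings

import pandas as pd
from Bio import SeqIO

from .sequence_qc import count_ambiguities, standardize_bases


class GenomeQcStatus(str, Enum):
    RETAINED = "retained"
    NO_16S = "no_16s"
    HAS_PARTIAL_OR_AMBIGUOUS = "has_partial_or_ambiguous"


@dataclass
class GenomeProfile:
    """A genome's extracted 16S copies, as a multiset of variant strings."""

    accession: str
    species_label: str = ""
    copies: list[str] = field(default_factory=list)   # genomic order
    qc_status: GenomeQcStatus | None = None

    @property
    def n_16s_copies(self) -> int:
        return len(self.copies)

    @property
    def variants(self) -> Counter:
        return Counter(self.copies)

    @property
    def variant_set(self) -> frozenset:
        return frozenset(self.copies)

    @property
    def n_distinct_variants(self) -> int:
        return len(set(self.copies))


_FEATURE_TYPES = ("rRNA", "gene", "misc_RNA", "misc_feature")


def extract_16s(genome_record) -> list[str]:
    """16S sequences from one GenBank record, in genomic order.

    Every rRNA/gene feature whose qualifier values mention '16S'
    (case-insensitively, in gene/product/note/any qualifier) is
    extracted; minus-strand features are reverse complemented.
    """
    if not genome_record.features:
        warnings.warn(f"record {genome_record.id} has no feature table")
        return []
    out: list[str] = []
    for feature in genome_record.features:
        if feature.type not in _FEATURE_TYPES:
            continue
        values = (v for vals in feature.qualifiers.values() for v in vals)
        if any("16s" in v.lower() for v in values):
            out.append(standardize_bases(str(feature.extract(genome_record.seq))))
    return out


def read_genome_profile(path: str | Path, species_label: str | None = None) -> GenomeProfile:
    """Profile one assembly from a (possibly multi-record) GenBank file.

    Copies are aggregated per assembly, i.e. per file; the accession is
    the first record's id and the species label defaults to the record's
    organism annotation.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    accession = records[0].id
    label = species_label or records[0].annotations.get("organism", "")
    copies: list[str] = []
    for rec in records:
        copies.extend(extract_16s(rec))
    return GenomeProfile(accession=accession, species_label=label, copies=copies)


def read_genome_profiles(
    paths,
    species_map: dict[str, str] | None = None,
) -> list[GenomeProfile]:
    profiles = []
    for path in paths:
        prof = read_genome_profile(path)
        if species_map and prof.accession in species_map:
            prof.species_label = species_map[prof.accession]
        profiles.append(prof)
    return profiles


def apply_genome_filter(
    profiles: list[GenomeProfile], min_length: int = 1200
) -> list[GenomeProfile]:
    """Assign qc_status to every profile and return the retained subset.

    A genome is retained only when it has at least one copy and *every*
    copy is >= ``min_length`` bp with zero ambiguity symbols.
    """
    retained = []
    for prof in profiles:
        if prof.n_16s_copies == 0:
            prof.qc_status = GenomeQcStatus.NO_16S
        elif any(
            len(c) < min_length or count_ambiguities(c) > 0 for c in prof.copies
        ):
            prof.qc_status = GenomeQcStatus.HAS_PARTIAL_OR_AMBIGUOUS
        else:
            prof.qc_status = GenomeQcStatus.RETAINED
            retained.append(prof)
    return retained


def copy_number_stats(profiles: list[GenomeProfile]) -> tuple[pd.DataFrame, dict]:
    """Copy-number and intragenomic-heterogeneity summary for retained genomes."""
    per_genome = pd.DataFrame(
        {
            "accession": [p.accession for p in profiles],
            "species_label": [p.species_label for p in profiles],
            "n_copies": [p.n_16s_copies for p in profiles],
            "n_distinct_variants": [p.n_distinct_variants for p in profiles],
        }
    )
    summary = {
        "n_genomes": len(profiles),
        "copy_number_histogram": dict(Counter(per_genome["n_copies"])) if len(per_genome) else {},
        "variant_count_histogram": dict(Counter(per_genome["n_distinct_variants"])) if len(per_genome) else {},
        "n_below_six": int((per_genome["n_copies"] < 6).sum()) if len(per_genome) else 0,
        "n_exactly_six": int((per_genome["n_copies"] == 6).sum()) if len(per_genome) else 0,
        "n_above_six": int((per_genome["n_copies"] > 6).sum()) if len(per_genome) else 0,
        "n_heterogeneous": int((per_genome["n_distinct_variants"] >= 2).sum()) if len(per_genome) else 0,
    }
    return per_genome, summary
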