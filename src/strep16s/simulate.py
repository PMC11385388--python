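"""Synthetic cohort generator with known ground truth.

Generates, from a single seed, everything the analysis consumes — a
hierarchy of genomes (genera -> species -> assemblies) written as
annotated GenBank records, a 16S reference database FASTA with realistic
label and sequence noise, an LPSN-style nomenclature table and a
names->taxID table — together with ground-truth tables sufficient to
verify every pipeline stage.

Genome model
------------
Whole-genome similarity is controlled by block architecture, because
substitutions alone cannot move alignment *coverage*: every genome is

    [A | B | C | D | 16S cassette]

where A is shared across all genera, B across one genus, C across one
species and D is genome-private random sequence.  Block sizes are solved
from the target coverages, and per-branch substitution rates from the
target ANI identities (accounting for the near-identical 16S cassette
that is always shared).  The cassette holds the genome's 16S loci
(random spacers between them, some loci on the minus strand), seeded
from one master 1540 bp sequence and diversified along the same
hierarchy, so 16S similarity correlates with — but can be made to
contradict — genome relatedness.

Planted contradictions: a species pair may share one byte-identical 16S
variant (cross-species, optionally cross-genus, sharing), and one
species can be arranged as a non-clique (its genomes connected through
overlapping variant sets without all pairs sharing a variant).

Database noise: truncations, exact duplicates, two-parent chimeras,
negative-binomially distributed ambiguity symbols, and label noise
(synonyms, typos, unclassified, foreign lineages, genus/species
conflicts, names missing from the table).  Chimera parents are drawn
from deep 16S lineages kept mutually diverged (default >= 12%), since a
breakpoint test — like any de novo chimera detector — cannot detect
chimeras of near-identical parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio import SeqIO

from .ani import AniRelation, reverse_complement
from .records import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMBIG = "RYSWKMN"
_16S_LENGTH = 1540
_SPACER_LENGTH = 100

_SYLLABLES = [
    "al", "bu", "ca", "do", "er", "fu", "ga", "hi", "ja", "ko", "li", "mo",
    "ne", "or", "pa", "qui", "ru", "sa", "ti", "ul", "ve", "wa", "xe", "yo", "za",
]

_FOREIGN_LINEAGE = ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus")
_EXPECTED_LINEAGE = (
    "Bacteria", "Actinobacteriota", "Actinobacteria",
    "Streptomycetales", "Streptomycetaceae", "Streptomyces",
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    # cohort shape
    n_genera: int = 4
    species_per_genus: int = 3
    genomes_per_species: int = 4
    genome_length: int = 100_000          # backbone (excluding 16S cassette)
    # ANI targets (percent), enforced by the block/rate solver
    within_species_ani: float = 98.0
    between_species_within_genus_ani: float = 88.0
    between_genus_ani: float = 80.0
    within_species_coverage: float = 93.0
    within_genus_coverage: float = 72.0
    between_genus_coverage: float = 35.0
    # 16S copy structure
    copy_number_distribution: tuple[tuple[int, float], ...] = (
        (1, 0.20), (2, 0.10), (3, 0.10), (4, 0.12), (5, 0.11),
        (6, 0.26), (7, 0.07), (8, 0.03), (10, 0.008), (12, 0.002),
    )
    p_intragenomic_variant: float = 0.27
    p_cross_species_shared_variant: float = 0.5
    n_cross_genus_shared_pairs: int = 0
    plant_non_clique: bool = True
    genus_16s_subs: int = 12
    species_16s_subs: int = 6
    # genome-level QC noise
    p_genome_no_16s: float = 0.04
    p_genome_partial: float = 0.15
    # 16S database emulation
    n_db_records: int = 800
    db_strain_subs_lambda: float = 1.0
    n_deep_lineages: int = 10
    deep_lineage_divergence: float = 0.10
    p_truncated: float = 0.12
    p_redundant: float = 0.30
    p_chimera: float = 0.05
    chimera_min_parent_divergence: float = 0.12
    chimera_breakpoint_range: tuple[float, float] = (0.3, 0.7)
    # most records carry no ambiguity symbols; the NB tail is heavy, so a
    # few records carry very many (the pathology an upper-quantile cutoff
    # is there to catch)
    ambiguity_nb_r: float = 0.05
    ambiguity_nb_p: float = 0.02
    # label noise (mutually exclusive classes; remainder is clean/valid)
    p_label_synonym: float = 0.03
    p_label_typo: float = 0.01
    p_label_unclassified: float = 0.45
    p_label_not_found: float = 0.02
    p_label_foreign_lineage: float = 0.02
    p_label_genus_conflict: float = 0.01

    def __post_init__(self) -> None:
        probs = [
            self.p_intragenomic_variant, self.p_cross_species_shared_variant,
            self.p_genome_no_16s, self.p_genome_partial, self.p_truncated,
            self.p_redundant, self.p_chimera, self.p_label_synonym,
            self.p_label_typo, self.p_label_unclassified, self.p_label_not_found,
            self.p_label_foreign_lineage, self.p_label_genus_conflict,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (
            self.within_species_ani > self.between_species_within_genus_ani > self.between_genus_ani
        ):
            raise ValueError("ANI targets must be ordered within-species > between-species > between-genus")
        dist = dict(self.copy_number_distribution)
        if not dist or abs(sum(dist.values()) - 1.0) > 1e-6:
            raise ValueError("copy_number_distribution must sum to 1")
        if any(k < 1 for k in dist):
            raise ValueError("copy numbers must be >= 1")


# --------------------------------------------------------------------------
# low-level sequence utilities

def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_to_identity(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute positions independently so expected identity ~= target.

    Substitutions only (each hit position becomes one of the three other
    bases); expected identity to the input is exactly ``target``.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0, 1]")
    if target_identity == 1.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < 1.0 - target_identity)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def substitute_positions(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly ``n_subs`` substitutions at distinct random positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(arr.size, size=min(n_subs, arr.size), replace=False)
    shift = rng.integers(1, 4, size=pos.size)
    idx = np.searchsorted(_BASES, arr[pos])
    arr[pos] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def make_chimera(parent_a: str, parent_b: str, breakpoint_fraction: float) -> str:
    """Prefix of ``parent_a`` up to the breakpoint column, suffix of
    ``parent_b`` after it (parents must be alignment-comparable, here
    equal length)."""
    if not 0.0 < breakpoint_fraction < 1.0:
        raise ValueError("breakpoint_fraction must be in (0, 1)")
    if len(parent_a) != len(parent_b):
        raise ValueError("chimera parents must have equal length")
    b = int(round(breakpoint_fraction * len(parent_a)))
    b = min(max(b, 1), len(parent_a) - 1)
    return parent_a[:b] + parent_b[b:]


def _hamming_div(a: str, b: str) -> float:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((xa != xb).mean())


# --------------------------------------------------------------------------
# naming

def _make_epithets(
    rng: np.random.Generator, n: int, min_distance: int = 5, avoid: list[str] | None = None
) -> list[str]:
    """Pseudo-Latin epithets kept pairwise Levenshtein > min_distance from
    each other and from ``avoid``, so single-edit typos always resolve to a
    unique nearest name."""
    from .taxonomy import levenshtein

    out: list[str] = []
    taken = list(avoid or [])
    while len(out) < n:
        k = rng.integers(3, 5)
        word = "".join(_SYLLABLES[i] for i in rng.integers(0, len(_SYLLABLES), size=k)) + "us"
        if any(levenshtein(word, w, cap=min_distance) <= min_distance for w in taken):
            continue
        out.append(word)
        taken.append(word)
    return out


# --------------------------------------------------------------------------
# ground truth containers

@dataclass
class PlantedGenome:
    accession: str
    genus_idx: int
    species_name: str
    fate: str                        # retained | no_16s | has_partial_or_ambiguous
    copy_variant_keys: list[str]     # one key per copy, genomic order
    seq: str = ""
    features: list = field(default_factory=list)


@dataclass
class GroundTruth:
    genomes: pd.DataFrame            # accession, genus_idx, species_name, fate, n_copies, n_variants
    variant_incidence: pd.DataFrame  # variant_key, accession (retained genomes only)
    components: list[frozenset]      # partition of retained accessions
    component_cliques: dict[frozenset, bool]
    component_classes: dict[frozenset, str]
    db_records: pd.DataFrame         # id, species_name, fate, label_class, ambiguity_count
    rates: dict

    def relation(self, acc_a: str, acc_b: str) -> AniRelation:
        row = self.genomes.set_index("accession")
        a, b = row.loc[acc_a], row.loc[acc_b]
        if a.species_name == b.species_name:
            return AniRelation.SAME_SPECIES
        if a.genus_idx == b.genus_idx:
            return AniRelation.SAME_GENUS_DIFF_SPECIES
        return AniRelation.DIFF_GENUS


@dataclass
class Cohort:
    config: SimConfig
    genomes: list[PlantedGenome]
    variant_seqs: dict[str, str]             # variant_key -> sequence
    db_records: list[SequenceRecord]
    lpsn: pd.DataFrame
    names: pd.DataFrame                      # taxid, name
    truth: GroundTruth

    def genome_seqs(self, retained_only: bool = True) -> dict[str, str]:
        return {
            g.accession: g.seq
            for g in self.genomes
            if not retained_only or g.fate == "retained"
        }

    def to_genbank_records(self) -> list[BioSeqRecord]:
        out = []
        for g in self.genomes:
            rec = BioSeqRecord(
                Seq(g.seq),
                id=g.accession,
                name=g.accession.replace(".", "_")[:16],
                description=f"{g.species_name} genome assembly (synthetic)",
                features=list(g.features),
            )
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["organism"] = g.species_name
            rec.annotations["topology"] = "linear"
            out.append(rec)
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        genome_dir = outdir / "genomes"
        truth_dir = outdir / "truth"
        genome_dir.mkdir(parents=True, exist_ok=True)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for rec, g in zip(self.to_genbank_records(), self.genomes):
            SeqIO.write([rec], str(genome_dir / f"{g.accession}.gbk"), "genbank")
        from .records import write_fasta

        write_fasta(self.db_records, outdir / "db_16s.fasta")
        self.lpsn.to_csv(outdir / "lpsn.csv", index=False)
        self.names.to_csv(outdir / "names.tsv", sep="\t", header=False, index=False)
        self.truth.genomes.to_csv(truth_dir / "genomes.csv", index=False)
        self.truth.variant_incidence.to_csv(truth_dir / "variant_incidence.csv", index=False)
        self.truth.db_records.to_csv(truth_dir / "db_records.csv", index=False)
        comp_rows = [
            {"component": i, "accession": acc}
            for i, comp in enumerate(self.truth.components)
            for acc in sorted(comp)
        ]
        pd.DataFrame(comp_rows).to_csv(truth_dir / "components.csv", index=False)


# --------------------------------------------------------------------------
# solvers

def _solve_blocks(cfg: SimConfig) -> dict:
    """Block lengths and branch substitution rates from the ANI targets.

    Coverage targets are satisfied by block sizing (the always-shared 16S
    cassette, at its expected size, counts towards every coverage);
    identity targets by per-branch substitution rates, correcting for the
    near-identical cassette that pulls aligned identity upwards.
    """
    copy_dist = dict(cfg.copy_number_distribution)
    n_nominal = sum(k * p for k, p in copy_dist.items())
    cass = n_nominal * _16S_LENGTH
    spacers = n_nominal * _SPACER_LENGTH
    total = cfg.genome_length + cass + spacers

    a_len = int(cfg.between_genus_coverage / 100.0 * total - cass)
    b_len = int((cfg.within_genus_coverage - cfg.between_genus_coverage) / 100.0 * total)
    c_len = int((cfg.within_species_coverage - cfg.within_genus_coverage) / 100.0 * total)
    d_len = cfg.genome_length - a_len - b_len - c_len
    if min(a_len, b_len, c_len, d_len) <= 0:
        raise ValueError("coverage targets are infeasible for this genome length")

    # cassette identities at each level of the hierarchy
    c_ws = 1.0 - 2.0 / _16S_LENGTH                      # intragenomic variants differ by ~2 subs
    c_bs = 1.0 - 2.0 * cfg.species_16s_subs / _16S_LENGTH
    c_bg = c_bs * (1.0 - 2.0 * cfg.genus_16s_subs / _16S_LENGTH)

    shared_ws = a_len + b_len + c_len
    x_g = (cfg.within_species_ani / 100.0 * (shared_ws + cass) - cass * c_ws) / shared_ws
    shared_bs = a_len + b_len
    y_s = (cfg.between_species_within_genus_ani / 100.0 * (shared_bs + cass) - cass * c_bs) / shared_bs
    y_g = (cfg.between_genus_ani / 100.0 * (a_len + cass) - cass * c_bg) / a_len
    if not 0.0 < y_g < y_s < x_g <= 1.0:
        raise ValueError("identity targets are infeasible after cassette correction")
    return {
        "a_len": a_len, "b_len": b_len, "c_len": c_len, "d_len": d_len,
        "rate_genome": 1.0 - np.sqrt(x_g),
        "rate_species": 1.0 - np.sqrt(y_s / x_g),
        "rate_genus": 1.0 - np.sqrt(y_g / y_s),
    }


# --------------------------------------------------------------------------
# cohort generation

def _draw_copy_number(rng: np.random.Generator, copy_dist: dict[int, float], minimum: int = 1) -> int:
    ks = sorted(copy_dist)
    ps = np.array([copy_dist[k] for k in ks])
    ps = ps / ps.sum()
    while True:
        n = int(rng.choice(ks, p=ps))
        if n >= minimum:
            return n


def _plant_16s_variants(cfg: SimConfig, rng: np.random.Generator):
    """Variant sequences per species plus the sharing/non-clique plan."""
    master = random_dna(rng, _16S_LENGTH)
    variant_seqs: dict[str, str] = {}
    species_core: dict[tuple[int, int], str] = {}
    for g in range(cfg.n_genera):
        genus_seq = substitute_positions(master, cfg.genus_16s_subs, rng)
        for s in range(cfg.species_per_genus):
            key = f"v_g{g}s{s}_core"
            species_core[(g, s)] = key
            variant_seqs[key] = substitute_positions(genus_seq, cfg.species_16s_subs, rng)

    # cross-species sharing within each genus: adjacent species pairs
    shared_pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for g in range(cfg.n_genera):
        for s in range(cfg.species_per_genus - 1):
            forced = g == 0 and s == 0 and cfg.p_cross_species_shared_variant > 0
            if forced or rng.random() < cfg.p_cross_species_shared_variant:
                shared_pairs.append(((g, s), (g, s + 1)))
    # optional cross-genus sharing (first species of consecutive genera)
    for i in range(min(cfg.n_cross_genus_shared_pairs, cfg.n_genera - 1)):
        shared_pairs.append(((i, 0), (i + 1, 0)))

    non_clique_species = None
    if cfg.plant_non_clique and cfg.genomes_per_species >= 3:
        shared_sp = {sp for pair in shared_pairs for sp in pair}
        candidates = [
            (g, s)
            for g in range(cfg.n_genera)
            for s in range(cfg.species_per_genus)
            if (g, s) not in shared_sp
        ]
        if candidates:
            non_clique_species = candidates[-1]
            g, s = non_clique_species
            alt_key = f"v_g{g}s{s}_alt"
            variant_seqs[alt_key] = substitute_positions(
                variant_seqs[species_core[(g, s)]], 2, rng
            )
    return variant_seqs, species_core, shared_pairs, non_clique_species


def _genome_variant_plan(
    cfg: SimConfig,
    rng: np.random.Generator,
    genus: int,
    sp: int,
    idx: int,
    species_core: dict,
    shared_with: list[str],
    non_clique_role: str | None,
    variant_seqs: dict[str, str],
) -> tuple[list[str], int]:
    """Variant keys for one genome plus its drawn copy number."""
    core = species_core[(genus, sp)]
    copy_dist = dict(cfg.copy_number_distribution)
    if non_clique_role is not None:
        alt = f"v_g{genus}s{sp}_alt"
        if non_clique_role == "left":
            base = [core]
        elif non_clique_role == "bridge":
            base = [core, alt]
        else:
            base = [alt]
    else:
        base = [core]
        for key in shared_with:
            base.append(key)
    n = _draw_copy_number(rng, copy_dist, minimum=max(1, len(base)))
    variants = list(base)
    if (
        non_clique_role is None
        and n > len(variants)
        and rng.random() < cfg.p_intragenomic_variant
    ):
        vkey = f"v_g{genus}s{sp}_intra{idx}"
        variant_seqs[vkey] = substitute_positions(variant_seqs[core], int(rng.integers(1, 3)), rng)
        variants.append(vkey)
    copies = list(variants)
    for _ in range(n - len(copies)):
        copies.append(core if non_clique_role is None else base[0])
    rng.shuffle(copies)
    return copies, n


def _assemble_genome(
    cfg: SimConfig,
    rng: np.random.Generator,
    blocks: dict[str, str],
    copy_keys: list[str],
    variant_seqs: dict[str, str],
    fate: str,
) -> tuple[str, list[SeqFeature]]:
    """Backbone + 16S cassette with rRNA features (genomic coordinates)."""
    parts = [blocks["A"], blocks["B"], blocks["C"], blocks["D"]]
    pos = sum(len(p) for p in parts)
    features: list[SeqFeature] = []
    qualifier_styles = (
        {"product": ["16S ribosomal RNA"]},
        {"gene": ["rrs"], "product": ["16S ribosomal RNA"]},
        {"note": ["16S rRNA gene, ribosomal RNA"]},
    )
    for i, key in enumerate(copy_keys):
        spacer = random_dna(rng, _SPACER_LENGTH)
        parts.append(spacer)
        pos += len(spacer)
        locus = variant_seqs[key]
        if fate == "has_partial_or_ambiguous" and i == 0:
            if rng.random() < 0.5:
                # ambiguity symbols inside the locus
                mid = len(locus) // 2
                locus = locus[:mid] + "NNN" + locus[mid + 3:]
                span = len(locus)
            else:
                span = 800  # feature annotates a partial copy
        else:
            span = len(locus)
        strand = -1 if rng.random() < 0.3 else 1
        genomic = locus if strand == 1 else reverse_complement(locus)
        parts.append(genomic)
        if fate != "no_16s":
            quals = dict(qualifier_styles[i % len(qualifier_styles)])
            quals["locus_tag"] = [f"rrn{i}"]
            if strand == 1:
                loc = FeatureLocation(pos, pos + span, strand=1)
            else:
                loc = FeatureLocation(pos + len(genomic) - span, pos + len(genomic), strand=-1)
            features.append(SeqFeature(loc, type="rRNA", qualifiers=quals))
        pos += len(genomic)
    # decoy feature that must not be extracted
    features.append(
        SeqFeature(
            FeatureLocation(0, min(2900, len(blocks["A"])), strand=1),
            type="rRNA",
            qualifiers={"product": ["23S ribosomal RNA"]},
        )
    )
    return "".join(parts), features


def _component_truth(genomes: list[PlantedGenome]) -> tuple[list[frozenset], dict, dict]:
    """Partition / clique flags / ANI classes from planted variant sets
    (union-find over retained genomes; no graph library involved)."""
    retained = [g for g in genomes if g.fate == "retained"]
    vsets = {g.accession: frozenset(g.copy_variant_keys) for g in retained}
    parent = {g.accession: g.accession for g in retained}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accs = sorted(vsets)
    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            if vsets[a] & vsets[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[str, set] = {}
    for a in accs:
        comps.setdefault(find(a), set()).add(a)
    components = sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), min(c)))

    meta = {g.accession: (g.genus_idx, g.species_name) for g in retained}
    cliques: dict[frozenset, bool] = {}
    classes: dict[frozenset, str] = {}
    for comp in components:
        members = sorted(comp)
        cliques[comp] = all(
            bool(vsets[a] & vsets[b])
            for i, a in enumerate(members)
            for b in members[i + 1:]
        )
        genera = {meta[m][0] for m in members}
        species = {meta[m][1] for m in members}
        if len(genera) > 1:
            classes[comp] = "multi_genus"
        elif len(species) > 1:
            classes[comp] = "multi_species_single_genus"
        else:
            classes[comp] = "single_species"
    return components, cliques, classes


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Build the full synthetic world (deterministic in config.seed)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    solved = _solve_blocks(cfg)

    # ---- 16S variants and sharing plan
    variant_seqs, species_core, shared_pairs, non_clique_species = _plant_16s_variants(cfg, rng)

    # ---- names
    n_species = cfg.n_genera * cfg.species_per_genus
    epithets = _make_epithets(rng, n_species + cfg.n_deep_lineages)
    species_names: dict[tuple[int, int], str] = {}
    for g in range(cfg.n_genera):
        for s in range(cfg.species_per_genus):
            species_names[(g, s)] = f"Streptomyces {epithets[g * cfg.species_per_genus + s]}"
    deep_names = [f"Streptomyces {e}" for e in epithets[n_species:]]

    # ---- backbone masters
    a_master = random_dna(rng, solved["a_len"])
    blocks_by_species: dict[tuple[int, int], dict[str, str]] = {}
    for g in range(cfg.n_genera):
        a_genus = mutate_to_identity(a_master, 1.0 - solved["rate_genus"], rng)
        b_genus = random_dna(rng, solved["b_len"])
        for s in range(cfg.species_per_genus):
            blocks_by_species[(g, s)] = {
                "A": mutate_to_identity(a_genus, 1.0 - solved["rate_species"], rng),
                "B": mutate_to_identity(b_genus, 1.0 - solved["rate_species"], rng),
                "C": random_dna(rng, solved["c_len"]),
            }

    # ---- genomes
    shared_by_species: dict[tuple[int, int], list[str]] = {}
    for left, right in shared_pairs:
        key = species_core[left]
        shared_by_species.setdefault(right, []).append(key)
    protected = {sp for pair in shared_pairs[:1] for sp in pair}
    if non_clique_species is not None:
        protected.add(non_clique_species)

    genomes: list[PlantedGenome] = []
    for g in range(cfg.n_genera):
        for s in range(cfg.species_per_genus):
            for i in range(cfg.genomes_per_species):
                accession = f"GCS_{g:02d}{s:02d}{i:02d}"
                u = rng.random()
                if (g, s) in protected:
                    fate = "retained"
                elif u < cfg.p_genome_no_16s:
                    fate = "no_16s"
                elif u < cfg.p_genome_no_16s + cfg.p_genome_partial:
                    fate = "has_partial_or_ambiguous"
                else:
                    fate = "retained"
                role = None
                if non_clique_species == (g, s):
                    role = ("left", "bridge", "right", "right")[min(i, 3)]
                copy_keys, _ = _genome_variant_plan(
                    cfg, rng, g, s, i, species_core,
                    shared_by_species.get((g, s), []), role, variant_seqs,
                )
                sp_blocks = blocks_by_species[(g, s)]
                own_blocks = {
                    "A": mutate_to_identity(sp_blocks["A"], 1.0 - solved["rate_genome"], rng),
                    "B": mutate_to_identity(sp_blocks["B"], 1.0 - solved["rate_genome"], rng),
                    "C": mutate_to_identity(sp_blocks["C"], 1.0 - solved["rate_genome"], rng),
                    "D": random_dna(rng, solved["d_len"]),
                }
                seq, feats = _assemble_genome(cfg, rng, own_blocks, copy_keys, variant_seqs, fate)
                genomes.append(
                    PlantedGenome(
                        accession=accession,
                        genus_idx=g,
                        species_name=species_names[(g, s)],
                        fate=fate,
                        copy_variant_keys=copy_keys,
                        seq=seq,
                        features=feats,
                    )
                )

    components, cliques, classes = _component_truth(genomes)

    # ---- nomenclature tables
    lpsn_rows = []
    synonym_of: dict[str, str] = {}
    all_valid = sorted(set(species_names.values()) | set(deep_names))
    # every valid name gets one historical synonym (so synonym-label noise
    # is injected at exactly its configured rate); synonym epithets stay
    # well-separated from the valid ones so typos always resolve uniquely
    syn_epithets = _make_epithets(rng, len(all_valid), avoid=epithets)
    for i, name in enumerate(all_valid):
        lpsn_rows.append({"name": name, "status": "valid", "correct_name": name})
        syn = f"Streptomyces {syn_epithets[i]}"
        lpsn_rows.append({"name": syn, "status": "synonym", "correct_name": name})
        synonym_of[name] = syn
    lpsn = pd.DataFrame(lpsn_rows, columns=["name", "status", "correct_name"])
    names = pd.DataFrame(
        {"taxid": [1000 + i for i in range(len(all_valid))], "name": all_valid}
    )

    # ---- 16S database records: each species' pool includes any variant
    # it adopted from a sharing partner, so distinct species can emit
    # byte-identical database sequences (the multi-species zOTU mechanism)
    species_pools = {
        sp: [species_core[sp]] + shared_by_species.get(sp, [])
        for sp in species_core
    }
    db_records, db_truth_rows = _generate_db(
        cfg, rng, species_names, species_pools, variant_seqs, deep_names, synonym_of, lpsn
    )

    truth = GroundTruth(
        genomes=pd.DataFrame(
            [
                {
                    "accession": g.accession,
                    "genus_idx": g.genus_idx,
                    "species_name": g.species_name,
                    "fate": g.fate,
                    "n_copies": len(g.copy_variant_keys),
                    "n_variants": len(set(g.copy_variant_keys)),
                }
                for g in genomes
            ]
        ),
        variant_incidence=pd.DataFrame(
            [
                {"variant_key": k, "accession": g.accession}
                for g in genomes
                if g.fate == "retained"
                for k in sorted(set(g.copy_variant_keys))
            ]
        ),
        components=components,
        component_cliques=cliques,
        component_classes=classes,
        db_records=pd.DataFrame(db_truth_rows),
        rates={
            "p_label_synonym": cfg.p_label_synonym,
            "p_label_typo": cfg.p_label_typo,
            "p_label_unclassified": cfg.p_label_unclassified,
            "p_label_not_found": cfg.p_label_not_found,
            "p_label_foreign_lineage": cfg.p_label_foreign_lineage,
            "p_label_genus_conflict": cfg.p_label_genus_conflict,
            "p_truncated": cfg.p_truncated,
            "p_redundant": cfg.p_redundant,
            "p_chimera": cfg.p_chimera,
        },
    )
    return Cohort(
        config=cfg,
        genomes=genomes,
        variant_seqs=variant_seqs,
        db_records=db_records,
        lpsn=lpsn,
        names=names,
        truth=truth,
    )


def make_chimera_benchmark(
    n_clean: int = 800,
    n_chimeras: int = 200,
    seed: int = 0,
    n_lineages: int = 60,
    lineage_divergence: float = 0.15,
    min_parent_divergence: float = 0.12,
    breakpoint_range: tuple[float, float] = (0.3, 0.7),
    seq_length: int = _16S_LENGTH,
):
    """Benchmark fixture for the chimera detector.

    Clean records come from ``n_lineages`` mutually diverged lineages
    (pairwise divergence well above ``min_parent_divergence``; close
    within-lineage strain variants of 1-3 substitutions are included).
    Chimeras join two distinct lineage representatives at a breakpoint
    drawn from ``breakpoint_range``.  Detectability note: with breakpoint
    fraction f and parent divergence d, the best single parent matches a
    chimera at 1 - d*min(f, 1-f), so parents must satisfy
    d >= (1 - id_one)/min(f, 1-f) for the default two-parent test to see
    them — the reason the lineage divergence here is far above the
    detector's id_one margin.

    Returns (records, abundances, truth) where truth maps record id ->
    'clean' | 'chimeric'.
    """
    rng = np.random.default_rng(seed)
    master = random_dna(rng, seq_length)
    lineages: list[str] = []
    while len(lineages) < n_lineages:
        cand = mutate_to_identity(master, 1.0 - lineage_divergence, rng)
        if all(_hamming_div(cand, other) >= min_parent_divergence for other in lineages):
            lineages.append(cand)

    records: list[SequenceRecord] = []
    abundances: dict[str, int] = {}
    truth: dict[str, str] = {}
    seen: set[str] = set(lineages)
    for i, seq in enumerate(lineages):
        rid = f"LIN{i:04d}"
        records.append(SequenceRecord(id=rid, seq=seq))
        abundances[rid] = 5
        truth[rid] = "clean"
    for j in range(n_clean - n_lineages):
        li = int(rng.integers(0, n_lineages))
        while True:
            var = substitute_positions(lineages[li], int(rng.integers(1, 4)), rng)
            if var not in seen:
                break
        seen.add(var)
        rid = f"VAR{j:04d}"
        records.append(SequenceRecord(id=rid, seq=var))
        abundances[rid] = 2
        truth[rid] = "clean"
    for j in range(n_chimeras):
        while True:
            ia, ib = rng.choice(n_lineages, size=2, replace=False)
            f = float(rng.uniform(*breakpoint_range))
            seq = make_chimera(lineages[int(ia)], lineages[int(ib)], f)
            if seq not in seen:
                break
        seen.add(seq)
        rid = f"CHI{j:04d}"
        records.append(SequenceRecord(id=rid, seq=seq))
        abundances[rid] = 1
        truth[rid] = "chimeric"
    return records, abundances, truth


def _generate_db(cfg, rng, species_names, species_pools, variant_seqs, deep_names, synonym_of, lpsn):
    """16S database records with sequence and label noise (plus truth rows).

    Unique, non-planted-duplicate sequences are enforced with a seen-set,
    so the 'redundant' fate in the truth table is exact (two independent
    records never coincide unless they carry the same planted variant and
    zero strain substitutions, in which case the later one is recorded as
    redundant).  Ambiguity symbols are injected into ordinary records
    only: duplicates must stay byte-identical to their source, and
    chimeras/anchors stay clean so the chimera ground truth is not
    confounded by the ambiguity filter.
    """
    species_list = sorted(species_names)
    master = variant_seqs[species_pools[species_list[0]][0]]

    # deep lineages: mutually diverged sequences that anchor chimera parents
    deep_seqs: list[str] = []
    while len(deep_seqs) < cfg.n_deep_lineages:
        cand = mutate_to_identity(master, 1.0 - cfg.deep_lineage_divergence, rng)
        if all(_hamming_div(cand, other) >= cfg.chimera_min_parent_divergence for other in deep_seqs):
            deep_seqs.append(cand)

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    seen: set[str] = set()
    counter = 0

    label_classes = ("synonym", "typo", "unclassified", "not_found", "foreign_lineage", "genus_conflict", "none")
    label_probs = np.array([
        cfg.p_label_synonym, cfg.p_label_typo, cfg.p_label_unclassified,
        cfg.p_label_not_found, cfg.p_label_foreign_lineage, cfg.p_label_genus_conflict,
    ])
    label_probs = np.append(label_probs, max(1.0 - label_probs.sum(), 0.0))

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:06d}"

    def label_record(true_name: str) -> tuple[list[str], str]:
        cls = label_classes[int(rng.choice(len(label_classes), p=label_probs))]
        lineage = list(_EXPECTED_LINEAGE)
        if cls == "synonym":
            if true_name not in synonym_of:
                return lineage + [true_name], "none"
            return lineage + [synonym_of[true_name]], "synonym"
        if cls == "typo":
            word = list(true_name)
            pos = int(rng.integers(len("Streptomyces ") + 1, len(word)))
            alphabet = [c for c in "abcdefghijklmnopqrstuvwxyz" if c != word[pos]]
            word[pos] = alphabet[int(rng.integers(0, len(alphabet)))]
            return lineage + ["".join(word)], "typo"
        if cls == "unclassified":
            return lineage + ["Streptomyces sp."], "unclassified"
        if cls == "not_found":
            # far from the generated epithet space, so it can never be
            # rescued as a near-miss typo
            return lineage + ["Streptomyces qqxxzzvvwwkkus"], "not_found"
        if cls == "foreign_lineage":
            return list(_FOREIGN_LINEAGE) + [true_name], "foreign_lineage"
        if cls == "genus_conflict":
            return lineage + ["Lactobacillus " + true_name.split()[1]], "genus_conflict"
        return lineage + [true_name], "none"

    def inject_ambiguities(seq: str) -> tuple[str, int]:
        if cfg.ambiguity_nb_r <= 0.0:
            return seq, 0
        n_amb = int(min(rng.negative_binomial(cfg.ambiguity_nb_r, cfg.ambiguity_nb_p), len(seq) // 2))
        if n_amb:
            arr = list(seq)
            for pos in rng.choice(len(seq), size=n_amb, replace=False):
                arr[pos] = _AMBIG[int(rng.integers(0, len(_AMBIG)))]
            seq = "".join(arr)
        return seq, n_amb

    def add_record(seq, true_name, fate, n_amb=0, label=None, variant_key=""):
        taxonomy, label_class = label if label is not None else label_record(true_name)
        rec = SequenceRecord(id=next_id(), seq=seq, source_db="synthetic", taxonomy=taxonomy)
        records.append(rec)
        truth_rows.append(
            {
                "id": rec.id,
                "species_name": true_name,
                "fate": fate,
                "label_class": label_class,
                "ambiguity_count": n_amb,
                "variant_key": variant_key,
            }
        )
        return rec

    clean_lineage = list(_EXPECTED_LINEAGE)

    # deep lineage anchors: clean, ambiguity-free, duplicated twice so they
    # outrank any chimera in abundance order
    for i, seq in enumerate(deep_seqs):
        seen.add(seq)
        add_record(seq, deep_names[i], "ok", label=(clean_lineage + [deep_names[i]], "none"), variant_key=f"deep{i}")
        for _ in range(2):
            add_record(seq, deep_names[i], "redundant", label=(clean_lineage + [deep_names[i]], "none"), variant_key=f"deep{i}")

    # ordinary records
    n_rest = max(cfg.n_db_records - cfg.n_deep_lineages * 3, 0)
    base_pool: list[tuple[str, str, str]] = []  # (seq, true_name, variant_key) of clean records
    for _ in range(n_rest):
        u = rng.random()
        if u < cfg.p_redundant and base_pool:
            seq, name, key = base_pool[int(rng.integers(0, len(base_pool)))]
            add_record(seq, name, "redundant", variant_key=key)
        elif u < cfg.p_redundant + cfg.p_chimera:
            while True:
                ia, ib = rng.choice(len(deep_seqs), size=2, replace=False)
                lo, hi = cfg.chimera_breakpoint_range
                f = float(rng.uniform(lo, hi))
                seq = make_chimera(deep_seqs[int(ia)], deep_seqs[int(ib)], f)
                if seq not in seen:
                    break
            seen.add(seq)
            add_record(
                seq, "Streptomyces sp.", "chimera",
                label=(clean_lineage + ["Streptomyces sp."], "unclassified"),
                variant_key=f"chimera:deep{int(ia)}+deep{int(ib)}",
            )
        elif u < cfg.p_redundant + cfg.p_chimera + cfg.p_truncated:
            sp = species_list[int(rng.integers(0, len(species_list)))]
            key = species_pools[sp][0]
            seq = variant_seqs[key]
            cut = int(rng.integers(300, 1200))
            add_record(seq[:cut], species_names[sp], "truncated", variant_key=key)
        else:
            sp = species_list[int(rng.integers(0, len(species_list)))]
            pool = species_pools[sp]
            key = pool[int(rng.integers(0, len(pool)))]
            base = variant_seqs[key]
            n_subs = int(rng.poisson(cfg.db_strain_subs_lambda))
            seq = substitute_positions(base, n_subs, rng) if n_subs else base
            seq, n_amb = inject_ambiguities(seq)
            # an exact coincidence with an earlier record is, operationally,
            # a redundant record: dereplication cannot tell it apart
            fate = "redundant" if seq in seen else "ok"
            seen.add(seq)
            add_record(seq, species_names[sp], fate, n_amb=n_amb, variant_key=key)
            if fate == "ok":
                base_pool.append((seq, species_names[sp], key))
    return records, truth_rows
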