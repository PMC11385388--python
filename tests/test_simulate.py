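"""The synthetic world itself: determinism, mutation calibration,
planted structure, and self-consistency of the ground truth."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from strep16s.alignment import pairwise_identity
from strep16s.ani import AniRelation
from strep16s.genomes import GenomeProfile, apply_genome_filter, extract_16s
from strep16s.network import build_graph, clique_test, components
from strep16s.simulate import (
    SimConfig,
    generate_cohort,
    make_chimera,
    mutate_to_identity,
    random_dna,
)

SMALL = SimConfig(
    seed=11,
    n_genera=2,
    species_per_genus=2,
    genomes_per_species=3,
    genome_length=30000,
    n_db_records=120,
)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SMALL)


class TestMutate:
    def test_target_one_unchanged(self, rng):
        seq = random_dna(rng, 500)
        assert mutate_to_identity(seq, 1.0, rng) == seq

    def test_target_identity_hit_on_long_sequence(self, rng):
        seq = random_dna(rng, 100_000)
        out = mutate_to_identity(seq, 0.95, rng)
        measured = np.mean(
            np.frombuffer(seq.encode(), np.uint8) == np.frombuffer(out.encode(), np.uint8)
        )
        assert measured == pytest.approx(0.95, abs=0.005)

    def test_independent_draws_compound(self, rng):
        seq = random_dna(rng, 50_000)
        a = mutate_to_identity(seq, 0.95, rng)
        b = mutate_to_identity(seq, 0.95, rng)
        measured = np.mean(
            np.frombuffer(a.encode(), np.uint8) == np.frombuffer(b.encode(), np.uint8)
        )
        assert measured == pytest.approx(0.9025, abs=0.01)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_to_identity("ACGT", 0.0, rng)


class TestChimeraUtility:
    def test_breakpoint_half_identical_parents(self, rng):
        a = random_dna(rng, 1000)
        assert make_chimera(a, a, 0.5) == a

    def test_prefix_suffix_structure(self, rng):
        a, b = random_dna(rng, 1000), random_dna(rng, 1000)
        chi = make_chimera(a, b, 0.5)
        assert chi[:500] == a[:500] and chi[500:] == b[500:]

    def test_degenerate_breakpoints_rejected(self, rng):
        a, b = random_dna(rng, 100), random_dna(rng, 100)
        for f in (0.0, 1.0):
            with pytest.raises(ValueError):
                make_chimera(a, b, f)


class TestDeterminism:
    def test_identical_seed_identical_world(self):
        c1 = generate_cohort(SMALL)
        c2 = generate_cohort(SMALL)
        assert [g.seq for g in c1.genomes] == [g.seq for g in c2.genomes]
        assert [(r.id, r.seq, tuple(r.taxonomy)) for r in c1.db_records] == [
            (r.id, r.seq, tuple(r.taxonomy)) for r in c2.db_records
        ]
        assert c1.lpsn.equals(c2.lpsn)
        assert c1.truth.genomes.equals(c2.truth.genomes)

    def test_different_seed_differs(self):
        c1 = generate_cohort(SMALL)
        c2 = generate_cohort(SimConfig(**{**SMALL.__dict__, "seed": 12}))
        assert [g.seq for g in c1.genomes] != [g.seq for g in c2.genomes]

    def test_write_roundtrip_bytes(self, tmp_path, small_cohort):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        small_cohort.write(d1)
        generate_cohort(SMALL).write(d2)
        for rel in ("db_16s.fasta", "lpsn.csv", "names.tsv", "truth/components.csv"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()


class TestPlantedStructure:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(within_species_ani=90, between_species_within_genus_ani=95)
        with pytest.raises(ValueError):
            SimConfig(copy_number_distribution=((1, 0.5),))
        with pytest.raises(ValueError):
            SimConfig(p_chimera=1.5)

    def test_copy_number_histogram_close_to_distribution(self, cohort):
        dist = dict(cohort.config.copy_number_distribution)
        counts = Counter(cohort.truth.genomes.n_copies)
        n = len(cohort.truth.genomes)
        for k, p in dist.items():
            if p < 0.05:
                continue
            # binomial 95% interval, plus slack for the conditional draws
            # forced on planted variant carriers
            half = 1.96 * np.sqrt(p * (1 - p) / n) + 0.05
            assert abs(counts.get(k, 0) / n - p) <= half

    def test_intragenomic_variants_present(self, cohort):
        assert (cohort.truth.genomes.n_variants >= 2).any()

    def test_cross_species_share_merges_components(self, cohort):
        truth = cohort.truth
        multi = [c for c, cls in truth.component_classes.items() if cls != "single_species"]
        assert multi, "stated world must contain cross-species components"

    def test_non_clique_planted(self, cohort):
        assert any(not v for v in cohort.truth.component_cliques.values())

    def test_relation_from_hierarchy(self, cohort):
        t = cohort.truth
        g = t.genomes
        same_sp = g[g.species_name == g.species_name.iloc[0]].accession.tolist()
        assert t.relation(same_sp[0], same_sp[1]) is AniRelation.SAME_SPECIES

    def test_no_sharing_means_single_species_components(self):
        cfg = SimConfig(
            seed=5, n_genera=2, species_per_genus=2, genomes_per_species=3,
            genome_length=30000, n_db_records=60,
            p_cross_species_shared_variant=0.0, plant_non_clique=False,
        )
        truth = generate_cohort(cfg).truth
        assert set(truth.component_classes.values()) == {"single_species"}

    def test_cross_genus_share_is_multi_genus(self):
        cfg = SimConfig(
            seed=6, n_genera=2, species_per_genus=2, genomes_per_species=2,
            genome_length=30000, n_db_records=60,
            p_cross_species_shared_variant=0.0, plant_non_clique=False,
            n_cross_genus_shared_pairs=1,
        )
        truth = generate_cohort(cfg).truth
        assert "multi_genus" in truth.component_classes.values()

    def test_db_truth_accounts_every_record(self, cohort):
        truth = cohort.truth.db_records
        assert len(truth) == len(cohort.db_records)
        assert set(truth.fate) <= {"ok", "redundant", "truncated", "chimera"}
        assert (truth.fate == "chimera").sum() > 0

    def test_genome_16s_correlates_with_species(self, small_cohort):
        """16S similarity tracks the genome hierarchy: within-species core
        variants are closer than between-genera ones."""
        core = {}
        for g in small_cohort.genomes:
            core.setdefault((g.genus_idx, g.species_name), g.copy_variant_keys[0])
        keys = list(core)
        seqs = {k: small_cohort.variant_seqs[core[k]] for k in keys}
        within = [
            pairwise_identity(seqs[a], seqs[b])
            for a in keys for b in keys
            if a < b and a[0] == b[0]
        ]
        between = [
            pairwise_identity(seqs[a], seqs[b])
            for a in keys for b in keys
            if a < b and a[0] != b[0]
        ]
        assert min(within) > max(between)


class TestGenomeSideTruth:
    def test_fates_match_extraction(self, small_cohort):
        profiles = []
        for rec, g in zip(small_cohort.to_genbank_records(), small_cohort.genomes):
            profiles.append(GenomeProfile(g.accession, g.species_name, copies=extract_16s(rec)))
        apply_genome_filter(profiles)
        truth_fate = dict(zip(small_cohort.truth.genomes.accession, small_cohort.truth.genomes.fate))
        for p in profiles:
            assert p.qc_status.value == truth_fate[p.accession]

    def test_partition_matches_pipeline(self, small_cohort):
        profiles = []
        for rec, g in zip(small_cohort.to_genbank_records(), small_cohort.genomes):
            profiles.append(GenomeProfile(g.accession, g.species_name, copies=extract_16s(rec)))
        retained = apply_genome_filter(profiles)
        graph = build_graph(retained)
        got = sorted((frozenset(c.members) for c in components(graph)), key=lambda c: (-len(c), min(c)))
        assert got == small_cohort.truth.components
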