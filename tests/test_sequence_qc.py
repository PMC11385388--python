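"""Unit tests for 16S sequence QC: base standardisation, length filter,
ambiguity modelling, dereplication and chimera flagging."""

from __future__ import annotations

import math

import numpy as np
import pytest

from strep16s.records import SequenceRecord
from strep16s.sequence_qc import (
    ChimeraConfig,
    QcConfig,
    count_ambiguities,
    dereplicate,
    detect_chimeras,
    filter_full_length,
    fit_ambiguity_threshold,
    run_qc,
    standardize_bases,
)
from strep16s.simulate import make_chimera, mutate_to_identity, random_dna


def _rec(i, seq):
    return SequenceRecord(id=f"r{i}", seq=seq)


class TestStandardize:
    @pytest.mark.parametrize(
        "raw,expected",
        [("acgu", "ACGT"), ("ACGT", "ACGT"), ("ARYN", "ARYN"), ("uuUU", "TTTT")],
    )
    def test_substitution(self, raw, expected):
        assert standardize_bases(raw) == expected

    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError):
            standardize_bases("ACGT-")
        with pytest.raises(ValueError):
            standardize_bases("ACG9")


class TestLengthFilter:
    def test_boundary_inclusive_at_min_length(self):
        records = [_rec(0, "A" * 1199), _rec(1, "A" * 1200), _rec(2, "A" * 1500)]
        kept = filter_full_length(records, 1200)
        assert [r.id for r in kept] == ["r1", "r2"]

    def test_empty_input(self):
        assert filter_full_length([], 1200) == []


class TestAmbiguities:
    def test_counts(self):
        assert count_ambiguities("ACGT") == 0
        assert count_ambiguities("ANNNT") == 3

    def test_count_matches_injection(self, rng):
        seq = list(random_dna(rng, 1500))
        k = 17
        for pos in rng.choice(1500, size=k, replace=False):
            seq[pos] = "N"
        assert count_ambiguities("".join(seq)) == k

    def test_all_zero_counts(self):
        assert fit_ambiguity_threshold([0] * 50, 0.999) == 0

    def test_degenerate_constant(self):
        assert fit_ambiguity_threshold([5] * 20, 0.9) == 5

    def test_nb_fit_matches_bruteforce_cdf(self, rng):
        counts = rng.negative_binomial(2, 0.5, size=5000)
        got = fit_ambiguity_threshold(counts, 0.999)
        # oracle: refit by moments, then sum the NB pmf term by term
        m, v = counts.mean(), counts.var()
        p = m / v
        r = m * m / (v - m)
        k, cdf, logpmf0 = 0, 0.0, r * math.log(p)
        cdf = math.exp(logpmf0)
        while cdf < 0.999:
            k += 1
            cdf += math.exp(
                math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
                + r * math.log(p) + k * math.log(1 - p)
            )
        assert got == k

    def test_poisson_fallback(self):
        # mean 1.0, variance 1/3 (underdispersed): Poisson(1), q=0.9 -> k=2
        counts = [1, 1, 1, 1, 0, 2]
        assert np.mean(counts) == 1.0 and np.var(counts) < 1.0
        assert fit_ambiguity_threshold(counts, 0.9) == 2

    def test_monotone_in_quantile(self, rng):
        counts = rng.negative_binomial(0.5, 0.1, size=2000)
        ks = [fit_ambiguity_threshold(counts, q) for q in (0.5, 0.9, 0.99, 0.999)]
        assert ks == sorted(ks)


class TestDereplicate:
    def test_two_identical(self):
        reps, members = dereplicate([_rec(0, "ACGT" * 300), _rec(1, "ACGT" * 300)])
        assert len(reps) == 1
        assert len(members[reps[0].id]) == 2

    def test_one_mismatch_kept_apart(self):
        a = "ACGT" * 300
        b = "T" + a[1:]
        reps, _ = dereplicate([_rec(0, a), _rec(1, b)])
        assert len(reps) == 2

    def test_matches_hash_grouping_oracle(self, rng):
        pool = [random_dna(rng, 80) for _ in range(40)]
        records = [
            SequenceRecord(id=f"x{i}", seq=pool[int(rng.integers(0, 40))])
            for i in range(300)
        ]
        reps, members = dereplicate(records)
        oracle: dict[str, list[str]] = {}
        for r in records:
            oracle.setdefault(r.seq, []).append(r.id)
        assert len(reps) == len(oracle)
        for rep in reps:
            assert sorted(m.id for m in members[rep.id]) == sorted(oracle[rep.seq])
            # representative rule: identical strings, so smallest id wins
            assert rep.id == min(oracle[rep.seq])


class TestChimeras:
    def test_query_identical_to_parent_is_clean(self, rng):
        base = random_dna(rng, 1000)
        other = mutate_to_identity(base, 0.85, rng)
        records = [_rec(0, base), _rec(1, other), _rec(2, base)]
        flags = detect_chimeras(records, abundances={"r0": 5, "r1": 5, "r2": 1})
        assert flags["r2"] == "clean"

    def test_two_parent_chimera_flagged(self, rng):
        a = random_dna(rng, 1400)
        b = mutate_to_identity(a, 0.88, rng)
        chi = make_chimera(a, b, 0.45)
        records = [_rec(0, a), _rec(1, b), _rec(2, chi)]
        flags = detect_chimeras(records, abundances={"r0": 5, "r1": 5, "r2": 1})
        assert flags == {"r0": "clean", "r1": "clean", "r2": "chimeric"}

    def test_fewer_than_two_parents_always_clean(self, rng):
        a = random_dna(rng, 1200)
        flags = detect_chimeras([_rec(0, a)])
        assert flags["r0"] == "clean"

    def test_breakpoint_scan_agrees_with_oracle(self, rng):
        """Explicit all-breakpoints oracle on an equal-length trio."""
        a = random_dna(rng, 1200)
        b = mutate_to_identity(a, 0.85, rng)
        chi = make_chimera(a, b, 0.6)
        cfg = ChimeraConfig()
        pa = np.frombuffer(chi.encode(), np.uint8) == np.frombuffer(a.encode(), np.uint8)
        pb = np.frombuffer(chi.encode(), np.uint8) == np.frombuffer(b.encode(), np.uint8)
        found = False
        for bp in range(1, 1200):
            if (
                pa[:bp].mean() >= cfg.id_two and pb[bp:].mean() >= cfg.id_two
            ) or (pb[:bp].mean() >= cfg.id_two and pa[bp:].mean() >= cfg.id_two):
                found = True
                break
        assert found
        flags = detect_chimeras(
            [_rec(0, a), _rec(1, b), _rec(2, chi)],
            abundances={"r0": 2, "r1": 2, "r2": 1},
        )
        assert flags["r2"] == "chimeric"


class TestPipeline:
    def test_stage_counts_monotone_and_dispositions(self, rng):
        base = random_dna(rng, 1300)
        records = [
            _rec(0, base),
            _rec(1, base),                      # redundant
            _rec(2, base[:800]),                # short
            _rec(3, mutate_to_identity(base, 0.95, rng)),
            _rec(4, "ACGU" * 325),              # RNA, standardised
        ]
        survivors, _, report = run_qc(records, QcConfig(), log=None)
        counts = report.stage_counts()
        assert counts == sorted(counts, reverse=True)
        assert report.dispositions["r1"] == "redundant"
        assert report.dispositions["r2"] == "short"
        assert all("U" not in r.seq for r in survivors)

    def test_invalid_alphabet_dropped_with_tag(self):
        records = [_rec(0, "ACGT" * 400), _rec(1, "ACG?" * 400)]
        survivors, _, report = run_qc(records, QcConfig(), log=None)
        assert report.dispositions["r1"] == "invalid_alphabet"
        assert [r.id for r in survivors] == ["r0"]

    def test_ambiguity_override_pins_threshold(self, rng):
        seq = list(random_dna(rng, 1300))
        for pos in range(10):
            seq[pos] = "N"
        records = [_rec(0, "".join(seq)), _rec(1, random_dna(rng, 1300))]
        _, _, rep_keep = run_qc(records, QcConfig(ambiguity_threshold_override=10), log=None)
        _, _, rep_drop = run_qc(records, QcConfig(ambiguity_threshold_override=9), log=None)
        assert rep_keep.dispositions["r0"] == "retained"
        assert rep_drop.dispositions["r0"] == "high_ambiguity"
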