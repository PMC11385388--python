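"""Fragment-based average nucleotide identity and taxonomic thresholds.

The estimator follows the ANIb convention: the query genome is cut into
consecutive fragments (default 1020 bp, the final fragment absorbing the
remainder), each fragment is locally aligned against the subject genome
on both strands, and fragments passing a keep rule (>= 30% identity over
>= 70% of the fragment) contribute to the statistics:

* identity  = mean percent identity over kept fragments,
* coverage  = kept aligned length / query length * 100.

Local alignment is seed-and-extend: exact k-mer hits (default k=13,
sampled every 3 positions) vote for a diagonal on either strand, and the
best diagonal's gap-free maximal-scoring segment (match +1, mismatch -1;
Kadane scan) is taken as the fragment's local alignment.  If that
segment explains the fragment poorly (< 70% identity), a full
Smith-Waterman on the candidate window is used instead, so small indels
are tolerated.  Fragments with no seed hit are unaligned - which is what
bounds coverage between unrelated genomes.

Symmetrisation takes the mean of the two directed identities but the
minimum of the two coverages: a pair is called same-genus only when both
genomes are substantially covered.  Thresholds (inclusive): >= 50%
coverage for the same candidate genus, and additionally >= 95% identity
for the same species.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import make_aligner

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AniRelation(str, Enum):
    SAME_SPECIES = "same_species"
    SAME_GENUS_DIFF_SPECIES = "same_genus_diff_species"
    DIFF_GENUS = "diff_genus"


@dataclass(frozen=True)
class AniConfig:
    species_identity_threshold: float = 95.0
    genus_coverage_threshold: float = 50.0
    fragment_length: int = 1020
    min_fragment_identity: float = 30.0
    min_fragment_coverage: float = 70.0
    seed_kmer: int = 13
    seed_stride: int = 3

    def __post_init__(self) -> None:
        for v in (self.species_identity_threshold, self.genus_coverage_threshold):
            if not 0.0 < v <= 100.0:
                raise ValueError("thresholds must be in (0, 100]")


@dataclass(frozen=True)
class DirectedAni:
    identity: float | None    # percent; None when no fragment was kept
    coverage: float           # percent of the query genome aligned


@dataclass
class AniResult:
    pair: tuple[str, str]
    identity: float | None
    coverage: float
    relation: AniRelation | None = None


class SubjectIndex:
    """Exact k-mer index of a subject genome, both strands."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.forward = seq
        self.reverse = reverse_complement(seq)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for strand, s in enumerate((self.forward, self.reverse)):
            idx = self.index
            for pos in range(len(s) - k + 1):
                idx.setdefault(s[pos:pos + k], []).append((strand, pos))

    def strand_seq(self, strand: int) -> str:
        return self.forward if strand == 0 else self.reverse


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring run under +1/-1 scoring (vectorised Kadane).

    Returns (start, end, n_matches) of the best half-open segment; ties
    resolve to the earliest-ending, then longest, segment.  The best
    segment sum is max_j (S[j] - min_{i<=j} S[i]) over prefix sums S.
    """
    score = np.where(match, 1, -1).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(score)))
    running_min = np.minimum.accumulate(prefix)
    gains = prefix - running_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return 0, 0, 0
    start = int(np.flatnonzero(prefix[:end] == running_min[end])[0])
    n_matches = int(match[start:end].sum())
    return start, end, n_matches


_LOCAL_ALIGNER = make_aligner("local")


def _align_fragment(fragment: str, subject: SubjectIndex, cfg: AniConfig) -> tuple[float, int] | None:
    """Best local alignment of one fragment: (percent identity, aligned length)."""
    votes: dict[tuple[int, int], int] = {}
    k = subject.k
    for off in range(0, len(fragment) - k + 1, cfg.seed_stride):
        for strand, pos in subject.index.get(fragment[off:off + k], ()):
            key = (strand, pos - off)
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    (strand, diag), _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    target = subject.strand_seq(strand)
    start = max(diag, 0)
    end = min(diag + len(fragment), len(target))
    if end <= start:
        return None
    window = target[start:end]
    frag_lo = start - diag
    frag_hi = frag_lo + len(window)
    fa = np.frombuffer(fragment[frag_lo:frag_hi].encode(), dtype=np.uint8)
    wa = np.frombuffer(window.encode(), dtype=np.uint8)
    seg_start, seg_end, n_match = _best_segment(fa == wa)
    seg_len = seg_end - seg_start
    if seg_len > 0 and n_match / seg_len >= 0.70:
        return 100.0 * n_match / seg_len, seg_len
    # gap-free segment is poor: fall back to Smith-Waterman on a padded window
    pad = len(fragment) // 4
    w_start = max(start - pad, 0)
    w_end = min(diag + len(fragment) + pad, len(target))
    alignments = _LOCAL_ALIGNER.align(fragment, target[w_start:w_end])
    if len(alignments) == 0:
        return None
    counts = alignments[0].counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return None
    return 100.0 * counts.identities / aligned, int(aligned)


def genome_fragments(seq: str, fragment_length: int) -> list[str]:
    """Consecutive fragments; the last fragment absorbs the remainder so
    the fragments tile the genome exactly."""
    n = max(len(seq) // fragment_length, 1)
    frags = [seq[i * fragment_length:(i + 1) * fragment_length] for i in range(n - 1)]
    frags.append(seq[(n - 1) * fragment_length:])
    return frags


def fragment_ani(
    genome_a: str,
    genome_b: str,
    config: AniConfig | None = None,
    subject_index: SubjectIndex | None = None,
) -> DirectedAni:
    """Directed fragment ANI of ``genome_a`` (query) against ``genome_b``."""
    cfg = config or AniConfig()
    if not genome_a or not genome_b:
        raise ValueError("genomes must be non-empty")
    subject = subject_index or SubjectIndex(genome_b, cfg.seed_kmer)
    identities: list[float] = []
    aligned_total = 0
    for frag in genome_fragments(genome_a, cfg.fragment_length):
        if len(frag) < subject.k:
            continue
        hit = _align_fragment(frag, subject, cfg)
        if hit is None:
            continue
        ident, aligned = hit
        if ident >= cfg.min_fragment_identity and 100.0 * aligned / len(frag) >= cfg.min_fragment_coverage:
            identities.append(ident)
            aligned_total += aligned
    if not identities:
        return DirectedAni(identity=None, coverage=0.0)
    return DirectedAni(
        identity=float(np.mean(identities)),
        coverage=100.0 * aligned_total / len(genome_a),
    )


def symmetrize(a_vs_b: DirectedAni, b_vs_a: DirectedAni, pair: tuple[str, str]) -> AniResult:
    """Mean of directed identities, min of directed coverages."""
    if a_vs_b is None or b_vs_a is None:
        raise ValueError("both directions are required")
    if a_vs_b.identity is None or b_vs_a.identity is None:
        identity = None
    else:
        identity = (a_vs_b.identity + b_vs_a.identity) / 2.0
    return AniResult(
        pair=pair,
        identity=identity,
        coverage=min(a_vs_b.coverage, b_vs_a.coverage),
    )


def classify_pair(result: AniResult, config: AniConfig | None = None) -> AniRelation:
    """Threshold rule: same genus needs >= 50% coverage (inclusive), same
    species additionally >= 95% identity (inclusive)."""
    cfg = config or AniConfig()
    if result.identity is None or result.coverage < cfg.genus_coverage_threshold:
        relation = AniRelation.DIFF_GENUS
    elif result.identity < cfg.species_identity_threshold:
        relation = AniRelation.SAME_GENUS_DIFF_SPECIES
    else:
        relation = AniRelation.SAME_SPECIES
    result.relation = relation
    return relation


def pairwise_ani(
    genomes: dict[str, str],
    pairs=None,
    config: AniConfig | None = None,
) -> dict[tuple[str, str], AniResult]:
    """Symmetrised, classified ANI for the requested accession pairs
    (default: all unordered pairs).  Subject indexes are cached."""
    cfg = config or AniConfig()
    wanted = [tuple(sorted(p)) for p in (pairs if pairs is not None else combinations(sorted(genomes), 2))]
    indexes: dict[str, SubjectIndex] = {}

    def index_of(acc: str) -> SubjectIndex:
        if acc not in indexes:
            indexes[acc] = SubjectIndex(genomes[acc], cfg.seed_kmer)
        return indexes[acc]

    results: dict[tuple[str, str], AniResult] = {}
    for a, b in wanted:
        if (a, b) in results:
            continue
        ab = fragment_ani(genomes[a], genomes[b], cfg, index_of(b))
        ba = fragment_ani(genomes[b], genomes[a], cfg, index_of(a))
        res = symmetrize(ab, ba, (a, b))
        classify_pair(res, cfg)
        results[(a, b)] = res
    return results


# -- pyANI-style matrix interoperability ------------------------------------

def write_ani_matrices(
    results: dict[tuple[str, str], AniResult],
    identity_path: str | Path,
    coverage_path: str | Path,
) -> None:
    labels = sorted({acc for pair in results for acc in pair})
    ident = pd.DataFrame(100.0, index=labels, columns=labels)
    cov = pd.DataFrame(100.0, index=labels, columns=labels)
    for (a, b), res in results.items():
        val = np.nan if res.identity is None else res.identity
        ident.loc[a, b] = ident.loc[b, a] = val
        cov.loc[a, b] = cov.loc[b, a] = res.coverage
    ident.to_csv(identity_path, sep="\t")
    cov.to_csv(coverage_path, sep="\t")


def load_ani_matrix(
    identity_path: str | Path,
    coverage_path: str | Path,
    config: AniConfig | None = None,
) -> dict[tuple[str, str], AniResult]:
    """Read labelled identity/coverage TSV matrices into AniResults.

    Validates consistent label sets, square shape and a 100% diagonal.
    """
    cfg = config or AniConfig()
    ident = pd.read_csv(identity_path, sep="\t", index_col=0)
    cov = pd.read_csv(coverage_path, sep="\t", index_col=0)
    for name, df in (("identity", ident), ("coverage", cov)):
        if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
            raise ValueError(f"{name} matrix is not square with matching labels")
    if list(ident.index) != list(cov.index):
        raise ValueError("identity and coverage matrices have different labels")
    diag = np.diag(cov.to_numpy())
    if not np.allclose(diag, 100.0):
        raise ValueError("coverage diagonal must be 100")
    results: dict[tuple[str, str], AniResult] = {}
    for a, b in combinations(ident.index, 2):
        iv = (float(ident.loc[a, b]) + float(ident.loc[b, a])) / 2.0
        identity = None if np.isnan(iv) else iv
        coverage = min(float(cov.loc[a, b]), float(cov.loc[b, a]))
        res = AniResult(pair=(a, b), identity=identity, coverage=coverage)
        classify_pair(res, cfg)
        results[(a, b)] = res
    return results
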