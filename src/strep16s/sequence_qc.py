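"""Quality control of raw 16S reference sequences.

The cleaning pipeline mirrors standard practice for building a
non-redundant full-length 16S set:

1. standardise bases (RNA -> DNA, uppercase; non-IUPAC records dropped),
2. discard sequences shorter than a full-length cutoff (default 1200 bp,
   which keeps all hypervariable regions of the ~1550 bp gene),
3. dereplicate strictly identical sequences, keeping one representative
   per identity class and a member map for taxonomy propagation,
4. discard sequences with an extreme number of ambiguity symbols, the
   cutoff being the upper quantile of a negative binomial fitted to the
   per-sequence ambiguity counts (Poisson fallback when underdispersed),
5. flag and remove chimaeras with an explicit two-parent breakpoint test.

The chimera detector is a transparent stand-in for UCHIME-de-novo: in
abundance order, a query is chimeric when some prefix matches one
already-accepted parent at >= ``id_two`` and the complementary suffix
matches a different parent at >= ``id_two``, while no single parent
explains the whole query at better than ``id_one``.  As with UCHIME,
chimeras whose parents are nearly identical are intrinsically
undetectable: with breakpoint fraction f and parent divergence d, the
best single parent matches the query at 1 - d*min(f, 1-f), so the
``id_one`` condition requires d*min(f, 1-f) >= 1 - id_one.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import make_aligner
from .records import SequenceRecord

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
_UNAMBIGUOUS = frozenset("ACGT")

_U_TO_T = str.maketrans({"U": "T", "u": "T"})


@dataclass(frozen=True)
class ChimeraConfig:
    """Parameters of the two-parent breakpoint test."""

    id_two: float = 0.99       # min prefix/suffix identity to each parent
    id_one: float = 0.97       # max full-length identity to any single parent
    top_parents: int = 8       # overall top candidates by whole-query k-mer overlap
    n_segments: int = 4        # query segments for diversity-aware selection
    parents_per_segment: int = 3
    kmer_size: int = 12


@dataclass(frozen=True)
class QcConfig:
    min_length: int = 1200
    ambiguity_quantile: float = 0.999
    ambiguity_threshold_override: int | None = None
    chimera: ChimeraConfig = field(default_factory=ChimeraConfig)

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0.0 < self.ambiguity_quantile < 1.0:
            raise ValueError("ambiguity_quantile must be in (0, 1)")


@dataclass
class QcReport:
    """Per-stage survivor counts and per-record dispositions.

    ``dispositions`` maps record id to one of: retained, invalid_alphabet,
    short, redundant, high_ambiguity, chimeric.  Counts are non-increasing
    along input -> full_length -> after_derep -> after_ambiguity ->
    after_chimera.
    """

    n_input: int = 0
    n_full_length: int = 0
    n_after_derep: int = 0
    n_after_ambiguity: int = 0
    n_after_chimera: int = 0
    ambiguity_threshold: int | None = None
    dispositions: dict[str, str] = field(default_factory=dict)

    def stage_counts(self) -> list[int]:
        return [
            self.n_input,
            self.n_full_length,
            self.n_after_derep,
            self.n_after_ambiguity,
            self.n_after_chimera,
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.dispositions.items()), columns=["id", "disposition"]
        )


def standardize_bases(seq: str) -> str:
    """Uppercase and replace uracil with thymine; reject non-IUPAC symbols."""
    out = seq.upper().translate(_U_TO_T)
    bad = set(out) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return out


def filter_full_length(records: list[SequenceRecord], min_length: int = 1200) -> list[SequenceRecord]:
    """Keep records of at least ``min_length`` bp (order preserved).

    The cutoff is inclusive: a record of exactly ``min_length`` is
    'full length'; only strictly shorter sequences are excluded.
    """
    return [r for r in records if r.length >= min_length]


def count_ambiguities(seq: str) -> int:
    """Number of symbols that are not an unambiguous A/C/G/T."""
    return sum(1 for c in seq if c not in _UNAMBIGUOUS)


def fit_ambiguity_threshold(counts, quantile: float = 0.999) -> int:
    """Quantile cutoff from a method-of-moments negative binomial fit.

    Returns the smallest k with fitted CDF(k) >= quantile; records with
    more than k ambiguity symbols are to be discarded.  When the counts
    are underdispersed (variance <= mean) a Poisson fit is used; a
    degenerate (constant) sample returns that constant.
    """
    x = np.asarray(list(counts), dtype=float)
    if x.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    m = x.mean()
    v = x.var()
    if v == 0.0:
        return int(x[0])
    if v <= m:
        return int(stats.poisson.ppf(quantile, m))
    # moments: mean = r(1-p)/p, var = mean/p  =>  p = m/v, r = m^2/(v-m)
    p = m / v
    r = m * m / (v - m)
    return int(stats.nbinom.ppf(quantile, r, p))


def dereplicate(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, list[SequenceRecord]]]:
    """Collapse byte-identical sequences to one representative each.

    The representative of an identity class is its longest member
    (identical strings tie, so effectively the lexicographically smallest
    id).  Returns representatives in first-seen order and a map from
    representative id to all class members (representative included), so
    taxonomy labels of removed duplicates can be propagated downstream.
    """
    classes: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        classes.setdefault(rec.seq, []).append(rec)
    reps: list[SequenceRecord] = []
    member_map: dict[str, list[SequenceRecord]] = {}
    for members in classes.values():
        rep = min(members, key=lambda r: (-r.length, r.id))
        reps.append(rep)
        member_map[rep.id] = members
    return reps, member_map


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1)}


def _match_profile(query: str, parent: str, aligner) -> np.ndarray:
    """Boolean per-query-position vector: does the position align to an
    identical parent base (ungapped fast path for equal lengths)."""
    if len(query) == len(parent):
        return _encode(query) == _encode(parent)
    alignment = aligner.align(query, parent)[0]
    prof = np.zeros(len(query), dtype=bool)
    qs, ps = alignment[0], alignment[1]
    qi = 0
    for qc, pc in zip(qs, ps):
        if qc != "-":
            if pc == qc:
                prof[qi] = True
            qi += 1
    return prof


def detect_chimeras(
    records: list[SequenceRecord],
    config: ChimeraConfig | None = None,
    abundances: dict[str, int] | None = None,
) -> dict[str, str]:
    """Flag each dereplicated record as ``clean`` or ``chimeric``.

    Records are processed in decreasing abundance (ties by id); the
    candidate parent pool for a query is every earlier record already
    flagged clean.  Candidates are pre-ranked by shared k-mer count both
    over the whole query and per query segment (so a parent matching
    only one flank of a chimera is not crowded out by close relatives of
    the other flank), and only the selected candidates are aligned.
    """
    cfg = config or ChimeraConfig()
    aligner = make_aligner("global")
    order = sorted(
        records,
        key=lambda r: (-(abundances or {}).get(r.id, 1), r.id),
    )
    flags: dict[str, str] = {}
    clean: list[tuple[SequenceRecord, set[str]]] = []
    for query in order:
        L = len(query.seq)
        bounds = np.linspace(0, L, cfg.n_segments + 1).astype(int)
        seg_kmers = [
            _kmer_set(query.seq[bounds[i]:bounds[i + 1]], cfg.kmer_size)
            for i in range(cfg.n_segments)
        ]
        scored = [
            (rec, [len(seg & kmers) for seg in seg_kmers])
            for rec, kmers in clean
        ]
        chosen: dict[str, SequenceRecord] = {}
        for rec, _ in sorted(scored, key=lambda it: (-sum(it[1]), it[0].id))[: cfg.top_parents]:
            chosen[rec.id] = rec
        for s in range(cfg.n_segments):
            ranked = sorted(scored, key=lambda it: (-it[1][s], it[0].id))
            for rec, _ in ranked[: cfg.parents_per_segment]:
                chosen[rec.id] = rec
        candidates = sorted(chosen.values(), key=lambda r: r.id)
        if _is_chimeric(query.seq, candidates, cfg, aligner):
            flags[query.id] = "chimeric"
        else:
            flags[query.id] = "clean"
            clean.append((query, _kmer_set(query.seq, cfg.kmer_size)))
    return flags


def _is_chimeric(query: str, candidates: list[SequenceRecord], cfg: ChimeraConfig, aligner) -> bool:
    if len(candidates) < 2:
        return False
    profiles = [_match_profile(query, c.seq, aligner) for c in candidates]
    best_single = max(p.mean() for p in profiles)
    if best_single > cfg.id_one:
        return False
    L = len(query)
    b = np.arange(1, L)
    prefix = [np.cumsum(p)[:-1] for p in profiles]          # matches in query[:b]
    totals = [int(p.sum()) for p in profiles]
    for ia in range(len(profiles)):
        pref_ok = prefix[ia] / b >= cfg.id_two
        if not pref_ok.any():
            continue
        for ib in range(len(profiles)):
            if ib == ia:
                continue
            suff_ok = (totals[ib] - prefix[ib]) / (L - b) >= cfg.id_two
            if np.any(pref_ok & suff_ok):
                return True
    return False


def run_qc(
    records: list[SequenceRecord],
    config: QcConfig | None = None,
    log=sys.stderr,
) -> tuple[list[SequenceRecord], dict[str, list[SequenceRecord]], QcReport]:
    """Full QC pipeline; returns survivors, the derep member map and a report."""
    cfg = config or QcConfig()
    report = QcReport(n_input=len(records))

    standardized: list[SequenceRecord] = []
    for rec in records:
        try:
            standardized.append(replace(rec, seq=standardize_bases(rec.seq)))
        except ValueError:
            report.dispositions[rec.id] = "invalid_alphabet"

    full = filter_full_length(standardized, cfg.min_length)
    for rec in standardized:
        if rec.length < cfg.min_length:
            report.dispositions[rec.id] = "short"
    report.n_full_length = len(full)

    reps, member_map = dereplicate(full)
    rep_ids = {r.id for r in reps}
    for rec in full:
        if rec.id not in rep_ids:
            report.dispositions[rec.id] = "redundant"
    report.n_after_derep = len(reps)

    counts = {r.id: count_ambiguities(r.seq) for r in reps}
    if cfg.ambiguity_threshold_override is not None:
        threshold = cfg.ambiguity_threshold_override
    elif reps:
        threshold = fit_ambiguity_threshold(list(counts.values()), cfg.ambiguity_quantile)
    else:
        threshold = 0
    report.ambiguity_threshold = threshold
    low_ambiguity = [r for r in reps if counts[r.id] <= threshold]
    for r in reps:
        if counts[r.id] > threshold:
            report.dispositions[r.id] = "high_ambiguity"
    report.n_after_ambiguity = len(low_ambiguity)

    abundances = {r.id: len(member_map[r.id]) for r in low_ambiguity}
    flags = detect_chimeras(low_ambiguity, cfg.chimera, abundances)
    survivors = [r for r in low_ambiguity if flags[r.id] == "clean"]
    for r in low_ambiguity:
        report.dispositions[r.id] = "retained" if flags[r.id] == "clean" else "chimeric"
    report.n_after_chimera = len(survivors)

    if log is not None:
        print(
            f"qc: {report.n_input} in -> {report.n_full_length} full-length -> "
            f"{report.n_after_derep} non-redundant -> {report.n_after_ambiguity} "
            f"low-ambiguity (cutoff {threshold}) -> {report.n_after_chimera} non-chimaeric",
            file=log,
        )
    return survivors, member_map, report
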