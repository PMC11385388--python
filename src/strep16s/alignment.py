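"""Global pairwise alignment identity.

Percentage-identity thresholds in greedy OTU clustering are defined on an
optimal global alignment.  The scoring scheme is fixed (match +1,
mismatch -1, gap open -2, gap extend -1) and identity is the fraction of
matching columns, by default over the alignment length excluding terminal
gap columns (the usual usearch/vsearch ``--id`` reading); an alternative
mode counts terminal gaps in the denominator.

Equal-length pairs get a fast exact path.  With d Hamming mismatches the
ungapped alignment scores L - 2d.  Any alignment whose path leaves a
diagonal band of half-width B must contain more than B insertion and B
deletion columns, loses those aligned pairs and pays at least two gap
openings, so it scores at most L - 3(B+1) - 2; hence for
B >= (2d - 5) / 3 the optimum over the band (computed by a numba-compiled
banded Gotoh DP) is the global optimum.  When the ungapped score attains
that optimum — which for substitution-dominated data is essentially
always — the identity is the Hamming identity; otherwise (or for unequal
lengths) Biopython's aligner produces an optimal alignment to count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio import Align
from numba import njit

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
OPEN_GAP_SCORE = -2.0
EXTEND_GAP_SCORE = -1.0


class IdentityMode(str, Enum):
    """How matching columns are normalised into an identity fraction."""

    IGNORE_TERMINAL_GAPS = "matching_cols_over_alignment_ignoring_terminal_gaps"
    FULL_ALIGNMENT = "matching_cols_over_alignment"


@dataclass(frozen=True)
class IdentityDefinition:
    mode: IdentityMode = IdentityMode.IGNORE_TERMINAL_GAPS


DEFAULT_IDENTITY = IdentityDefinition()


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = OPEN_GAP_SCORE
    aligner.extend_gap_score = EXTEND_GAP_SCORE
    return aligner


_GLOBAL_ALIGNER = make_aligner("global")


def hamming_mismatches(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (vectorised)."""
    if len(a) != len(b):
        raise ValueError("hamming comparison requires equal lengths")
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int((xa != xb).sum())


@njit(cache=False)
def _banded_global_score(a: np.ndarray, b: np.ndarray, band: int,
                         match: float, mismatch: float, open_gap: float, extend_gap: float) -> float:
    """Optimal global alignment score restricted to |i - j| <= band.

    Affine gaps, Biopython convention: a gap of length g costs
    open_gap + (g - 1) * extend_gap.  Equal-length sequences only.
    """
    n = a.size
    width = 2 * band + 1
    neg = -1e18
    m_prev = np.full(width, neg)
    x_prev = np.full(width, neg)   # gap in b (consuming a)
    y_prev = np.full(width, neg)   # gap in a (consuming b)
    m_cur = np.full(width, neg)
    x_cur = np.full(width, neg)
    y_cur = np.full(width, neg)
    # row i = 0: only insertions in b (j = 1..band)
    for j in range(0, band + 1):
        k = j + band  # offset j - i + band with i = 0
        if j == 0:
            m_prev[k] = 0.0
        else:
            y_prev[k] = open_gap + (j - 1) * extend_gap
    for i in range(1, n + 1):
        for k in range(width):
            m_cur[k] = neg
            x_cur[k] = neg
            y_cur[k] = neg
        lo = max(i - band, 0)
        hi = min(i + band, n)
        for j in range(lo, hi + 1):
            k = j - i + band
            # X: consume a[i-1] against a gap (same j, previous i -> k+1)
            if k + 1 < width:
                best = m_prev[k + 1] + open_gap
                alt = x_prev[k + 1] + extend_gap
                if alt > best:
                    best = alt
                alt = y_prev[k + 1] + open_gap
                if alt > best:
                    best = alt
                x_cur[k] = best
            # Y: consume b[j-1] against a gap (same i, previous j -> k-1)
            if j >= 1 and k - 1 >= 0:
                best = m_cur[k - 1] + open_gap
                alt = y_cur[k - 1] + extend_gap
                if alt > best:
                    best = alt
                alt = x_cur[k - 1] + open_gap
                if alt > best:
                    best = alt
                y_cur[k] = best
            # M: consume both (previous i and j -> same k)
            if j >= 1:
                best = m_prev[k]
                if x_prev[k] > best:
                    best = x_prev[k]
                if y_prev[k] > best:
                    best = y_prev[k]
                if best > neg / 2:
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    m_cur[k] = best + s
        for k in range(width):
            m_prev[k] = m_cur[k]
            x_prev[k] = x_cur[k]
            y_prev[k] = y_cur[k]
    k = n - n + band
    best = m_prev[k]
    if x_prev[k] > best:
        best = x_prev[k]
    if y_prev[k] > best:
        best = y_prev[k]
    return best


def optimal_global_score(a: str, b: str) -> float:
    """Optimal global alignment score under the module's scoring scheme.

    Equal-length pairs use the certified banded DP; otherwise Biopython.
    """
    if len(a) == len(b):
        xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
        xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
        d = int((xa != xb).sum())
        if d == 0:
            return float(len(a)) * MATCH_SCORE
        band = max(4, -(-(2 * d - 5) // 3))
        if band < len(a):
            return float(
                _banded_global_score(
                    xa, xb, band, MATCH_SCORE, MISMATCH_SCORE, OPEN_GAP_SCORE, EXTEND_GAP_SCORE
                )
            )
    return float(_GLOBAL_ALIGNER.score(a, b))


def _identity_from_alignment(alignment: Align.Alignment, identity_def: IdentityDefinition) -> float:
    counts = alignment.counts()
    matches = counts.identities
    length = alignment.length
    if identity_def.mode is IdentityMode.IGNORE_TERMINAL_GAPS:
        length -= counts.left_gaps + counts.right_gaps
    if length <= 0:
        return 0.0
    return matches / length


def pairwise_identity(
    a: str,
    b: str,
    identity_def: IdentityDefinition = DEFAULT_IDENTITY,
) -> float:
    """Identity fraction of an optimal global alignment of ``a`` and ``b``.

    Symmetric in its arguments; 1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if len(a) == len(b):
        d = hamming_mismatches(a, b)
        if d <= 2:
            # ungapped alignment provably optimal; no terminal gaps
            return (len(a) - d) / len(a)
        ungapped_score = len(a) - 2 * d
        if optimal_global_score(a, b) <= ungapped_score:
            # the ungapped alignment is optimal; use it (deterministic
            # tie-break) — no terminal gaps, so both modes agree
            return (len(a) - d) / len(a)
    alignment = _GLOBAL_ALIGNER.align(a, b)[0]
    return _identity_from_alignment(alignment, identity_def)


class IdentityCache:
    """Memoised symmetric identity lookups keyed by record id.

    A threshold sweep re-queries the same pairs at every threshold; the
    cache makes the sweep cost proportional to the number of *distinct*
    pairs inspected.
    """

    def __init__(self, identity_def: IdentityDefinition = DEFAULT_IDENTITY):
        self.identity_def = identity_def
        self._store: dict[tuple[str, str], float] = {}

    def identity(self, id_a: str, seq_a: str, id_b: str, seq_b: str) -> float:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        hit = self._store.get(key)
        if hit is None:
            hit = pairwise_identity(seq_a, seq_b, self.identity_def)
            self._store[key] = hit
        return hit

    def __len__(self) -> int:
        return len(self._store)
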