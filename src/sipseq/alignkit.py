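"""Exact pairwise alignment core with affine gaps and e-value estimation.

Implements Needleman-Wunsch (global) and Smith-Waterman (local) alignment
under Gotoh's affine-gap recurrences, for nucleotide (match/mismatch) and
protein (BLOSUM62) scoring. A run of k gap columns scores
``-(gap_open + k*gap_extend)``. Traceback is deterministic with tie-break
order diagonal > up > left (up = gap in the subject, consuming the query).

Significance of local hits is estimated with the Karlin-Altschul formula
E = K*m*n*exp(-lambda*score) using standard published parameters for the
default scoring schemes; these are not bit-identical to BLAST's internal
estimates, so e-values here are thresholds, not reproductions.

Database-scale searches (a read or genome fragment against a long target)
first locate the best candidate window with a fast banded edit-distance
scan (edlib, infix mode) and then run the exact affine DP inside that
window; scores, identities and e-values always come from the exact DP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from numba import njit

import edlib

__all__ = [
    "ScoringScheme",
    "Alignment",
    "global_align",
    "local_align",
    "best_local_nt",
    "evalue",
    "percent_identity",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "hits_to_tsv",
]

NEG_INF = np.iinfo(np.int64).min // 4

#: Karlin-Altschul (lambda, K) defaults: gapped nucleotide +1/-2 and
#: gapped BLOSUM62 protein search (standard published values).
KARLIN_NT = (1.33, 0.621)
KARLIN_PROT = (0.267, 0.041)


@dataclass(frozen=True)
class ScoringScheme:
    kind: str = "nucleotide"  # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -2
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self):
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    @property
    def alphabet(self) -> str:
        if self.kind == "nucleotide":
            return "ACGT"
        return str(_blosum(self.matrix_name).alphabet)

    @property
    def karlin(self):
        """(lambda, K) for e-value estimation under this scheme."""
        return KARLIN_NT if self.kind == "nucleotide" else KARLIN_PROT

    def score_matrix(self) -> np.ndarray:
        if self.kind == "nucleotide":
            n = 4
            mat = np.full((n, n), self.mismatch, dtype=np.int64)
            np.fill_diagonal(mat, self.match)
            return mat
        return np.asarray(_blosum(self.matrix_name), dtype=np.int64)

    def encode(self, seq: str) -> np.ndarray:
        alpha = self.alphabet
        lut = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate(alpha):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out = lut[codes]
        if (out < 0).any():
            bad = sorted({seq[i] for i in np.nonzero(out < 0)[0]})
            raise ValueError(f"illegal residue(s) {bad} for {self.kind} alphabet")
        return out.astype(np.int8)


@lru_cache(maxsize=4)
def _blosum(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class Alignment:
    """One pairwise alignment with BLAST-style summary statistics.

    Spans are 0-based half-open on the given strand of the subject.
    ``identity_pct`` uses all alignment columns (BLAST convention);
    :func:`percent_identity` recomputes it in either mode.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    matches: int
    mismatches: int
    gap_columns: int
    gap_opens: int
    identity_pct: float
    mode: str  # "global" | "local"
    strand: str = "+"
    evalue: float | None = None

    @property
    def length(self) -> int:
        return self.matches + self.mismatches + self.gap_columns


# ---------------------------------------------------------------------------
# Gotoh dynamic programming (numba kernels)
# ---------------------------------------------------------------------------
# State matrices: M (last column aligned residue/residue), IU (gap in
# subject: "up", consumes query), IL (gap in query: "left", consumes
# subject). Pointer codes: 0 = stop/start, 1 = from M, 2 = from IU,
# 3 = from IL (for M: predecessor of the diagonal step; for IU/IL:
# 1 = gap opened from M, 2/3 = gap extended).


@njit(cache=True)
def _gotoh_fill(a, b, S, gap_open, gap_extend, local):
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    IU = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    IL = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pU = np.zeros((m + 1, n + 1), dtype=np.int8)
    pL = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0
    if not local:
        for i in range(1, m + 1):
            IU[i, 0] = -(gap_open + i * gap_extend)
            pU[i, 0] = 1 if i == 1 else 2
        for j in range(1, n + 1):
            IL[0, j] = -(gap_open + j * gap_extend)
            pL[0, j] = 1 if j == 1 else 3
    else:
        for i in range(m + 1):
            M[i, 0] = 0
        for j in range(n + 1):
            M[0, j] = 0
    for i in range(1, m + 1):
        if local:
            M[i, 0] = 0
        for j in range(1, n + 1):
            # IU: gap in subject (consume a_i)
            open_u = M[i - 1, j] - gap_open - gap_extend
            ext_u = IU[i - 1, j] - gap_extend
            if open_u >= ext_u:
                IU[i, j] = open_u
                pU[i, j] = 1
            else:
                IU[i, j] = ext_u
                pU[i, j] = 2
            # IL: gap in query (consume b_j)
            open_l = M[i, j - 1] - gap_open - gap_extend
            ext_l = IL[i, j - 1] - gap_extend
            if open_l >= ext_l:
                IL[i, j] = open_l
                pL[i, j] = 1
            else:
                IL[i, j] = ext_l
                pL[i, j] = 3
            # M: diagonal step; tie-break M > IU > IL
            best = M[i - 1, j - 1]
            ptr = 1
            if IU[i - 1, j - 1] > best:
                best = IU[i - 1, j - 1]
                ptr = 2
            if IL[i - 1, j - 1] > best:
                best = IL[i - 1, j - 1]
                ptr = 3
            s = best + S[a[i - 1], b[j - 1]]
            if local and s < 0:
                M[i, j] = 0
                pM[i, j] = 0
            else:
                M[i, j] = s
                pM[i, j] = ptr
    return M, IU, IL, pM, pU, pL


@njit(cache=True)
def _local_argmax(M):
    best = np.int64(0)
    bi, bj = 0, 0
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    return best, bi, bj


def _traceback(a, b, mats, start_state, i, j, local):
    """Walk pointers back from (i, j); returns counts and query/subject spans.

    In local mode the walk stops on reaching a fresh-start M cell
    (pointer 0); in global mode it terminates at the (0, 0) corner.
    """
    _M, _IU, _IL, pM, pU, pL = mats
    matches = mismatches = gap_columns = gap_opens = 0
    state = start_state
    end_i, end_j = i, j
    while True:
        if state == 1:  # M: diagonal step into (i, j)
            if (i == 0 and j == 0) or pM[i, j] == 0:
                break
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == 2:  # IU: gap column consuming the query
            gap_columns += 1
            if pU[i, j] == 1:
                gap_opens += 1
                state = 1
            i -= 1
        elif state == 3:  # IL: gap column consuming the subject
            gap_columns += 1
            if pL[i, j] == 1:
                gap_opens += 1
                state = 1
            j -= 1
        else:
            break
    return matches, mismatches, gap_columns, gap_opens, i, j, end_i, end_j


def _finish(query_id, subject_id, a, b, scheme, mats, score, state, i, j, mode, strand):
    matches, mismatches, gaps, gap_opens, qs, ss, qe, se = _traceback(
        a, b, mats, state, i, j, mode == "local"
    )
    length = matches + mismatches + gaps
    ident = 100.0 * matches / length if length else 0.0
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        score=int(score),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        gap_opens=gap_opens,
        identity_pct=ident,
        mode=mode,
        strand=strand,
    )


def global_align(a: str, b: str, scheme: ScoringScheme = ScoringScheme(), query_id="query", subject_id="subject") -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment under affine gaps."""
    if not a or not b:
        raise ValueError("global alignment requires non-empty sequences")
    ea, eb = scheme.encode(a), scheme.encode(b)
    S = scheme.score_matrix()
    mats = _gotoh_fill(ea, eb, S, scheme.gap_open, scheme.gap_extend, False)
    M, IU, IL = mats[0], mats[1], mats[2]
    m, n = len(ea), len(eb)
    # tie-break M > IU > IL at the terminal cell
    score, state = M[m, n], 1
    if IU[m, n] > score:
        score, state = IU[m, n], 2
    if IL[m, n] > score:
        score, state = IL[m, n], 3
    return _finish(query_id, subject_id, ea, eb, scheme, mats, score, state, m, n, "global", "+")


def local_align(a: str, b: str, scheme: ScoringScheme = ScoringScheme(), query_id="query", subject_id="subject") -> Alignment:
    """Optimal local (Smith-Waterman) alignment; empty alignment scores 0.

    The maximal cell is chosen deterministically (first in row-major
    order among co-optimal cells).
    """
    if not a or not b:
        raise ValueError("local alignment requires non-empty sequences")
    ea, eb = scheme.encode(a), scheme.encode(b)
    S = scheme.score_matrix()
    mats = _gotoh_fill(ea, eb, S, scheme.gap_open, scheme.gap_extend, True)
    score, bi, bj = _local_argmax(mats[0])
    if score <= 0:
        return Alignment(query_id, subject_id, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, "local", "+")
    return _finish(query_id, subject_id, ea, eb, scheme, mats, score, 1, bi, bj, "local", "+")


# ---------------------------------------------------------------------------
# Windowed database search
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def best_local_nt(
    query: str,
    target: str,
    scheme: ScoringScheme = ScoringScheme(),
    both_strands: bool = True,
    margin: int = 80,
    query_id="query",
    subject_id="subject",
) -> Alignment:
    """Best local alignment of a nucleotide query against a long target.

    The candidate window on each strand is located with a fast infix
    edit-distance scan (the whole query placed anywhere in the target),
    padded by ``margin`` bp, and scored with the exact affine DP. Subject
    coordinates refer to the forward target strand origin of the scanned
    strand; ``strand`` records which strand matched.
    """
    candidates = []
    strands = [("+", target)]
    if both_strands:
        strands.append(("-", reverse_complement(target)))
    for strand, t in strands:
        if len(t) <= len(query) + 2 * margin:
            aln = local_align(query, t, scheme, query_id, subject_id)
            candidates.append(replace(aln, strand=strand))
            continue
        hit = edlib.align(query.upper(), t.upper(), mode="HW", task="locations")
        loc = hit["locations"][0]
        lo = max(0, (loc[0] or 0) - margin)
        hi = min(len(t), loc[1] + 1 + margin)
        aln = local_align(query, t[lo:hi], scheme, query_id, subject_id)
        candidates.append(replace(aln, s_start=aln.s_start + lo, s_end=aln.s_end + lo, strand=strand))
    # deterministic: prefer higher score, then '+' strand
    candidates.sort(key=lambda x: (-x.score, x.strand))
    return candidates[0]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def evalue(score: float, m: int, n: int, params=KARLIN_NT) -> float:
    """Karlin-Altschul expected number of chance hits: K*m*n*exp(-lambda*s)."""
    lam, K = params
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return float(K * m * n * np.exp(-lam * score))


def with_evalue(aln: Alignment, m: int, n: int, scheme: ScoringScheme) -> Alignment:
    return replace(aln, evalue=evalue(aln.score, m, n, scheme.karlin))


def percent_identity(aln: Alignment, mode: str = "all_columns") -> float:
    """Identity % over all columns (BLAST-style) or ungapped columns only."""
    if aln.length == 0:
        raise ValueError("identity undefined for an empty alignment")
    if mode == "all_columns":
        return 100.0 * aln.matches / aln.length
    if mode == "ungapped_columns":
        pairs = aln.matches + aln.mismatches
        if pairs == 0:
            raise ValueError("identity undefined: no residue-residue columns")
        return 100.0 * aln.matches / pairs
    raise ValueError(f"unknown identity mode {mode!r}")


# ---------------------------------------------------------------------------
# FASTA and tabular IO
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """FASTA file -> {id: uppercase sequence} (lowercase tolerated)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    """Write sequences wrapped at 60 columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


def hits_to_tsv(alignments, path) -> None:
    """Write hits in a 12-column tabular layout (BLAST outfmt-6 order).

    Coordinates are converted to 1-based inclusive; the score column holds
    the raw alignment score.
    """
    with open(path, "w") as fh:
        for a in alignments:
            ev = a.evalue if a.evalue is not None else float("nan")
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id,
                        a.subject_id,
                        f"{a.identity_pct:.2f}",
                        a.length,
                        a.mismatches,
                        a.gap_opens,
                        a.q_start + 1,
                        a.q_end,
                        a.s_start + 1,
                        a.s_end,
                        f"{ev:.2e}",
                        a.score,
                    )
                )
                + "\n"
            )
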