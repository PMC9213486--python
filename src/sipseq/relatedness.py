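"""Genome and proteome relatedness: fragment ANI, RBH-AAI, TETRA signatures.

Three relatedness indices widely used for species delineation:

* **ANI** — the query genome is cut into consecutive ~1020 bp fragments,
  each locally aligned (both strands) against the other genome; fragments
  aligning at >= 30 % identity over >= 70 % of their length contribute, and
  ANI is the mean identity of contributing fragments, symmetrised over
  both directions (the JSpecies fragment convention).
* **AAI** — mean identity over reciprocal best hits (RBH) between two
  proteomes under local protein alignment.
* **TETRA** — Pearson correlation of 256-component tetranucleotide z-score
  signatures against a maximal-order (trinucleotide) Markov expectation,
  counted on both strands.

Species cut-offs follow common practice: 95 % ANI, ~70 % AAI. The module
also hosts the MAG quality filter (completeness > 70 %, contamination
< 5 %, both strict) and single-linkage dereplication retaining the best
MAG per cluster (score = completeness - 5 x contamination).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignkit
from .alignkit import Alignment, ScoringScheme

__all__ = [
    "GenomeRecord",
    "RelatednessResult",
    "SpeciesCall",
    "ani",
    "aai",
    "tetra",
    "tetra_correlation",
    "same_species",
    "quality_filter",
    "quality_report",
    "dereplicate",
    "DereplicationResult",
    "read_metadata",
]

NT_SCHEME = ScoringScheme(kind="nucleotide")
PROT_SCHEME = ScoringScheme(kind="protein")


@dataclass
class GenomeRecord:
    """A genome or MAG: contigs plus optional proteome and quality metadata."""

    id: str
    contigs: dict = field(default_factory=dict)  # name -> nucleotide sequence
    proteome: dict | None = None  # name -> protein sequence
    completeness: float | None = None  # %
    contamination: float | None = None  # %

    def __post_init__(self):
        if self.completeness is not None and not 0 <= self.completeness <= 100:
            raise ValueError("completeness must lie in [0, 100]")
        if self.contamination is not None and self.contamination < 0:
            raise ValueError("contamination must be >= 0")

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def score(self) -> float:
        """dRep-style quality score used to pick cluster representatives."""
        if self.completeness is None or self.contamination is None:
            raise ValueError(f"{self.id}: quality metadata missing")
        return self.completeness - 5.0 * self.contamination


@dataclass
class RelatednessResult:
    a: str
    b: str
    ani: float | None = None
    ani_fragments_used: int = 0
    aai: float | None = None
    rbh_count: int = 0
    tetra_r: float | None = None
    reason: str | None = None


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def _fragments(genome: GenomeRecord, fragment_bp: int, min_tail: int = 100):
    """Consecutive per-contig fragments; tails shorter than min_tail dropped."""
    for name, seq in genome.contigs.items():
        for k in range(0, len(seq), fragment_bp):
            frag = seq[k : k + fragment_bp]
            if len(frag) >= min_tail:
                yield f"{name}:{k}", frag


def _directional_ani(a: GenomeRecord, b: GenomeRecord, fragment_bp, min_identity, min_coverage):
    identities = []
    for frag_id, frag in _fragments(a, fragment_bp):
        best: Alignment | None = None
        for cname, contig in b.contigs.items():
            aln = alignkit.best_local_nt(frag, contig, NT_SCHEME, query_id=frag_id, subject_id=cname)
            if best is None or aln.score > best.score:
                best = aln
        if best is None or best.length == 0:
            continue
        coverage_pct = 100.0 * (best.q_end - best.q_start) / len(frag)
        if best.identity_pct >= min_identity and coverage_pct >= min_coverage:
            identities.append(best.identity_pct)
    return identities


def ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_bp: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_coverage: float = 70.0,
) -> RelatednessResult:
    """Symmetrised fragment-based average nucleotide identity (%)."""
    if not a.contigs or not b.contigs:
        raise ValueError("both genomes must be non-empty")
    fwd = _directional_ani(a, b, fragment_bp, min_frag_identity, min_frag_coverage)
    rev = _directional_ani(b, a, fragment_bp, min_frag_identity, min_frag_coverage)
    used = len(fwd) + len(rev)
    directional = [np.mean(v) for v in (fwd, rev) if v]
    if not directional:
        return RelatednessResult(a.id, b.id, ani=None, ani_fragments_used=0, reason="no fragment passed the identity/coverage thresholds")
    return RelatednessResult(a.id, b.id, ani=float(np.mean(directional)), ani_fragments_used=used)


# ---------------------------------------------------------------------------
# AAI (reciprocal best hits)
# ---------------------------------------------------------------------------

def aai(
    a_proteome: dict,
    b_proteome: dict,
    min_identity: float = 20.0,
    max_evalue: float = 1e-5,
    min_coverage: float = 50.0,
    ids=("a", "b"),
) -> RelatednessResult:
    """Average amino acid identity over reciprocal best hits.

    Every query's best hit (by score, ties broken by subject id) must pass
    the identity/e-value/coverage thresholds; pairs that are mutually best
    form the RBH set and AAI is their mean all-column identity. Symmetric
    in its arguments by construction.
    """
    if not a_proteome or not b_proteome:
        raise ValueError("both proteomes must be non-empty")
    n_db_a = sum(len(s) for s in a_proteome.values())
    n_db_b = sum(len(s) for s in b_proteome.values())

    # full pairwise alignment matrix serves both search directions
    alns: dict = {}
    for qa, sa in a_proteome.items():
        for qb, sb in b_proteome.items():
            alns[qa, qb] = alignkit.local_align(sa, sb, PROT_SCHEME, query_id=qa, subject_id=qb)

    def best_hits(queries, subjects, db_len, flip):
        out = {}
        for q in queries:
            cands = []
            for s in subjects:
                aln = alns[(s, q)] if flip else alns[(q, s)]
                qlen = len(queries[q])
                if aln.length == 0:
                    continue
                qspan = (aln.s_end - aln.s_start) if flip else (aln.q_end - aln.q_start)
                ev = alignkit.evalue(aln.score, qlen, db_len, PROT_SCHEME.karlin)
                if (
                    aln.identity_pct >= min_identity
                    and ev <= max_evalue
                    and qspan >= min_coverage / 100.0 * qlen
                ):
                    cands.append((aln.score, s, aln))
            if cands:
                cands.sort(key=lambda t: (-t[0], t[1]))
                out[q] = (cands[0][1], cands[0][2])
        return out

    best_ab = best_hits(a_proteome, b_proteome, n_db_b, flip=False)
    best_ba = best_hits(b_proteome, a_proteome, n_db_a, flip=True)
    rbh = [
        (qa, sb, aln)
        for qa, (sb, aln) in best_ab.items()
        if best_ba.get(sb) is not None and best_ba[sb][0] == qa
    ]
    if not rbh:
        return RelatednessResult(ids[0], ids[1], aai=None, rbh_count=0, reason="empty RBH set")
    mean_id = float(np.mean([aln.identity_pct for _, _, aln in rbh]))
    return RelatednessResult(ids[0], ids[1], aai=mean_id, rbh_count=len(rbh))


# ---------------------------------------------------------------------------
# TETRA
# ---------------------------------------------------------------------------

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _kmer_counts(genome: GenomeRecord, k: int) -> np.ndarray:
    """Both-strand k-mer counts; windows containing non-ACGT are dropped."""
    counts = np.zeros(4**k, dtype=np.float64)
    mult = 4 ** np.arange(k - 1, -1, -1)
    comp = np.array([3, 2, 1, 0])
    for seq in genome.contigs.values():
        codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = (windows >= 0).all(axis=1)
        w = windows[ok]
        if not w.size:
            continue
        idx = w @ mult
        np.add.at(counts, idx, 1.0)
        idx_rc = comp[w[:, ::-1]] @ mult
        np.add.at(counts, idx_rc, 1.0)
    return counts


def tetra(genome: GenomeRecord, warn_below_bp: int = 10_000) -> np.ndarray:
    """256-component tetranucleotide z-score signature (Teeling-style).

    The expected count of tetramer n1n2n3n4 under a maximal-order Markov
    model is c(n1n2n3)*c(n2n3n4)/c(n2n3); z-scores standardise the
    observed both-strand counts against that expectation.
    """
    if genome.length < warn_below_bp:
        import warnings

        warnings.warn(f"{genome.id}: {genome.length} bp is short for a stable TETRA signature", stacklevel=2)
    c4 = _kmer_counts(genome, 4)
    c3 = _kmer_counts(genome, 3)
    c2 = _kmer_counts(genome, 2)
    z = np.zeros(256)
    for idx in range(256):
        n1, n2, n3, n4 = idx >> 6 & 3, idx >> 4 & 3, idx >> 2 & 3, idx & 3
        left = c3[(n1 << 4) | (n2 << 2) | n3]
        right = c3[(n2 << 4) | (n3 << 2) | n4]
        mid = c2[(n2 << 2) | n3]
        if mid == 0:
            continue
        exp = left * right / mid
        var = exp * (1.0 - left / mid) * (1.0 - right / mid)
        if var > 0:
            z[idx] = (c4[idx] - exp) / np.sqrt(var)
    return z


def tetra_correlation(a: GenomeRecord, b: GenomeRecord) -> float:
    """Pearson correlation of the two TETRA signatures."""
    za, zb = tetra(a), tetra(b)
    return float(np.corrcoef(za, zb)[0, 1])


# ---------------------------------------------------------------------------
# Species calls, quality filter, dereplication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesCall:
    a: str
    b: str
    ani: float | None
    aai: float | None
    ani_cutoff: float
    aai_cutoff: float
    ani_same: bool | None
    aai_same: bool | None
    same_species: bool


def same_species(result: RelatednessResult, ani_cutoff: float = 95.0, aai_cutoff: float = 70.0) -> SpeciesCall:
    """Species-boundary decision: ANI >= 95 when defined, else AAI >= 70."""
    if result.ani is None and result.aai is None:
        raise ValueError("uncallable: both ANI and AAI are undefined")
    ani_same = None if result.ani is None else result.ani >= ani_cutoff
    aai_same = None if result.aai is None else result.aai >= aai_cutoff
    verdict = ani_same if ani_same is not None else aai_same
    return SpeciesCall(result.a, result.b, result.ani, result.aai, ani_cutoff, aai_cutoff, ani_same, aai_same, bool(verdict))


def quality_filter(records, min_completeness: float = 70.0, max_contamination: float = 5.0):
    """Retain MAGs with completeness > 70 % and contamination < 5 % (strict).

    Records missing quality metadata are excluded (with a reason in
    :func:`quality_report`).
    """
    return [
        r
        for r in records
        if r.completeness is not None
        and r.contamination is not None
        and r.completeness > min_completeness
        and r.contamination < max_contamination
    ]


def quality_report(records, min_completeness: float = 70.0, max_contamination: float = 5.0) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.completeness is None or r.contamination is None:
            retained, reason = False, "missing quality metadata"
        elif r.completeness <= min_completeness:
            retained, reason = False, f"completeness <= {min_completeness}"
        elif r.contamination >= max_contamination:
            retained, reason = False, f"contamination >= {max_contamination}"
        else:
            retained, reason = True, ""
        rows.append(
            {
                "id": r.id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "retained": retained,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DereplicationResult:
    representatives: list
    clusters: list  # list of lists of ids, sorted

    @property
    def representative_ids(self):
        return [r.id for r in self.representatives]


def dereplicate(records, ani_threshold: float = 95.0, pairwise_ani=None) -> DereplicationResult:
    """Single-linkage dereplication at an ANI threshold.

    ``pairwise_ani`` may supply precomputed values as {(id_a, id_b): ANI}
    (either key order); otherwise fragment ANI is computed here. Undefined
    ANI counts as below threshold. Per cluster the highest-scoring record
    (completeness - 5*contamination, ties by id) is retained.
    """
    if not records:
        raise ValueError("no records to dereplicate")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for ra, rb in itertools.combinations(records, 2):
        if pairwise_ani is not None:
            val = pairwise_ani.get((ra.id, rb.id), pairwise_ani.get((rb.id, ra.id)))
        else:
            val = ani(ra, rb).ani
        if val is not None and val >= ani_threshold:
            union(ra.id, rb.id)

    by_id = {r.id: r for r in records}
    clusters: dict = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    reps, members = [], []
    for root in sorted(clusters):
        group = sorted(clusters[root])
        best = min(group, key=lambda g: (-by_id[g].score, g))
        reps.append(by_id[best])
        members.append(group)
    return DereplicationResult(reps, members)


def read_metadata(path) -> pd.DataFrame:
    """Read a MAG quality table TSV (id, completeness, contamination)."""
    return pd.read_csv(path, sep="\t")
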