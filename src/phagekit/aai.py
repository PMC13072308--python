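"""Pairwise proteome average amino-acid identity (AAI).

AAI between two proteomes is the mean percent identity over their
reciprocal-best-hit (RBH) ortholog pairs: protein p in proteome A and q in
B are orthologs when q is p's best-scoring local alignment in B, p is q's
best in A, and the hit passes the identity and coverage filters in both
directions. Alignments are Smith-Waterman local alignments under BLOSUM62
with BLAST-convention affine gaps (a gap of length L costs
``open + L * extend``, default 11 + L).

Default filters mirror standard AAI workflows: minimum 30% identity over
aligned columns, alignment length at least 70% of the query length (applied
with each protein of the pair as query), and a minimum raw alignment score
(default 50 BLOSUM62 units) standing in for an e-value cutoff.

Mean AAI is the unweighted mean over ortholog pairs. The relationship tiers
used for species delineation: AAI above 95% indicates a conspecific pair,
below 60% distinct species, in between a related pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import require

__all__ = [
    "ProteinRecord",
    "AlignmentHit",
    "OrthologPair",
    "AAIResult",
    "make_aligner",
    "align_pair",
    "reciprocal_best_hits",
    "mean_aai",
    "classify_aai",
    "aai_matrix",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier and uppercase amino-acid sequence (20 letters + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        require(len(self.sequence) > 0, f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALLOWED
        require(not bad, f"protein {self.id!r} has invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query against a subject."""

    query_id: str
    subject_id: str
    identity: float  # percent identical columns over aligned columns
    align_len: int  # aligned columns, gaps included
    query_cover: float  # align_len / query length
    score: float


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best hit that passed all filters in both directions."""

    id_a: str
    id_b: str
    identity: float
    align_len: int
    score: float


@dataclass(frozen=True)
class AAIResult:
    """Per-genome-pair AAI summary.

    ``mean_aai`` is NaN (with ``undefined=True``, tier ``"unresolved"``)
    when no ortholog pair survives the filters.
    """

    genome_a: str
    genome_b: str
    mean_aai: float
    ortholog_count: int
    orthologous_fraction: float
    tier: str
    undefined: bool = False


def make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    """Local BLOSUM62 aligner; a gap of length L costs ``gap_open + L*gap_extend``."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    query: ProteinRecord,
    subject: ProteinRecord,
    aligner: PairwiseAligner | None = None,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of *query* against *subject*.

    Identity is the percentage of identical columns over all aligned
    columns (gap columns included, BLAST-style); ``query_cover`` is the
    alignment length as a fraction of the query length.
    """
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(query.sequence, subject.sequence)[0]
    counts = alignment.counts()
    n_cols = alignment.length
    identity = 100.0 * counts.identities / n_cols if n_cols else 0.0
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity=identity,
        align_len=int(n_cols),
        query_cover=n_cols / len(query),
        score=float(alignment.score),
    )


def _best_hits(
    queries: list[ProteinRecord],
    subjects: list[ProteinRecord],
    aligner: PairwiseAligner,
    score_cache: dict[tuple[str, str], float],
) -> dict[str, AlignmentHit]:
    """Best subject per query by score; ties broken by identity then subject id."""
    best: dict[str, AlignmentHit] = {}
    for q in queries:
        scores = []
        for s in subjects:
            pair = (q.id, s.id)
            if pair not in score_cache:
                sc = float(aligner.score(q.sequence, s.sequence))
                score_cache[pair] = sc
            scores.append(score_cache[pair])
        top = max(scores)
        candidates = [s for s, sc in zip(subjects, scores) if sc == top]
        hits = [align_pair(q, s, aligner) for s in candidates]
        hits.sort(key=lambda h: (-h.identity, h.subject_id))
        best[q.id] = hits[0]
    return best


def reciprocal_best_hits(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    min_identity: float = 30.0,
    min_cover: float = 0.70,
    min_score: float = 50.0,
    cover_mode: str = "query",
    aligner: PairwiseAligner | None = None,
) -> list[OrthologPair]:
    """Ortholog pairs by reciprocal best hit under identity/coverage filters.

    A pair (p, q) is kept when q is p's best hit in B, p is q's best in A,
    and the alignment has identity >= *min_identity*, score >= *min_score*,
    and length >= *min_cover* of the query length in both directions
    (``cover_mode="query"``) or of the shorter protein (``"shorter"``).
    """
    require(bool(proteome_a) and bool(proteome_b), "proteomes must be nonempty")
    require(cover_mode in {"query", "shorter"}, "cover_mode: 'query' or 'shorter'")
    if aligner is None:
        aligner = make_aligner()
    # scores are symmetric in sequence order; one cache serves both directions
    cache: dict[tuple[str, str], float] = {}
    fwd = _best_hits(proteome_a, proteome_b, aligner, cache)
    rev_cache = {(b, a): s for (a, b), s in cache.items()}
    rev = _best_hits(proteome_b, proteome_a, aligner, rev_cache)

    len_a = {p.id: len(p) for p in proteome_a}
    len_b = {p.id: len(p) for p in proteome_b}
    pairs: list[OrthologPair] = []
    for pid, hit in fwd.items():
        qid = hit.subject_id
        if rev[qid].subject_id != pid:
            continue
        if hit.score < min_score or hit.identity < min_identity:
            continue
        if cover_mode == "query":
            covered = (
                hit.align_len >= min_cover * len_a[pid]
                and hit.align_len >= min_cover * len_b[qid]
            )
        else:
            covered = hit.align_len >= min_cover * min(len_a[pid], len_b[qid])
        if not covered:
            continue
        pairs.append(
            OrthologPair(
                id_a=pid,
                id_b=qid,
                identity=hit.identity,
                align_len=hit.align_len,
                score=hit.score,
            )
        )
    pairs.sort(key=lambda p: p.id_a)
    return pairs


def classify_aai(mean_aai: float) -> str:
    """Species-delineation tier: conspecific (>95), distinct (<60), else related."""
    if np.isnan(mean_aai):
        return "unresolved"
    require(0 <= mean_aai <= 100, "mean AAI must lie in [0, 100]")
    if mean_aai > 95:
        return "conspecific"
    if mean_aai < 60:
        return "distinct"
    return "related"


def mean_aai(
    pairs: list[OrthologPair],
    genome_a: str,
    genome_b: str,
    size_a: int,
    size_b: int,
) -> AAIResult:
    """Unweighted mean identity over ortholog pairs, with orthologous fraction.

    The orthologous fraction is the pair count over the smaller proteome
    size. With zero pairs the AAI is undefined (NaN, tier "unresolved"),
    never reported as 0.
    """
    require(size_a > 0 and size_b > 0, "proteome sizes must be positive")
    count = len(pairs)
    fraction = count / min(size_a, size_b)
    if count == 0:
        warnings.warn(
            f"no ortholog pairs between {genome_a!r} and {genome_b!r}; AAI undefined",
            stacklevel=2,
        )
        return AAIResult(genome_a, genome_b, float("nan"), 0, 0.0, "unresolved", True)
    value = float(np.mean([p.identity for p in pairs]))
    return AAIResult(genome_a, genome_b, value, count, fraction, classify_aai(value))


def aai_matrix(
    proteomes: list[tuple[str, list[ProteinRecord]]],
    min_identity: float = 30.0,
    min_cover: float = 0.70,
    min_score: float = 50.0,
    cover_mode: str = "query",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], AAIResult]]:
    """All-vs-all AAI over labelled proteomes.

    Each unordered pair is computed once and mirrored, so the matrix is
    symmetric by construction; the diagonal is 100. Returns the AAI matrix,
    the ortholog-count matrix, and the per-pair results keyed by sorted
    label pair.
    """
    labels = [label for label, _ in proteomes]
    require(len(labels) >= 2, "need at least two proteomes")
    require(len(set(labels)) == len(labels), f"duplicate genome labels in {labels}")
    aligner = make_aligner()
    aai = pd.DataFrame(100.0, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    by_label = dict(proteomes)
    for label in labels:
        counts.loc[label, label] = len(by_label[label])
    results: dict[tuple[str, str], AAIResult] = {}
    for (la, pa), (lb, pb) in combinations(proteomes, 2):
        pairs = reciprocal_best_hits(
            pa, pb, min_identity, min_cover, min_score, cover_mode, aligner
        )
        res = mean_aai(pairs, la, lb, len(pa), len(pb))
        results[(la, lb)] = res
        aai.loc[la, lb] = aai.loc[lb, la] = res.mean_aai
        counts.loc[la, lb] = counts.loc[lb, la] = res.ortholog_count
    return aai, counts, results


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA into protein records."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    require(bool(records), f"no sequences in {path}")
    return records


def write_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")
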