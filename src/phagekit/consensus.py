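"""Multi-tool gene-prediction consensus.

Different gene callers routinely disagree on the start codon of a gene
(5' end) while agreeing on its stop codon, which is fixed by the reading
frame. Two calls are therefore treated as the same gene when they share
strand and 3' coordinate: the ``stop`` field for + strand calls and the
``start`` field for - strand calls. On circular genomes a call spanning the
origin is keyed by its 3' coordinate reduced modulo the genome length, so a
wrapped call and its linearized equivalent match.

Given one prediction set per tool, the module computes:

* the k-of-N consensus (a gene is high-confidence when called by >= k of the
  N tools; k defaults to 4 of 7) and the consensus rate, the consensus count
  as a percentage of the union of all keys;
* the pairwise Jaccard concordance matrix |A n B| / |A u B|;
* exclusive intersection counts over every nonempty tool subset (the numbers
  an UpSet plot displays), which partition the union;
* per-tool unique-prediction counts (the singleton regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import require, round_half_up

__all__ = [
    "GeneCall",
    "PredictionSet",
    "ConsensusResult",
    "match_key",
    "consensus",
    "jaccard_matrix",
    "upset_intersections",
    "unique_predictions",
    "read_gff",
    "write_gff",
]


@dataclass(frozen=True)
class GeneCall:
    """One CDS call: 1-based inclusive coordinates and strand.

    ``wraps_origin`` marks calls on circular genomes that span the origin;
    such calls have ``start > stop`` in linearized coordinates.
    """

    start: int
    stop: int
    strand: str
    source_tool: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        require(self.start >= 1, "coordinates are 1-based: start >= 1")
        require(self.stop >= 1, "coordinates are 1-based: stop >= 1")
        require(self.strand in {"+", "-"}, f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps_origin:
            require(self.start <= self.stop, "start > stop requires wraps_origin=True")


@dataclass(frozen=True)
class PredictionSet:
    """All gene calls from one tool on one genome."""

    tool: str
    genome_id: str
    genome_length: int
    topology: str
    calls: tuple[GeneCall, ...]

    def __post_init__(self) -> None:
        require(self.genome_length >= 1, "genome_length must be positive")
        require(
            self.topology in {"circular", "linear"},
            f"topology must be 'circular' or 'linear', got {self.topology!r}",
        )
        object.__setattr__(self, "calls", tuple(self.calls))
        seen = set()
        for c in self.calls:
            require(
                1 <= c.start <= self.genome_length and 1 <= c.stop <= self.genome_length,
                f"call {c.start}..{c.stop} outside genome of length {self.genome_length}",
            )
            if c.wraps_origin:
                require(
                    self.topology == "circular",
                    "wrap-around calls are only valid on circular genomes",
                )
            key = match_key(c, self.genome_length, self.topology)
            require(key not in seen, f"duplicate call key {key} in tool {self.tool!r}")
            seen.add(key)

    def keys(self) -> frozenset[tuple[str, int]]:
        """Match keys of all calls."""
        return frozenset(match_key(c, self.genome_length, self.topology) for c in self.calls)


def match_key(
    call: GeneCall, genome_length: int, topology: str
) -> tuple[str, int]:
    """Gene identity key: strand plus 3' coordinate.

    The 3' end is ``stop`` on the + strand and ``start`` on the - strand.
    On circular genomes the coordinate is reduced modulo the genome length
    so origin-spanning calls match their linearized equivalents.
    """
    if call.wraps_origin:
        require(topology == "circular", "linear genomes cannot hold wrap-around calls")
    three_prime = call.stop if call.strand == "+" else call.start
    if topology == "circular":
        three_prime = (three_prime - 1) % genome_length + 1
    return (call.strand, int(three_prime))


@dataclass(frozen=True)
class ConsensusResult:
    """k-of-N consensus with concordance metrics.

    ``intersections`` maps each nonempty tool subset (sorted tuple of tool
    names) to the count of keys present in exactly those tools; the counts
    partition the union of all keys.
    """

    k: int
    n_tools: int
    consensus_genes: tuple[dict, ...]
    union_size: int
    consensus_rate: float
    jaccard: pd.DataFrame
    intersections: dict[tuple[str, ...], int]
    unique_counts: dict[str, int]
    tools: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_tools": self.n_tools,
            "union_size": self.union_size,
            "consensus_size": len(self.consensus_genes),
            "consensus_rate": self.consensus_rate,
            "consensus_genes": list(self.consensus_genes),
            "jaccard": self.jaccard.to_dict(),
            "intersections": {" & ".join(k): v for k, v in self.intersections.items()},
            "unique_counts": dict(self.unique_counts),
        }


def _key_memberships(sets: list[PredictionSet]) -> dict[tuple[str, int], set[str]]:
    """Map every match key in the union to the set of tools calling it."""
    members: dict[tuple[str, int], set[str]] = {}
    for ps in sets:
        for key in ps.keys():
            members.setdefault(key, set()).add(ps.tool)
    return members


def _validate_sets(sets: list[PredictionSet]) -> None:
    require(len(sets) >= 2, "need at least two prediction sets")
    genome_ids = {ps.genome_id for ps in sets}
    require(len(genome_ids) == 1, f"mixed genome ids: {sorted(genome_ids)}")
    tools = [ps.tool for ps in sets]
    require(len(set(tools)) == len(tools), "duplicate tool names")


def consensus(sets: list[PredictionSet], k: int = 4) -> ConsensusResult:
    """k-of-N consensus over prediction sets plus all concordance metrics."""
    _validate_sets(sets)
    require(1 <= k <= len(sets), f"k must be in [1, {len(sets)}]")
    members = _key_memberships(sets)
    union_size = len(members)

    consensus_genes = tuple(
        {"strand": key[0], "three_prime": key[1], "tools": sorted(tools)}
        for key, tools in sorted(members.items())
        if len(tools) >= k
    )
    rate = (
        round_half_up(100.0 * len(consensus_genes) / union_size, 1) if union_size else 0.0
    )
    return ConsensusResult(
        k=k,
        n_tools=len(sets),
        consensus_genes=consensus_genes,
        union_size=union_size,
        consensus_rate=rate,
        jaccard=jaccard_matrix(sets),
        intersections=upset_intersections(sets),
        unique_counts=unique_predictions(sets),
        tools=tuple(ps.tool for ps in sets),
    )


def jaccard_matrix(sets: list[PredictionSet]) -> pd.DataFrame:
    """Pairwise Jaccard index |A n B| / |A u B| over match keys.

    A pair of empty sets is perfectly concordant by convention (J = 1,
    with a warning, since the ratio is 0/0).
    """
    _validate_sets(sets)
    tools = [ps.tool for ps in sets]
    keysets = {ps.tool: ps.keys() for ps in sets}
    mat = pd.DataFrame(np.eye(len(tools)), index=tools, columns=tools)
    for a, b in combinations(tools, 2):
        union = keysets[a] | keysets[b]
        if not union:
            warnings.warn(
                f"tools {a!r} and {b!r} both predict no genes; Jaccard set to 1",
                stacklevel=2,
            )
            j = 1.0
        else:
            j = len(keysets[a] & keysets[b]) / len(union)
        mat.loc[a, b] = mat.loc[b, a] = j
    return mat


def upset_intersections(sets: list[PredictionSet]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts over every nonempty tool subset.

    The value for subset S is the number of keys present in exactly the
    tools of S (no others) — the bar heights of an UpSet plot. Counts over
    all 2^N - 1 subsets sum to the union size.
    """
    _validate_sets(sets)
    tools = [ps.tool for ps in sets]
    members = _key_memberships(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(tools) + 1):
        for combo in combinations(tools, r):
            counts[tuple(sorted(combo))] = 0
    for tool_set in members.values():
        counts[tuple(sorted(tool_set))] += 1
    return counts


def unique_predictions(sets: list[PredictionSet]) -> dict[str, int]:
    """Per-tool count of keys no other tool calls (UpSet singleton regions)."""
    _validate_sets(sets)
    members = _key_memberships(sets)
    counts = {ps.tool: 0 for ps in sets}
    for tool_set in members.values():
        if len(tool_set) == 1:
            counts[next(iter(tool_set))] += 1
    return counts


def read_gff(
    path: str | Path,
    genome_length: int,
    topology: str = "linear",
    tool: str | None = None,
    genome_id: str | None = None,
) -> PredictionSet:
    """Read CDS features from a GFF3 file into a :class:`PredictionSet`.

    ``tool`` defaults to the file's stem; ``genome_id`` defaults to the
    seqid of the first CDS. Features whose coordinates fall outside
    ``[1, genome_length]`` raise a validation error. GFF3 cannot represent
    origin-spanning features as single lines, so wrap-around calls never
    come from this reader.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ValueError(f"failed to parse GFF3 file {path}: {exc}") from exc

    calls = []
    seqids = set()
    for feat in db.features_of_type("CDS", order_by="start"):
        seqids.add(feat.seqid)
        calls.append(
            GeneCall(
                start=feat.start,
                stop=feat.end,
                strand=feat.strand,
                source_tool=tool or path.stem,
            )
        )
    require(bool(calls), f"no CDS features in {path}")
    require(len(seqids) == 1, f"multiple seqids in {path}: {sorted(seqids)}")
    return PredictionSet(
        tool=tool or path.stem,
        genome_id=genome_id or next(iter(seqids)),
        genome_length=genome_length,
        topology=topology,
        calls=tuple(calls),
    )


def write_gff(pset: PredictionSet, path: str | Path) -> None:
    """Write a prediction set as GFF3 (one CDS line per call)."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(pset.calls, start=1):
        lines.append(
            "\t".join(
                [
                    pset.genome_id,
                    pset.tool,
                    "CDS",
                    str(c.start),
                    str(c.stop),
                    ".",
                    c.strand,
                    "0",
                    f"ID={pset.tool}_cds_{i}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
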