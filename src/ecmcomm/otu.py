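"""OTU delimitation: pairwise identity, single-linkage clustering at a
similarity cut-off, consensus sequences, and the genus-confidence rule.

Identity is computed from a global alignment (match +1, mismatch -1, linear
gap -2) as matches divided by aligned columns, excluding terminal-gap
columns so that reads of unequal length are not penalized at their ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ecmcomm.errors import DegenerateInputError, EmptyInputError, ValidationError
from ecmcomm.seqio import SequenceRecord, TaxonomyHits

# base-set -> IUPAC ambiguity code
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1
    aln.mismatch_score = -1
    aln.open_gap_score = -2
    aln.extend_gap_score = -2
    return aln


_ALIGNER = _aligner()


def _aligned_strings(a: str, b: str) -> tuple[str, str]:
    if a == b:
        return a, b
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _first_last_nongap(g: str) -> tuple[int, int]:
    first = len(g) - len(g.lstrip("-"))
    last = len(g.rstrip("-"))
    return first, last


def _trim_terminal_gaps(ga: str, gb: str) -> tuple[str, str]:
    """Drop columns inside either sequence's leading/trailing gap run."""
    fa, la = _first_last_nongap(ga)
    fb, lb = _first_last_nongap(gb)
    start, end = max(fa, fb), min(la, lb)
    if start >= end:
        return "", ""
    return ga[start:end], gb[start:end]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned columns between two sequences."""
    if not a or not b:
        raise EmptyInputError("pairwise_identity requires non-empty sequences")
    ga, gb = _aligned_strings(a.upper(), b.upper())
    ga, gb = _trim_terminal_gaps(ga, gb)
    if not ga:
        return 0.0
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("identity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValidationError("identity matrix diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValidationError("identity values must lie in [0,1]")


def identity_matrix(sequences: list[str], ids: list[str] | None = None) -> IdentityMatrix:
    ids = ids if ids is not None else [str(i) for i in range(len(sequences))]
    n = len(sequences)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_identity(sequences[i], sequences[j])
    return IdentityMatrix(ids=ids, values=vals)


@dataclass
class OTU:
    """A species-level cluster of sequences."""

    otu_id: str
    member_ids: list[str]
    consensus: str
    genus: str | None = None
    samples: set[str] = field(default_factory=set)


def consensus_sequence(members: list[str]) -> str:
    """Majority-rule consensus of cluster members.

    Members are pairwise-aligned to the seed (the longest member; first on
    ties).  Ties at a column yield the IUPAC ambiguity code; columns where
    the majority of members have a gap are dropped; insertions relative to
    the seed are ignored.
    """
    if not members:
        raise EmptyInputError("consensus_sequence requires at least one member")
    members = [m.upper() for m in members]
    seed = max(members, key=len)
    cols: list[list[str]] = [[] for _ in range(len(seed))]
    for mem in members:
        ga, gb = _aligned_strings(seed, mem)
        pos = 0
        for x, y in zip(ga, gb):
            if x == "-":
                continue  # insertion in member relative to seed
            cols[pos].append(y)
            pos += 1
    out: list[str] = []
    for col in cols:
        n_gap = col.count("-")
        if n_gap * 2 > len(col):
            continue
        bases = [c for c in col if c != "-"]
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, c in counts.items() if c == top)
        out.append(_IUPAC.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
    if not out:
        raise DegenerateInputError("consensus collapsed to an empty sequence")
    return "".join(out)


def cluster_otus(
    records: list[SequenceRecord],
    threshold: float = 0.95,
    precomputed: IdentityMatrix | None = None,
) -> list[OTU]:
    """Single-linkage clustering of ITS sequences at an identity threshold.

    Records are joined into one OTU iff a chain of pairs with identity >=
    threshold connects them.  OTUs are labelled in order of first appearance
    of a member in the input.  Identical residue strings are deduplicated
    before alignment, which makes clustering of resequenced morphotypes cheap.
    """
    if not records:
        raise EmptyInputError("cluster_otus requires at least one record")
    markers = {r.marker for r in records if r.marker is not None}
    if markers - {"ITS"}:
        raise ValidationError(f"cluster_otus accepts ITS records only, got {sorted(markers)}")

    uniq: dict[str, int] = {}
    member_of: list[int] = []  # record index -> unique-sequence index
    uniq_seqs: list[str] = []
    for rec in records:
        if rec.residues not in uniq:
            uniq[rec.residues] = len(uniq_seqs)
            uniq_seqs.append(rec.residues)
        member_of.append(uniq[rec.residues])

    if precomputed is not None:
        ident = precomputed
        if len(ident.ids) != len(uniq_seqs):
            raise ValidationError("precomputed identity matrix size mismatch")
    else:
        ident = identity_matrix(uniq_seqs)

    # union-find over unique sequences
    parent = list(range(len(uniq_seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(uniq_seqs)
    for i in range(n):
        for j in range(i + 1, n):
            if ident.values[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    cluster_order: dict[int, int] = {}
    groups: dict[int, list[SequenceRecord]] = {}
    for rec, ui in zip(records, member_of):
        root = find(ui)
        if root not in cluster_order:
            cluster_order[root] = len(cluster_order)
        groups.setdefault(root, []).append(rec)

    otus: list[OTU] = []
    for root, rank in sorted(cluster_order.items(), key=lambda kv: kv[1]):
        members = groups[root]
        uniq_members = sorted({m.residues for m in members})
        consensus = (
            uniq_members[0] if len(uniq_members) == 1 else consensus_sequence(
                [m.residues for m in members]
            )
        )
        otus.append(
            OTU(
                otu_id=f"OTU{rank + 1:04d}",
                member_ids=[m.id for m in members],
                consensus=consensus,
                samples={m.sample_id for m in members if m.sample_id is not None},
            )
        )
    return otus


@dataclass
class GenusAssignment:
    genus: str | None
    reason: str

    @property
    def assigned(self) -> bool:
        return self.genus is not None


def assign_genus(hits: TaxonomyHits, min_hits: int = 20) -> GenusAssignment:
    """Accept a genus iff the first ``min_hits`` hits exist and agree."""
    if len(hits.hits) < min_hits:
        return GenusAssignment(None, f"only {len(hits.hits)} hits (< {min_hits})")
    head = hits.hits[:min_hits]
    genera = set(head)
    if len(genera) == 1:
        return GenusAssignment(head[0], f"first {min_hits} hits agree")
    return GenusAssignment(None, f"first {min_hits} hits span {len(genera)} genera")
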