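"""Dereplication and abundance-sorted greedy centroid clustering of phylotypes.

Sequence identity is defined over a global (end-to-end) alignment scored
match +1 / mismatch -1 / gap -2, as matches divided by alignment columns
(terminal gaps count as columns).  Because reads are 5'-anchored prefixes of
a common amplicon, the clustering stage truncates each pair to the shorter
length before computing identity, so that read-length variation does not
masquerade as sequence divergence.

Clustering is the classic abundance-sorted greedy scan: a sequence joins the
first centroid it matches at >= threshold identity, otherwise it founds a new
centroid.  The founding sequence remains the centroid for all comparisons;
after the scan each cluster's representative is its most abundant member.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from collections.abc import Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from .readprep import TaggedRead

DEFAULT_THRESHOLD = 0.99

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identity is matches / alignment columns of the optimal global alignment
    under match +1, mismatch -1, gap -2.  Symmetric.  No length truncation
    is applied here; callers that treat sequences as prefixes of a common
    amplicon (see :func:`greedy_cluster`) truncate before calling.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if b < a:  # canonical argument order makes the result exactly symmetric
        a, b = b, a
    # Exact fast path: for equal lengths with Hamming distance d <= 2 the
    # ungapped alignment is uniquely score-optimal (a gap pair costs 4 + an
    # extra column and can only pay off when it can realign >= 3 mismatches),
    # so identity is (L - d) / L.
    if len(a) == len(b):
        d = _hamming(np.frombuffer(a.encode(), np.uint8),
                     np.frombuffer(b.encode(), np.uint8))
        if d <= 2:
            return (len(a) - d) / len(a)
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _identity_at_least(
    a: str, b: str, a_arr: np.ndarray, b_arr: np.ndarray, threshold: float
) -> bool:
    """Decide identity(a, b) >= threshold for equal-length sequences.

    Uses two sound screens before falling back to the full aligner:

    * Hamming distance d <= 2: identity is exactly (L - d) / L.
    * Levenshtein distance k (edlib): any global alignment has at least k/2
      non-match columns per aligned character, so identity <= 1 - k / (2 L);
      if that bound is below the threshold the pair cannot match.
    """
    L = len(a)
    d = _hamming(a_arr, b_arr)
    if d == 0:
        return True
    if d <= 2:
        return (L - d) / L >= threshold
    k = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    if 1.0 - k / (2.0 * L) < threshold:
        return False
    return pairwise_identity(a, b) >= threshold


@dataclasses.dataclass
class UniqueSequence:
    """An exact-string dereplicated sequence with per-library counts."""

    bases: str
    abundance: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.abundance != sum(self.counts.values()) or self.abundance < 1:
            raise ValueError("abundance must equal the sum of per-library counts (>= 1)")


@dataclasses.dataclass
class Phylotype:
    """A cluster of unique sequences at >= threshold identity.

    The representative is the most abundant member (ties broken by
    lexicographically smallest sequence); the founding centroid used during
    the greedy scan is retained separately for the membership invariant.
    """

    phylotype_id: str
    representative: str
    members: list[UniqueSequence]
    total_abundance: int
    counts: dict[str, int]
    centroid: str = ""


def dereplicate(
    reads_by_sample: Mapping[str, Sequence[TaggedRead]],
) -> list[UniqueSequence]:
    """Group identical read strings across samples, most abundant first.

    Ties in abundance are broken lexicographically by sequence so the output
    order (and everything downstream of the greedy scan) is deterministic.
    """
    per_lib: dict[str, Counter] = defaultdict(Counter)
    for sample_id, reads in reads_by_sample.items():
        for read in reads:
            per_lib[read.bases][sample_id] += 1
    uniques = [
        UniqueSequence(bases=bases, abundance=sum(c.values()), counts=dict(c))
        for bases, c in per_lib.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.bases))
    return uniques


def greedy_cluster(
    uniques: Sequence[UniqueSequence],
    threshold: float = DEFAULT_THRESHOLD,
    truncate: bool = True,
) -> list[Phylotype]:
    """Abundance-sorted greedy centroid clustering at ``threshold`` identity.

    ``uniques`` must be sorted as produced by :func:`dereplicate`.  With
    ``truncate`` (the default) each candidate/centroid pair is cut to the
    shorter of the two lengths before the identity computation, treating
    reads as 5'-anchored prefixes of the same amplicon.
    """
    centroids: list[tuple[str, np.ndarray]] = []
    clusters: list[list[UniqueSequence]] = []
    for u in uniques:
        u_arr = np.frombuffer(u.bases.encode(), np.uint8)
        hit = None
        for idx, (c_bases, c_arr) in enumerate(centroids):
            if truncate:
                L = min(len(u.bases), len(c_bases))
                a, b = u.bases[:L], c_bases[:L]
                if _identity_at_least(a, b, u_arr[:L], c_arr[:L], threshold):
                    hit = idx
                    break
            else:
                if pairwise_identity(u.bases, c_bases) >= threshold:
                    hit = idx
                    break
        if hit is None:
            centroids.append((u.bases, u_arr))
            clusters.append([u])
        else:
            clusters[hit].append(u)

    phylotypes: list[Phylotype] = []
    for members, (c_bases, _) in zip(clusters, centroids):
        rep = min(members, key=lambda m: (-m.abundance, m.bases)).bases
        counts: Counter = Counter()
        for m in members:
            counts.update(m.counts)
        phylotypes.append(
            Phylotype(
                phylotype_id="",
                representative=rep,
                members=members,
                total_abundance=sum(m.abundance for m in members),
                counts=dict(counts),
                centroid=c_bases,
            )
        )
    phylotypes.sort(key=lambda p: (-p.total_abundance, p.representative))
    width = max(3, len(str(len(phylotypes))))
    for i, p in enumerate(phylotypes, start=1):
        p.phylotype_id = f"PT{i:0{width}d}"
    return phylotypes


def validate_membership(
    phylotypes: Sequence[Phylotype],
    threshold: float = DEFAULT_THRESHOLD,
    truncate: bool = True,
) -> None:
    """Assert post hoc that every member matches its founding centroid."""
    for p in phylotypes:
        for m in p.members:
            a, b = m.bases, p.centroid
            if truncate:
                L = min(len(a), len(b))
                a, b = a[:L], b[:L]
            ident = pairwise_identity(a, b)
            if ident < threshold:
                raise AssertionError(
                    f"{p.phylotype_id}: member at identity {ident:.4f} "
                    f"< {threshold} to its centroid"
                )
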