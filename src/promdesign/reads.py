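"""Error-tolerant sequence determination from NGS reads.

Full-length reads of a sorted library are clustered so that reads deriving
from the same library member (but carrying PCR / sequencing errors) are
grouped, then reduced to a consensus by per-position plurality vote.  The
clustering sorts reads lexicographically and compares each read with the
next using a global-alignment distance; because lexicographic order hides
differences near the start of a read, the pass is repeated on the reversed
strings and clusters sharing reads are merged.  Consensus sequences are
linked to short bin-tagged counting reads through the fully randomized
35-bp key at the start of each library member.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scaffold import LibraryScaffold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment distance penalties (lower total = more similar)."""

    gap_penalty: int = 5
    mismatch_penalty: int = 1
    match_penalty: int = 0

    def __post_init__(self) -> None:
        if min(self.gap_penalty, self.mismatch_penalty, self.match_penalty) < 0:
            raise ValueError("penalties must be nonnegative")


@dataclass
class ReadCluster:
    member_read_ids: tuple[int, ...]
    member_sequences: tuple[str, ...]
    consensus: str | None = None
    rejected_reason: str = "none"  # none | singleton | no_majority


def nw_distance(s1: str, s2: str, params: AlignmentParams = AlignmentParams()) -> int:
    """Minimal global-alignment cost between two sequences.

    Needleman-Wunsch with distance semantics: 0 iff identical, symmetric.
    The inner recurrence is vectorized row-wise; the left-gap chain
    ``D[i, j] = min_k<=j (c[k] + (j - k) * gap)`` is a running minimum of
    ``c[k] - gap * k``, which keeps the whole row in numpy.
    """
    if not s1 or not s2:
        raise ValueError("sequences must be nonempty")
    if s1 == s2:
        return 0
    g, mm, ma = params.gap_penalty, params.mismatch_penalty, params.match_penalty
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    m = len(b)
    j = np.arange(m + 1, dtype=np.int64)
    prev = g * j
    for i in range(1, len(a) + 1):
        sub = np.where(b == a[i - 1], ma, mm)
        cand = np.minimum(prev[:-1] + sub, prev[1:] + g)
        arr = np.concatenate(([prev[0] + g], cand))
        cur = np.minimum.accumulate(arr - g * j) + g * j
        prev = cur
    return int(prev[-1])


def cluster_pass(
    reads: list[str],
    cutoff: int,
    params: AlignmentParams = AlignmentParams(),
    reverse: bool = False,
) -> list[list[int]]:
    """One sort-and-compare clustering pass.

    Reads are sorted lexicographically (on the reversed strings when
    ``reverse``); a cluster is a maximal run of consecutive sorted reads in
    which each adjacent pair is within ``cutoff`` alignment distance.
    Returns a partition of read indices.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    n = len(reads)
    if n == 0:
        return []
    keyed = [(reads[i][::-1] if reverse else reads[i], i) for i in range(n)]
    keyed.sort()

    def within(s1: str, s2: str) -> bool:
        if s1 == s2:
            return True
        if len(s1) == len(s2):
            # substitution-only alignment upper-bounds the optimal cost
            h = sum(a != b for a, b in zip(s1, s2))
            bound = h * params.mismatch_penalty + (len(s1) - h) * params.match_penalty
            if bound <= cutoff:
                return True
        return nw_distance(s1, s2, params) <= cutoff

    clusters: list[list[int]] = [[keyed[0][1]]]
    for (ks_prev, _), (ks, idx) in zip(keyed, keyed[1:]):
        if within(ks_prev, ks):
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def merge_passes(
    forward_clusters: list[list[int]], reverse_clusters: list[list[int]]
) -> list[list[int]]:
    """Merge two clusterings: connected components of the overlap graph.

    Both inputs must partition the same set of read ids.  Union-find over
    reads, seeded by cluster co-membership in either pass.
    """
    ids_f = sorted(i for c in forward_clusters for i in c)
    ids_r = sorted(i for c in reverse_clusters for i in c)
    if ids_f != ids_r:
        raise ValueError("cluster passes cover different read sets")

    parent: dict[int, int] = {i: i for i in ids_f}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for clusters in (forward_clusters, reverse_clusters):
        for c in clusters:
            for i in c[1:]:
                union(c[0], i)

    groups: dict[int, list[int]] = {}
    for i in ids_f:
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sorted(groups.values())]


def consensus(member_ids: list[int], member_seqs: list[str]) -> ReadCluster:
    """Per-position plurality consensus over reads of the modal length.

    Singletons are rejected; so are clusters where the modal length is tied
    or where any position lacks a unique strict-plurality winner.
    """
    if not member_seqs:
        raise ValueError("cluster is empty")
    cluster = ReadCluster(tuple(member_ids), tuple(member_seqs))
    if len(member_seqs) == 1:
        cluster.rejected_reason = "singleton"
        return cluster
    lengths: dict[int, int] = {}
    for s in member_seqs:
        lengths[len(s)] = lengths.get(len(s), 0) + 1
    best = max(lengths.values())
    modal = [ln for ln, c in lengths.items() if c == best]
    if len(modal) != 1:
        cluster.rejected_reason = "no_majority"
        return cluster
    voters = [s for s in member_seqs if len(s) == modal[0]]
    out = []
    for p in range(modal[0]):
        tally: dict[str, int] = {}
        for s in voters:
            tally[s[p]] = tally.get(s[p], 0) + 1
        top = max(tally.values())
        winners = [b for b, c in tally.items() if c == top]
        if len(winners) != 1:
            cluster.rejected_reason = "no_majority"
            return cluster
        out.append(winners[0])
    cluster.consensus = "".join(out)
    return cluster


def cluster_reads(
    reads: list[str],
    cutoff: int = 10,
    params: AlignmentParams = AlignmentParams(),
) -> list[ReadCluster]:
    """Full pipeline: forward pass, reverse pass, merge, consensus."""
    fwd = cluster_pass(reads, cutoff, params, reverse=False)
    rev = cluster_pass(reads, cutoff, params, reverse=True)
    merged = merge_passes(fwd, rev)
    return [consensus(c, [reads[i] for i in c]) for c in merged]


def link_counts(
    consensi: list[str],
    counting_reads: list[tuple[int, str]],
    n_bins: int,
    key_length: int = 35,
) -> tuple[np.ndarray, dict]:
    """Assign bin-tagged counting reads to consensus sequences by exact
    match of the first ``key_length`` bases.

    Returns an (n_consensi, n_bins) count matrix plus a tally of dropped
    reads.  Consensi sharing a key are excluded (counts stay zero) with a
    logged warning.
    """
    for s in consensi:
        if len(s) < key_length:
            raise ValueError("all consensi must be at least key_length long")
    keys: dict[str, int] = {}
    dup: set[str] = set()
    for i, s in enumerate(consensi):
        k = s[:key_length]
        if k in keys:
            dup.add(k)
        else:
            keys[k] = i
    if dup:
        logger.warning("%d duplicate %d-bp keys; affected sequences excluded", len(dup), key_length)
    counts = np.zeros((len(consensi), n_bins), dtype=int)
    dropped = {"no_match": 0, "ambiguous_key": 0}
    for b, read in counting_reads:
        k = read[:key_length]
        if k in dup:
            dropped["ambiguous_key"] += 1
        elif k in keys:
            counts[keys[k], b] += 1
        else:
            dropped["no_match"] += 1
    excluded = sorted(keys[k] for k in dup if k in keys)
    for i in excluded:
        counts[i, :] = 0
    return counts, {"dropped": dropped, "excluded_sequences": excluded}


def filter_constant_regions(seq: str, scaffold: LibraryScaffold) -> bool:
    """True iff the sequence matches every constant scaffold segment
    verbatim (length mismatches fail)."""
    return scaffold.matches_constant_regions(seq)
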