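"""Complete-linkage MOTU clustering at a fixed divergence threshold.

Validated items (variants and contigs) span different overlapping
windows of the same locus, so divergence is measured on a semi-global
pairwise alignment (end gaps free): distance = (mismatches + internal
gap bases) / aligned overlap length. Clustering is agglomerative with
complete linkage, cut so that no merge happens beyond the threshold —
every intra-MOTU pairwise distance is therefore <= threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    # free end gaps on both sequences (semi-global)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_distance(a: str, b: str, min_overlap: int = 20) -> float:
    """Divergence of two sequences on their semi-global alignment.

    (mismatches + internal gap bases) / (matches + mismatches + internal
    gap bases); end overhangs are ignored. Returns 1.0 when the aligned
    overlap is shorter than ``min_overlap``. Symmetric; d(a, a) = 0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 1.0
    matches = mismatches = gaps = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for x, y in zip(a[ts:te], b[qs:qe]):
            if x == y:
                matches += 1
            else:
                mismatches += 1
    for i in range(1, len(t_blocks)):
        gaps += t_blocks[i][0] - t_blocks[i - 1][1]
        gaps += q_blocks[i][0] - q_blocks[i - 1][1]
    overlap = matches + mismatches + gaps
    if overlap < min_overlap:
        return 1.0
    return (mismatches + gaps) / overlap


def distance_matrix(seqs: dict[str, str], min_overlap: int = 20) -> tuple[list[str], np.ndarray]:
    ids = sorted(seqs)
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pairwise_distance(seqs[ids[i]], seqs[ids[j]], min_overlap)
    return ids, D


@dataclass
class MOTU:
    motu_id: str
    members: list[str]
    representative: str


def complete_linkage(
    seqs: dict[str, str],
    threshold: float = 0.03,
    precomputed: tuple[list[str], np.ndarray] | None = None,
) -> list[MOTU]:
    """Agglomerative complete-linkage clustering cut at ``threshold``.

    Repeatedly merges the pair of clusters with the smallest complete
    linkage (maximum member-pair) distance while it is <= threshold.
    Ties are broken by merging the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member id), so
    the partition is deterministic and order-independent. The
    representative of a MOTU is its longest member sequence (ties:
    lexicographically smallest id).
    """
    if not seqs:
        return []
    ids, D = precomputed if precomputed is not None else distance_matrix(seqs)
    D = D.copy()
    members: list[list[int] | None] = [[i] for i in range(len(ids))]
    labels: list[str | None] = list(ids)
    active = set(range(len(ids)))

    n = len(ids)
    work = D.copy()
    work[np.tril_indices(n)] = np.inf  # consider each unordered pair once
    while len(active) > 1:
        dmin = work.min()
        if not np.isfinite(dmin) or dmin > threshold:
            break
        cand = np.argwhere(work == dmin)
        i, j = min(
            ((int(a), int(b)) for a, b in cand),
            key=lambda p: tuple(sorted((labels[p[0]], labels[p[1]]))),
        )
        # complete linkage update: new cluster distance = max of the pair
        row = np.maximum(D[i], D[j])
        D[i] = row
        D[:, i] = row
        D[i, i] = 0.0
        work[i, :] = np.where(np.isfinite(work[i, :]), row, np.inf)
        work[:, i] = np.where(np.isfinite(work[:, i]), row, np.inf)
        work[j, :] = np.inf
        work[:, j] = np.inf
        members[i] = sorted(members[i] + members[j])
        labels[i] = min(labels[i], labels[j])
        members[j] = None
        labels[j] = None
        active.discard(j)

    clusters = sorted((labels[i], members[i]) for i in active)
    motus = []
    for k, (_, idx) in enumerate(clusters, start=1):
        ms = sorted(ids[i] for i in idx)
        rep = max(ms, key=lambda m: (len(seqs[m]), [-ord(c) for c in m]))
        motus.append(MOTU(motu_id=f"motu_{k:04d}", members=ms, representative=rep))
    return motus
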