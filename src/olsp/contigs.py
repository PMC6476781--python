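"""Cross-marker contig building.

The three primer sets amplify nested/overlapping windows of the same COI
barcode region, so variants originating from one template are identical
over their overlap. Validated variants from *different* markers are
combined into a contig when they overlap perfectly over at least
``min_overlap`` bases; the merged sequence is the union of the member
spans. Components that would require two variants of the same marker, or
whose implied base assignments conflict, are left unmerged and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import Variant


@dataclass(frozen=True)
class Overlap:
    offset: int  # start of b in a's coordinates (may be negative)
    length: int
    identical: bool = True


@dataclass
class Contig:
    contig_id: str
    members: dict[str, str]  # marker -> variant_id
    seq: str
    offsets: dict[str, int] = field(default_factory=dict)  # variant_id -> start in seq


def pairwise_overlap(a: Variant, b: Variant, min_overlap: int = 100) -> Overlap | None:
    """Best perfect ungapped overlap between two variants of different markers.

    Enumerates every relative offset; returns the offset maximizing the
    overlap length subject to 100% identity and length >= ``min_overlap``
    (ties broken toward smaller absolute offset), or None.
    """
    if a.marker == b.marker:
        raise ValueError("pairwise_overlap compares variants of different markers")
    sa, sb = a.seq, b.seq
    best: Overlap | None = None
    for offset in range(-(len(sb) - min_overlap), len(sa) - min_overlap + 1):
        lo_a, hi_a = max(0, offset), min(len(sa), offset + len(sb))
        length = hi_a - lo_a
        if length < min_overlap:
            continue
        lo_b = lo_a - offset
        if sa[lo_a:hi_a] != sb[lo_b : lo_b + length]:
            continue
        if best is None or length > best.length or (length == best.length and abs(offset) < abs(best.offset)):
            best = Overlap(offset, length)
    return best


def _candidate_offsets(sa: str, sb: str, k: int) -> set[int]:
    """Offsets of b in a at which the pair shares an aligned k-mer.

    Any perfect overlap of length >= k places at least one shared k-mer
    at aligned positions, so this is an exact prefilter for overlap
    searches with min_overlap >= k.
    """
    pos_a: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        pos_a.setdefault(sa[i : i + k], []).append(i)
    offsets: set[int] = set()
    for j in range(len(sb) - k + 1):
        for i in pos_a.get(sb[j : j + k], ()):
            offsets.add(i - j)
    return offsets


def _verify_offset(sa: str, sb: str, offset: int, min_overlap: int) -> int | None:
    lo_a, hi_a = max(0, offset), min(len(sa), offset + len(sb))
    length = hi_a - lo_a
    if length < min_overlap:
        return None
    lo_b = lo_a - offset
    return length if sa[lo_a:hi_a] == sb[lo_b : lo_b + length] else None


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_contigs(
    variants: list[Variant], min_overlap: int = 100, kmer: int = 32
) -> tuple[list[Contig], list[Variant], list[dict]]:
    """Merge validated variants across markers into contigs.

    Builds a graph with an edge for every perfect cross-marker overlap of
    at least ``min_overlap`` bases, then turns each connected component
    into a contig iff it has at most one variant per marker and all
    implied base assignments agree; otherwise the whole component stays
    unmerged and is logged as ambiguous. Every input variant ends up in
    exactly one contig or in the unmerged list. Deterministic: ids are
    assigned over components sorted by member ids.

    Candidate offsets are located by shared ``kmer`` seeds (exact for
    min_overlap >= kmer; an exhaustive scan is used otherwise).
    """
    variants = sorted(variants, key=lambda v: v.variant_id)
    by_id = {v.variant_id: v for v in variants}
    uf = _UnionFind(by_id)
    edges: dict[tuple[str, str], Overlap] = {}

    use_seed = min_overlap >= kmer
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            if a.marker == b.marker:
                continue
            if use_seed:
                best: Overlap | None = None
                for off in _candidate_offsets(a.seq, b.seq, kmer):
                    length = _verify_offset(a.seq, b.seq, off, min_overlap)
                    if length is None:
                        continue
                    if (
                        best is None
                        or length > best.length
                        or (length == best.length and abs(off) < abs(best.offset))
                    ):
                        best = Overlap(off, length)
                ov = best
            else:
                ov = pairwise_overlap(a, b, min_overlap)
            if ov is not None:
                edges[(a.variant_id, b.variant_id)] = ov
                uf.union(a.variant_id, b.variant_id)

    components: dict[str, list[str]] = {}
    for vid in by_id:
        components.setdefault(uf.find(vid), []).append(vid)

    contigs: list[Contig] = []
    unmerged: list[Variant] = []
    ambiguous: list[dict] = []
    n = 0
    for root in sorted(components):
        member_ids = sorted(components[root])
        if len(member_ids) == 1:
            unmerged.append(by_id[member_ids[0]])
            continue
        markers = [by_id[v].marker for v in member_ids]
        if len(set(markers)) != len(markers):
            ambiguous.append({"members": member_ids, "reason": "multiple variants of one marker"})
            unmerged.extend(by_id[v] for v in member_ids)
            continue
        placed = _place(member_ids, by_id, edges)
        if placed is None:
            ambiguous.append({"members": member_ids, "reason": "conflicting base assignments"})
            unmerged.extend(by_id[v] for v in member_ids)
            continue
        offsets, seq = placed
        n += 1
        contigs.append(
            Contig(
                contig_id=f"contig_{n:04d}",
                members={by_id[v].marker: v for v in member_ids},
                seq=seq,
                offsets=offsets,
            )
        )
    return contigs, unmerged, ambiguous


def _place(member_ids, by_id, edges):
    """Assign global offsets by BFS over overlap edges; None on conflict."""
    start = member_ids[0]
    offsets = {start: 0}
    queue = [start]
    adj: dict[str, list[tuple[str, int]]] = {v: [] for v in member_ids}
    for (a, b), ov in edges.items():
        if a in adj and b in adj:
            adj[a].append((b, ov.offset))
            adj[b].append((a, -ov.offset))
    while queue:
        cur = queue.pop(0)
        for nxt, rel in sorted(adj[cur]):
            want = offsets[cur] + rel
            if nxt in offsets:
                if offsets[nxt] != want:
                    return None
            else:
                offsets[nxt] = want
                queue.append(nxt)
    base = min(offsets.values())
    offsets = {v: o - base for v, o in offsets.items()}
    length = max(offsets[v] + len(by_id[v].seq) for v in member_ids)
    merged = [""] * length
    for v in member_ids:
        seq = by_id[v].seq
        off = offsets[v]
        for i, ch in enumerate(seq):
            cur = merged[off + i]
            if cur and cur != ch:
                return None
            merged[off + i] = ch
    if "" in merged:
        return None  # members do not tile a contiguous span
    return offsets, "".join(merged)
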