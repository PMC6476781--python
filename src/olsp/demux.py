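"""Demultiplexing of merged tagged amplicon reads, and dereplication.

Each merged read is expected to carry, in order: forward tag, forward
primer, insert, reverse complement of the reverse primer, reverse
complement of the reverse tag. Reads are assigned to a PCR only when both
ends match a tag pair known to the run design (tags exactly, primers with
IUPAC degeneracy plus a small mismatch tolerance); anything else goes to
an explicit unassigned bin with a reason code. Assigned reads are trimmed
of tags and primers, then pooled into exact variants per marker.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .counts import ReadCountTable
from .design import RunDesign, Variant
from .seqs import IUPAC, revcomp

PcrKey = tuple[str, str, int]  # (sample, marker, replicate)


@dataclass
class DemuxStats:
    total_reads: int = 0
    assigned_reads: int = 0
    unassigned_reads: int = 0
    per_pcr_read_counts: dict[PcrKey, int] = field(default_factory=dict)
    unassigned_reasons: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "assigned_reads": self.assigned_reads,
            "unassigned_reads": self.unassigned_reads,
            "per_pcr_read_counts": {
                "|".join([s, m, str(r)]): n for (s, m, r), n in sorted(self.per_pcr_read_counts.items())
            },
            "unassigned_reasons": dict(sorted(self.unassigned_reasons.items())),
        }


def read_seqs(path):
    """Yield (id, uppercase sequence) from a FASTA or FASTQ file."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()


class _Matcher:
    """Precompiled per-run lookup tables for read assignment."""

    def __init__(self, design: RunDesign, primer_mismatches: int):
        self.tol = primer_mismatches
        self.markers = []
        for name, marker in sorted(design.markers.items()):
            fwd_tags: dict[int, set[str]] = {}
            rc_rev_tags: dict[int, dict[str, str]] = {}
            for (m, ftag, rtag) in design.tag_map:
                if m != name:
                    continue
                fwd_tags.setdefault(len(ftag), set()).add(ftag)
                rc_rev_tags.setdefault(len(rtag), {})[revcomp(rtag)] = rtag
            fwd_sets = [tuple(IUPAC[p]) for p in marker.fwd]
            rc_rev = revcomp(marker.rev)
            rc_rev_sets = [tuple(IUPAC[p]) for p in rc_rev]
            self.markers.append(
                (name, fwd_tags, rc_rev_tags, marker.fwd, len(marker.fwd), rc_rev, len(rc_rev))
            )
        self.tag_map = design.tag_map

    @staticmethod
    def _mm_ok(pattern: str, seq: str, tol: int) -> bool:
        mm = 0
        for p, b in zip(pattern, seq):
            if b not in IUPAC[p]:
                mm += 1
                if mm > tol:
                    return False
        return True

    def candidates(self, read: str):
        """All (pcr_key, insert) assignments compatible with one orientation."""
        out = []
        n = len(read)
        for name, fwd_tags, rc_rev_tags, fwd, lf, rc_rev, lr in self.markers:
            for Lf, tags in fwd_tags.items():
                prefix = read[:Lf]
                if prefix not in tags:
                    continue
                if n < Lf + lf:
                    continue
                if not self._mm_ok(fwd, read[Lf : Lf + lf], self.tol):
                    continue
                for Lr, rmap in rc_rev_tags.items():
                    if n < Lf + lf + lr + Lr + 1:
                        continue
                    rtag = rmap.get(read[n - Lr :])
                    if rtag is None:
                        continue
                    if not self._mm_ok(rc_rev, read[n - Lr - lr : n - Lr], self.tol):
                        continue
                    hit = self.tag_map.get((name, prefix, rtag))
                    if hit is None:
                        continue
                    sample, rep = hit
                    out.append(((sample, name, rep), read[Lf + lf : n - Lr - lr]))
        return out


def demultiplex(
    reads,
    design: RunDesign,
    primer_mismatches: int = 2,
) -> tuple[dict[PcrKey, Counter], DemuxStats, list[str]]:
    """Assign merged reads to PCRs by their tag combination.

    ``reads`` is an iterable of (read_id, sequence). Both the given
    orientation and the reverse complement are searched; a read matching
    more than one construct is unassigned with reason "ambiguous".

    Returns (per-PCR insert multisets, stats, unassigned read ids).
    """
    matcher = _Matcher(design, primer_mismatches)
    per_pcr: dict[PcrKey, Counter] = {}
    stats = DemuxStats()
    unassigned_ids: list[str] = []
    for read_id, seq in reads:
        stats.total_reads += 1
        cands = matcher.candidates(seq)
        rc = revcomp(seq)
        if rc != seq:
            cands += matcher.candidates(rc)
        cands = sorted(set(cands))
        if len(cands) == 1:
            (key, insert), = cands
            per_pcr.setdefault(key, Counter())[insert] += 1
            stats.assigned_reads += 1
            stats.per_pcr_read_counts[key] = stats.per_pcr_read_counts.get(key, 0) + 1
        else:
            stats.unassigned_reads += 1
            reason = "ambiguous" if len(cands) > 1 else (
                "too_short" if len(seq) < 60 else "no_tag_primer_match"
            )
            stats.unassigned_reasons[reason] += 1
            unassigned_ids.append(read_id)
    return per_pcr, stats, unassigned_ids


def dereplicate(
    per_pcr: dict[PcrKey, Counter],
) -> tuple[ReadCountTable, int]:
    """Pool identical trimmed reads into variants with per-PCR counts.

    Variant identity is (marker, sequence); reads containing non-ACGT
    symbols are discarded (their total is returned alongside the table).
    Variant ids are assigned deterministically from the sorted (marker,
    sequence) list, so the result is independent of read order.
    """
    discarded = 0
    clean: dict[tuple[str, str], dict[tuple[str, int], int]] = {}
    for (sample, marker, rep), inserts in per_pcr.items():
        for seq, n in inserts.items():
            if not seq or any(b not in "ACGT" for b in seq):
                discarded += n
                continue
            clean.setdefault((marker, seq), {})
            clean[(marker, seq)][(sample, rep)] = clean[(marker, seq)].get((sample, rep), 0) + n

    variants: dict[str, Variant] = {}
    ids: dict[tuple[str, str], str] = {}
    per_marker_index: Counter = Counter()
    for marker, seq in sorted(clean):
        per_marker_index[marker] += 1
        vid = f"{marker}_{per_marker_index[marker]:06d}"
        ids[(marker, seq)] = vid
        variants[vid] = Variant(vid, marker, seq)

    records = []
    for key, cells in clean.items():
        vid = ids[key]
        for (sample, rep), n in cells.items():
            records.append((vid, sample, rep, n))
    return ReadCountTable.from_records(records, variants), discarded
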