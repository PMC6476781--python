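"""Lowest-taxonomic-group (LTG) assignment against a local reference set.

Each validated item is aligned against a reference FASTA with known
taxonomy. Hits are banded by percent identity (>=97, >=95, >=90, >=85,
>=80 by default); within the highest non-empty band the item is assigned
to the lowest rank at which a single taxon accounts for at least 90% of
the hits, capped per band (97 -> species ... 80 -> class) so weak
identity can never award a species-level name. The identification
resolution (IR) score maps the assigned rank to 0..6 (species = 6,
kingdom or unassigned = 0); a sample's IR is the mean over its validated
Macrometazoan items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd
from Bio import SeqIO

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: rank -> IR score (kingdom or NA scores 0)
IR_SCALE = {
    "species": 6,
    "genus": 5,
    "family": 4,
    "order": 3,
    "class": 2,
    "phylum": 1,
    "kingdom": 0,
    None: 0,
}

DEFAULT_LADDER: tuple[tuple[float, str], ...] = (
    (97.0, "species"),
    (95.0, "genus"),
    (90.0, "family"),
    (85.0, "order"),
    (80.0, "class"),
)

#: taxa treated as non-target (passive ingestion, secondary predation,
#: parasites): microinvertebrates, diatoms, algae, plants, parasites.
DEFAULT_EXCLUSIONS = (
    "Amoebozoa",
    "Acari",
    "Tardigrada",
    "Rotifera",
    "Bacillariophyta",
    "Chlorophyta",
    "Rhodophyta",
    "Streptophyta",
    "Acanthocephala",
    "Nematoda",
)


@dataclass(frozen=True)
class TaxonPath:
    """Taxonomic names ordered kingdom -> species; a suffix may be absent,

    but ranks are contiguous from kingdom (no internal gaps)."""

    names: tuple[str | None, ...]

    def __post_init__(self):
        if len(self.names) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(self.names)}")
        seen_gap = False
        for name in self.names:
            if not name:
                seen_gap = True
            elif seen_gap:
                raise ValueError(f"non-contiguous taxon path {self.names}")

    @classmethod
    def from_names(cls, *names: str | None) -> "TaxonPath":
        names = tuple(n or None for n in names)
        return cls(names + (None,) * (len(RANKS) - len(names)))

    def at(self, rank: str) -> str | None:
        return self.names[_RANK_INDEX[rank]]

    def truncated(self, rank: str) -> "TaxonPath":
        i = _RANK_INDEX[rank]
        return TaxonPath(self.names[: i + 1] + (None,) * (len(RANKS) - i - 1))

    @property
    def resolution_rank(self) -> str | None:
        deepest = None
        for rank, name in zip(RANKS, self.names):
            if name:
                deepest = rank
        return deepest

    @property
    def deepest_name(self) -> str | None:
        rank = self.resolution_rank
        return self.at(rank) if rank else None


@dataclass(frozen=True)
class Hit:
    ref_id: str
    path: TaxonPath
    identity: float  # percent, in [0, 100]

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of range: {self.identity}")


@dataclass
class Assignment:
    item_id: str
    ltg: TaxonPath | None
    method: str = "ltg_auto"
    n_hits: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def resolution_rank(self) -> str | None:
        return self.ltg.resolution_rank if self.ltg else None


@dataclass
class ReferenceDB:
    seqs: dict[str, str]
    taxonomy: dict[str, TaxonPath]

    @classmethod
    def load(cls, fasta_path, taxonomy_path) -> "ReferenceDB":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
        taxonomy = {
            row["ref_id"]: TaxonPath.from_names(*(row[r] for r in RANKS))
            for _, row in tax.iterrows()
        }
        missing = set(seqs) - set(taxonomy)
        if missing:
            raise ValueError(f"references without taxonomy: {sorted(missing)[:5]}")
        return cls(seqs, taxonomy)


def search_reference(
    seq: str,
    db: ReferenceDB,
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
) -> list[Hit]:
    """All references matching ``seq`` at or above the identity floor.

    Identity is computed from the semi-global edit distance of the
    shorter sequence against the longer (100 * (1 - distance / shorter
    length)); the shorter sequence must cover at least ``min_coverage``
    of the item, so items much longer than any reference cannot pick up
    spurious full-identity hits.
    """
    hits = []
    for ref_id in sorted(db.seqs):
        ref = db.seqs[ref_id]
        query, target = (seq, ref) if len(seq) <= len(ref) else (ref, seq)
        if len(query) < min_coverage * len(seq):
            continue
        res = edlib.align(query, target, mode="HW", task="distance")
        dist = res["editDistance"]
        identity = 100.0 * (1.0 - dist / len(query))
        if identity >= min_identity:
            hits.append(Hit(ref_id, db.taxonomy[ref_id], max(identity, 0.0)))
    return hits


def ltg_assign(
    item_id: str,
    hits: list[Hit],
    ladder: tuple[tuple[float, str], ...] = DEFAULT_LADDER,
    inclusion: float = 0.9,
) -> Assignment:
    """Lowest taxonomic group of a hit list.

    Uses the highest identity band of the ladder containing at least one
    hit; within that band, returns the lowest rank whose single most
    frequent taxon contains >= ``inclusion`` of the band's hits, never
    deeper than the band's rank cap. Empty hits -> unassigned.
    """
    if not hits:
        return Assignment(item_id, None, n_hits=0, flags=["no_hits"])
    band = None
    for floor, cap in sorted(ladder, reverse=True):
        selected = [h for h in hits if h.identity >= floor]
        if selected:
            band = (floor, cap, selected)
            break
    if band is None:
        return Assignment(item_id, None, n_hits=len(hits), flags=["below_ladder"])
    _, cap, selected = band
    cap_idx = _RANK_INDEX[cap]
    for rank in reversed(RANKS[: cap_idx + 1]):
        names = [h.path.at(rank) for h in selected]
        counts: dict[str, int] = {}
        for name in names:
            if name:
                counts[name] = counts.get(name, 0) + 1
        if not counts:
            continue
        top = max(sorted(counts), key=lambda n: counts[n])
        if counts[top] >= inclusion * len(selected):
            path = next(h.path for h in selected if h.path.at(rank) == top)
            return Assignment(item_id, path.truncated(rank), n_hits=len(selected))
    return Assignment(item_id, None, n_hits=len(selected), flags=["no_consensus"])


def ir_score(assignment: Assignment | None) -> int:
    """Identification-resolution score of one assignment (0..6)."""
    if assignment is None or assignment.ltg is None:
        return 0
    return IR_SCALE[assignment.resolution_rank]


def sample_ir(assignments: list[Assignment]) -> float:
    """Mean IR score over one sample's validated items."""
    if not assignments:
        raise ValueError("sample_ir of an empty sample is undefined")
    return sum(ir_score(a) for a in assignments) / len(assignments)


def macrometazoan_filter(
    assignments: list[Assignment],
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
) -> tuple[list[Assignment], list[Assignment]]:
    """Partition items into Macrometazoan targets and excluded items.

    An item is excluded when any taxon on its path is on the exclusion
    list. Unassigned items are conservatively retained and flagged.
    """
    excluded_names = set(exclusions)
    kept, excluded = [], []
    for a in assignments:
        if a.ltg is None:
            a.flags.append("unassigned_retained")
            kept.append(a)
        elif any(name in excluded_names for name in a.ltg.names if name):
            excluded.append(a)
        else:
            kept.append(a)
    return kept, excluded


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        names = a.ltg.names if a.ltg else (None,) * len(RANKS)
        rows.append(
            {
                "item": a.item_id,
                **dict(zip(RANKS, names)),
                "resolution_rank": a.resolution_rank or "",
                "ir_score": ir_score(a),
                "method": a.method,
                "n_hits": a.n_hits,
                "flags": ";".join(a.flags),
            }
        )
    return pd.DataFrame(rows)


def apply_overrides(assignments: list[Assignment], overrides: pd.DataFrame) -> list[Assignment]:
    """Replace automatic assignments with curated ones.

    ``overrides`` columns: item plus the rank columns kingdom..species.
    Overridden assignments are tagged method="override".
    """
    by_item = {}
    for _, row in overrides.iterrows():
        by_item[row["item"]] = TaxonPath.from_names(*(row.get(r, "") for r in RANKS))
    out = []
    for a in assignments:
        if a.item_id in by_item:
            out.append(Assignment(a.item_id, by_item[a.item_id], method="override", n_hits=a.n_hits))
        else:
            out.append(a)
    return out
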