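"""Run-design model: markers, sample tags, and the PCR layout of a run.

A metabarcoding run amplifies every sample with each primer set (marker)
in R replicate PCRs, each PCR labelled by a (forward tag, reverse tag)
combination unique within the run. The design table records that layout
together with sample metadata (category, predator, habitat).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .seqs import is_iupac

EDNA = "edna"
MOCK = "mock"
NEGATIVE_CATEGORIES = ("neg_extraction", "neg_aerosol", "neg_pcr", "neg_tag")
CATEGORIES = (EDNA, MOCK) + NEGATIVE_CATEGORIES

DESIGN_COLUMNS = (
    "run",
    "marker",
    "sample",
    "category",
    "replicate",
    "fwd_tag",
    "rev_tag",
    "predator",
    "habitat",
)


class DesignError(ValueError):
    """Malformed or internally inconsistent design table."""


@dataclass(frozen=True)
class Marker:
    """A primer set: name plus forward/reverse primers (IUPAC, primer

    orientation — the reverse primer is given as the oligo sequence, i.e.
    the reverse complement of the top-strand site it binds)."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self):
        if not self.name:
            raise DesignError("marker name must be non-empty")
        for label, seq in (("forward", self.fwd), ("reverse", self.rev)):
            if not is_iupac(seq):
                raise DesignError(
                    f"marker {self.name}: {label} primer contains non-IUPAC symbols: {seq!r}"
                )


@dataclass(frozen=True)
class TagPair:
    fwd_tag: str
    rev_tag: str

    def __post_init__(self):
        for t in (self.fwd_tag, self.rev_tag):
            if not (11 <= len(t) <= 13):
                raise DesignError(f"tag length must be in [11, 13]: {t!r}")
            if not is_iupac(t):
                raise DesignError(f"tag contains non-IUPAC symbols: {t!r}")


@dataclass
class SampleRecord:
    """One biological sample or control within a run."""

    sample_id: str
    category: str
    predator: str | None = None
    habitat: str | None = None
    #: for mocks: list of (taxon name, expected variant/contig id or "").
    expected_taxa: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DesignError(
                f"sample {self.sample_id}: unknown category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )

    @property
    def is_negative(self) -> bool:
        return self.category in NEGATIVE_CATEGORIES


@dataclass(frozen=True)
class Variant:
    """An exact dereplicated amplicon sequence, scoped to one marker."""

    variant_id: str
    marker: str
    seq: str

    def __post_init__(self):
        if not self.seq or any(b not in "ACGT" for b in self.seq):
            raise ValueError(f"variant {self.variant_id}: sequence must be non-empty ACGT")


@dataclass
class RunDesign:
    """The PCR layout of a single sequencing run.

    ``tag_map`` maps (marker, fwd_tag, rev_tag) to (sample_id, replicate);
    it is injective per marker by construction.
    """

    run_id: str
    markers: dict[str, Marker]
    samples: dict[str, SampleRecord]
    tag_map: dict[tuple[str, str, str], tuple[str, int]]

    def pcrs(self) -> list[tuple[str, str, int]]:
        """All (sample, marker, replicate) PCRs of the run, sorted."""
        return sorted(
            (sample, marker, rep) for (marker, _, _), (sample, rep) in self.tag_map.items()
        )

    def replicates(self, sample_id: str, marker: str) -> list[int]:
        return sorted(
            rep for (m, _, _), (s, rep) in self.tag_map.items() if s == sample_id and m == marker
        )

    def validate(self) -> None:
        for (marker, ftag, rtag) in self.tag_map:
            if marker not in self.markers:
                raise DesignError(f"run {self.run_id}: tag map references unknown marker {marker}")
            TagPair(ftag, rtag)
        for sample_id in self.samples:
            for marker in self.markers:
                reps = self.replicates(sample_id, marker)
                if reps != list(range(1, len(reps) + 1)):
                    raise DesignError(
                        f"run {self.run_id}: sample {sample_id} marker {marker} has "
                        f"non-contiguous replicates {reps}"
                    )


def validate_tagset(tags: list[str]) -> tuple[int, bool]:
    """Minimum pairwise mismatch count of a tag set and whether it is

    acceptable (>= 3 mismatches between every pair).

    Tags of unequal length are compared over their shared prefix (tags
    anchor at the 5' end of the primer construct).
    """
    if not tags:
        raise ValueError("empty tag set")
    if len(tags) == 1:
        return (min(len(tags[0]), 13), True)
    min_mm = None
    for a, b in itertools.combinations(tags, 2):
        n = min(len(a), len(b))
        mm = sum(1 for x, y in zip(a[:n], b[:n]) if x != y)
        if min_mm is None or mm < min_mm:
            min_mm = mm
    return (min_mm, min_mm >= 3)


def _parse_rows(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(DESIGN_COLUMNS) - set(header)
        if missing:
            raise DesignError(f"{path}: missing design columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise DesignError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            row = dict(zip(header, fields))
            try:
                row["replicate"] = int(row["replicate"])
            except ValueError as exc:
                raise DesignError(f"{path}:{lineno}: bad replicate {row['replicate']!r}") from exc
            row["_lineno"] = lineno
            rows.append(row)
    if not rows:
        raise DesignError(f"{path}: design table has no rows")
    return rows


def parse_design_all(path, markers: dict[str, Marker]) -> dict[str, RunDesign]:
    """Parse a design TSV (possibly spanning several runs) into one

    RunDesign per run. ``markers`` supplies primer sequences for the
    marker names used in the table.
    """
    by_run: dict[str, dict] = {}
    for row in _parse_rows(path):
        run = row["run"]
        d = by_run.setdefault(run, {"samples": {}, "tag_map": {}, "markers": {}})
        marker = row["marker"]
        if marker not in markers:
            raise DesignError(f"{path}:{row['_lineno']}: unknown marker {marker!r}")
        d["markers"][marker] = markers[marker]
        key = (marker, row["fwd_tag"], row["rev_tag"])
        if key in d["tag_map"]:
            raise DesignError(
                f"{path}:{row['_lineno']}: duplicate tag pair {key} in run {run} "
                f"(design conflict)"
            )
        d["tag_map"][key] = (row["sample"], row["replicate"])
        rec = d["samples"].get(row["sample"])
        if rec is None:
            d["samples"][row["sample"]] = SampleRecord(
                sample_id=row["sample"],
                category=row["category"],
                predator=row["predator"] or None,
                habitat=row["habitat"] or None,
            )
        elif rec.category != row["category"]:
            raise DesignError(
                f"{path}:{row['_lineno']}: sample {row['sample']} listed with "
                f"conflicting categories"
            )
    designs = {}
    for run, d in sorted(by_run.items()):
        rd = RunDesign(run_id=run, markers=d["markers"], samples=d["samples"], tag_map=d["tag_map"])
        rd.validate()
        designs[run] = rd
    return designs


def parse_design(path, markers: dict[str, Marker], run: str | None = None) -> RunDesign:
    """Parse the design table and return one run's layout.

    ``run`` may be omitted when the table contains a single run.
    """
    designs = parse_design_all(path, markers)
    if run is not None:
        if run not in designs:
            raise DesignError(f"{path}: run {run!r} not present (has {sorted(designs)})")
        return designs[run]
    if len(designs) != 1:
        raise DesignError(f"{path}: multiple runs {sorted(designs)}; specify one")
    return next(iter(designs.values()))


def write_design(designs: dict[str, RunDesign] | RunDesign, path) -> None:
    if isinstance(designs, RunDesign):
        designs = {designs.run_id: designs}
    with open(path, "w") as fh:
        fh.write("\t".join(DESIGN_COLUMNS) + "\n")
        for run_id, rd in sorted(designs.items()):
            rows = sorted(
                (marker, sample, rep, ftag, rtag)
                for (marker, ftag, rtag), (sample, rep) in rd.tag_map.items()
            )
            for marker, sample, rep, ftag, rtag in rows:
                rec = rd.samples[sample]
                fh.write(
                    "\t".join(
                        [
                            run_id,
                            marker,
                            sample,
                            rec.category,
                            str(rep),
                            ftag,
                            rtag,
                            rec.predator or "",
                            rec.habitat or "",
                        ]
                    )
                    + "\n"
                )


def load_mock_expectations(path) -> dict[str, list[tuple[str, str]]]:
    """Read a mock-expectations TSV (sample, taxon, role) into a mapping."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample", "taxon"]:
            raise DesignError(f"{path}: expected columns sample, taxon[, role]")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sample, taxon = fields[0], fields[1]
            role = fields[2] if len(fields) > 2 and fields[2] else "prey"
            out.setdefault(sample, []).append((taxon, role))
    return out


def attach_mock_expectations(
    designs: dict[str, RunDesign], expectations: dict[str, list[tuple[str, str]]]
) -> None:
    """Attach expected taxa to the mock SampleRecords of parsed designs."""
    for rd in designs.values():
        for sample_id, rec in rd.samples.items():
            if rec.category == MOCK and sample_id in expectations:
                rec.expected_taxa = list(expectations[sample_id])


def edna_samples(designs: dict[str, RunDesign]) -> list[str]:
    """Unique eDNA sample ids across runs, sorted."""
    out = set()
    for rd in designs.values():
        out.update(s for s, rec in rd.samples.items() if rec.category == EDNA)
    return sorted(out)
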