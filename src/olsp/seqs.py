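"""Nucleotide sequence utilities shared across the pipeline.

IUPAC-aware primer matching, reverse complementation, and in-silico PCR
(locating primer binding sites on a template to predict the trimmed
amplicon a primer set would produce).
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return bool(seq) and all(b in IUPAC for b in seq)


def iupac_mismatches(pattern: str, seq: str, stop_after: int | None = None) -> int:
    """Count positions of ``seq`` not covered by the IUPAC ``pattern``.

    Both strings must have equal length. ``stop_after`` allows early exit
    once the count exceeds a tolerance (the return value is then a lower
    bound > ``stop_after``).
    """
    if len(pattern) != len(seq):
        raise ValueError("pattern and sequence must have equal length")
    mm = 0
    for p, b in zip(pattern, seq):
        if b not in IUPAC[p]:
            mm += 1
            if stop_after is not None and mm > stop_after:
                return mm
    return mm


@dataclass(frozen=True)
class PrimerSite:
    """A primer binding site located on a template (template coordinates,

    0-based half-open), with the number of pattern mismatches."""

    start: int
    end: int
    mismatches: int


def find_site(template: str, pattern: str, max_mismatches: int) -> PrimerSite | None:
    """Best ungapped match of an IUPAC ``pattern`` in ``template``.

    Returns the lowest-mismatch site (leftmost on ties) with at most
    ``max_mismatches`` mismatches, or None.
    """
    L = len(pattern)
    best: PrimerSite | None = None
    for start in range(0, len(template) - L + 1):
        mm = iupac_mismatches(pattern, template[start : start + L], stop_after=max_mismatches)
        if mm <= max_mismatches and (best is None or mm < best.mismatches):
            best = PrimerSite(start, start + L, mm)
            if mm == 0:
                break
    return best


def in_silico_pcr(template: str, fwd: str, rev: str, max_mismatches: int = 2) -> str | None:
    """Trimmed amplicon a primer pair would yield from ``template``.

    The forward primer is matched on the top strand and the reverse primer
    as its reverse complement downstream of it. Returns the insert between
    the two binding sites (primers excluded), or None if either site is
    missing at the allowed mismatch tolerance or the sites are not in
    amplifiable orientation/order.
    """
    fsite = find_site(template, fwd, max_mismatches)
    if fsite is None:
        return None
    rsite = find_site(template[fsite.end :], revcomp(rev), max_mismatches)
    if rsite is None:
        return None
    start = fsite.end
    end = fsite.end + rsite.start
    if end <= start:
        return None
    return template[start:end]


def realize_iupac(pattern: str, rng) -> str:
    """Resolve degenerate positions to concrete bases using ``rng``."""
    out = []
    for p in pattern:
        opts = sorted(IUPAC[p])
        out.append(opts[0] if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)
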