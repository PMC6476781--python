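"""The per-occurrence read count table transformed by every filter.

An *occurrence* is a (variant, sample, replicate) triple with a positive
read count N_ijk. The table also carries the variant registry (marker and
sequence per variant id) so downstream stages can recover sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Variant

COUNT_COLUMNS = ["variant", "sample", "replicate", "count"]

Occurrence = tuple[str, str, int]


@dataclass
class ReadCountTable:
    df: pd.DataFrame
    variants: dict[str, Variant] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records, variants: dict[str, Variant]) -> "ReadCountTable":
        """``records``: iterable of (variant_id, sample_id, replicate, count)."""
        df = pd.DataFrame(list(records), columns=COUNT_COLUMNS)
        return cls(df, variants)._normalized()

    def _normalized(self) -> "ReadCountTable":
        df = self.df
        if (df["count"] < 0).any():
            raise ValueError("negative read count")
        df = df[df["count"] > 0]
        df = df.sort_values(COUNT_COLUMNS[:3], kind="mergesort").reset_index(drop=True)
        return ReadCountTable(df, self.variants)

    # -- aggregates ------------------------------------------------------
    def n_occurrences(self) -> int:
        return len(self.df)

    def total_reads(self) -> int:
        return int(self.df["count"].sum())

    def variant_totals(self) -> pd.Series:
        """N_i.. : run-wide total reads per variant."""
        return self.df.groupby("variant")["count"].sum()

    def replicate_totals(self) -> pd.Series:
        """N_.jk : total reads per (sample, replicate) PCR."""
        return self.df.groupby(["sample", "replicate"])["count"].sum()

    def occurrences(self) -> set[Occurrence]:
        return set(map(tuple, self.df[COUNT_COLUMNS[:3]].itertuples(index=False, name=None)))

    def get(self, occ: Occurrence) -> int:
        v, s, r = occ
        m = self.df[
            (self.df["variant"] == v) & (self.df["sample"] == s) & (self.df["replicate"] == r)
        ]
        return int(m["count"].iloc[0]) if len(m) else 0

    def marker_of(self, variant_id: str) -> str:
        return self.variants[variant_id].marker

    # -- transforms ------------------------------------------------------
    def keep_mask(self, mask) -> "ReadCountTable":
        mask = np.asarray(mask, dtype=bool)
        return ReadCountTable(self.df[mask].reset_index(drop=True), self.variants)

    def drop_occurrences(self, occs: set[Occurrence]) -> "ReadCountTable":
        keys = list(self.df[COUNT_COLUMNS[:3]].itertuples(index=False, name=None))
        mask = [k not in occs for k in keys]
        return self.keep_mask(pd.Series(mask, index=self.df.index))

    def subset_samples(self, sample_ids) -> "ReadCountTable":
        wanted = set(sample_ids)
        return self.keep_mask(self.df["sample"].isin(wanted))

    def subset_marker(self, marker: str) -> "ReadCountTable":
        markers = self.df["variant"].map(lambda v: self.variants[v].marker)
        return self.keep_mask(markers == marker)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["marker"] = out["variant"].map(lambda v: self.variants[v].marker)
        out["sequence"] = out["variant"].map(lambda v: self.variants[v].seq)
        out[["variant", "marker", "sample", "replicate", "count", "sequence"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ReadCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str, "sample": str})
        variants = {
            row.variant: Variant(row.variant, row.marker, row.sequence)
            for row in df.drop_duplicates("variant").itertuples()
        }
        return cls.from_records(
            df[COUNT_COLUMNS].itertuples(index=False, name=None), variants
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadCountTable):
            return NotImplemented
        a = self.df.sort_values(COUNT_COLUMNS[:3]).reset_index(drop=True)
        b = other.df.sort_values(COUNT_COLUMNS[:3]).reset_index(drop=True)
        return a.equals(b)
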