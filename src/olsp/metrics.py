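"""Coverage, complementarity and diet-composition metrics.

All metrics operate on the *item table*: one row per (validated item,
sample) with the set of markers that detected the item in that sample,
its MOTU, and its taxonomic path. The Minimal Number of Individuals
(MNI) of a sample at a level is the number of distinct validated items
per taxon at that level — a semiquantitative abundance proxy.

* Bc (coverage ratio): taxa detected by one primer set / taxa detected
  by all primer sets together.
* Com (complementarity): taxa detected by exactly one primer set / all
  detected taxa.
* Wsd: within-sample Bray-Curtis dissimilarity between the per-primer-set
  MNI vectors of one sample (technical noise).
* Bsd: between-sample Bray-Curtis dissimilarity on combined MNI vectors
  (biological signal).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .taxonomy import RANKS

LEVELS = ("phylum", "class", "order", "family", "motu", "variant")


def item_label(row, level: str) -> str:
    """Taxon label of an item at an aggregation level.

    Items unresolved at a rank keep a stable pseudo-label derived from
    their deepest assigned name (or their own id when unassigned), so
    every item contributes to exactly one cell at every level and
    aggregation conserves per-sample item totals.
    """
    if level == "variant":
        return row["item"]
    if level == "motu":
        return row["motu"]
    name = row.get(level)
    if isinstance(name, str) and name:
        return name
    deepest = None
    for rank in RANKS:
        value = row.get(rank)
        if isinstance(value, str) and value:
            deepest = value
    return f"indet_{deepest}" if deepest else f"unassigned_{row['item']}"


def _labelled(items: pd.DataFrame, level: str) -> pd.Series:
    return items.apply(lambda row: item_label(row, level), axis=1)


def mni_matrix(items: pd.DataFrame, level: str) -> pd.DataFrame:
    """Samples x taxa matrix of distinct validated item counts."""
    if items.empty:
        return pd.DataFrame()
    df = items.copy()
    df["label"] = _labelled(df, level)
    mat = df.groupby(["sample", "label"])["item"].nunique().unstack(fill_value=0)
    return mat.sort_index().sort_index(axis=1)


def detection_sets(
    items: pd.DataFrame, level: str
) -> tuple[dict[tuple[str, str], set[str]], dict[str, set[str]]]:
    """Detected taxa per (sample, marker) and pooled per marker.

    An item counts as detected by marker p in a sample iff one of its
    member variants of marker p was itself validated in that sample (the
    item table's ``markers`` column).
    """
    per_sample: dict[tuple[str, str], set[str]] = {}
    pooled: dict[str, set[str]] = {}
    if items.empty:
        return per_sample, pooled
    df = items.copy()
    df["label"] = _labelled(df, level)
    for row in df.itertuples():
        for marker in row.markers:
            per_sample.setdefault((row.sample, marker), set()).add(row.label)
            pooled.setdefault(marker, set()).add(row.label)
    return per_sample, pooled


def coverage_bc(detected_by_p: set, detected_by_all: set) -> float | None:
    """|taxa detected by primer set p| / |taxa detected by all sets|."""
    if not detected_by_p <= detected_by_all:
        raise ValueError("per-primer detections must be a subset of the union")
    if not detected_by_all:
        return None
    return len(detected_by_p) / len(detected_by_all)


def complementarity_com(per_marker: dict[str, set]) -> float | None:
    """Fraction of detected taxa found by exactly one primer set."""
    if len(per_marker) < 2:
        raise ValueError("complementarity needs >= 2 primer sets")
    union = set().union(*per_marker.values())
    if not union:
        return None
    exactly_one = {t for t in union if sum(t in s for s in per_marker.values()) == 1}
    return len(exactly_one) / len(union)


def bray_curtis(x, y) -> float | None:
    """1 - 2 sum(min(x, y)) / (sum x + sum y); None when both are zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be aligned")
    total = x.sum() + y.sum()
    if total == 0:
        return None
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def bc_table(items: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Per-sample and pooled coverage ratios, per level and marker."""
    rows = []
    for level in LEVELS:
        per_sample, pooled = detection_sets(items, level)
        samples = sorted({s for s, _ in per_sample})
        for sample in samples:
            union = set().union(*(per_sample.get((sample, m), set()) for m in markers))
            for marker in markers:
                value = coverage_bc(per_sample.get((sample, marker), set()), union)
                if value is not None:
                    rows.append(
                        {"scope": "sample", "sample": sample, "level": level, "marker": marker, "value": value}
                    )
        union_all = set().union(*(pooled.get(m, set()) for m in markers)) if pooled else set()
        for marker in markers:
            value = coverage_bc(pooled.get(marker, set()), union_all) if union_all else None
            if value is not None:
                rows.append(
                    {"scope": "pooled", "sample": "", "level": level, "marker": marker, "value": value}
                )
    return pd.DataFrame(rows)


def com_table(items: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Per-sample and pooled complementarity, per level."""
    rows = []
    for level in LEVELS:
        per_sample, pooled = detection_sets(items, level)
        samples = sorted({s for s, _ in per_sample})
        for sample in samples:
            sets = {m: per_sample.get((sample, m), set()) for m in markers}
            value = complementarity_com(sets)
            if value is not None:
                rows.append({"scope": "sample", "sample": sample, "level": level, "value": value})
        if pooled:
            value = complementarity_com({m: pooled.get(m, set()) for m in markers})
            if value is not None:
                rows.append({"scope": "pooled", "sample": "", "level": level, "value": value})
    return pd.DataFrame(rows)


def wsd_table(items: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Within-sample dissimilarity between primer sets.

    For each sample and level, the Bray-Curtis dissimilarity between the
    MNI vectors computed from each primer set's own detections. Samples
    validated under fewer than two primer sets at a level are excluded.
    """
    rows = []
    for level in LEVELS:
        per_sample, _ = detection_sets(items, level)
        df = items.copy()
        if df.empty:
            continue
        df["label"] = _labelled(df, level)
        for sample, grp in df.groupby("sample"):
            labels = sorted(set(grp["label"]))
            vectors = {}
            for marker in markers:
                detected = per_sample.get((sample, marker), set())
                if not detected:
                    continue
                counts = (
                    grp[grp["markers"].map(lambda ms: marker in ms)]
                    .groupby("label")["item"]
                    .nunique()
                )
                vectors[marker] = np.array([counts.get(l, 0) for l in labels], dtype=float)
            if len(vectors) < 2:
                continue
            for m1, m2 in itertools.combinations(sorted(vectors), 2):
                value = bray_curtis(vectors[m1], vectors[m2])
                if value is not None:
                    rows.append(
                        {"sample": sample, "level": level, "pair": f"{m1}-{m2}", "value": value}
                    )
    return pd.DataFrame(rows)


def bsd_table(items: pd.DataFrame) -> pd.DataFrame:
    """Between-sample dissimilarity on combined MNI vectors, per level."""
    rows = []
    for level in LEVELS:
        mat = mni_matrix(items, level)
        if mat.empty:
            continue
        samples = list(mat.index)
        X = mat.to_numpy(dtype=float)
        for i, j in itertools.combinations(range(len(samples)), 2):
            value = bray_curtis(X[i], X[j])
            if value is not None:
                rows.append(
                    {"sample_a": samples[i], "sample_b": samples[j], "level": level, "value": value}
                )
    return pd.DataFrame(rows)


def mni_summary(items: pd.DataFrame, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sample MNI totals plus per-group mean +- sd (n-1 denominator)."""
    per_sample = items.groupby("sample")["item"].nunique()
    rows = [
        {"scope": "sample", "key": s, "mni": int(n), "mean": np.nan, "sd": np.nan}
        for s, n in per_sample.items()
    ]
    if groups:
        gseries = per_sample.groupby(per_sample.index.map(groups.get))
        for group, vals in gseries:
            if group is None:
                continue
            rows.append(
                {
                    "scope": "group",
                    "key": group,
                    "mni": int(vals.sum()),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def ir_table(items: pd.DataFrame, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Mean IR score per sample (requires an ``ir_score`` column)."""
    per_sample = items.groupby("sample")["ir_score"].mean()
    rows = [{"scope": "sample", "key": s, "value": float(v)} for s, v in per_sample.items()]
    if groups:
        gseries = per_sample.groupby(per_sample.index.map(groups.get))
        for group, vals in gseries:
            if group is None:
                continue
            rows.append({"scope": "group", "key": group, "value": float(vals.mean())})
    rows.append({"scope": "all", "key": "", "value": float(per_sample.mean())})
    return pd.DataFrame(rows)
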