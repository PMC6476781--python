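"""Low-frequency-noise (LFN) filtering calibrated on control samples.

Tag switching, cross-contamination and PCR errors leave spurious
low-abundance occurrences in amplicon count tables. Three thresholds are
applied to every occurrence (variant i, sample j, replicate k):

* ``t_abs``: minimum absolute read count N_ijk;
* ``t_var``: minimum N_ijk / N_i.. (share of the variant's run total);
* ``t_rep``: minimum N_ijk / N_.jk (share of the replicate's reads).

Thresholds are calibrated per run (and typically per marker) against the
controls: every expected occurrence in the mock communities must survive
(hard constraint) while as many occurrences as possible in negative
controls — and any other known artefacts — are eliminated (objective).
Contaminants that no feasible threshold can remove are reported rather
than silently kept or dropped.

Replicate reproducibility is enforced by (a) discarding PCR replicates
whose Renkonen distance to the other replicates of the same sample is
high and (b) validating a variant in a sample only when it occurs in at
least two surviving replicates. After taxonomic assignment flags
habitat-incompatible detections, a second calibration pass re-runs the
whole chain on the original dereplicated table with those occurrences
added to the elimination set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import Occurrence, ReadCountTable


@dataclass(frozen=True)
class LFNThresholds:
    t_abs: int = 0
    t_var: float = 0.0
    t_rep: float = 0.0

    def __post_init__(self):
        if self.t_abs < 0 or not (0.0 <= self.t_var <= 1.0) or not (0.0 <= self.t_rep <= 1.0):
            raise ValueError(f"invalid thresholds {self}")

    def as_dict(self) -> dict:
        return {"t_abs": int(self.t_abs), "t_var": float(self.t_var), "t_rep": float(self.t_rep)}


@dataclass
class FilterTrace:
    """Ordered audit log: each step's input is the previous step's output."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, occurrences_removed: int, replicates_removed: int = 0, **extra):
        self.steps.append(
            {
                "filter": name,
                "occurrences_removed": int(occurrences_removed),
                "replicates_removed": int(replicates_removed),
                **extra,
            }
        )

    def total_removed(self) -> int:
        return sum(s["occurrences_removed"] for s in self.steps)


@dataclass
class CalibrationReport:
    thresholds: LFNThresholds
    retained_expected: int
    eliminated_unexpected: int
    unremovable: list[tuple[Occurrence, str]]
    mock_dropouts: list[Occurrence]

    def as_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.as_dict(),
            "retained_expected": self.retained_expected,
            "eliminated_unexpected": self.eliminated_unexpected,
            "unremovable": [list(o) + [w] for o, w in self.unremovable],
            "mock_dropouts": [list(o) for o in self.mock_dropouts],
        }


def _occurrence_stats(table: ReadCountTable) -> pd.DataFrame:
    """Per-occurrence count, variant-relative and replicate-relative shares,

    with denominators computed on this table."""
    df = table.df
    out = df.copy()
    out["var_total"] = df.groupby("variant")["count"].transform("sum")
    out["rep_total"] = df.groupby(["sample", "replicate"])["count"].transform("sum")
    out["var_ratio"] = out["count"] / out["var_total"]
    out["rep_ratio"] = out["count"] / out["rep_total"]
    return out


def lfn_filter(
    table: ReadCountTable, th: LFNThresholds, trace: FilterTrace | None = None
) -> tuple[ReadCountTable, FilterTrace]:
    """Apply the three LFN sub-filters.

    All denominators (N_i.. and N_.jk) are computed once on the input
    table rather than cascaded between sub-filters, so the three checks
    are order-independent. The operation is idempotent: re-filtering the
    output can only shrink denominators, so every kept ratio stays at or
    above its threshold.
    """
    trace = trace if trace is not None else FilterTrace()
    stats = _occurrence_stats(table)
    keep = pd.Series(True, index=stats.index)
    for name, column, threshold in (
        ("lfn_absolute", "count", th.t_abs),
        ("lfn_variant", "var_ratio", th.t_var),
        ("lfn_replicate", "rep_ratio", th.t_rep),
    ):
        fails = keep & (stats[column] < threshold)
        trace.add(name, int(fails.sum()))
        keep &= ~fails
    return table.keep_mask(keep), trace


def _survives(stats_row, th: LFNThresholds) -> bool:
    return (
        stats_row["count"] >= th.t_abs
        and stats_row["var_ratio"] >= th.t_var
        and stats_row["rep_ratio"] >= th.t_rep
    )


def calibrate(
    table: ReadCountTable,
    must_keep: set[Occurrence],
    must_drop: set[Occurrence],
) -> CalibrationReport:
    """Choose LFN thresholds from the controls.

    Feasible thresholds retain every ``must_keep`` occurrence (expected
    mock-community members). Among feasible threshold triples on the
    candidate grid of observed occurrence statistics (plus an epsilon
    step above each), the calibration maximizes the number of
    ``must_drop`` occurrences removed and, among maximizers, returns the
    lexicographically smallest (t_abs, t_var, t_rep). ``must_drop``
    occurrences that no feasible threshold removes are reported as
    unremovable; ``must_keep`` occurrences with zero reads are reported
    as mock dropouts.
    """
    stats = _occurrence_stats(table)
    keyed = stats.set_index(["variant", "sample", "replicate"])
    present = set(keyed.index)

    mock_dropouts = sorted(o for o in must_keep if o not in present)
    keep_rows = keyed.loc[sorted(must_keep - set(mock_dropouts))] if must_keep - set(mock_dropouts) else None
    drop_occs = sorted(o for o in must_drop if o in present)
    drop_rows = keyed.loc[drop_occs] if drop_occs else None

    # Per-axis feasibility caps: the filter keeps an occurrence iff its
    # statistic is >= the threshold, so each cap is the weakest expected
    # occurrence's statistic on that axis.
    counts = stats["count"].to_numpy()
    var_ratios = stats["var_ratio"].to_numpy()
    rep_ratios = stats["rep_ratio"].to_numpy()

    def grid(values: np.ndarray, integer: bool) -> np.ndarray:
        vals = np.unique(values)
        eps = vals + 1 if integer else np.nextafter(vals, np.inf)
        g = np.unique(np.concatenate([[0], vals, eps]))
        # ratio thresholds live in [0, 1]; an occurrence at ratio 1.0 can
        # never be removed by a relative filter
        return g if integer else g[g <= 1.0]

    g_abs = grid(counts, integer=True)
    g_var = grid(var_ratios, integer=False)
    g_rep = grid(rep_ratios, integer=False)

    if keep_rows is not None and len(keep_rows):
        cap_abs = int(keep_rows["count"].min())
        cap_var = float(keep_rows["var_ratio"].min())
        cap_rep = float(keep_rows["rep_ratio"].min())
    else:
        cap_abs, cap_var, cap_rep = int(g_abs[-1]), float(g_var[-1]), float(g_rep[-1])
    g_abs = g_abs[g_abs <= cap_abs]
    g_var = g_var[g_var <= cap_var]
    g_rep = g_rep[g_rep <= cap_rep]

    if drop_rows is not None and len(drop_rows):
        dc = drop_rows["count"].to_numpy()
        dv = drop_rows["var_ratio"].to_numpy()
        dr = drop_rows["rep_ratio"].to_numpy()

        def removed(a: float, v: float, r: float) -> int:
            return int(np.count_nonzero((dc < a) | (dv < v) | (dr < r)))

        best = removed(g_abs[-1], g_var[-1], g_rep[-1])
        # Lexicographic minimization at constant removal count.
        a = next(float(x) for x in g_abs if removed(x, g_var[-1], g_rep[-1]) == best)
        v = next(float(x) for x in g_var if removed(a, x, g_rep[-1]) == best)
        r = next(float(x) for x in g_rep if removed(a, v, x) == best)
        th = LFNThresholds(int(a), v, r)
        eliminated = best
    else:
        th = LFNThresholds(0, 0.0, 0.0)
        eliminated = 0

    unremovable = []
    if drop_rows is not None and len(drop_rows):
        for occ, (_, row) in zip(drop_occs, drop_rows.iterrows()):
            if _survives(row, th):
                unremovable.append((occ, "above weakest expected mock occurrence"))

    retained = len(must_keep) - len(mock_dropouts)
    return CalibrationReport(th, retained, eliminated, unremovable, mock_dropouts)


def renkonen_distance(p: np.ndarray, q: np.ndarray) -> float:
    """1 - sum of elementwise minima of two relative-abundance profiles."""
    return float(1.0 - np.minimum(p, q).sum())


def renkonen_screen(
    table: ReadCountTable, cutoff: float = 0.5
) -> tuple[ReadCountTable, list[tuple[str, str, int, str]], FilterTrace]:
    """Drop outlier PCR replicates by within-sample Renkonen distance.

    For each (sample, marker), replicate profiles are counts normalized
    to sum 1; a replicate is dropped when its mean Renkonen distance to
    the other replicates exceeds ``cutoff``. Singleton replicates pass
    untouched. Dropping is simultaneous (all means computed on the input).

    Returns (screened table, dropped (sample, marker, replicate, reason),
    trace).
    """
    df = table.df.copy()
    df["marker"] = df["variant"].map(lambda v: table.variants[v].marker)
    dropped: list[tuple[str, str, int, str]] = []
    for (sample, marker), grp in df.groupby(["sample", "marker"]):
        pivot = grp.pivot_table(
            index="variant", columns="replicate", values="count", aggfunc="sum", fill_value=0
        )
        reps = list(pivot.columns)
        if len(reps) < 2:
            continue
        profiles = pivot.to_numpy(dtype=float)
        totals = profiles.sum(axis=0)
        profiles = profiles / totals
        for i, rep in enumerate(reps):
            others = [j for j in range(len(reps)) if j != i]
            mean_d = float(
                np.mean([renkonen_distance(profiles[:, i], profiles[:, j]) for j in others])
            )
            if mean_d > cutoff:
                dropped.append((sample, marker, int(rep), f"mean Renkonen {mean_d:.3f} > {cutoff}"))

    drop_keys = {(s, m, r) for s, m, r, _ in dropped}
    mask = [
        (row.sample, row.marker, row.replicate) not in drop_keys for row in df.itertuples()
    ]
    out = table.keep_mask(pd.Series(mask, index=table.df.index))
    trace = FilterTrace()
    trace.add(
        "renkonen_screen",
        table.n_occurrences() - out.n_occurrences(),
        replicates_removed=len(dropped),
    )
    return out, dropped, trace


def replicate_consensus(
    table: ReadCountTable, min_replicates: int = 2
) -> tuple[pd.DataFrame, FilterTrace]:
    """Validate (variant, sample) presences supported by enough replicates.

    A variant is validated in a sample iff it has a positive count in at
    least ``min_replicates`` surviving replicates; its pooled count is the
    sum over those replicates. Returns a long table with columns
    (variant, marker, sample, count, n_replicates).
    """
    df = table.df
    grouped = df.groupby(["variant", "sample"]).agg(
        count=("count", "sum"), n_replicates=("replicate", "nunique")
    )
    validated = grouped[grouped["n_replicates"] >= min_replicates].reset_index()
    validated["marker"] = validated["variant"].map(lambda v: table.variants[v].marker)
    validated = validated[["variant", "marker", "sample", "count", "n_replicates"]]
    validated = validated.sort_values(["variant", "sample"]).reset_index(drop=True)
    removed_occ = len(df) - int(
        df.set_index(["variant", "sample"]).index.isin(
            validated.set_index(["variant", "sample"]).index
        ).sum()
    )
    trace = FilterTrace()
    trace.add("replicate_consensus", removed_occ)
    return validated, trace


def filter_chain(
    table: ReadCountTable,
    thresholds: LFNThresholds,
    renkonen_cutoff: float = 0.5,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, ReadCountTable, FilterTrace]:
    """LFN filter -> Renkonen screen -> replicate consensus.

    Returns (validated long table, screened occurrence table, trace).
    """
    filtered, trace = lfn_filter(table, thresholds)
    screened, _, t2 = renkonen_screen(filtered, renkonen_cutoff)
    trace.steps.extend(t2.steps)
    validated, t3 = replicate_consensus(screened, min_replicates)
    trace.steps.extend(t3.steps)
    return validated, screened, trace


def habitat_unexpected_occurrences(
    table: ReadCountTable,
    validated: pd.DataFrame,
    sample_habitats: dict[str, str | None],
    variant_taxa: dict[str, str | None],
    habitat_map: dict[str, set[str]],
) -> tuple[set[Occurrence], list[str]]:
    """Occurrences of habitat-incompatible variants in eDNA samples.

    ``sample_habitats`` maps eDNA sample ids to their habitat (samples of
    other categories must not be included); ``variant_taxa`` maps variant
    ids to the taxon used for the habitat lookup. Taxa absent from
    ``habitat_map`` are treated as compatible everywhere and logged.
    """
    flagged: set[Occurrence] = set()
    unknown: list[str] = []
    bad_pairs = set()
    for row in validated.itertuples():
        habitat = sample_habitats.get(row.sample)
        if habitat is None:
            continue
        taxon = variant_taxa.get(row.variant)
        if taxon is None:
            continue
        allowed = habitat_map.get(taxon)
        if allowed is None:
            unknown.append(taxon)
            continue
        if habitat not in allowed:
            bad_pairs.add((row.variant, row.sample))
    if bad_pairs:
        for t in table.df.itertuples():
            if (t.variant, t.sample) in bad_pairs:
                flagged.add((t.variant, t.sample, t.replicate))
    return flagged, sorted(set(unknown))


def second_pass(
    table: ReadCountTable,
    must_keep: set[Occurrence],
    must_drop: set[Occurrence],
    unexpected: set[Occurrence],
    renkonen_cutoff: float = 0.5,
    min_replicates: int = 2,
) -> tuple[CalibrationReport, pd.DataFrame, FilterTrace]:
    """Recalibrate with habitat-unexpected occurrences and re-filter.

    Calibration and filtering restart from the original dereplicated
    table; with an empty ``unexpected`` set the result equals the first
    pass.
    """
    report = calibrate(table, must_keep, must_drop | unexpected)
    validated, _, trace = filter_chain(table, report.thresholds, renkonen_cutoff, min_replicates)
    return report, validated, trace
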