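import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olsp.counts import ReadCountTable
from olsp.design import Variant
from olsp.lfn import (
    LFNThresholds,
    calibrate,
    filter_chain,
    lfn_filter,
    renkonen_distance,
    renkonen_screen,
    replicate_consensus,
    second_pass,
)


def make_table(records):
    """records: (variant, sample, replicate, count); marker = variant prefix."""
    variants = {
        v: Variant(v, v.split("_")[0], "ACGTACGTACGTACGTACGT") for v, _, _, _ in records
    }
    return ReadCountTable.from_records(records, variants)


def random_table(rng, n_occurrences, max_count=8):
    keys = set()
    while len(keys) < n_occurrences:
        keys.add(
            (
                f"M_{rng.integers(1, 8):03d}",
                f"s{rng.integers(1, 5)}",
                int(rng.integers(1, 4)),
            )
        )
    records = [(v, s, r, int(rng.integers(1, max_count + 1))) for v, s, r in sorted(keys)]
    return make_table(records)


class TestLfnFilter:
    def test_absolute_threshold(self):
        table = make_table([("M_001", "s1", 1, 10)])
        out, trace = lfn_filter(table, LFNThresholds(t_abs=11))
        assert out.n_occurrences() == 0
        assert trace.total_removed() == 1

    def test_variant_ratio_threshold(self):
        table = make_table([("M_001", "s1", 1, 95), ("M_001", "s2", 1, 5)])
        out, _ = lfn_filter(table, LFNThresholds(t_abs=0, t_var=0.10, t_rep=0.0))
        assert out.occurrences() == {("M_001", "s1", 1)}

    def test_replicate_ratio_threshold(self):
        table = make_table([("M_001", "s1", 1, 2), ("M_002", "s1", 1, 98)])
        out, _ = lfn_filter(table, LFNThresholds(t_rep=0.05))
        assert out.occurrences() == {("M_002", "s1", 1)}

    def test_zero_thresholds_are_identity(self):
        table = make_table([("M_001", "s1", 1, 1), ("M_002", "s1", 2, 3)])
        out, trace = lfn_filter(table, LFNThresholds())
        assert out == table
        assert trace.total_removed() == 0

    def test_denominators_fixed_on_input(self):
        # M_001 in s1 (90 reads, 0.9% of its PCR) fails t_rep; under
        # cascaded denominators the s2 occurrence would then be rescued
        # (4/4 = 1.0), but denominators are fixed on the input: 4/94 < 5%.
        table = make_table(
            [("M_001", "s1", 1, 90), ("M_002", "s1", 1, 9910), ("M_001", "s2", 1, 4)]
        )
        out, _ = lfn_filter(table, LFNThresholds(t_rep=0.01, t_var=0.05))
        assert out.occurrences() == {("M_002", "s1", 1)}

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotence_and_monotonicity(self, data):
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(3, 25)))
        th = LFNThresholds(
            t_abs=int(rng.integers(0, 6)),
            t_var=float(rng.random() * 0.3),
            t_rep=float(rng.random() * 0.3),
        )
        once, trace = lfn_filter(table, th)
        twice, _ = lfn_filter(once, th)
        assert once == twice  # idempotent
        # conservation: input occurrences = kept + removed
        assert table.n_occurrences() == once.n_occurrences() + trace.total_removed()
        # monotonicity: raising any threshold never adds an occurrence
        higher = LFNThresholds(th.t_abs + 1, min(th.t_var + 0.05, 1.0), th.t_rep)
        stricter, _ = lfn_filter(table, higher)
        assert stricter.occurrences() <= once.occurrences()


def oracle_calibrate(table, must_keep, must_drop):
    """Exhaustive 3D search over the candidate threshold grid.

    Enumerates every (t_abs, t_var, t_rep) combination on the grid of
    observed statistics (+ epsilon above each), checks must_keep
    survival directly, maximizes must_drop removal, and picks the
    lexicographically smallest maximizer.
    """
    df = table.df.copy()
    df["var_total"] = df.groupby("variant")["count"].transform("sum")
    df["rep_total"] = df.groupby(["sample", "replicate"])["count"].transform("sum")
    df["vr"] = df["count"] / df["var_total"]
    df["rr"] = df["count"] / df["rep_total"]
    keyed = df.set_index(["variant", "sample", "replicate"])

    def grid(vals, integer):
        vals = np.unique(vals)
        eps = vals + 1 if integer else np.nextafter(vals, np.inf)
        g = np.unique(np.concatenate([[0], vals, eps]))
        return g if integer else g[g <= 1.0]

    ga = grid(df["count"].to_numpy(), True)
    gv = grid(df["vr"].to_numpy(), False)
    gr = grid(df["rr"].to_numpy(), False)

    keep = [o for o in sorted(must_keep) if o in keyed.index]
    drop = [o for o in sorted(must_drop) if o in keyed.index]
    kc = keyed.loc[keep]["count"].to_numpy() if keep else np.empty(0)
    kv = keyed.loc[keep]["vr"].to_numpy() if keep else np.empty(0)
    kr = keyed.loc[keep]["rr"].to_numpy() if keep else np.empty(0)
    dc = keyed.loc[drop]["count"].to_numpy() if drop else np.empty(0)
    dv = keyed.loc[drop]["vr"].to_numpy() if drop else np.empty(0)
    dr = keyed.loc[drop]["rr"].to_numpy() if drop else np.empty(0)

    shape = (len(ga), len(gv), len(gr))
    infeasible = np.zeros(shape, dtype=bool)
    for n in range(len(kc)):
        bad = (
            (ga[:, None, None] > kc[n])
            | (gv[None, :, None] > kv[n])
            | (gr[None, None, :] > kr[n])
        )
        infeasible |= bad
    removed = np.zeros(shape, dtype=np.int32)
    for n in range(len(dc)):
        removed += (
            (ga[:, None, None] > dc[n])
            | (gv[None, :, None] > dv[n])
            | (gr[None, None, :] > dr[n])
        )
    removed_masked = np.where(infeasible, -1, removed)
    best = removed_masked.max()
    ia, iv, ir = np.argwhere(removed_masked == best)[0]  # lexicographic min
    return LFNThresholds(int(ga[ia]), float(gv[iv]), float(gr[ir])), int(best)


class TestCalibrate:
    def test_absolute_separation_gives_t_abs_plus_one(self):
        records = [
            ("M_001", "Tpos1", 1, 50),
            ("M_001", "Tpos1", 2, 60),
            ("M_002", "neg", 1, 5),
        ]
        table = make_table(records)
        keep = {("M_001", "Tpos1", 1), ("M_001", "Tpos1", 2)}
        drop = {("M_002", "neg", 1)}
        report = calibrate(table, keep, drop)
        assert report.thresholds.t_abs == 6
        assert report.eliminated_unexpected == 1
        assert report.unremovable == []
        assert report.retained_expected == 2

    def test_strong_contaminant_is_unremovable(self):
        records = [("M_001", "Tpos1", 1, 20), ("M_002", "neg", 1, 500)]
        table = make_table(records)
        report = calibrate(
            table, {("M_001", "Tpos1", 1)}, {("M_002", "neg", 1)}
        )
        # the contaminant cannot be removed without losing the mock member
        assert [o for o, _ in report.unremovable] == [("M_002", "neg", 1)]

    def test_zero_read_expected_occurrence_is_a_dropout(self):
        table = make_table([("M_001", "Tpos1", 1, 20)])
        report = calibrate(
            table, {("M_001", "Tpos1", 1), ("M_001", "Tpos1", 2)}, set()
        )
        assert report.mock_dropouts == [("M_001", "Tpos1", 2)]
        assert report.retained_expected == 1

    def test_empty_drop_set_keeps_zero_thresholds(self):
        table = make_table([("M_001", "s1", 1, 3)])
        report = calibrate(table, {("M_001", "s1", 1)}, set())
        assert report.thresholds == LFNThresholds(0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(8, 30)))
        occs = sorted(table.occurrences())
        rng.shuffle(occs)
        n_keep = int(rng.integers(1, 4))
        n_drop = int(rng.integers(1, max(2, len(occs) - n_keep)))
        keep = set(occs[:n_keep])
        drop = set(occs[n_keep : n_keep + n_drop])
        report = calibrate(table, keep, drop)
        oracle_th, oracle_removed = oracle_calibrate(table, keep, drop)
        assert report.thresholds == oracle_th
        assert report.eliminated_unexpected == oracle_removed


class TestRenkonenScreen:
    def test_formula(self):
        assert renkonen_distance(np.array([0.7, 0.3]), np.array([0.5, 0.5])) == pytest.approx(0.2)
        assert renkonen_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_identical_profiles_kept(self):
        table = make_table(
            [("M_001", "s1", 1, 10), ("M_001", "s1", 2, 20),
             ("M_002", "s1", 1, 30), ("M_002", "s1", 2, 60)]
        )
        out, dropped, _ = renkonen_screen(table, cutoff=0.5)
        assert dropped == []
        assert out == table

    def test_disjoint_profiles_both_dropped(self):
        table = make_table([("M_001", "s1", 1, 10), ("M_002", "s1", 2, 10)])
        out, dropped, trace = renkonen_screen(table, cutoff=0.5)
        assert len(dropped) == 2
        assert out.n_occurrences() == 0
        assert trace.steps[0]["replicates_removed"] == 2

    def test_outlier_replicate_dropped(self):
        table = make_table(
            [("M_001", "s1", 1, 50), ("M_001", "s1", 2, 50), ("M_002", "s1", 3, 50)]
        )
        _, dropped, _ = renkonen_screen(table, cutoff=0.5)
        assert [(s, m, r) for s, m, r, _ in dropped] == [("s1", "M", 3)]

    def test_singleton_replicate_passes(self):
        table = make_table([("M_001", "s1", 1, 5)])
        out, dropped, _ = renkonen_screen(table, cutoff=0.5)
        assert dropped == [] and out == table


class TestReplicateConsensus:
    def test_two_of_three_replicates_validated(self):
        table = make_table([("M_001", "s1", 1, 10), ("M_001", "s1", 3, 15)])
        validated, _ = replicate_consensus(table, min_replicates=2)
        assert len(validated) == 1
        assert validated.iloc[0]["count"] == 25

    def test_single_replicate_removed(self):
        table = make_table([("M_001", "s1", 2, 10)])
        validated, trace = replicate_consensus(table, min_replicates=2)
        assert validated.empty
        assert trace.total_removed() == 1


class TestSecondPass:
    def test_empty_unexpected_set_is_fixed_point(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, 15)
        occs = sorted(table.occurrences())
        keep, drop = {occs[0]}, set(occs[5:9])
        pass1 = calibrate(table, keep, drop)
        report, _, _ = second_pass(table, keep, drop, set())
        assert report.thresholds == pass1.thresholds

    def test_planted_unexpected_occurrence_removed(self):
        records = [
            ("M_001", "Tpos1", 1, 100), ("M_001", "Tpos1", 2, 110),
            ("M_002", "brackish_sample", 1, 8), ("M_002", "brackish_sample", 2, 9),
        ]
        table = make_table(records)
        keep = {("M_001", "Tpos1", 1), ("M_001", "Tpos1", 2)}
        unexpected = {("M_002", "brackish_sample", 1), ("M_002", "brackish_sample", 2)}
        report, validated, _ = second_pass(table, keep, set(), unexpected)
        assert report.eliminated_unexpected == 2
        assert "M_002" not in set(validated["variant"])
        assert {("M_001", "Tpos1")} == set(zip(validated["variant"], validated["sample"]))


class TestFilterChainConservation:
    def test_occurrence_conservation_across_trace(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, 25)
        validated, screened, trace = filter_chain(table, LFNThresholds(t_abs=3), 0.5, 2)
        kept_occurrences = sum(
            1
            for row in screened.df.itertuples()
            if (row.variant, row.sample) in set(zip(validated["variant"], validated["sample"]))
        )
        assert table.n_occurrences() == kept_occurrences + trace.total_removed()
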