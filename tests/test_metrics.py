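import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis

from olsp.metrics import (
    bc_table,
    bray_curtis,
    bsd_table,
    com_table,
    complementarity_com,
    coverage_bc,
    ir_table,
    mni_matrix,
    mni_summary,
    wsd_table,
)

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def item_row(item, sample, markers, motu, *names, ir=6):
    names = names + (None,) * (len(RANK_NAMES) - len(names))
    return {
        "item": item,
        "sample": sample,
        "markers": frozenset(markers),
        "motu": motu,
        **dict(zip(RANK_NAMES, names)),
        "ir_score": ir,
        "macro": True,
    }


@pytest.fixture
def items():
    rows = [
        item_row("v1", "s1", {"A", "B"}, "m1",
                 "Animalia", "Arthropoda", "Insecta", "Diptera", "Chironomidae",
                 "Chironomus", "Chironomus riparius"),
        item_row("v2", "s1", {"A"}, "m1",
                 "Animalia", "Arthropoda", "Insecta", "Diptera", "Chironomidae",
                 "Chironomus", "Chironomus plumosus"),
        item_row("v3", "s1", {"C"}, "m2",
                 "Animalia", "Arthropoda", "Insecta", "Ephemeroptera", "Baetidae",
                 "Baetis", "Baetis fuscatus", ir=5),
        item_row("v1", "s2", {"B"}, "m1",
                 "Animalia", "Arthropoda", "Insecta", "Diptera", "Chironomidae",
                 "Chironomus", "Chironomus riparius"),
    ]
    return pd.DataFrame(rows)


class TestCoverageBc:
    def test_fraction(self):
        assert coverage_bc({"t1", "t2"}, {"t1", "t2", "t3"}) == pytest.approx(2 / 3)

    def test_full_union(self):
        assert coverage_bc({"t1"}, {"t1"}) == 1.0

    def test_empty_union_excluded(self):
        assert coverage_bc(set(), set()) is None

    def test_subset_violation_raises(self):
        with pytest.raises(ValueError):
            coverage_bc({"t1"}, {"t2"})


class TestComplementarityCom:
    def test_exactly_one_fraction(self):
        value = complementarity_com({"A": {"t1", "t2"}, "B": {"t2"}, "C": {"t3"}})
        assert value == pytest.approx(2 / 3)

    def test_identical_sets_zero(self):
        assert complementarity_com({"A": {"t"}, "B": {"t"}}) == 0.0

    def test_disjoint_sets_one(self):
        assert complementarity_com({"A": {"t1"}, "B": {"t2"}}) == 1.0

    def test_single_set_is_an_error(self):
        with pytest.raises(ValueError):
            complementarity_com({"A": {"t"}})


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([2, 1], [2, 1]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([2, 0], [0, 3]) == 1.0

    def test_formula(self):
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_both_zero_undefined(self):
        assert bray_curtis([0, 0], [0, 0]) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, size=6).astype(float)
        y = rng.integers(0, 10, size=6).astype(float)
        if x.sum() + y.sum() == 0:
            return
        assert bray_curtis(x, y) == pytest.approx(braycurtis(x, y))


class TestMniMatrix:
    def test_variant_level_one_cell_per_item(self, items):
        mat = mni_matrix(items, "variant")
        assert mat.loc["s1"].sum() == 3
        assert mat.loc["s2"].sum() == 1
        assert set(mat.columns) == {"v1", "v2", "v3"}

    def test_aggregation_conserves_totals(self, items):
        for level in ("phylum", "class", "order", "family", "motu"):
            mat = mni_matrix(items, level)
            assert mat.loc["s1"].sum() == 3, level
            assert mat.loc["s2"].sum() == 1, level

    def test_coarser_levels_have_fewer_cells(self, items):
        nonzero = {
            level: (mni_matrix(items, level).loc["s1"] > 0).sum()
            for level in ("phylum", "order", "motu", "variant")
        }
        assert nonzero["phylum"] <= nonzero["order"] <= nonzero["motu"] <= nonzero["variant"]

    def test_unassigned_items_get_stable_pseudo_label(self):
        rows = [item_row("vx", "s1", {"A"}, "m9")]
        mat = mni_matrix(pd.DataFrame(rows), "family")
        assert list(mat.columns) == ["unassigned_vx"]


class TestDetectionTables:
    def test_bc_per_sample(self, items):
        bc = bc_table(items, ["A", "B", "C"])
        s1 = bc[(bc["scope"] == "sample") & (bc["sample"] == "s1") & (bc["level"] == "variant")]
        values = dict(zip(s1["marker"], s1["value"]))
        assert values == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3),
                          "C": pytest.approx(1 / 3)}

    def test_com_per_sample(self, items):
        com = com_table(items, ["A", "B", "C"])
        s1 = com[(com["scope"] == "sample") & (com["sample"] == "s1") & (com["level"] == "variant")]
        # v2 (A only) and v3 (C only) are exclusive; v1 is shared
        assert s1["value"].iloc[0] == pytest.approx(2 / 3)

    def test_wsd_identical_vectors_zero(self):
        rows = [
            item_row("v1", "s1", {"A", "B"}, "m1", "Animalia"),
            item_row("v2", "s1", {"A", "B"}, "m2", "Animalia"),
        ]
        wsd = wsd_table(pd.DataFrame(rows), ["A", "B"])
        assert (wsd["value"] == 0.0).all()

    def test_wsd_disjoint_detections_one(self):
        rows = [
            item_row("v1", "s1", {"A"}, "m1", "Animalia"),
            item_row("v2", "s1", {"B"}, "m2", "Animalia"),
        ]
        wsd = wsd_table(pd.DataFrame(rows), ["A", "B"])
        at_variant = wsd[wsd["level"] == "variant"]
        assert at_variant["value"].iloc[0] == 1.0

    def test_wsd_single_marker_sample_excluded(self):
        rows = [item_row("v1", "s1", {"A"}, "m1", "Animalia")]
        wsd = wsd_table(pd.DataFrame(rows), ["A", "B"])
        assert wsd.empty

    def test_bsd_duplicate_samples_zero(self, items):
        dup = items.copy()
        dup.loc[dup["sample"] == "s2", "sample"] = "s1b"
        rows = pd.concat(
            [items[items["sample"] == "s1"],
             items[items["sample"] == "s1"].assign(sample="s1copy")],
            ignore_index=True,
        )
        bsd = bsd_table(rows)
        assert (bsd["value"] == 0.0).all()

    def test_bsd_values_in_unit_interval(self, items):
        bsd = bsd_table(items)
        assert ((bsd["value"] >= 0) & (bsd["value"] <= 1)).all()


class TestSummaries:
    def test_mni_per_sample_and_group(self, items):
        out = mni_summary(items, groups={"s1": "fish", "s2": "fish"})
        per_sample = out[out["scope"] == "sample"].set_index("key")["mni"]
        assert per_sample["s1"] == 3 and per_sample["s2"] == 1
        grp = out[out["scope"] == "group"].iloc[0]
        assert grp["mean"] == pytest.approx(2.0)
        assert grp["sd"] == pytest.approx(np.std([3, 1], ddof=1))

    def test_group_sd_formula(self):
        rows = [item_row(f"v{i}", "sa", {"A"}, f"m{i}", "Animalia") for i in range(2)]
        rows += [item_row(f"w{i}", "sb", {"A"}, f"n{i}", "Animalia") for i in range(4)]
        out = mni_summary(pd.DataFrame(rows), groups={"sa": "g", "sb": "g"})
        grp = out[out["scope"] == "group"].iloc[0]
        assert grp["mean"] == 3.0
        assert grp["sd"] == pytest.approx(1.4142135623730951)

    def test_ir_table_means(self, items):
        out = ir_table(items)
        per_sample = out[out["scope"] == "sample"].set_index("key")["value"]
        assert per_sample["s1"] == pytest.approx((6 + 6 + 5) / 3)
        assert per_sample["s2"] == 6.0
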