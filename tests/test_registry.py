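import numpy as np
import pytest

from polyphenolkit.errors import SchemaError
from polyphenolkit.registry import (
    CompoundRecord,
    OutlierConfig,
    coverage_summary,
    flag_mass_outliers,
    load_compound_table,
    reconcile,
)
from tests.conftest import write_csv

KEY_A = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
KEY_A_STEREO = "AAAAAAAAAAAAAA-CCCCCCCCCC-N"
KEY_B = "DDDDDDDDDDDDDD-EEEEEEEEEE-N"


def rec(cid, key=None, subclass="flavonols", cls="flavonoid", source="phytohub", **kw):
    return CompoundRecord(
        compound_id=cid,
        name=kw.pop("name", cid),
        cls=cls,
        subclass=subclass,
        inchikey=key,
        sources=frozenset({source}),
        **kw,
    )


class TestLoad:
    def test_three_rows_three_records(self, tmp_path):
        p = write_csv(
            tmp_path / "t.csv",
            "name,subclass,inchikey\n"
            f"quercetin,flavonols,{KEY_A}\n"
            f"rutin,flavonols,{KEY_B}\n"
            "mystery,chalcones,",
        )
        records = load_compound_table(p, "phytohub")
        assert len(records) == 3
        assert all(r.sources == {"phytohub"} for r in records)
        assert records[2].inchikey is None  # blank cell -> absent, not ""
        assert records[0].cls == "flavonoid"  # filled from taxonomy

    def test_missing_subclass_column_raises(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", "name\nquercetin")
        with pytest.raises(SchemaError) as exc:
            load_compound_table(p, "phytohub")
        assert exc.value.column == "subclass"

    def test_malformed_inchikey_rejected(self):
        with pytest.raises(ValueError, match="InChIKey"):
            rec("x", key="not-a-key")


class TestReconcile:
    def test_same_key_two_sources_merges(self):
        a = rec("a", KEY_A, source="phytohub")
        b = rec("b", KEY_A, source="phenol_explorer", registry_number="CHEMBL1")
        result = reconcile([[a], [b]])
        assert len(result.records) == 1
        merged = result.records[0]
        assert merged.sources == {"phytohub", "phenol_explorer"}
        assert merged.registry_number == "CHEMBL1"  # filled from lower-precedence source

    def test_disjoint_keys_concatenate(self):
        result = reconcile([[rec("a", KEY_A)], [rec("b", KEY_B, source="chembl")]])
        assert len(result.records) == 2
        assert not result.conflicts

    def test_conflicting_subclass_reports_and_precedence_wins(self):
        # 4-record fixture enumerated by hand: two agree on KEY_A but disagree
        # on subclass; one keyless record; one distinct key
        records = [
            [rec("a", KEY_A, subclass="flavonols", source="phytohub")],
            [rec("b", KEY_A, subclass="flavones", source="chembl")],
            [rec("c", None), rec("d", KEY_B)],
        ]
        result = reconcile(records)
        assert len(result.records) == 3  # merged + keyless + distinct
        assert len(result.conflicts) == 1
        conflict = result.conflicts[0]
        assert conflict.field == "subclass"
        assert conflict.winner == "flavonols"  # phytohub outranks chembl

    def test_idempotent(self):
        coll = [
            [rec("a", KEY_A), rec("c", None)],
            [rec("b", KEY_A, source="chembl"), rec("d", KEY_B, source="chembl")],
        ]
        once = reconcile(coll).records
        twice = reconcile([once]).records
        assert [(r.inchikey, r.sources) for r in once] == [
            (r.inchikey, r.sources) for r in twice
        ]

    def test_order_insensitive(self):
        colls = [[rec("a", KEY_A, source="phytohub")], [rec("b", KEY_A, source="chembl")]]
        fwd = reconcile(colls).records[0]
        rev = reconcile(colls[::-1]).records[0]
        assert fwd.sources == rev.sources and fwd.compound_id == rev.compound_id

    def test_skeleton_match_reported_not_merged(self):
        result = reconcile([[rec("a", KEY_A)], [rec("b", KEY_A_STEREO, source="chembl")]])
        assert len(result.records) == 2  # stereoisomers stay distinct
        assert (KEY_A, KEY_A_STEREO) in result.skeleton_matches


class TestCoverage:
    def test_reported_flavonol_fraction(self):
        # 324 unique flavonols of which 187 carry registry numbers -> 57.7%
        records = [
            rec(f"c{i}", registry_number="CHEMBL%d" % i if i < 187 else None)
            for i in range(324)
        ]
        summary = coverage_summary(records)
        row = summary.loc[summary["subclass"] == "flavonols"].iloc[0]
        assert row["n_unique"] == 324 and row["n_with_registry"] == 187
        assert row["pct_with_registry"] == pytest.approx(57.716, abs=0.001)

    def test_anthocyanin_count_from_percentage(self):
        # 71% of 89 anthocyanins -> 63 with registry numbers
        n_reg = round(0.71 * 89)
        records = [
            rec(f"c{i}", subclass="anthocyanins",
                registry_number="R%d" % i if i < n_reg else None)
            for i in range(89)
        ]
        row = coverage_summary(records).iloc[0]
        assert row["n_with_registry"] == 63
        assert row["pct_with_registry"] == pytest.approx(100 * 63 / 89)

    def test_empty_collection(self):
        assert coverage_summary([]).empty

    def test_unique_counts_partition_distinct_records(self):
        records = [rec("a", KEY_A), rec("dup", KEY_A), rec("b", KEY_B, subclass="flavones"),
                   rec("c", None, subclass="chalcones")]
        summary = coverage_summary(records)
        distinct = len({r.inchikey or f"id:{r.compound_id}" for r in records})
        assert summary["n_unique"].sum() == distinct


class TestMassOutliers:
    def test_published_reference_stats_flag_ellagitannins(self):
        # z for MW 1084.72 against mean 357.41, SD 176.96 is 4.11
        records = [rec(f"c{i}", subclass="hydroxybenzoic acids") for i in range(3)]
        mw = {"c0": 1084.72, "c1": 357.41, "c2": 2805.91}
        out = dict(
            (cid, (z, fl))
            for cid, z, fl in flag_mass_outliers(
                records, mw, OutlierConfig(z_threshold=3.0), reference=(357.41, 176.96)
            )
        )
        assert out["c0"][0] == pytest.approx(4.110, abs=0.001) and out["c0"][1]
        assert out["c1"][0] == 0.0 and not out["c1"][1]
        assert out["c2"][1]  # 2805.91 g/mol is flagged

    def test_leave_one_out_does_not_mask_single_outlier(self):
        typical = [300.0, 320.0, 340.0, 360.0, 380.0, 400.0]
        records = [rec(f"c{i}") for i in range(7)]
        mw = {f"c{i}": v for i, v in enumerate(typical + [1800.0])}
        flags = {cid: fl for cid, _, fl in flag_mass_outliers(records, mw)}
        assert flags["c6"] and not any(flags[f"c{i}"] for i in range(6))

    def test_small_subclass_skipped_with_warning(self):
        records = [rec("a"), rec("b")]
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = flag_mass_outliers(records, {"a": 100.0, "b": 200.0})
        assert out == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            OutlierConfig(z_threshold=0)

    def test_exact_flag_set_on_fixture(self, rng):
        values = np.concatenate([rng.normal(350, 50, 30), [1200.0, 2400.0]])
        records = [rec(f"c{i}") for i in range(32)]
        mw = {f"c{i}": float(v) for i, v in enumerate(values)}
        result = flag_mass_outliers(records, mw, reference=(350.0, 50.0))
        expected = {f"c{i}": abs((mw[f"c{i}"] - 350.0) / 50.0) > 3 for i in range(32)}
        assert {cid: fl for cid, _, fl in result} == expected
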