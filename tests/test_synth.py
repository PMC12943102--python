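import json

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from scipy import stats

from polyphenolkit import bioactivity, food
from polyphenolkit.registry import CompoundRecord, OutlierConfig, flag_mass_outliers
from polyphenolkit.synth import (
    ScaffoldLibrary,
    SynthesisConfig,
    generate_activities,
    generate_compounds,
    generate_foods,
    write_run,
)


class TestCompounds:
    def test_requested_counts_and_classes(self, small_compounds, small_config):
        df, truth = small_compounds
        by_cls = df.groupby("cls").size()
        extra = small_config.n_misclassified_heavy
        assert by_cls["flavonoid"] == small_config.n_flavonoids
        assert by_cls["phenolic_acid"] == small_config.n_phenolic_acids + extra

    def test_structures_parse_and_roundtrip(self, small_compounds):
        df, _ = small_compounds
        canon = []
        for smi in df["smiles"]:
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            canon.append(Chem.MolToSmiles(Chem.MolFromSmiles(Chem.MolToSmiles(mol))))
        assert len(set(canon)) == len(canon)  # unique within the run

    def test_inchikeys_match_structures(self, small_compounds):
        df, _ = small_compounds
        row = df.iloc[0]
        assert Chem.MolToInchiKey(Chem.MolFromSmiles(row["smiles"])) == row["inchikey"]

    def test_registry_coverage_within_binomial_interval(self):
        config = SynthesisConfig(
            seed=5,
            n_flavonoids=50,
            n_phenolic_acids=0,
            subclass_proportions={"flavonols": 1.0},
            n_misclassified_heavy=0,
        )
        df, _ = generate_compounds(config)
        k = int(df["registry_number"].notna().sum())
        lo, hi = stats.binom.interval(0.95, 50, 0.58)
        assert lo <= k <= hi

    def test_empty_request_empty_tables(self):
        config = SynthesisConfig(
            seed=0, n_flavonoids=0, n_phenolic_acids=0, n_misclassified_heavy=0
        )
        df, _ = generate_compounds(config)
        assert df.empty

    def test_heavy_misfiled_compounds_are_flagged_downstream(self):
        from polyphenolkit.descriptors import compute_descriptors

        # subclass large enough that three poly-glycosylated intruders are a
        # realistic (low) contamination rate; robust statistics resist them
        config = SynthesisConfig(seed=19, n_flavonoids=10, n_phenolic_acids=90)
        df, truth = generate_compounds(config)
        sub = df[df["subclass"] == "hydroxybenzoic acids"]
        records = [
            CompoundRecord(
                compound_id=r["compound_id"], name=r["name"], cls=r["cls"],
                subclass=r["subclass"], sources=frozenset({"synthetic"}),
            )
            for _, r in sub.iterrows()
        ]
        mw = {
            r["compound_id"]: compute_descriptors(r["smiles"]).mw
            for _, r in sub.iterrows()
        }
        flags = {
            cid
            for cid, _, fl in flag_mass_outliers(records, mw, OutlierConfig(robust=True))
            if fl
        }
        assert set(truth["misclassified_heavy_ids"]) <= flags


class TestActivities:
    def test_truncation_bounds_respected(self, small_compounds, small_config):
        df, _ = small_compounds
        act, _ = generate_activities(small_config, df)
        kept, _ = bioactivity.filter_records(act)
        p = bioactivity.add_pchembl(kept)["pchembl"]
        assert p.min() >= 6.01 - 1e-9 and p.max() <= 9.70 + 1e-9

    def test_violating_fraction_ground_truth_bookkeeping(self, small_compounds):
        df, _ = small_compounds
        config = SynthesisConfig(
            seed=3,
            violating_fraction=0.3,
            duplicate_assay_fraction=0.0,
            n_activities={"flavonoid": 100, "phenolic_acid": 0},
        )
        act, truth = generate_activities(config, df)
        kept, _ = bioactivity.filter_records(act)
        assert len(act) == 100
        assert len(kept) == 70  # exactly n - round(0.3 n)
        rejected_ids = set(act["record_id"]) - set(kept["record_id"])
        assert rejected_ids == {v["record_id"] for v in truth["violating"]}

    def test_shared_targets_present_in_both_pools(self, small_compounds, small_config):
        df, _ = small_compounds
        act, _ = generate_activities(small_config, df)
        for cls in ("flavonoid", "phenolic_acid"):
            targets = set(act.loc[act["cls"] == cls, "target_id"])
            assert {"SLCO1B1", "SLCO1B3", "p53"} & targets

    def test_collapsed_pairs_match_ground_truth(self, small_compounds, small_config):
        df, _ = small_compounds
        act, truth = generate_activities(small_config, df)
        kept, _ = bioactivity.filter_records(act)
        collapsed = bioactivity.collapse_best(bioactivity.add_pchembl(kept))
        by_cls = collapsed.groupby("cls").size().to_dict()
        assert by_cls == truth["n_pairs"]


class TestFoods:
    def test_tier_anchor_recovery(self, small_compounds, small_config):
        df, _ = small_compounds
        table, truth = generate_foods(small_config, df)
        kept, _ = food.standardize_table(table)
        totals = food.tier_table(food.food_totals(kept)).set_index("food_name")
        expected = {"herbs and spices": "high", "fruits": "medium", "nuts and seeds": "lower"}
        for group, tier in expected.items():
            anchor = f"food-{group.replace(' ', '-')}-00"
            assert totals.loc[anchor, "tier"] == tier

    def test_dominant_group_primary_share(self, small_compounds, small_config):
        df, _ = small_compounds
        table, truth = generate_foods(small_config, df)
        kept, _ = food.standardize_table(table)
        profiles = {p.food_group: p for p in food.group_profiles(kept)}
        assert profiles[truth["dominant_group"]].primary_pct > 90.0

    def test_mixed_units_present(self, small_compounds, small_config):
        df, _ = small_compounds
        table, _ = generate_foods(small_config, df)
        assert set(table["unit"]) == {"mg/kg", "mg/100g"}


class TestDeterminism:
    def test_same_seed_byte_identical_run(self, tmp_path, small_config):
        d1 = write_run(small_config, tmp_path / "a")
        d2 = write_run(small_config, tmp_path / "b")
        for name in ("compounds.csv", "activities.csv", "foods.csv", "ground_truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self, tmp_path, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        d1 = write_run(small_config, tmp_path / "a")
        d2 = write_run(other, tmp_path / "b")
        assert (d1 / "compounds.csv").read_bytes() != (d2 / "compounds.csv").read_bytes()

    def test_ground_truth_sidecar_written(self, tmp_path, small_config):
        rundir = write_run(small_config, tmp_path / "runs")
        truth = json.loads((rundir / "ground_truth.json").read_text())
        assert set(truth) == {"compounds", "activities", "foods"}


class TestConfigValidation:
    def test_bad_coverage_probability(self):
        with pytest.raises(ValueError, match="coverage"):
            SynthesisConfig(registry_coverage={"flavonols": 1.5})

    def test_pool_smaller_than_shared_list(self):
        with pytest.raises(ValueError, match="shared"):
            SynthesisConfig(target_pool_sizes={"flavonoid": 2, "phenolic_acid": 33})
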