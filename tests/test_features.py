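"""Feature engineering: mutation classification, molecular aggregation,
property joins and correlation-based feature selection."""

import numpy as np
import pandas as pd
import pytest

import driversvm as dv
from driversvm.errors import InputError
from driversvm.features import EXCLUDED_PROPERTIES, JoinReport


@pytest.mark.parametrize(
    "variant_class,damaging,hotspot,expected",
    [
        ("frameshift", False, False, "truncating"),
        ("stop_gained", True, False, "truncating"),
        ("stop_lost", False, False, "truncating"),
        ("splice_site", False, False, "truncating"),
        ("missense", True, False, "nontruncating_damaging"),
        ("inframe_indel", True, False, "nontruncating_damaging"),
        ("missense", True, True, "nontruncating_damaging"),
        ("missense", False, True, "hotspot_only"),
        ("missense", False, False, "nontruncating_other"),
        ("synonymous", False, False, "not_damaging"),
        ("other", False, False, "not_damaging"),
    ],
)
def test_classify_mutation_map(variant_class, damaging, hotspot, expected):
    assert dv.classify_mutation(variant_class, damaging, hotspot) == expected


def test_classify_mutation_rejects_unknown_class():
    with pytest.raises(InputError, match="nonsense"):
        dv.classify_mutation("nonsense")


class TestMolecularFeatures:
    def test_counts_per_gene(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        feats = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        kras = feats[(feats["sample"] == "S1") & (feats["gene"] == "KRAS")].iloc[0]
        assert kras["mutational_load"] == 3
        assert kras["n_nontrunc_damaging"] == 2
        assert kras["n_truncating"] == 1
        assert kras["n_hotspot"] == 1
        assert not kras["is_amplified"] and not kras["is_deleted"]

    def test_amplification_alone_is_damage(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        feats = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        myc = feats[(feats["sample"] == "S1") & (feats["gene"] == "MYC")]
        assert len(myc) == 1 and bool(myc.iloc[0]["is_amplified"])
        cdkn2a = feats[(feats["sample"] == "S2") & (feats["gene"] == "CDKN2A")]
        assert bool(cdkn2a.iloc[0]["is_deleted"])

    def test_undamaged_pairs_not_emitted(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        feats = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        pairs = set(zip(feats["sample"], feats["gene"]))
        assert ("S1", "GENEX") not in pairs  # synonymous only
        assert ("S2", "GENEY") not in pairs  # benign missense
        assert ("S1", "GENEZ") not in pairs  # copy-neutral

    def test_missing_ploidy_rejected(self, tiny_mutations, tiny_cnvs):
        ploidy = pd.DataFrame({"sample": ["S1"], "ploidy": [2.0]})
        with pytest.raises(InputError, match="S2"):
            dv.build_molecular_features(tiny_mutations, tiny_cnvs, ploidy)

    def test_every_emitted_row_is_damaged(self, small_cohort):
        feats = dv.build_molecular_features(small_cohort.mutations, small_cohort.cnvs, small_cohort.ploidy)
        damaged = (
            (feats["n_truncating"] > 0)
            | (feats["n_nontrunc_damaging"] > 0)
            | (feats["n_hotspot"] > 0)
            | feats["is_amplified"]
            | feats["is_deleted"]
        )
        assert damaged.all()
        assert not feats.duplicated(subset=["sample", "gene"]).any()

    def test_rerun_is_identical(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        a = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        b = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        pd.testing.assert_frame_equal(a, b)


class TestJoinFeatures:
    def _props(self, genes):
        rng = np.random.default_rng(0)
        spec = dv.FixtureSpec(n_genes=10, n_driver_genes=1, n_samples=1, n_candidate_genes=1,
                              n_false_positive_genes=1, seed=0)
        base = dv.generate_fixture_cohort(spec).properties.iloc[: len(genes)].copy()
        base["gene"] = genes
        return base.reset_index(drop=True)

    def test_drop_report_accounts_for_all_rows(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        molecular = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        props = self._props(["KRAS", "TP53", "MYC"])  # CDKN2A missing
        joined, report = dv.join_features(molecular, props)
        assert report.n_output + report.n_dropped == report.n_input == len(molecular)
        assert report.dropped_genes == ["CDKN2A"]
        assert set(dv.ALL_FEATURES) <= set(joined.columns)

    def test_duplicate_gene_key_rejected(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        molecular = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        props = self._props(["KRAS", "KRAS", "TP53"])
        with pytest.raises(InputError, match="duplicated"):
            dv.join_features(molecular, props)

    def test_excluded_properties_dropped(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        molecular = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        props = self._props(["KRAS", "TP53", "MYC", "CDKN2A"])
        props["protein_length"] = 500.0
        props["n_domains"] = 3.0
        joined, _ = dv.join_features(molecular, props)
        for col in EXCLUDED_PROPERTIES:
            assert col not in joined.columns

    def test_empty_join_rejected(self, tiny_mutations, tiny_cnvs, tiny_ploidy):
        molecular = dv.build_molecular_features(tiny_mutations, tiny_cnvs, tiny_ploidy)
        props = self._props(["OTHER1", "OTHER2"])
        with pytest.raises(InputError, match="no annotatable"):
            dv.join_features(molecular, props)


class TestSelectFeatures:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        retained, report = dv.select_features(df)
        assert retained == ["b", "c"] or retained == ["a", "c"]
        sig = report[report["significant"]]
        assert {"a", "b"} == set(sig[["feature_a", "feature_b"]].iloc[0])

    def test_independent_columns_none_removed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 8)), columns=[f"f{i}" for i in range(8)])
        retained, _ = dv.select_features(df)
        assert retained == list(df.columns)

    def test_correlated_quartet_flagged(self):
        # two tissue-expression features and two network features built to
        # correlate pairwise above the threshold, as in real property tables
        rng = np.random.default_rng(3)
        n = 500
        expr = rng.normal(size=n)
        net = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "expr_mid": expr + rng.normal(scale=0.3, size=n),
                "expr_high": expr + rng.normal(scale=0.3, size=n),
                "prot_low": expr + rng.normal(scale=0.3, size=n),
                "central": net,
                "degree": net + rng.normal(scale=0.3, size=n),
                "unrelated": rng.normal(size=n),
            }
        )
        retained, report = dv.select_features(df)
        assert "unrelated" in retained
        flagged = set(df.columns) - set(retained)
        # greedy removal breaks every significant pair
        sig = report[report["significant"]]
        assert all(a in flagged or b in flagged for a, b in zip(sig["feature_a"], sig["feature_b"]))
        assert flagged <= {"expr_mid", "expr_high", "prot_low", "central", "degree"}
        assert len(flagged) >= 3

    def test_non_numeric_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": ["x", "y", "z"]})
        with pytest.raises(InputError, match="'b'"):
            dv.select_features(df)

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InputError):
            dv.select_features(df)
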