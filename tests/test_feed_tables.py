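import pytest

from ne_pipeline.errors import DomainError, SchemaError, ValidationError
from ne_pipeline.feed_tables import (
    DietFormulation,
    IngredientComposition,
    cp_from_nitrogen,
    derive_sdf,
    read_ingredient_table,
    summarize_compositions,
    write_ingredient_table,
)


def make_ingredient(**overrides):
    base = dict(
        ingredient_id="x", GE=18.7, DM=88.0, CP=17.3, EE=2.1, starch=12.8,
        NDF=51.0, ADF=14.5, IDF=46.9, SDF=3.55, TDF=50.45, ash=6.7,
    )
    base.update(overrides)
    return IngredientComposition(**base)


class TestDerivedChemistry:
    @pytest.mark.parametrize(
        "tdf, idf, expected",
        [(21.49, 16.93, 4.56), (10.0, 10.0, 0.0), (50.45, 46.88, 3.57)],
    )
    def test_sdf_is_total_minus_insoluble(self, tdf, idf, expected):
        assert derive_sdf(tdf, idf) == pytest.approx(expected)

    def test_sdf_rejects_insoluble_above_total(self):
        with pytest.raises(DomainError):
            derive_sdf(10.0, 11.0)

    @pytest.mark.parametrize("n, expected", [(0.0, 0.0), (2.9152, 18.22), (3.2, 20.0)])
    def test_crude_protein_from_nitrogen(self, n, expected):
        assert cp_from_nitrogen(n) == pytest.approx(expected)

    def test_negative_nitrogen_rejected(self):
        with pytest.raises(DomainError):
            cp_from_nitrogen(-0.1)


class TestIngredientValidation:
    def test_sdf_filled_when_absent(self):
        r = make_ingredient(SDF=None)
        assert r.SDF == pytest.approx(50.45 - 46.9)

    def test_adf_above_ndf_rejected(self):
        with pytest.raises(ValidationError, match="ADF"):
            make_ingredient(ADF=52.0)

    def test_inconsistent_sdf_rejected(self):
        with pytest.raises(ValidationError, match="SDF"):
            make_ingredient(SDF=5.0)

    def test_cp_must_match_nitrogen_when_both_given(self):
        make_ingredient(N=17.3 / 6.25)  # consistent: ok
        with pytest.raises(ValidationError, match="6.25"):
            make_ingredient(N=3.2)

    def test_percentages_bounded(self):
        with pytest.raises(ValidationError):
            make_ingredient(NDF=104.0)


class TestDietValidation:
    def test_inclusions_must_sum_to_100(self):
        with pytest.raises(ValidationError, match="sum"):
            DietFormulation(
                diet_id="d", inclusions={"corn": 50.0, "bran": 30.0},
                analyzed={"GE": 18.4, "DM": 88.0, "CP": 19.0, "EE": 2.0,
                          "NDF": 20.0, "ADF": 6.0, "ash": 6.0},
                mixture_ids=frozenset({"corn"}), test_id="bran",
            )


class TestIngredientTableIO:
    def test_reference_table_loads_seven_validated_records(self, reference_tables):
        records = reference_tables["ingredients"]
        assert len(records) == 7
        by_id = {r.ingredient_id: r for r in records}
        assert by_id["wheat bran 1"].NDF == pytest.approx(51.01)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(
            "ingredient_id,GE_MJ_kgDM,DM_pct,CP_pctDM,EE_pctDM,starch_pctDM,"
            "NDF_pctDM,ADF_pctDM,IDF_pctDM,SDF_pctDM,TDF_pctDM,ash_pctDM\n"
        )
        assert read_ingredient_table(p) == []

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ingredient_id,GE_MJ_kgDM\nx,18.7\n")
        with pytest.raises(SchemaError, match="DM_pct"):
            read_ingredient_table(p)

    def test_absent_sdf_column_is_derived(self, tmp_path):
        p = tmp_path / "nosdf.csv"
        p.write_text(
            "ingredient_id,GE_MJ_kgDM,DM_pct,CP_pctDM,EE_pctDM,starch_pctDM,"
            "NDF_pctDM,ADF_pctDM,IDF_pctDM,TDF_pctDM,ash_pctDM\n"
            "x,18.72,87.95,17.32,2.13,12.81,51.01,14.47,46.88,50.45,6.66\n"
        )
        (r,) = read_ingredient_table(p)
        assert r.SDF == pytest.approx(3.57)

    def test_write_read_round_trip_identity(self, reference_tables, tmp_path):
        records = reference_tables["ingredients"]
        p = tmp_path / "rt.csv"
        write_ingredient_table(records, p)
        back = read_ingredient_table(p)
        for a, b in zip(records, back):
            for f in ("GE", "DM", "CP", "EE", "starch", "NDF", "ADF", "IDF", "SDF", "TDF", "ash"):
                assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-6)


class TestCompositionSummary:
    def test_bran_crude_protein_mean_and_population_cv(self, reference_tables):
        brans = [r for r in reference_tables["ingredients"] if "bran" in r.ingredient_id]
        s = summarize_compositions(brans, analytes=["CP"])
        assert s.mean["CP"] == pytest.approx(18.20, abs=0.01)
        assert s.cv_pct["CP"] == pytest.approx(5.98, abs=0.01)

    def test_identical_values_give_zero_cv(self):
        recs = [make_ingredient(ingredient_id=f"r{i}") for i in range(3)]
        s = summarize_compositions(recs, analytes=["CP"])
        assert s.cv_pct["CP"] == 0.0

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(DomainError):
            summarize_compositions([make_ingredient()], analytes=["CP"])

    def test_mean_order_invariant_and_cv_scale_invariant(self, reference_tables):
        brans = [r for r in reference_tables["ingredients"] if "bran" in r.ingredient_id]
        s1 = summarize_compositions(brans, analytes=["NDF"])
        s2 = summarize_compositions(list(reversed(brans)), analytes=["NDF"])
        assert s1.mean["NDF"] == pytest.approx(s2.mean["NDF"])
        scaled = [
            make_ingredient(ingredient_id=r.ingredient_id, NDF=r.NDF / 2,
                            ADF=min(r.ADF, r.NDF / 2))
            for r in brans
        ]
        s3 = summarize_compositions(scaled, analytes=["NDF"])
        assert s3.cv_pct["NDF"] == pytest.approx(s1.cv_pct["NDF"], rel=1e-9)

    def test_sample_denominator_is_larger(self, reference_tables):
        brans = [r for r in reference_tables["ingredients"] if "bran" in r.ingredient_id]
        pop = summarize_compositions(brans, analytes=["CP"], denominator="population")
        samp = summarize_compositions(brans, analytes=["CP"], denominator="sample")
        assert samp.cv_pct["CP"] > pop.cv_pct["CP"]
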