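"""Survey readers, schema maps, rejection accounting, and CSV round-trips."""

import pandas as pd
import pytest

from rpgen.errors import DataQualityError, RecodeError, SchemaError
from rpgen.schema import SchemaMap
from rpgen.survey_io import (
    read_energy_survey,
    read_housing_survey,
    read_person_survey,
    read_population,
    write_population,
)
from rpgen.synthetic import (
    energy_schema_map,
    housing_schema_map,
    person_schema_map,
)

PERSON_HEADER = "PID,HHID,AGEP,SEX,RAC1P,HISP,ST,PUMA,DENSITY,HINCP,NRA,NRC,BLD,PWGTP"


def _person_csv(tmp_path, rows):
    path = tmp_path / "p.csv"
    path.write_text("\n".join([PERSON_HEADER] + rows) + "\n")
    return path


def _person_row(pid="P1", weight="100.0", age="30", sex="1"):
    return f"{pid},H1,{age},{sex},1,1,36,3600101,200,50000,2,0,01,{weight}"


class TestGoldenFixtures:
    """The committed 20-row fixtures read back with zero rejections."""

    def test_person_fixture(self, data_dir):
        df = read_person_survey(data_dir / "person_survey.csv",
                                SchemaMap.from_file(data_dir / "person_schema.yaml"))
        assert len(df) == 20
        assert df["gender"].isin(["M", "F"]).all()
        assert (df["weight"] > 0).all()

    def test_housing_fixture(self, data_dir):
        df = read_housing_survey(data_dir / "housing_survey.csv",
                                 SchemaMap.from_file(data_dir / "housing_schema.yaml"))
        assert (df["rooms"] >= df["bedrooms"]).all()
        assert df["occupancy"].isin(["occupied", "vacant"]).all()

    def test_energy_fixture(self, data_dir):
        df = read_energy_survey(data_dir / "energy_survey.csv",
                                SchemaMap.from_file(data_dir / "energy_schema.yaml"))
        assert len(df) == 20
        assert df["has_washer"].dtype == bool


class TestPersonReader:
    def test_valid_rows_pass_through(self, tmp_path):
        path = _person_csv(tmp_path, [_person_row(f"P{i}") for i in range(3)])
        df = read_person_survey(path, person_schema_map())
        assert len(df) == 3
        assert df.loc[0, "gender"] == "M"  # raw code "1" recoded

    def test_zero_weight_row_rejected_not_fatal(self, tmp_path, caplog):
        rows = [_person_row("P1"), _person_row("P2", weight="0"), _person_row("P3")]
        path = _person_csv(tmp_path, rows)
        with caplog.at_level("WARNING", logger="rpgen"):
            df = read_person_survey(path, person_schema_map())
        assert len(df) == 2
        assert "rejected 1 of 3" in caplog.text

    def test_age_out_of_range_rejected(self, tmp_path):
        path = _person_csv(tmp_path, [_person_row("P1", age="100"), _person_row("P2")])
        df = read_person_survey(path, person_schema_map())
        assert df["person_id"].tolist() == ["P2"]

    def test_unmapped_gender_code_raises_recode_error(self, tmp_path):
        path = _person_csv(tmp_path, [_person_row("P1", sex="9")])
        with pytest.raises(RecodeError, match="'9'"):
            read_person_survey(path, person_schema_map())

    def test_missing_mapped_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("PID,HHID\nP1,H1\n")
        with pytest.raises(SchemaError, match="AGEP"):
            read_person_survey(path, person_schema_map())

    def test_schema_without_weight_field_raises(self, tmp_path):
        schema = person_schema_map()
        del schema.columns["weight"]
        path = _person_csv(tmp_path, [_person_row()])
        with pytest.raises(SchemaError, match="weight"):
            read_person_survey(path, schema)

    def test_majority_rejection_aborts(self, tmp_path):
        rows = [_person_row(f"P{i}", weight="0") for i in range(3)] + [_person_row("P9")]
        path = _person_csv(tmp_path, rows)
        with pytest.raises(DataQualityError):
            read_person_survey(path, person_schema_map())


class TestHousingReader:
    HEADER = ("CONTROL,ROOMS,BEDRMS,BATHS,UNITSF,BLD,METRO,REGION,HINCP,TEN,"
              "VAC,CEILFAN,WINDOWS,POOL,VEH,HICEIL,NRA,NRC,WEIGHT")

    def _csv(self, tmp_path, rows):
        path = tmp_path / "h.csv"
        path.write_text("\n".join([self.HEADER] + rows) + "\n")
        return path

    def _row(self, hid="A1", rooms="5", bedrooms="2", vac="0"):
        return (f"{hid},{rooms},{bedrooms},1,1500,01,1,1,60000,1,{vac},"
                f"1,8,2,1,2,2,1,55.5")

    def test_vacant_rows_are_retained_at_read_time(self, tmp_path):
        path = self._csv(tmp_path, [self._row(vac="1")])
        df = read_housing_survey(path, housing_schema_map())
        assert df["occupancy"].tolist() == ["vacant"]

    def test_rooms_fewer_than_bedrooms_rejected(self, tmp_path):
        path = self._csv(tmp_path, [self._row("A1", rooms="3", bedrooms="5"),
                                    self._row("A2")])
        df = read_housing_survey(path, housing_schema_map())
        assert df["housing_id"].tolist() == ["A2"]

    def test_valid_rows_identity(self, tmp_path):
        path = self._csv(tmp_path, [self._row("A1"), self._row("A2")])
        df = read_housing_survey(path, housing_schema_map())
        assert len(df) == 2
        assert df["metro_class"].tolist() == ["metropolitan"] * 2


class TestEnergyReader:
    HEADER = "DOEID,WASHER,NUMCOOK,FUEL,METRO,REGION,MONEYPY,TYPEHUQ,NRA,NRC,NWEIGHT"

    def _csv(self, tmp_path, rows):
        path = tmp_path / "e.csv"
        path.write_text("\n".join([self.HEADER] + rows) + "\n")
        return path

    def _row(self, eid="E1", cooktops="1"):
        return f"{eid},1,{cooktops},1,METRO,2,45000,03,2,1,70.1"

    def test_five_valid_rows(self, tmp_path):
        path = self._csv(tmp_path, [self._row(f"E{i}") for i in range(5)])
        df = read_energy_survey(path, energy_schema_map())
        assert len(df) == 5
        assert df["fuel"].unique().tolist() == ["electricity"]

    def test_negative_cooktops_rejected(self, tmp_path):
        path = self._csv(tmp_path, [self._row("E1", cooktops="-1"), self._row("E2")])
        df = read_energy_survey(path, energy_schema_map())
        assert df["energy_id"].tolist() == ["E2"]


class TestPopulationRoundTrip:
    def test_write_then_read_is_lossless(self, tmp_path):
        pop = pd.DataFrame({
            "person_id": ["P1", "P2"], "age": [30, 7], "gender": ["M", "F"],
            "pool": [1, 288], "inccat": [1, 3], "income": [83000.5, 12000.25],
            "height_cm": [180.123456789, 120.5], "housing_has_pool": [True, False],
            "fallback_level": [0, 0],
        })
        path = tmp_path / "pop.csv"
        write_population(pop, path)
        back = read_population(path)
        pd.testing.assert_frame_equal(back, pop)

    def test_header_and_one_row(self, tmp_path):
        pop = pd.DataFrame({"person_id": ["P1"], "pool": [42]})
        path = tmp_path / "one.csv"
        write_population(pop, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[0] == "person_id,pool"

    def test_empty_population_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_population(pd.DataFrame(), tmp_path / "x.csv")
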