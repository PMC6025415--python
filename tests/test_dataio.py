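"""File dialect round-trips and validation behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from cdompae.dataio import (
    AbsorptionSpectrum,
    EEMGrid,
    SampleRecord,
    SurveyTable,
    read_absorbance,
    read_eem,
    read_samples,
    write_absorbance,
    write_eem,
    write_samples,
)
from cdompae.exceptions import MissingInputError, ParseError, ValidationError


def toy_eem():
    return EEMGrid(
        excitation_nm=[220.0, 225.0, 230.0],
        emission_nm=[250.0, 251.0, 252.0, 253.0],
        intensity=np.arange(12.0).reshape(3, 4) / 7.0,
        sample_id="toy",
    )


class TestEEM:
    def test_round_trip_values_and_bytes(self, tmp_path):
        eem = toy_eem()
        path = tmp_path / "toy.csv"
        write_eem(eem, path)
        back = read_eem(path)
        np.testing.assert_array_equal(back.excitation_nm, eem.excitation_nm)
        np.testing.assert_array_equal(back.emission_nm, eem.emission_nm)
        np.testing.assert_array_equal(back.intensity, eem.intensity)
        path2 = tmp_path / "again.csv"
        write_eem(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_default_grid_dimensions(self, tmp_path, uniform_eem):
        path = tmp_path / "grid.csv"
        write_eem(uniform_eem, path)
        back = read_eem(path)
        assert back.intensity.shape == (47, 351)
        assert back.excitation_nm[0] == 220 and back.excitation_nm[-1] == 450
        assert back.emission_nm[0] == 250 and back.emission_nm[-1] == 600

    def test_transpose_flag(self, tmp_path):
        eem = toy_eem()
        path = tmp_path / "t.csv"
        # write transposed by hand: excitation across the columns
        rows = ["em_nm/ex_nm," + ",".join(map(str, eem.excitation_nm))]
        for j, em in enumerate(eem.emission_nm):
            rows.append(",".join([str(em)] + [str(v) for v in eem.intensity[:, j]]))
        path.write_text("\n".join(rows) + "\n")
        back = read_eem(path, transpose=True)
        np.testing.assert_allclose(back.intensity, eem.intensity)

    def test_descending_excitation_rejected(self, tmp_path):
        path = tmp_path / "desc.csv"
        path.write_text("ex/em,250,251\n230,1,2\n225,3,4\n")
        with pytest.raises(ValidationError, match="strictly increasing"):
            read_eem(path)

    def test_ragged_row_names_line(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("ex/em,250,251\n220,1,2\n225,3\n")
        with pytest.raises(ParseError, match="line 3"):
            read_eem(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingInputError):
            read_eem(tmp_path / "absent.csv")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            EEMGrid([220.0, 225.0], [250.0, 251.0], np.ones((3, 2)))

    def test_nonfinite_intensity_rejected(self):
        bad = np.ones((2, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            EEMGrid([220.0, 225.0], [250.0, 251.0], bad)


class TestAbsorbance:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("250,0.10\n251,0.09\n")
        spec = read_absorbance(path)
        assert spec.wavelength_nm.size == 2
        assert spec.path_length_m == 0.01

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("250,0.10\n250,0.09\n251,0.08\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_absorbance(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ParseError):
            read_absorbance(path)

    def test_exponential_round_trip_full_precision(self, tmp_path):
        wl = np.arange(200.0, 801.0)
        od = 0.05 * np.exp(-0.018 * (wl - 200.0))
        spec = AbsorptionSpectrum(wl, od, sample_id="exp")
        path = tmp_path / "exp.csv"
        write_absorbance(spec, path)
        back = read_absorbance(path)
        np.testing.assert_array_equal(back.optical_density, od)
        np.testing.assert_array_equal(back.wavelength_nm, wl)

    def test_no_extrapolation(self):
        spec = AbsorptionSpectrum([250.0, 600.0], [0.1, 0.01])
        with pytest.raises(ValidationError, match="outside"):
            spec.od_at(601.0)


class TestSamples:
    def test_survey_round_trip_counts(self, tmp_path, cohort_seed1):
        path = tmp_path / "samples.csv"
        write_samples(cohort_seed1.survey, path)
        table = read_samples(path)
        assert len(table) == 45
        seasons = [r.season for r in table.records]
        assert seasons.count("JUN") == 25 and seasons.count("OCT") == 20
        # readers must not reorder
        assert [r.sample_id for r in table.records] == \
            [r.sample_id for r in cohort_seed1.samples]

    def test_missing_cell_is_nan_not_zero(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "site_id,season,doc_mg_per_l,dmp_mg_per_l,dep_mg_per_l,dbp_mg_per_l\n"
            "1,JUN,,0.01,0.3,0.006\n")
        table = read_samples(path)
        assert math.isnan(table.records[0].doc_mg_per_l)

    def test_unknown_season_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("site_id,season,dmp_mg_per_l,dep_mg_per_l,dbp_mg_per_l\n"
                        "1,JULY,0.01,0.3,0.006\n")
        with pytest.raises(ValidationError, match="JULY"):
            read_samples(path)

    def test_negative_concentration_names_row(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("site_id,season,dmp_mg_per_l,dep_mg_per_l,dbp_mg_per_l\n"
                        "1,JUN,0.01,0.3,0.006\n"
                        "2,JUN,0.01,-0.3,0.006\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_samples(path)

    def test_duplicate_site_season_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("site_id,season,dmp_mg_per_l,dep_mg_per_l,dbp_mg_per_l\n"
                        "1,JUN,0.01,0.3,0.006\n1,JUN,0.02,0.4,0.007\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_samples(path)

    def test_unknown_columns_kept_as_side_table(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("site_id,season,dmp_mg_per_l,dep_mg_per_l,dbp_mg_per_l,turbidity\n"
                        "1,JUN,0.01,0.3,0.006,4.2\n")
        table = read_samples(path)
        assert list(table.extra.columns) == ["turbidity"]
        assert table.extra["turbidity"].iloc[0] == 4.2
        assert "turbidity" in table.to_frame().columns

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            SampleRecord(site_id=26, season="JUN")
        with pytest.raises(ValidationError):
            SampleRecord(site_id=1, season="JUN", dep_mg_per_l=-1.0)
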