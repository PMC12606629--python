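"""Region classification, Table-1 CSV schema, and the excited-state parser."""

import math

import pytest
from hypothesis import given, strategies as st

from tmc_excite import (
    Excitation,
    ExcitationList,
    GeneratorConfig,
    InputError,
    ParseError,
    Phase,
    RecordError,
    SchemaError,
    SpectralRegion,
    classify_region,
    parse_excited_state_block,
    read_table1_csv,
    simulate_dataset,
    write_table1_csv,
)
from tmc_excite.records_io import DerivedRecord

from conftest import make_record, stick


@pytest.mark.parametrize(
    "wavelength, region",
    [
        (349.9, SpectralRegion.UV),
        (350.0, SpectralRegion.VIS),
        (825.0, SpectralRegion.VIS),
        (825.1, SpectralRegion.NIR),
        (100.0, SpectralRegion.UV),
        (1200.0, SpectralRegion.NIR),
    ],
)
def test_region_boundaries(wavelength, region):
    """350 nm and 825 nm belong to the visible band; strict elsewhere."""
    assert classify_region(wavelength) is region


@pytest.mark.parametrize("bad", [0.0, -5.0, math.nan, math.inf])
def test_region_rejects_nonphysical_wavelengths(bad):
    with pytest.raises(InputError):
        classify_region(bad)


@given(st.floats(min_value=1.0, max_value=2000.0, exclude_min=True))
def test_region_partition_is_exhaustive_and_exclusive(w):
    """Each wavelength satisfies exactly one of the three region predicates."""
    predicates = [w < 350.0, 350.0 <= w <= 825.0, w > 825.0]
    assert sum(predicates) == 1
    assert classify_region(w) is list(SpectralRegion)[predicates.index(True)]


def test_excitation_list_invariants():
    with pytest.raises(InputError):
        Excitation(0, 400.0, 0.1)  # state counter starts at 1
    with pytest.raises(InputError):
        Excitation(1, 400.0, -0.1)  # negative intensity
    with pytest.raises(InputError):
        ExcitationList((Excitation(2, 400, 0.1), Excitation(2, 500, 0.1)), Phase.GASPHASE)
    with pytest.raises(InputError):
        stick([(400.0, 0.1)] * 31)  # more than 30 states


class TestTable1Csv:
    HEADER = "csd_code,metal,charge,lambda_1_gasphase,f_1_gasphase,lambda_1_acetone,f_1_acetone"

    def test_single_row(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text(self.HEADER + "\nAAAAAA,Fe,0,400,0.5,,\n")
        (rec,) = read_table1_csv(p)
        assert len(rec.gas) == 1
        assert rec.gas.entries[0] == Excitation(1, 400.0, 0.5)
        assert len(rec.acetone) == 0  # empty cells are absent, not zero

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(self.HEADER + "\n")
        assert read_table1_csv(p) == []

    def test_missing_column_names_first_offender(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("csd_code,lambda_1_gasphase,f_1_gasphase\nAAAAAA,400,0.5\n")
        with pytest.raises(SchemaError, match="lambda_1_acetone"):
            read_table1_csv(p)

    def test_non_numeric_cell_names_record(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(self.HEADER + "\nBBBBBB,Fe,0,oops,0.5,,\n")
        with pytest.raises(RecordError, match="BBBBBB"):
            read_table1_csv(p)

    def test_roundtrip_is_identity(self, tmp_path):
        records = simulate_dataset(GeneratorConfig(n_records=50, seed=11)).records
        p = tmp_path / "round.csv"
        write_table1_csv(records, p)
        back = read_table1_csv(p)
        for a, b in zip(records, back):
            assert (a.identifier, a.metal_symbol, a.total_charge) == (
                b.identifier,
                b.metal_symbol,
                b.total_charge,
            )
            assert a.gas == b.gas and a.acetone == b.acetone

    def test_sparse_state_indices_survive_roundtrip(self, tmp_path):
        rec = make_record([(400.0, 0.5)], [(500.0, 0.2)])
        rec.gas = ExcitationList(
            (Excitation(3, 400.0, 0.5), Excitation(17, 900.0, 0.02)), Phase.GASPHASE
        )
        p = tmp_path / "sparse.csv"
        write_table1_csv([rec], p)
        (back,) = read_table1_csv(p)
        assert back.gas == rec.gas

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(InputError):
            write_table1_csv([], tmp_path / "x.csv", dialect="suffix-soup")


class TestDerivedColumns:
    def _one_record_derived(self):
        from tmc_excite import analyze_record, region_maxima

        rec = make_record([(500.0, 0.30)], [(530.0, 0.25)])
        derived = DerivedRecord(
            maxima={
                Phase.GASPHASE: region_maxima(rec.gas),
                Phase.ACETONE: region_maxima(rec.acetone),
            },
            solvatochromism=analyze_record(rec),
        )
        return rec, derived

    def test_case1_row_contents(self, tmp_path):
        rec, derived = self._one_record_derived()
        p = tmp_path / "d.csv"
        write_table1_csv([rec], p, derived={rec.identifier: derived})
        text = p.read_text()
        header, row = text.strip().splitlines()
        cells = dict(zip(header.split(","), row.split(",")))
        assert cells["lambda_max_vis_gasphase"] == "500.0"
        assert cells["lambda_max_uv_gasphase"] == ""  # absent maximum: empty cell
        assert float(cells["lambda_delta"]) == 30.0
        assert cells["vis_to_vis"] == "True"
        assert cells["bathochromic"] == "True"

    def test_phase_first_dialect_reorders_suffixes(self, tmp_path):
        rec, derived = self._one_record_derived()
        p = tmp_path / "d.csv"
        write_table1_csv([rec], p, derived={rec.identifier: derived}, dialect="phase-first")
        header = p.read_text().splitlines()[0]
        assert "lambda_max_gasphase_vis" in header
        assert "lambda_max_vis_gasphase" not in header

    def test_case4_row_is_all_zero_and_false(self, tmp_path):
        from tmc_excite import analyze_record, region_maxima

        rec = make_record([(200.0, 0.3)], [(210.0, 0.3)])  # UV only: no Vis activity
        derived = DerivedRecord(
            maxima={
                Phase.GASPHASE: region_maxima(rec.gas),
                Phase.ACETONE: region_maxima(rec.acetone),
            },
            solvatochromism=analyze_record(rec),
        )
        p = tmp_path / "d.csv"
        write_table1_csv([rec], p, derived={rec.identifier: derived})
        header, row = p.read_text().strip().splitlines()
        cells = dict(zip(header.split(","), row.split(",")))
        assert float(cells["lambda_delta"]) == 0.0
        assert float(cells["f_delta"]) == 0.0
        for flag in ("vis_to_vis", "uv_to_vis", "nir_to_vis", "vis_to_uv", "vis_to_nir"):
            assert cells[flag] == "False"

    def test_inconsistent_case4_shift_rejected(self, tmp_path):
        from tmc_excite import SolvatochromismResult

        rec = make_record([(200.0, 0.3)], [(210.0, 0.3)])
        bad = SolvatochromismResult(4, 0.0, 0.0)
        object.__setattr__(bad, "delta_lambda_nm", 12.0)  # corrupt past the constructor
        derived = DerivedRecord(solvatochromism=bad)
        with pytest.raises(InputError, match="case-4"):
            write_table1_csv([rec], tmp_path / "d.csv", derived={rec.identifier: derived})


class TestExcitedStateParser:
    def test_single_line(self):
        text = "Excited State   1: Singlet-A  3.20 eV  387.45 nm  f=0.0123"
        out = parse_excited_state_block(text)
        assert [(e.state_index, e.wavelength_nm, e.oscillator_strength) for e in out] == [
            (1, 387.45, 0.0123)
        ]

    def test_empty_text(self):
        assert len(parse_excited_state_block("")) == 0

    def test_duplicate_state_index(self):
        text = (
            "Excited State 1: Singlet-A 3.2 eV 387.0 nm f=0.01\n"
            "Excited State 1: Singlet-B 3.3 eV 380.0 nm f=0.02\n"
        )
        with pytest.raises(ParseError):
            parse_excited_state_block(text)

    def test_interleaved_noise_is_ignored(self):
        clean = "\n".join(
            f"Excited State {i}: Singlet-A 3.0 eV {300 + i}.50 nm f=0.0{i}" for i in range(1, 31)
        )
        noisy = "\n".join(
            line
            for pair in zip(clean.splitlines(), ["SCF Done: E = -1", "", " Total Energy"] * 10)
            for line in pair
        )
        assert parse_excited_state_block(noisy) == parse_excited_state_block(clean)
        assert len(parse_excited_state_block(clean)) == 30
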