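"""NTO moiety densities, relative contributions, and charge-transfer labels."""

import numpy as np
import pytest

from tmc_excite import (
    CTLabel,
    DegenerateNTOError,
    InputError,
    MissingNTOError,
    Moiety,
    NTOPair,
    ParseError,
    classify_ct,
    ct_for_record,
    ct_from_nto,
    moiety_densities,
    read_nto_file,
    relative_contribution,
    select_dominant_pair,
    simulate_nto,
    write_nto_file,
)

from conftest import make_record


def make_pair(ev_occ=0.9, ev_virt=0.9):
    table = {0: (0.5, 0.5), 1: (0.5, 0.5)}
    return NTOPair(
        occupied=table,
        virtual=table,
        moiety_map={0: Moiety.METAL, 1: Moiety.LIGAND},
        eigenvalue_occupied=ev_occ,
        eigenvalue_virtual=ev_virt,
    )


class TestSelectDominantPair:
    def test_single_candidate(self):
        p = make_pair()
        assert select_dominant_pair([p]) is p

    def test_strict_maximum(self):
        pairs = [make_pair(0.92), make_pair(0.05), make_pair(0.03)]
        assert select_dominant_pair(pairs) is pairs[0]

    def test_tie_broken_by_virtual_then_order(self):
        a, b = make_pair(0.5, 0.5), make_pair(0.5, 0.4)
        assert select_dominant_pair([b, a]) is a
        c = make_pair(0.5, 0.5)
        assert select_dominant_pair([a, c]) is a  # full tie: first wins

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            select_dominant_pair([])


class TestMoietyDensities:
    MAP = {0: Moiety.METAL, 1: Moiety.LIGAND}

    def test_all_on_metal(self):
        rho_m, rho_l = moiety_densities({0: (0.3, 0.4), 1: (0.0, 0.0)}, self.MAP)
        assert rho_l == 0.0 and rho_m == pytest.approx(0.25)

    def test_hand_example(self):
        rho_m, rho_l = moiety_densities({0: (0.5, 0.5), 1: (0.5, 0.5)}, self.MAP)
        assert (rho_m, rho_l) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_quadratic_scaling(self):
        table = {0: (0.2, 0.1), 1: (0.4, 0.3)}
        doubled = {k: tuple(2 * c for c in v) for k, v in table.items()}
        rm, rl = moiety_densities(table, self.MAP)
        rm2, rl2 = moiety_densities(doubled, self.MAP)
        assert rm2 == pytest.approx(4 * rm) and rl2 == pytest.approx(4 * rl)

    def test_unmapped_atom_rejected(self):
        with pytest.raises(InputError):
            moiety_densities({0: (0.5,), 7: (0.1,)}, self.MAP)

    def test_matches_double_loop_oracle(self, rng):
        moiety_map = {0: Moiety.METAL, **{i: Moiety.LIGAND for i in range(1, 6)}}
        for _ in range(50):
            table = {i: tuple(rng.normal(size=8)) for i in range(6)}
            rho_m, rho_l = moiety_densities(table, moiety_map)
            exp_m = exp_l = 0.0
            for atom, coeffs in table.items():
                for c in coeffs:
                    if moiety_map[atom] is Moiety.METAL:
                        exp_m += c * c
                    else:
                        exp_l += c * c
            assert rho_m == pytest.approx(exp_m, rel=1e-12)
            assert rho_l == pytest.approx(exp_l, rel=1e-12)


class TestRelativeContribution:
    def test_hand_example(self):
        assert relative_contribution(0.3, 0.1) == pytest.approx(0.75)

    @pytest.mark.parametrize("x", [1e-9, 0.5, 7.0])
    def test_sole_contributor_is_one(self, x):
        assert relative_contribution(x, 0.0) == 1.0

    def test_symmetry_gives_half(self):
        assert relative_contribution(0.37, 0.37) == 0.5

    def test_degenerate_pair_rejected(self):
        with pytest.raises(DegenerateNTOError):
            relative_contribution(0.0, 0.0)


class TestClassifyCt:
    @pytest.mark.parametrize(
        "rel_o, rel_v, label",
        [
            (0.8, 0.2, CTLabel.MLCT),
            (0.2, 0.8, CTLabel.LMCT),
            (0.4, 0.4, CTLabel.LLCT),
            (0.7, 0.9, CTLabel.DDT),
            (0.5, 0.5, CTLabel.DDT),  # boundary inclusive on the metal side
            (0.5, 0.2, CTLabel.MLCT),
        ],
    )
    def test_label_table(self, rel_o, rel_v, label):
        assert classify_ct(rel_o, rel_v) is label

    def test_threshold_is_adjustable(self):
        assert classify_ct(0.9, 0.1, threshold=0.95) is CTLabel.LLCT
        assert classify_ct(0.9, 0.1, threshold=0.5) is CTLabel.MLCT

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify_ct(1.2, 0.5)


class TestCtPipeline:
    def test_normalization_and_label_invariance_under_rescaling(self, rng):
        nto, _ = simulate_nto(0.7, 0.3, rng=rng)
        res = ct_from_nto(nto)
        assert res.rho_M_O_rel + res.rho_L_O_rel == pytest.approx(1.0, abs=1e-12)
        assert res.rho_M_V_rel + res.rho_L_V_rel == pytest.approx(1.0, abs=1e-12)
        scaled = NTOPair(
            occupied={k: tuple(17.0 * c for c in v) for k, v in nto.occupied.items()},
            virtual={k: tuple(17.0 * c for c in v) for k, v in nto.virtual.items()},
            moiety_map=nto.moiety_map,
            eigenvalue_occupied=nto.eigenvalue_occupied,
            eigenvalue_virtual=nto.eigenvalue_virtual,
        )
        assert ct_from_nto(scaled).label is res.label

    def test_record_without_vis_maximum_is_absent(self):
        rec = make_record([(300.0, 0.5)], [(300.0, 0.5)])
        assert ct_for_record(rec) is None

    def test_engineered_mlct_with_percent_contributions(self, rng):
        nto, intended = simulate_nto(0.9, 0.1, rng=rng)
        rec = make_record([(500.0, 0.3)], [], identifier="MLCTAA")
        res = ct_for_record(rec, nto)
        assert res.label is CTLabel.MLCT is intended
        assert res.m_contribution_occupied_percent == pytest.approx(90.0, abs=1e-6)
        assert res.l_contribution_occupied_percent == pytest.approx(10.0, abs=1e-6)

    def test_raising_threshold_relabels(self, rng):
        nto, _ = simulate_nto(0.9, 0.1, rng=rng)
        rec = make_record([(500.0, 0.3)], [])
        assert ct_for_record(rec, nto, threshold=0.95).label is CTLabel.LLCT

    def test_eligible_record_without_nto_is_flagged(self):
        rec = make_record([(500.0, 0.3)], [])
        with pytest.raises(MissingNTOError):
            ct_for_record(rec)


class TestNtoFileFormat:
    def test_roundtrip(self, tmp_path, rng):
        nto, _ = simulate_nto(0.42, 0.88, rng=rng)
        p = tmp_path / "x.nto"
        write_nto_file(nto, p)
        assert read_nto_file(p) == nto

    def test_moiety_conflict_rejected(self, tmp_path):
        p = tmp_path / "bad.nto"
        p.write_text(
            "eigenvalue_occupied 0.9\neigenvalue_virtual 0.9\n"
            "occupied:\natom 0 metal 0.5\natom 1 ligand 0.5\n"
            "virtual:\natom 0 ligand 0.5\natom 1 metal 0.5\n"
        )
        with pytest.raises(ParseError, match="moiety"):
            read_nto_file(p)

    def test_missing_eigenvalue_rejected(self, tmp_path):
        p = tmp_path / "bad.nto"
        p.write_text("eigenvalue_occupied 0.9\noccupied:\natom 0 metal 0.5\natom 1 ligand 1\nvirtual:\natom 0 metal 0.5\natom 1 ligand 1\n")
        with pytest.raises(ParseError, match="eigenvalue_virtual"):
            read_nto_file(p)

    def test_pair_invariants(self):
        with pytest.raises(InputError):
            NTOPair({0: (1.0,)}, {0: (1.0,)}, {0: Moiety.LIGAND}, 0.9, 0.9)  # no metal
        with pytest.raises(InputError):
            make_pair(ev_occ=1.5)
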