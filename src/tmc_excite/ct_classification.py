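"""Charge-transfer character of the strongest visible excitation.

For a complex absorbing in the visible with significant intensity, the
dominant natural transition orbital (NTO) pair — occupied (O) and virtual (V),
selected by largest eigenvalue (electron occupation) — is partitioned between
the metal center and the ligands.  The ligand density is the sum of squared
atomic-orbital coefficients over all ligand atoms,

    ρ(L) = Σ_i Σ_j c_{i,j}²,

the metal density the same sum over the single metal atom, and the relative
contribution of moiety τ to orbital γ ∈ {O, V} is

    ρ(τ)_γ^rel = ρ(τ)_γ / (ρ(M)_γ + ρ(L)_γ).

The donor is the metal iff ρ(M)_O^rel ≥ threshold (default 0.5), the acceptor
the metal iff ρ(M)_V^rel ≥ threshold; the D→A label is one of MLCT, LMCT,
LLCT, with metal→metal relabeled ddT (a d→d transition at the metal center).
The relative form makes the label invariant to any global rescaling of the
coefficients, so no normalization convention is imposed on the input vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateNTOError, InputError, MissingNTOError, ParseError
from .records_io import Phase, SpectralRegion, TMCRecord
from .band_analysis import DEFAULT_F_THRESHOLD, region_maxima

DEFAULT_CT_THRESHOLD = 0.5


class Moiety(str, Enum):
    METAL = "metal"
    LIGAND = "ligand"


class CTLabel(str, Enum):
    """Transition nature of the strongest Vis excitation."""

    DDT = "ddT"
    LMCT = "LMCT"
    MLCT = "MLCT"
    LLCT = "LLCT"


CoefficientTable = Mapping[int, Sequence[float]]


@dataclass(frozen=True)
class NTOPair:
    """Dominant occupied/virtual NTO coefficients with a metal/ligand map.

    ``occupied`` and ``virtual`` map atom index → atomic-orbital coefficients;
    ``moiety_map`` assigns every atom to the (single) metal or to a ligand.
    Eigenvalues are the electron occupations of the pair, in (0, 1].
    """

    occupied: CoefficientTable
    virtual: CoefficientTable
    moiety_map: Mapping[int, Moiety]
    eigenvalue_occupied: float
    eigenvalue_virtual: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "moiety_map", {int(k): Moiety(v) for k, v in self.moiety_map.items()}
        )
        for name in ("occupied", "virtual"):
            table = {int(k): tuple(float(c) for c in v) for k, v in getattr(self, name).items()}
            object.__setattr__(self, name, table)
            for atom, coeffs in table.items():
                if len(coeffs) == 0:
                    raise InputError(f"atom {atom} has an empty coefficient list ({name})")
                if atom not in self.moiety_map:
                    raise InputError(f"atom {atom} ({name}) missing from moiety map")
        n_metal = sum(1 for m in self.moiety_map.values() if m is Moiety.METAL)
        if n_metal != 1:
            raise InputError(f"exactly one metal atom required, found {n_metal}")
        for name in ("eigenvalue_occupied", "eigenvalue_virtual"):
            ev = getattr(self, name)
            if not (0.0 < ev <= 1.0) or not math.isfinite(ev):
                raise InputError(f"{name} must lie in (0, 1], got {ev}")


@dataclass(frozen=True)
class CTResult:
    """Moiety densities, relative contributions, and the D→A label."""

    rho_L_O: float
    rho_M_O: float
    rho_L_V: float
    rho_M_V: float
    rho_M_O_rel: float
    rho_M_V_rel: float
    rho_L_O_rel: float
    rho_L_V_rel: float
    label: CTLabel

    @property
    def m_contribution_occupied_percent(self) -> float:
        return 100.0 * self.rho_M_O_rel

    @property
    def m_contribution_virtual_percent(self) -> float:
        return 100.0 * self.rho_M_V_rel

    @property
    def l_contribution_occupied_percent(self) -> float:
        return 100.0 * self.rho_L_O_rel

    @property
    def l_contribution_virtual_percent(self) -> float:
        return 100.0 * self.rho_L_V_rel


def select_dominant_pair(candidates: Sequence[NTOPair]) -> NTOPair:
    """Pick the NTO pair with the largest occupied eigenvalue.

    Ties on the occupied eigenvalue fall back to the virtual eigenvalue, then
    to list order (first wins).
    """
    if len(candidates) == 0:
        raise InputError("select_dominant_pair requires at least one candidate")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.eigenvalue_occupied > best.eigenvalue_occupied or (
            cand.eigenvalue_occupied == best.eigenvalue_occupied
            and cand.eigenvalue_virtual > best.eigenvalue_virtual
        ):
            best = cand
    return best


def moiety_densities(
    coeffs: CoefficientTable, moiety_map: Mapping[int, Moiety]
) -> tuple[float, float]:
    """Sum of squared coefficients over the metal atom and over all ligand atoms.

    Returns ``(rho_M, rho_L)``.
    """
    rho_m = 0.0
    rho_l = 0.0
    for atom, orbital_coeffs in coeffs.items():
        try:
            moiety = Moiety(moiety_map[atom])
        except KeyError:
            raise InputError(f"atom {atom} missing from moiety map") from None
        contrib = float(np.sum(np.square(np.asarray(orbital_coeffs, dtype=float))))
        if moiety is Moiety.METAL:
            rho_m += contrib
        else:
            rho_l += contrib
    return rho_m, rho_l


def relative_contribution(rho_tau: float, rho_other: float) -> float:
    """ρ(τ)/(ρ(τ)+ρ(other)); errors when both densities vanish."""
    if rho_tau < 0 or rho_other < 0:
        raise InputError("densities must be non-negative")
    total = rho_tau + rho_other
    if total == 0.0:
        raise DegenerateNTOError("both moiety densities vanish; relative form undefined")
    return rho_tau / total


def classify_ct(
    rho_M_O_rel: float,
    rho_M_V_rel: float,
    threshold: float = DEFAULT_CT_THRESHOLD,
) -> CTLabel:
    """Donor→acceptor label from the metal's relative NTO contributions.

    The donor is the metal iff the occupied relative contribution is at or
    above the threshold (tie assigned to the metal, matching the inclusive
    ≥ 0.5 convention); likewise the acceptor from the virtual side.
    Metal→metal is relabeled ddT.
    """
    for name, value in (("rho_M_O_rel", rho_M_O_rel), ("rho_M_V_rel", rho_M_V_rel)):
        if not (0.0 <= value <= 1.0):
            raise InputError(f"{name} must lie in [0, 1], got {value}")
    donor_metal = rho_M_O_rel >= threshold
    acceptor_metal = rho_M_V_rel >= threshold
    if donor_metal and acceptor_metal:
        return CTLabel.DDT
    if donor_metal:
        return CTLabel.MLCT
    if acceptor_metal:
        return CTLabel.LMCT
    return CTLabel.LLCT


def ct_from_nto(nto: NTOPair, threshold: float = DEFAULT_CT_THRESHOLD) -> CTResult:
    """Full density → relative → label chain for one NTO pair."""
    rho_m_o, rho_l_o = moiety_densities(nto.occupied, nto.moiety_map)
    rho_m_v, rho_l_v = moiety_densities(nto.virtual, nto.moiety_map)
    rel_m_o = relative_contribution(rho_m_o, rho_l_o)
    rel_m_v = relative_contribution(rho_m_v, rho_l_v)
    return CTResult(
        rho_L_O=rho_l_o,
        rho_M_O=rho_m_o,
        rho_L_V=rho_l_v,
        rho_M_V=rho_m_v,
        rho_M_O_rel=rel_m_o,
        rho_M_V_rel=rel_m_v,
        rho_L_O_rel=1.0 - rel_m_o,
        rho_L_V_rel=1.0 - rel_m_v,
        label=classify_ct(rel_m_o, rel_m_v, threshold),
    )


def ct_for_record(
    record: TMCRecord,
    nto: NTOPair | None = None,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    *,
    phase: Phase = Phase.GASPHASE,
    threshold: float = DEFAULT_CT_THRESHOLD,
) -> CTResult | None:
    """Charge-transfer result for a record's strongest Vis excitation.

    Returns None when the record has no Vis excitation with f above the
    intensity threshold (the excitation the label refers to does not exist).
    An eligible record without NTO data raises rather than being silently
    skipped.
    """
    if nto is None:
        nto = record.nto
    maxima = region_maxima(record.excitations(phase), f_threshold)
    if not maxima[SpectralRegion.VIS].has_maximum:
        return None
    if nto is None:
        raise MissingNTOError(
            f"record {record.identifier!r} has a significant Vis excitation but no NTO data"
        )
    return ct_from_nto(nto, threshold)


# ---------------------------------------------------------------------------
# NTO structured-text format
# ---------------------------------------------------------------------------
# One document per complex:
#
#     eigenvalue_occupied 0.92
#     eigenvalue_virtual 0.91
#     occupied:
#     atom 0 metal 0.5 0.5
#     atom 1 ligand 0.3 0.1
#     virtual:
#     atom 0 metal 0.1
#     atom 1 ligand 0.7 0.2
#
# Blank lines and '#' comments are ignored; the moiety of each atom must be
# consistent between the two blocks.


def write_nto_file(nto: NTOPair, path: str | Path) -> None:
    """Serialize one NTO pair to the structured-text format above."""
    lines = [
        f"eigenvalue_occupied {nto.eigenvalue_occupied!r}",
        f"eigenvalue_virtual {nto.eigenvalue_virtual!r}",
    ]
    for name in ("occupied", "virtual"):
        lines.append(f"{name}:")
        table = getattr(nto, name)
        for atom in sorted(table):
            coeffs = " ".join(repr(float(c)) for c in table[atom])
            lines.append(f"atom {atom} {nto.moiety_map[atom].value} {coeffs}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_nto_file(path: str | Path) -> NTOPair:
    """Parse one NTO structured-text document into an :class:`NTOPair`."""
    eigenvalues: dict[str, float] = {}
    tables: dict[str, dict[int, tuple[float, ...]]] = {"occupied": {}, "virtual": {}}
    moiety_map: dict[int, Moiety] = {}
    block: str | None = None
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(("eigenvalue_occupied", "eigenvalue_virtual")):
            key, _, value = line.partition(" ")
            eigenvalues[key] = float(value)
        elif line in ("occupied:", "virtual:"):
            block = line[:-1]
        elif line.startswith("atom "):
            if block is None:
                raise ParseError(f"line {lineno}: atom line outside occupied:/virtual: block")
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: expected 'atom <idx> <moiety> <c1> ...'")
            atom = int(parts[1])
            moiety = Moiety(parts[2])
            if atom in moiety_map and moiety_map[atom] is not moiety:
                raise ParseError(f"line {lineno}: atom {atom} changes moiety between blocks")
            moiety_map[atom] = moiety
            if atom in tables[block]:
                raise ParseError(f"line {lineno}: duplicate atom {atom} in {block} block")
            tables[block][atom] = tuple(float(c) for c in parts[3:])
        else:
            raise ParseError(f"line {lineno}: unrecognized line {line!r}")
    for key in ("eigenvalue_occupied", "eigenvalue_virtual"):
        if key not in eigenvalues:
            raise ParseError(f"missing {key} header")
    return NTOPair(
        occupied=tables["occupied"],
        virtual=tables["virtual"],
        moiety_map=moiety_map,
        eigenvalue_occupied=eigenvalues["eigenvalue_occupied"],
        eigenvalue_virtual=eigenvalues["eigenvalue_virtual"],
    )
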