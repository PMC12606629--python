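"""Domain types and I/O for per-complex TD-DFT excitation data.

The central objects are :class:`ExcitationList` (the first ~30 vertical
excitations of one transition metal complex in one phase, each a wavelength in
nm plus a dimensionless oscillator strength) and :class:`TMCRecord` (a complex
with both gas-phase and acetone excitation lists).  The module also owns the
UV / Vis / nIR spectral-region partition, the tabular CSV schema used to ship
such datasets, and a minimal parser for excited-state summary lines from
quantum-chemistry log text.

Spectral regions partition the positive wavelength axis:

* UV:  λ < 350 nm
* Vis: 350 nm ≤ λ ≤ 825 nm  (both boundaries inclusive on the Vis side)
* nIR: λ > 825 nm
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .errors import InputError, ParseError, RecordError, SchemaError

logger = logging.getLogger(__name__)

#: Wavelength (nm) separating UV from Vis; 350 nm itself is Vis.
UV_VIS_BOUNDARY_NM = 350.0
#: Wavelength (nm) separating Vis from nIR; 825 nm itself is Vis.
VIS_NIR_BOUNDARY_NM = 825.0

#: Maximum number of excitations stored per complex and phase.
MAX_STATES = 30


class Phase(str, Enum):
    """Computational phase of a TD-DFT run: vacuum or implicit acetone."""

    GASPHASE = "gasphase"
    ACETONE = "acetone"


class SpectralRegion(str, Enum):
    """The three wavelength bands used throughout the analysis."""

    UV = "uv"
    VIS = "vis"
    NIR = "nir"


def classify_region(wavelength_nm: float) -> SpectralRegion:
    """Assign a wavelength (nm) to exactly one of UV, Vis, nIR.

    The boundaries 350 nm and 825 nm both belong to the visible band.

    Raises
    ------
    InputError
        If the wavelength is non-positive or non-finite.
    """
    w = float(wavelength_nm)
    if not math.isfinite(w) or w <= 0.0:
        raise InputError(f"wavelength must be finite and positive, got {wavelength_nm!r}")
    if w < UV_VIS_BOUNDARY_NM:
        return SpectralRegion.UV
    if w <= VIS_NIR_BOUNDARY_NM:
        return SpectralRegion.VIS
    return SpectralRegion.NIR


@dataclass(frozen=True)
class Excitation:
    """One vertical excitation: state counter, wavelength (nm), oscillator strength."""

    state_index: int
    wavelength_nm: float
    oscillator_strength: float

    def __post_init__(self) -> None:
        if int(self.state_index) < 1:
            raise InputError(f"state index must be >= 1, got {self.state_index}")
        if not math.isfinite(self.wavelength_nm) or self.wavelength_nm <= 0:
            raise InputError(f"wavelength must be finite and positive, got {self.wavelength_nm}")
        if not math.isfinite(self.oscillator_strength) or self.oscillator_strength < 0:
            raise InputError(
                f"oscillator strength must be finite and non-negative, got {self.oscillator_strength}"
            )

    @property
    def region(self) -> SpectralRegion:
        return classify_region(self.wavelength_nm)


@dataclass(frozen=True)
class ExcitationList:
    """Ordered excitations of one complex in one phase (at most 30 states)."""

    entries: tuple[Excitation, ...]
    phase: Phase

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "phase", Phase(self.phase))
        if len(self.entries) > MAX_STATES:
            raise InputError(f"at most {MAX_STATES} excitations allowed, got {len(self.entries)}")
        indices = [e.state_index for e in self.entries]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise InputError(f"state indices must be strictly increasing, got {indices}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def in_region(self, region: SpectralRegion) -> tuple[Excitation, ...]:
        """Subset of entries whose wavelength falls in *region*."""
        region = SpectralRegion(region)
        return tuple(e for e in self.entries if e.region is region)


@dataclass
class TMCRecord:
    """One transition metal complex with paired gas-phase/acetone excitations.

    The total charge is constrained to {-1, 0, +1}, the charge window of the
    parent dataset.  ``nto`` optionally carries the dominant natural transition
    orbital pair used for charge-transfer classification.
    """

    identifier: str
    metal_symbol: str
    total_charge: int
    gas: ExcitationList
    acetone: ExcitationList
    nto: Any | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise InputError("record identifier must be non-empty")
        if self.total_charge not in (-1, 0, 1):
            raise InputError(f"total charge must be in {{-1, 0, +1}}, got {self.total_charge}")
        if Phase(self.gas.phase) is not Phase.GASPHASE:
            raise InputError("gas ExcitationList must carry phase 'gasphase'")
        if Phase(self.acetone.phase) is not Phase.ACETONE:
            raise InputError("acetone ExcitationList must carry phase 'acetone'")

    def excitations(self, phase: Phase) -> ExcitationList:
        return self.gas if Phase(phase) is Phase.GASPHASE else self.acetone


# ---------------------------------------------------------------------------
# Tabular CSV schema
# ---------------------------------------------------------------------------

#: Suffix-order dialects for derived columns: ``region-first`` produces
#: e.g. ``lambda_max_uv_gasphase``; ``phase-first`` produces
#: ``lambda_max_gasphase_uv``.  Raw per-state columns (``lambda_1_gasphase``)
#: are identical in both dialects.
DIALECTS = ("region-first", "phase-first")

_ID_COLUMNS = ("csd_code", "metal", "charge")


def _fmt(x: float) -> str:
    # shortest repr that round-trips the double exactly
    return repr(float(x))


def _state_columns() -> list[str]:
    cols = []
    for phase in Phase:
        for i in range(1, MAX_STATES + 1):
            cols.append(f"lambda_{i}_{phase.value}")
            cols.append(f"f_{i}_{phase.value}")
    return cols


def _suffixed(base: str, first: str, phase: str, dialect: str) -> str:
    if dialect == "region-first":
        return f"{base}_{first}_{phase}"
    return f"{base}_{phase}_{first}"


def _derived_columns(dialect: str) -> list[str]:
    cols: list[str] = []
    for phase in Phase:
        for region in SpectralRegion:
            for base in ("lambda_max", "f_max", "sigma"):
                cols.append(_suffixed(base, region.value, phase.value, dialect))
        for orb in ("occupied", "virtual"):
            for base in ("M_contribution", "L_contribution"):
                cols.append(_suffixed(base, orb, phase.value, dialect))
        cols.append(f"transition_nature_vis_{phase.value}")
    cols += [
        "lambda_delta",
        "f_delta",
        "vis_to_vis",
        "uv_to_vis",
        "nir_to_vis",
        "vis_to_uv",
        "vis_to_nir",
        "bathochromic",
        "hypsochromic",
        "hyperchromic",
        "hypochromic",
    ]
    return cols


def read_table1_csv(
    path: str | Path,
    *,
    dialect: str = "region-first",
) -> list[TMCRecord]:
    """Read complexes from a Table-1-schema CSV.

    Empty cells denote absent values (shorter excitation lists, missing
    maxima); they are never interpreted as zero.  Rows with fewer than 30
    states simply yield shorter :class:`ExcitationList` objects.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Suffix order used by derived columns; raw ``lambda_i``/``f_i``
        columns are dialect-independent.  Accepted for symmetry with
        :func:`write_table1_csv`.

    Raises
    ------
    SchemaError
        If a required ``lambda_1_*``/``f_1_*`` column is missing; the first
        missing column is named.
    RecordError
        If a cell cannot be parsed as a number; the row identifier is named.
    """
    if dialect not in DIALECTS:
        raise InputError(f"unknown schema dialect {dialect!r}; expected one of {DIALECTS}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("lambda_1_gasphase", "f_1_gasphase", "lambda_1_acetone", "f_1_acetone"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    records: list[TMCRecord] = []
    for idx, row in df.iterrows():
        ident = row.get("csd_code", "") or f"R{idx:05d}"
        metal = row.get("metal", "") or "Fe"
        charge_cell = row.get("charge", "")
        try:
            charge = int(charge_cell) if charge_cell != "" else 0
        except ValueError as exc:
            raise RecordError(f"record {ident!r}: non-integer charge {charge_cell!r}") from exc
        lists: dict[Phase, ExcitationList] = {}
        for phase in Phase:
            entries = []
            for i in range(1, MAX_STATES + 1):
                lcol, fcol = f"lambda_{i}_{phase.value}", f"f_{i}_{phase.value}"
                lcell = str(row[lcol]).strip() if lcol in df.columns else ""
                fcell = str(row[fcol]).strip() if fcol in df.columns else ""
                if lcell == "" and fcell == "":
                    continue
                if lcell == "" or fcell == "":
                    raise RecordError(
                        f"record {ident!r}: state {i} ({phase.value}) has only one of "
                        f"wavelength/oscillator strength"
                    )
                try:
                    entries.append(Excitation(i, float(lcell), float(fcell)))
                except ValueError as exc:
                    raise RecordError(
                        f"record {ident!r}: non-numeric cell in state {i} ({phase.value})"
                    ) from exc
            lists[phase] = ExcitationList(tuple(entries), phase)
        records.append(
            TMCRecord(ident, metal, charge, gas=lists[Phase.GASPHASE], acetone=lists[Phase.ACETONE])
        )
    return records


@dataclass
class DerivedRecord:
    """Downstream results for one record, attached at serialization time.

    ``maxima`` maps phase → region → per-region summary, ``ct`` maps phase →
    charge-transfer result (or None), ``solvatochromism`` is the four-case
    gas→acetone comparison result (or None).  Attribute access only; this
    module does not depend on the analysis modules.
    """

    maxima: Mapping[Any, Mapping[Any, Any]] = field(default_factory=dict)
    ct: Mapping[Any, Any] = field(default_factory=dict)
    solvatochromism: Any | None = None


def _validate_solva(ident: str, s: Any) -> None:
    booleans = [s.vis_to_vis, s.uv_to_vis, s.nir_to_vis, s.vis_to_uv, s.vis_to_nir]
    if sum(booleans) > 1:
        raise InputError(f"record {ident!r}: more than one shift Boolean set")
    if int(s.case_id) == 4 and (s.delta_lambda_nm != 0.0 or s.delta_f != 0.0):
        raise InputError(f"record {ident!r}: case-4 record with nonzero shift")
    if s.bathochromic and s.hypsochromic:
        raise InputError(f"record {ident!r}: both bathochromic and hypsochromic set")
    if s.hyperchromic and s.hypochromic:
        raise InputError(f"record {ident!r}: both hyperchromic and hypochromic set")


def write_table1_csv(
    records: Sequence[TMCRecord],
    path: str | Path,
    *,
    derived: Mapping[str, DerivedRecord] | None = None,
    dialect: str = "region-first",
) -> None:
    """Write complexes (and optionally all downstream results) to CSV.

    Column names follow the base_region_phase suffix order by default
    (e.g. ``lambda_max_uv_gasphase``); ``dialect='phase-first'`` swaps the two
    suffixes.  Absent maxima are written as empty cells, Booleans as
    ``True``/``False``, floats at full precision so that a write→read
    roundtrip is the identity.

    Raises
    ------
    InputError
        If a derived result is internally inconsistent (e.g. a case-4
        solvatochromism result with a nonzero shift).
    """
    if dialect not in DIALECTS:
        raise InputError(f"unknown schema dialect {dialect!r}; expected one of {DIALECTS}")
    columns = list(_ID_COLUMNS) + _state_columns()
    if derived is not None:
        columns += _derived_columns(dialect)

    rows = []
    for rec in records:
        row: dict[str, str] = {c: "" for c in columns}
        row["csd_code"] = rec.identifier
        row["metal"] = rec.metal_symbol
        row["charge"] = str(rec.total_charge)
        for phase in Phase:
            for e in rec.excitations(phase):
                row[f"lambda_{e.state_index}_{phase.value}"] = _fmt(e.wavelength_nm)
                row[f"f_{e.state_index}_{phase.value}"] = _fmt(e.oscillator_strength)
        if derived is not None and rec.identifier in derived:
            d = derived[rec.identifier]
            for phase in Phase:
                maxima = d.maxima.get(phase, {})
                for region in SpectralRegion:
                    summ = maxima.get(region)
                    if summ is None:
                        continue
                    pre = (region.value, phase.value)
                    if summ.lambda_max_nm is not None:
                        row[_suffixed("lambda_max", *pre, dialect)] = _fmt(summ.lambda_max_nm)
                        row[_suffixed("f_max", *pre, dialect)] = _fmt(summ.f_max)
                    row[_suffixed("sigma", *pre, dialect)] = _fmt(summ.sigma_nm)
                ct = d.ct.get(phase) if d.ct else None
                if ct is not None:
                    for orb, m_rel in (
                        ("occupied", ct.rho_M_O_rel),
                        ("virtual", ct.rho_M_V_rel),
                    ):
                        row[_suffixed("M_contribution", orb, phase.value, dialect)] = _fmt(
                            100.0 * m_rel
                        )
                        row[_suffixed("L_contribution", orb, phase.value, dialect)] = _fmt(
                            100.0 * (1.0 - m_rel)
                        )
                    row[f"transition_nature_vis_{phase.value}"] = str(
                        getattr(ct.label, "value", ct.label)
                    )
            s = d.solvatochromism
            if s is not None:
                _validate_solva(rec.identifier, s)
                row["lambda_delta"] = _fmt(s.delta_lambda_nm)
                row["f_delta"] = _fmt(s.delta_f)
                for name in (
                    "vis_to_vis",
                    "uv_to_vis",
                    "nir_to_vis",
                    "vis_to_uv",
                    "vis_to_nir",
                    "bathochromic",
                    "hypsochromic",
                    "hyperchromic",
                    "hypochromic",
                ):
                    row[name] = str(bool(getattr(s, name)))
        rows.append(row)

    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Excited-state log-block parser
# ---------------------------------------------------------------------------

_STATE_RE = re.compile(
    r"Excited State\s+(?P<idx>\d+)\s*:"
    r".*?(?P<nm>[0-9]+(?:\.[0-9]+)?)\s*nm"
    r".*?f\s*=\s*(?P<f>[0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?)"
)


def parse_excited_state_block(text: str, phase: Phase = Phase.GASPHASE) -> ExcitationList:
    """Parse ``Excited State <i>: ... <λ> nm f=<f>`` lines into an ExcitationList.

    A single fixed dialect is supported; lines that do not match are ignored
    with a logged warning.  Entries are returned ordered by state index.

    Raises
    ------
    ParseError
        If a state index appears more than once.
    """
    found: dict[int, Excitation] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _STATE_RE.search(line)
        if m is None:
            if "Excited State" in line:
                logger.warning("ignoring malformed excited-state line: %s", line.strip())
            continue
        idx = int(m.group("idx"))
        if idx in found:
            raise ParseError(f"duplicate state index {idx} in excited-state block")
        found[idx] = Excitation(idx, float(m.group("nm")), float(m.group("f")))
    entries = tuple(found[i] for i in sorted(found))
    return ExcitationList(entries, phase)
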