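"""Four-case quantification of gas-phase → acetone solvatochromism.

A complex is assigned one of four cases from the presence of a significant
(f > 0.01) visible-band maximum in each phase:

* Case 1 — Vis maximum in both phases.  Δλ = λ_max,Vis(ac) − λ_max,Vis(gp),
  Δf likewise; the vis_to_vis flag is set.
* Case 2 — Vis maximum only in acetone.  The acetone Vis maximum is compared
  against the gas-phase UV or nIR maximum, whichever lies closer in
  wavelength; uv_to_vis or nir_to_vis is set accordingly.
* Case 3 — Vis maximum only in the gas phase; mirror of Case 2 against the
  acetone UV/nIR maxima, setting vis_to_uv or vis_to_nir.
* Case 4 — Vis maximum in neither phase.  Δλ = Δf = 0 and all five shift
  flags are False.  Case 2/3 records whose comparison phase offers neither a
  UV nor an nIR maximum fall through to the same zero/all-False treatment
  (their case id is kept, since case membership is defined purely by Vis
  presence).

Chromic flags follow the sign of the shifts: Δλ > 0 bathochromic, Δλ < 0
hypsochromic, Δf > 0 hyperchromic, Δf < 0 hypochromic; an exactly zero shift
sets neither member of the pair.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .band_analysis import DEFAULT_F_THRESHOLD, RegionSummary, region_maxima
from .errors import TmcExciteError
from .records_io import Phase, SpectralRegion, TMCRecord

logger = logging.getLogger(__name__)

RegionMaxima = Mapping[SpectralRegion, RegionSummary]

_SHIFT_FLAGS = ("vis_to_vis", "uv_to_vis", "nir_to_vis", "vis_to_uv", "vis_to_nir")
_CHROMIC_FLAGS = ("bathochromic", "hypsochromic", "hyperchromic", "hypochromic")


class CaseInconsistencyError(TmcExciteError, RuntimeError):
    """The supplied case id contradicts the supplied region maxima."""


@dataclass(frozen=True)
class SolvatochromismResult:
    """Shift, case membership, and the nine Boolean flags for one complex."""

    case_id: int
    delta_lambda_nm: float
    delta_f: float
    vis_to_vis: bool = False
    uv_to_vis: bool = False
    nir_to_vis: bool = False
    vis_to_uv: bool = False
    vis_to_nir: bool = False
    bathochromic: bool = False
    hypsochromic: bool = False
    hyperchromic: bool = False
    hypochromic: bool = False

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3, 4):
            raise CaseInconsistencyError(f"case id must be 1-4, got {self.case_id}")
        n_shift = sum(getattr(self, f) for f in _SHIFT_FLAGS)
        if n_shift > 1:
            raise CaseInconsistencyError("at most one shift flag may be set")
        if self.case_id == 4 and (
            n_shift or self.delta_lambda_nm != 0.0 or self.delta_f != 0.0
        ):
            raise CaseInconsistencyError("case 4 requires zero shifts and no shift flags")
        if self.bathochromic and self.hypsochromic:
            raise CaseInconsistencyError("bathochromic and hypsochromic are exclusive")
        if self.hyperchromic and self.hypochromic:
            raise CaseInconsistencyError("hyperchromic and hypochromic are exclusive")
        if self.bathochromic and not self.delta_lambda_nm > 0:
            raise CaseInconsistencyError("bathochromic requires delta_lambda > 0")
        if self.hypsochromic and not self.delta_lambda_nm < 0:
            raise CaseInconsistencyError("hypsochromic requires delta_lambda < 0")

    @property
    def fell_through(self) -> bool:
        """True for Case 2/3 records reported with the Case-4 zero treatment."""
        return self.case_id in (2, 3) and not any(getattr(self, f) for f in _SHIFT_FLAGS)


def determine_case(gas_maxima: RegionMaxima, acetone_maxima: RegionMaxima) -> int:
    """Case id (1–4) from the presence of significant Vis maxima per phase."""
    in_gas = gas_maxima[SpectralRegion.VIS].has_maximum
    in_acetone = acetone_maxima[SpectralRegion.VIS].has_maximum
    if in_gas and in_acetone:
        return 1
    if in_acetone:
        return 2
    if in_gas:
        return 3
    return 4


def _chromic(delta_lambda: float, delta_f: float) -> dict[str, bool]:
    return {
        "bathochromic": delta_lambda > 0,
        "hypsochromic": delta_lambda < 0,
        "hyperchromic": delta_f > 0,
        "hypochromic": delta_f < 0,
    }


def _closest_competitor(
    maxima: RegionMaxima, reference_nm: float
) -> RegionSummary | None:
    """UV or nIR maximum closest in wavelength to the reference; None if neither exists.

    An exact distance tie (not addressed by the strict inequalities defining
    the selection) deterministically resolves to the UV comparison.
    """
    uv = maxima[SpectralRegion.UV]
    nir = maxima[SpectralRegion.NIR]
    if uv.has_maximum and nir.has_maximum:
        d_uv = abs(reference_nm - uv.lambda_max_nm)
        d_nir = abs(reference_nm - nir.lambda_max_nm)
        if d_nir < d_uv:
            return nir
        if d_nir == d_uv:
            logger.info(
                "UV/nIR competitors equidistant from %.6g nm; tie resolved to UV", reference_nm
            )
        return uv
    if uv.has_maximum:
        return uv
    if nir.has_maximum:
        return nir
    return None


def compute_shift(
    case_id: int,
    gas_maxima: RegionMaxima,
    acetone_maxima: RegionMaxima,
) -> SolvatochromismResult:
    """Δλ, Δf and all nine Boolean flags for a record of known case.

    Raises
    ------
    CaseInconsistencyError
        If ``case_id`` disagrees with the Vis-maximum presence pattern of the
        supplied maxima.
    """
    if case_id != determine_case(gas_maxima, acetone_maxima):
        raise CaseInconsistencyError(
            f"case {case_id} inconsistent with the supplied region maxima"
        )
    gas_vis = gas_maxima[SpectralRegion.VIS]
    ac_vis = acetone_maxima[SpectralRegion.VIS]

    if case_id == 1:
        dl = ac_vis.lambda_max_nm - gas_vis.lambda_max_nm
        df = ac_vis.f_max - gas_vis.f_max
        return SolvatochromismResult(1, dl, df, vis_to_vis=True, **_chromic(dl, df))

    if case_id == 2:
        comp = _closest_competitor(gas_maxima, ac_vis.lambda_max_nm)
        if comp is None:
            return SolvatochromismResult(2, 0.0, 0.0)
        dl = ac_vis.lambda_max_nm - comp.lambda_max_nm
        df = ac_vis.f_max - comp.f_max
        flag = "uv_to_vis" if comp.region is SpectralRegion.UV else "nir_to_vis"
        return SolvatochromismResult(2, dl, df, **{flag: True}, **_chromic(dl, df))

    if case_id == 3:
        comp = _closest_competitor(acetone_maxima, gas_vis.lambda_max_nm)
        if comp is None:
            return SolvatochromismResult(3, 0.0, 0.0)
        dl = comp.lambda_max_nm - gas_vis.lambda_max_nm
        df = comp.f_max - gas_vis.f_max
        flag = "vis_to_uv" if comp.region is SpectralRegion.UV else "vis_to_nir"
        return SolvatochromismResult(3, dl, df, **{flag: True}, **_chromic(dl, df))

    return SolvatochromismResult(4, 0.0, 0.0)


def analyze_record(
    record: TMCRecord, f_threshold: float = DEFAULT_F_THRESHOLD
) -> SolvatochromismResult:
    """Full per-record pipeline: region maxima in both phases, case, shift."""
    gas_maxima = region_maxima(record.gas, f_threshold)
    acetone_maxima = region_maxima(record.acetone, f_threshold)
    case = determine_case(gas_maxima, acetone_maxima)
    return compute_shift(case, gas_maxima, acetone_maxima)


def solvatochromism_table(
    records: Sequence[TMCRecord], f_threshold: float = DEFAULT_F_THRESHOLD
) -> list[SolvatochromismResult]:
    """Per-record solvatochromism results, with summary counts logged."""
    results = [analyze_record(rec, f_threshold) for rec in records]
    summary = summarize(results)
    logger.info("solvatochromism summary: %s", summary)
    return results


def summarize(results: Sequence[SolvatochromismResult]) -> dict:
    """Case and chromic-flag counts, with percentages over two denominators.

    Percentages are reported both over all records and over the
    solvatochromically active subset (Cases 1–3 that did not fall through),
    since either convention is defensible for the "share of batho/hypsochromic
    complexes" question.
    """
    n = len(results)
    cases = Counter(r.case_id for r in results)
    flags = {f: sum(getattr(r, f) for r in results) for f in _SHIFT_FLAGS + _CHROMIC_FLAGS}
    n_active = sum(1 for r in results if r.case_id != 4 and not r.fell_through)
    out = {
        "n_records": n,
        "case_counts": {c: cases.get(c, 0) for c in (1, 2, 3, 4)},
        "n_fell_through": sum(r.fell_through for r in results),
        "flag_counts": flags,
    }
    if n:
        out["flag_percent_of_all"] = {f: 100.0 * v / n for f, v in flags.items()}
    if n_active:
        out["flag_percent_of_active"] = {f: 100.0 * v / n_active for f, v in flags.items()}
    out["n_active"] = n_active
    return out
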