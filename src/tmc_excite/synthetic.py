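"""Synthetic excitation data with known ground truth.

Emulates the statistical shape of a large TD-DFT excitation dataset of
transition metal complexes — 30 excitations per complex and phase, spectral
region occupancies near the 90% UV / 9% Vis / <1% nIR gas-phase split,
heavy-tailed oscillator strengths with a controllable fraction above the
f > 0.01 significance threshold, NTO pairs with prescribed metal
localization, and paired gas/acetone spectra with injected wavelength and
intensity shifts — so that every analysis stage can be exercised against a
known answer without the deposited dataset.

Construction is exact where the downstream check is exact: NTO coefficient
tables are rescaled so the realized metal relative contribution equals the
requested target, and phase pairs plant the per-region maxima that make the
four-case solvatochromism logic recover the injected shifts.  Case counts
are stratified (largest-remainder), not multinomially sampled.  All sampling
flows from a single mandatory seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ct_classification import (
    DEFAULT_CT_THRESHOLD,
    CTLabel,
    Moiety,
    NTOPair,
    classify_ct,
    write_nto_file,
)
from .errors import GenerationError, InputError
from .records_io import (
    Excitation,
    ExcitationList,
    Phase,
    SpectralRegion,
    TMCRecord,
    write_table1_csv,
)
from .solvatochromism import SolvatochromismResult, _chromic

#: Wavelength bands sampled per region (nm).  The UV floor and nIR ceiling
#: bracket the peak positions seen in real averaged spectra of such datasets
#: without modeling any physics.
REGION_BANDS = {
    SpectralRegion.UV: (100.0, 350.0),
    SpectralRegion.VIS: (350.0, 825.0),
    SpectralRegion.NIR: (825.0, 1200.0),
}

_METALS = ("Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ru", "Rh", "Pd", "Ir", "Pt")

#: Background (non-planted) oscillator strengths stay strictly below this so
#: planted maxima are the only significant excitations in engineered records.
_BACKGROUND_F_CAP = 0.009


@dataclass(frozen=True)
class ShiftLaw:
    """Ranges from which solvatochromic shifts are drawn (nm, unitless)."""

    delta_lambda_range: tuple[float, float] = (-100.0, 100.0)
    delta_f_range: tuple[float, float] = (-0.25, 0.5)

    def __post_init__(self) -> None:
        for lo, hi in (self.delta_lambda_range, self.delta_f_range):
            if not lo < hi:
                raise InputError("shift ranges must satisfy lo < hi")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``region_weights`` defaults to the 90/9/1 UV/Vis/nIR occupancy of
    gas-phase excitations in the reference dataset; ``case_mix`` defaults to
    roughly half the complexes having no significant visible absorption in
    either phase (Case 4), with the visibly active remainder dominated by
    within-Vis shifts (Case 1), since the gas and acetone Vis occupancies are
    nearly equal.  The oscillator-strength law is log-normal with median
    0.003 and a spread fixed by the requested exceedance probability
    P(f > 0.01).  The seed is mandatory: there is no implicit entropy.
    """

    n_records: int
    seed: int
    region_weights: tuple[float, float, float] = (0.90, 0.09, 0.01)
    n_states: int = 30
    f_median: float = 0.003
    p_f_above_threshold: float = 0.25
    f_threshold: float = 0.01
    case_mix: tuple[float, float, float, float] = (0.40, 0.05, 0.05, 0.50)
    shift_law: ShiftLaw = field(default_factory=ShiftLaw)

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InputError("n_records must be positive")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise InputError("region weights must sum to 1")
        if abs(sum(self.case_mix) - 1.0) > 1e-9:
            raise InputError("case mix must sum to 1")
        if not 0.0 < self.p_f_above_threshold < 0.5:
            raise InputError("P(f > threshold) must lie in (0, 0.5) for a sub-threshold median")
        if not 0.0 < self.f_median < self.f_threshold:
            raise InputError("f median must lie strictly below the significance threshold")

    @property
    def f_sigma(self) -> float:
        """Log-normal shape parameter reproducing the requested exceedance."""
        return float(
            np.log(self.f_threshold / self.f_median) / norm.ppf(1.0 - self.p_f_above_threshold)
        )


def _sample_region(rng: np.random.Generator, weights: Sequence[float]) -> SpectralRegion:
    return list(SpectralRegion)[rng.choice(3, p=np.asarray(weights, dtype=float))]


def _sample_wavelength(rng: np.random.Generator, region: SpectralRegion) -> float:
    lo, hi = REGION_BANDS[region]
    if region is SpectralRegion.UV:
        # half-open [100, 350)
        w = rng.uniform(lo, hi)
        return w if w < hi else np.nextafter(hi, lo)
    if region is SpectralRegion.NIR:
        # half-open (825, 1200]
        w = hi - rng.uniform(0.0, hi - lo)
        return w if w > lo else np.nextafter(lo, hi)
    return rng.uniform(lo, hi)


def simulate_spectrum(
    config: GeneratorConfig,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    phase: Phase = Phase.GASPHASE,
) -> ExcitationList:
    """Draw one excitation list: region by weight, wavelength uniform in band,
    oscillator strength log-normal."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_states
    regions = rng.choice(3, size=n, p=np.asarray(config.region_weights, dtype=float))
    u = rng.uniform(size=n)
    bands = np.array([REGION_BANDS[r] for r in SpectralRegion])
    lo, hi = bands[regions, 0], bands[regions, 1]
    wavelengths = lo + u * (hi - lo)
    # nIR band is open at 825 nm: sample from the top so the floor is excluded
    nir = regions == 2
    wavelengths[nir] = hi[nir] - u[nir] * (hi[nir] - lo[nir])
    wavelengths = np.clip(
        wavelengths, np.nextafter(bands[regions, 0], np.inf), np.nextafter(bands[regions, 1], 0)
    )
    f = config.f_median * np.exp(config.f_sigma * rng.standard_normal(n))
    entries = tuple(
        Excitation(i + 1, float(w), float(fi)) for i, (w, fi) in enumerate(zip(wavelengths, f))
    )
    return ExcitationList(entries, phase)


# ---------------------------------------------------------------------------
# NTO pairs with prescribed metal localization
# ---------------------------------------------------------------------------


def _scaled_side(
    rng: np.random.Generator, target_rel: float, n_ligand_atoms: int, n_orbitals: int
) -> dict[int, tuple[float, ...]]:
    """Random coefficient table whose metal relative contribution equals the target.

    A random direction is drawn for the metal (atom 0) and ligand atoms, then
    the metal block is rescaled so ρ(M)/(ρ(M)+ρ(L)) hits ``target_rel``
    exactly (to floating precision).
    """
    metal = rng.standard_normal(n_orbitals)
    ligands = rng.standard_normal((n_ligand_atoms, n_orbitals))
    rho_m = float(np.sum(metal**2))
    rho_l = float(np.sum(ligands**2))
    if target_rel >= 1.0:
        ligands = np.zeros_like(ligands)
    elif target_rel <= 0.0:
        metal = np.zeros_like(metal)
    else:
        metal = metal * np.sqrt(target_rel * rho_l / ((1.0 - target_rel) * rho_m))
    table = {0: tuple(float(c) for c in metal)}
    for i in range(n_ligand_atoms):
        table[i + 1] = tuple(float(c) for c in ligands[i])
    return table


def simulate_nto(
    target_rel_O: float,
    target_rel_V: float,
    n_ligand_atoms: int = 5,
    n_orbitals: int = 8,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    threshold: float = DEFAULT_CT_THRESHOLD,
) -> tuple[NTOPair, CTLabel]:
    """NTO pair whose realized metal relatives equal the targets, plus the
    label the classifier is intended to recover."""
    for name, t in (("target_rel_O", target_rel_O), ("target_rel_V", target_rel_V)):
        if not 0.0 <= t <= 1.0:
            raise InputError(f"{name} must lie in [0, 1], got {t}")
    if rng is None:
        rng = np.random.default_rng(seed)
    moiety_map = {0: Moiety.METAL, **{i + 1: Moiety.LIGAND for i in range(n_ligand_atoms)}}
    pair = NTOPair(
        occupied=_scaled_side(rng, target_rel_O, n_ligand_atoms, n_orbitals),
        virtual=_scaled_side(rng, target_rel_V, n_ligand_atoms, n_orbitals),
        moiety_map=moiety_map,
        eigenvalue_occupied=float(rng.uniform(0.7, 1.0)),
        eigenvalue_virtual=float(rng.uniform(0.7, 1.0)),
    )
    return pair, classify_ct(target_rel_O, target_rel_V, threshold)


# ---------------------------------------------------------------------------
# Paired-phase records with injected solvatochromism
# ---------------------------------------------------------------------------


def _background_entries(
    rng: np.random.Generator,
    n: int,
    region_weights: Sequence[float],
) -> list[tuple[float, float]]:
    """Sub-threshold filler excitations drawn over the region mixture."""
    out = []
    for _ in range(n):
        region = _sample_region(rng, region_weights)
        out.append((_sample_wavelength(rng, region), float(rng.uniform(1e-4, _BACKGROUND_F_CAP))))
    return out


def _assemble(
    rng: np.random.Generator,
    planted: list[tuple[float, float]],
    n_states: int,
    region_weights: Sequence[float],
    phase: Phase,
) -> ExcitationList:
    if len(planted) > n_states:
        raise GenerationError("more planted excitations than states")
    values = planted + _background_entries(rng, n_states - len(planted), region_weights)
    rng.shuffle(values)
    entries = tuple(Excitation(i + 1, w, f) for i, (w, f) in enumerate(values))
    return ExcitationList(entries, phase)


def _draw(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def simulate_phase_pair(
    case_target: int,
    shift_law: ShiftLaw | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    delta_lambda: float | None = None,
    delta_f: float | None = None,
    n_states: int = 30,
    region_weights: Sequence[float] = (0.90, 0.09, 0.01),
    identifier: str | None = None,
) -> tuple[TMCRecord, SolvatochromismResult]:
    """One gas/acetone record engineered to land in ``case_target`` (1–4).

    For Cases 1–3 a wavelength shift and intensity change are injected
    (drawn from ``shift_law`` unless given explicitly) and the returned
    ground truth carries the realized values, which the analysis pipeline
    recovers exactly.  Case-2/3 records plant both a UV and an nIR
    competitor in the comparison phase, with the competitor implied by the
    shift's sign strictly closer, exercising the closest-wavelength rule.

    Raises
    ------
    GenerationError
        If the requested shift is infeasible (e.g. a Case-2 shift of exactly
        zero, which cannot occur across region boundaries).
    """
    if case_target not in (1, 2, 3, 4):
        raise InputError(f"case_target must be 1-4, got {case_target}")
    if rng is None:
        rng = np.random.default_rng(seed)
    law = shift_law or ShiftLaw()

    def record(gas_planted, ac_planted) -> TMCRecord:
        ident = identifier or "".join(rng.choice(list(string.ascii_uppercase), 6))
        return TMCRecord(
            identifier=ident,
            metal_symbol=str(rng.choice(_METALS)),
            total_charge=int(rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1])),
            gas=_assemble(rng, gas_planted, n_states, region_weights, Phase.GASPHASE),
            acetone=_assemble(rng, ac_planted, n_states, region_weights, Phase.ACETONE),
        )

    vis_lo, vis_hi = REGION_BANDS[SpectralRegion.VIS]

    if case_target == 4:
        # significant excitations outside the Vis band only
        gas_planted = [((_sample_wavelength(rng, SpectralRegion.UV)), _draw(rng, (0.02, 0.4)))]
        ac_planted = [((_sample_wavelength(rng, SpectralRegion.UV)), _draw(rng, (0.02, 0.4)))]
        truth = SolvatochromismResult(4, 0.0, 0.0)
        return record(gas_planted, ac_planted), truth

    dl = _draw(rng, law.delta_lambda_range) if delta_lambda is None else float(delta_lambda)
    df = _draw(rng, law.delta_f_range) if delta_f is None else float(delta_f)

    if case_target == 1:
        lo = max(vis_lo, vis_lo - dl)
        hi = min(vis_hi, vis_hi - dl)
        if not lo < hi:
            raise GenerationError(f"Case-1 shift of {dl} nm leaves no feasible Vis wavelength")
        lam_gp = _draw(rng, (lo, hi))
        lam_ac = lam_gp + dl
        f_gp = max(0.02, 0.02 - df) + _draw(rng, (0.0, 0.4))
        f_ac = f_gp + df
        gas_planted = [(lam_gp, f_gp)]
        ac_planted = [(lam_ac, f_ac)]
        dl_real, df_real = lam_ac - lam_gp, f_ac - f_gp
        truth = SolvatochromismResult(
            1, dl_real, df_real, vis_to_vis=True, **_chromic(dl_real, df_real)
        )
        return record(gas_planted, ac_planted), truth

    # Cases 2 and 3: a Vis maximum in one phase, UV+nIR competitors in the other.
    if dl == 0.0:
        raise GenerationError("a cross-region shift of exactly 0 nm is infeasible")
    uv_lo, uv_hi = REGION_BANDS[SpectralRegion.UV]
    nir_lo, nir_hi = REGION_BANDS[SpectralRegion.NIR]

    if case_target == 2:
        # acetone Vis maximum; nearer gas competitor fixed by the shift's sign
        if dl > 0:  # UV competitor: lambda_vis_ac - lambda_uv_gp = dl
            lo, hi = max(vis_lo, uv_lo + dl), min(vis_hi, uv_hi + dl)
            if not lo < hi:
                raise GenerationError(f"Case-2 shift of {dl} nm infeasible from the UV")
            lam_vis = _draw(rng, (lo, hi))
            near = (lam_vis - dl, SpectralRegion.UV)
        else:  # nIR competitor: lambda_vis_ac - lambda_nir_gp = dl < 0
            lo, hi = max(vis_lo, nir_lo + dl), min(vis_hi, nir_hi + dl)
            if not lo < hi:
                raise GenerationError(f"Case-2 shift of {dl} nm infeasible from the nIR")
            # strict lower bound: the competitor must land strictly above 825 nm
            lam_vis = _draw(rng, (float(np.nextafter(lo, hi)), hi))
            near = (lam_vis - dl, SpectralRegion.NIR)
        far_region = (
            SpectralRegion.NIR if near[1] is SpectralRegion.UV else SpectralRegion.UV
        )
        lam_far = _sample_wavelength(rng, far_region)
        if abs(lam_far - lam_vis) <= abs(dl):
            raise GenerationError("far competitor landed closer than the injected shift")
        f_vis = max(0.02, 0.02 + df) + _draw(rng, (0.0, 0.3))
        f_near = f_vis - df
        f_far = _draw(rng, (0.011, 0.3))
        ac_planted = [(lam_vis, f_vis)]
        gas_planted = [(near[0], f_near), (lam_far, f_far)]
        dl_real, df_real = lam_vis - near[0], f_vis - f_near
        flag = "uv_to_vis" if near[1] is SpectralRegion.UV else "nir_to_vis"
        truth = SolvatochromismResult(
            2, dl_real, df_real, **{flag: True}, **_chromic(dl_real, df_real)
        )
        return record(gas_planted, ac_planted), truth

    # case 3: gas Vis maximum; nearer acetone competitor fixed by the sign
    if dl < 0:  # UV competitor: lambda_uv_ac - lambda_vis_gp = dl
        lo, hi = max(vis_lo, uv_lo - dl), min(vis_hi, uv_hi - dl)
        if not lo < hi:
            raise GenerationError(f"Case-3 shift of {dl} nm infeasible toward the UV")
        lam_vis = _draw(rng, (lo, hi))
        near = (lam_vis + dl, SpectralRegion.UV)
    else:  # nIR competitor: lambda_nir_ac - lambda_vis_gp = dl > 0
        lo, hi = max(vis_lo, nir_lo - dl), min(vis_hi, nir_hi - dl)
        if not lo < hi:
            raise GenerationError(f"Case-3 shift of {dl} nm infeasible toward the nIR")
        # strict lower bound: the competitor must land strictly above 825 nm
        lam_vis = _draw(rng, (float(np.nextafter(lo, hi)), hi))
        near = (lam_vis + dl, SpectralRegion.NIR)
    far_region = SpectralRegion.NIR if near[1] is SpectralRegion.UV else SpectralRegion.UV
    lam_far = _sample_wavelength(rng, far_region)
    if abs(lam_far - lam_vis) <= abs(dl):
        raise GenerationError("far competitor landed closer than the injected shift")
    f_vis = max(0.02, 0.02 - df) + _draw(rng, (0.0, 0.3))
    f_near = f_vis + df
    f_far = _draw(rng, (0.011, 0.3))
    gas_planted = [(lam_vis, f_vis)]
    ac_planted = [(near[0], f_near), (lam_far, f_far)]
    dl_real, df_real = near[0] - lam_vis, f_near - f_vis
    flag = "vis_to_uv" if near[1] is SpectralRegion.UV else "vis_to_nir"
    truth = SolvatochromismResult(
        3, dl_real, df_real, **{flag: True}, **_chromic(dl_real, df_real)
    )
    return record(gas_planted, ac_planted), truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def _stratified_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n records over the case mix."""
    raw = [n * w for w in mix]
    counts = [int(x) for x in raw]
    remainders = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % len(mix)]] += 1
    return counts


@dataclass
class SyntheticDataset:
    """Records plus the ground truth the analysis modules must re-derive."""

    config: GeneratorConfig
    records: list[TMCRecord]
    truth_solvatochromism: dict[str, SolvatochromismResult]
    truth_ct: dict[str, tuple[CTLabel, float, float]]
    ntos: dict[str, NTOPair]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            s = self.truth_solvatochromism[rec.identifier]
            row = {
                "csd_code": rec.identifier,
                "case_id": s.case_id,
                "lambda_delta": repr(s.delta_lambda_nm),
                "f_delta": repr(s.delta_f),
            }
            for flag in (
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
                row[flag] = str(getattr(s, flag))
            if rec.identifier in self.truth_ct:
                label, t_o, t_v = self.truth_ct[rec.identifier]
                row["ct_label"] = label.value
                row["target_rel_occupied"] = repr(t_o)
                row["target_rel_virtual"] = repr(t_v)
            else:
                row["ct_label"] = ""
                row["target_rel_occupied"] = ""
                row["target_rel_virtual"] = ""
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        """Write the Table-1-schema CSV, per-record NTO files, and truth CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table1_csv(self.records, out / "records.csv")
        self.truth_frame().to_csv(out / "ground_truth.csv", index=False)
        nto_dir = out / "nto"
        nto_dir.mkdir(exist_ok=True)
        for ident, nto in self.ntos.items():
            write_nto_file(nto, nto_dir / f"{ident}.nto")


def _away_from_threshold(
    rng: np.random.Generator, threshold: float, margin: float = 0.05
) -> float:
    """Target relative contribution at least ``margin`` away from the threshold."""
    below = rng.random() < 0.5
    if below:
        hi = threshold - margin
        return _draw(rng, (0.0, hi)) if hi > 0 else 0.0
    lo = threshold + margin
    return _draw(rng, (lo, 1.0)) if lo < 1 else 1.0


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full stratified dataset with solvatochromism and CT ground truth.

    NTO pairs (and CT ground truth) are attached to every record whose gas
    phase carries a significant Vis maximum, with target metal relatives kept
    at least 0.05 from the classification threshold so recovery is exact.
    """
    rng = np.random.default_rng(config.seed)
    counts = _stratified_counts(config.n_records, config.case_mix)
    records: list[TMCRecord] = []
    truth_s: dict[str, SolvatochromismResult] = {}
    truth_ct: dict[str, tuple[CTLabel, float, float]] = {}
    ntos: dict[str, NTOPair] = {}
    seen: set[str] = set()
    for case, n_case in zip((1, 2, 3, 4), counts):
        for _ in range(n_case):
            rec, truth = simulate_phase_pair(
                case,
                config.shift_law,
                rng=rng,
                n_states=config.n_states,
                region_weights=config.region_weights,
            )
            while rec.identifier in seen:  # 26^6 namespace; collisions are rare
                rec, truth = simulate_phase_pair(
                    case,
                    config.shift_law,
                    rng=rng,
                    n_states=config.n_states,
                    region_weights=config.region_weights,
                )
            seen.add(rec.identifier)
            if case in (1, 3):  # gas phase has a significant Vis maximum
                t_o = _away_from_threshold(rng, DEFAULT_CT_THRESHOLD)
                t_v = _away_from_threshold(rng, DEFAULT_CT_THRESHOLD)
                nto, label = simulate_nto(t_o, t_v, rng=rng)
                rec.nto = nto
                ntos[rec.identifier] = nto
                truth_ct[rec.identifier] = (label, t_o, t_v)
            records.append(rec)
            truth_s[rec.identifier] = truth
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return SyntheticDataset(config, records, truth_s, truth_ct, ntos)
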