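# Methods

## Scope and data model

The package post-processes vertical electron excitations of mononuclear,
closed-shell transition metal complexes, computed by TD-DFT in two phases
(vacuum and implicit acetone). Each complex carries up to 30 excitations per
phase, each a wavelength λ (nm, finite, positive) and an oscillator strength
*f* (dimensionless, non-negative). State indices are strictly increasing
counters starting at 1; they may be sparse (a CSV row with missing states
yields a shorter list — empty cells mean *absent*, never zero, because a
0 nm wavelength would be meaningful-looking garbage).

## Spectral regions

UV: λ < 350 nm; Vis: 350 ≤ λ ≤ 825 nm; nIR: λ > 825 nm. Both boundaries are
inclusive on the Vis side. The three predicates partition (0, ∞), which is
enforced by a property test over 10⁵ random wavelengths.

## Per-region maxima and band broadness

Within each region, the reported maximum is the excitation with the largest
*f* among those with *f* strictly above the significance threshold (default
0.01). The strict comparison matches the convention "*f* > 0.01" and is
applied uniformly to all three regions. Ties in *f* resolve to the smaller
state index. Regions with no significant excitation report an absent maximum.

Band broadness is σ_R = |Δλ_R| · n_R, the wavelength span (max − min) of the
region's excitations multiplied by their count, with σ_R = 0 for n_R ≤ 1.
Note σ grows with excitation density; a per-excitation spacing
(span / count) is arguably also a "broadness" and is available as
`broadness-mode ratio`, but the product form is the definition and the
default. σ and n_R are computed over **all** of a region's excitations, not
only the significant ones; the threshold gates only the maxima.

## Averaged spectra

The dataset-averaged spectrum sums, over all retained excitations of all
records, a Lorentzian centered at each excitation's wavelength with peak
amplitude equal to its *f* (amplitude-, not area-normalized, so intensity
units track oscillator strength), then divides by the record count. Defaults:
half-width-at-half-maximum 10 nm, grid 100–1000 nm in 1 nm steps; both are
parameters, since no single kernel width is canonical for such averaged
spectra. Peaks of the averaged curve therefore depend on the kernel width and
on dataset composition; they are descriptive, not invariants.

## (Δλ, Δf) densities

`density2d` standardizes each axis (zero mean, unit variance) so the
nm-scale wavelength axis and the unit-scale intensity axis are weighted
evenly, applies a Gaussian KDE (Scott's rule by default), evaluates it at the
data points, and min–max normalizes to [0, 1]. Numerical choices: if exactly
one axis has zero spread, the 2-D covariance is singular and the density is
computed on the varying axis alone; fully coincident points are rejected; if
all evaluated densities are equal (possible for two points), the normalized
values are defined as 1.

## Charge-transfer classification

For the strongest significant Vis excitation, the dominant NTO pair (largest
occupied eigenvalue; virtual eigenvalue, then list order, as tie-breaks)
is partitioned between the single metal atom and the ligands:
ρ(L) = Σᵢ Σⱼ c²ᵢⱼ over ligand atoms, ρ(M) the same sum over the metal's
orbitals, computed separately for the occupied and virtual NTOs. Relative
contributions ρ(τ)^rel = ρ(τ)/(ρ(M)+ρ(L)) are scale-free, so no
normalization convention (Σc² = 1 or otherwise) is imposed on input
coefficients. Donor = metal iff ρ(M)_O^rel ≥ threshold; acceptor = metal iff
ρ(M)_V^rel ≥ threshold; default threshold 0.5 with the tie assigned to the
metal on both sides. Metal→metal is relabeled ddT after classification, never
as a fifth branch. Both densities vanishing is a degenerate input and raises;
an eligible record without NTO data raises rather than being skipped, so
missing data is always visible. Contributions are serialized as percentages
(rel × 100).

NTO input/output uses a one-document-per-complex structured text format
(`eigenvalue_occupied`/`eigenvalue_virtual` headers, `occupied:`/`virtual:`
blocks of `atom <idx> <moiety> <c1> <c2> ...` lines), chosen because no
standard interchange format exists for per-atom NTO coefficient vectors.

## Solvatochromism

Case membership depends only on the presence of a significant Vis maximum in
each phase, under the same threshold object used everywhere else:

1. both phases → Δλ = λ_max,Vis^ac − λ_max,Vis^gp and Δf likewise;
   `vis_to_vis` set.
2. acetone only → the acetone Vis maximum is compared against the gas-phase
   UV or nIR maximum closer in wavelength; `uv_to_vis` or `nir_to_vis` set.
3. gas only → mirror of case 2 against the acetone UV/nIR maxima;
   `vis_to_uv` or `vis_to_nir` set.
4. neither → Δλ = Δf = 0, all five route flags False.

An exact UV/nIR distance tie in cases 2/3 is not covered by the strict
inequalities that define the selection; it resolves deterministically to the
UV comparison and is logged. Case 2/3 records whose comparison phase has
neither a UV nor an nIR significant maximum receive the case-4 treatment
(zero shifts, all route flags False) while keeping their determined case id,
since case membership is defined purely by Vis presence; summaries count
these fall-through records separately. Chromic flags follow strict signs:
Δλ > 0 bathochromic, Δλ < 0 hypsochromic, Δf > 0 hyperchromic, Δf < 0
hypochromic; exact zeros set neither flag of a pair. Summary percentages are
reported over two denominators (all records, and solvatochromically active
records), since both conventions are in use for "share of bathochromic
complexes".

## Tabular schema

The CSV schema stores per-state columns `lambda_i_<phase>` / `f_i_<phase>`
(i ∈ 1–30, phases `gasphase`/`acetone`) plus identity columns
(`csd_code`, `metal`, `charge`; charge restricted to {−1, 0, +1}). Derived
columns use the suffix order base_region_phase (`lambda_max_vis_acetone`);
a `phase-first` dialect swaps the suffixes for compatibility with deposits
whose ordering differs, since no single ordering is universal. Booleans are
serialized as `True`/`False`; floats are written with the shortest
representation that round-trips the double exactly, so write→read is the
identity on records — this is the package's roundtrip guarantee and is
preferred over fixed-precision truncation. The excited-state log parser
accepts exactly one dialect (`Excited State <i>: ... <λ> nm f=<f>`); full
quantum-chemistry log parsing is out of scope.

## Synthetic data generator

The generator emulates the statistical shape of a large TMC excitation
dataset, not its physics:

* **Region occupancy** defaults to (0.90, 0.09, 0.01) for UV/Vis/nIR,
  the gas-phase occupancy split reported for such datasets. Wavelengths are
  uniform within each band: UV on [100, 350), Vis on [350, 825],
  nIR on (825, 1200]; the 100 nm floor and 1200 nm ceiling bracket observed
  averaged-spectrum peaks without modeling transition physics.
* **Oscillator strengths** are log-normal with median 0.003 and shape set by
  the requested exceedance P(f > 0.01) (default 0.25). No empirical intensity
  law is being fitted; only the role of the 0.01 threshold matters
  downstream, so the exceedance is the controlled quantity.
* **Case mix** defaults to (0.40, 0.05, 0.05, 0.50): about half of real TMCs
  show no significant Vis activity in either phase, and because gas and
  acetone Vis occupancies are nearly equal, most visibly active complexes
  stay visible in both phases (case 1). Case counts are stratified by
  largest-remainder apportionment, never multinomially sampled, so tests are
  deterministic.
* **Injected shifts** are drawn from Δλ ∈ [−100, 100] nm and
  Δf ∈ [−0.25, 0.5], the ranges where real (Δλ, Δf) scatter concentrates.
  Engineered records plant the phase maxima that realize the requested case;
  case-2/3 records plant *both* a UV and an nIR competitor with the
  sign-implied one strictly closer, exercising the closest-wavelength rule.
  Ground truth stores the *realized* shift (the exact floating-point
  difference of the planted maxima), which the pipeline must reproduce
  bit-exactly. Background excitations are kept strictly below the
  significance threshold so planted maxima are unambiguous.
* **NTO targets** are realized exactly by rescaling the metal block of a
  random coefficient table so the metal relative contribution equals the
  target; dataset-level targets stay ≥ 0.05 from the classification
  threshold so label recovery is exact. NTO data is attached to records
  whose gas phase has a significant Vis maximum (cases 1 and 3).
* **Determinism.** The seed is mandatory; identical configurations produce
  byte-identical output files.

What passing tests on synthetic data do *not* show: agreement with any real
TD-DFT dataset's peak positions, class proportions, or shift distributions —
those depend on chemistry the generator deliberately does not model
(intensity–wavelength correlations, vibronic structure, metal-specific
spectra, near-threshold ambiguity in NTO localization).

## Problem sizes

Default verification scales: 10⁵ wavelengths for the partition property,
10³ random lists for the broadness oracle, 10³ NTO pairs for label recovery,
a 400-record stratified set for solvatochromism recovery, 200 records for the
CSV roundtrip, and 10⁴ records (3×10⁵ excitations) for the region-occupancy
sanity check with a three-standard-error binomial tolerance. These sizes make
every stochastic check tight while keeping the full suite and the acceptance
script fast on a single core.

## Known limitations

* Single-metal (mononuclear), closed-shell complexes only; no spin-resolved
  analysis.
* The two-phase gas/acetone design is hard-coded; other solvents or
  continuous polarity models are out of scope.
* Averaged-spectrum peak positions are kernel-width dependent by
  construction.
* The log parser reads one excited-state dialect; it is a convenience, not a
  general quantum-chemistry parser.
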