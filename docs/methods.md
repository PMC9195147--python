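# Methods

## Scope and data model

The package analyzes three kinds of measurement of Co²⁺ binding to frataxin
fragments: near-edge X-ray absorption (XANES), extended fine structure
(EXAFS), and CD thermal denaturation. All stages consume the containers in
`xasmelt.types`: `Spectrum` (μ vs. E in eV, strictly increasing, ≥16
points), `MeltingCurve` (Θ₂₂₂ vs. T in °C), `AtomRecord` (orthogonal-Å
site atoms) and `StabilityRecord` (the per-sample join of melting and
XANES outputs). File I/O is whitespace-delimited two-column ASCII with `#`
comments; rows are sorted and exact duplicate abscissae averaged, since
multi-scan merges produce duplicates. PDB parsing is delegated to gemmi
(element columns with atom-name fallback); only ATOM/HETATM records of the
first model are used, with no symmetry expansion.

## Synthetic data: what it emulates and what it does not

No measured spectra or melts are distributed, so `xasmelt.synth` generates
all inputs with known truth. Generators are pure functions of their
parameters and a mandatory seed whenever noise is requested.

**XANES references.** μ(E) is an arctan step of unit height (conventional
phenomenology; an error-function edge would serve equally) plus Gaussian
features: a 1s→3d pre-edge peak near 7710 eV — the octahedral Co²⁺
marker — a white line, and shape resonances, plus a linear post-edge slope
that vanishes below the edge. The bound-complex and buffer profiles differ
in edge position, width and feature structure so a two-component fit is
well conditioned.

**EXAFS-bearing μ(E).** μ = bkg·(1+χ) above the edge, where χ comes from
the same single-scattering forward model the fitter uses and bkg is a
monotone (PCHIP) cubic spline through control points. Monotone
interpolation matters: an ordinary cubic spline through an edge jump rings,
putting spurious structure into the "smooth" background that no background
-removal method could be expected to take out. The default control points
describe a flat pre-edge near 0.09 and an atomic absorption that jumps to
~1.2 and decays exponentially on a ~250 eV scale — deliberately free of
white-line structure, which physically belongs to the near-edge signal,
not to μ₀. χ is embedded only where the Fermi-shifted photoelectron energy
is positive.

**Melting curves.** Two-state van't Hoff transitions with ΔCp = 0
(equilibrium treatment is justified by the reversibility of the scans;
only Tm is interpreted downstream), superposed for two-step melts:
Θ(T) = Σⱼ aⱼ·[θNⱼ + (θUⱼ−θNⱼ)·fUⱼ(T)], fU = K/(1+K),
K = exp[−(ΔH/R)(1/T − 1/Tm)] in kelvin. Defaults: ΔH = 300 kJ/mol,
native/unfolded baselines −20000/−2000 deg·cm²·dmol⁻¹, grid 20–95 °C at
0.5 °C — the measurement protocol.

**Site geometry.** Octahedral placement on ±x, ±y, ±z in a fixed order
(shells assigned by descending ligand count), so fixtures are reproducible
byte for byte.

**Noise defaults.** Measured noise levels are unavailable, so they are
package choices made once: sd 0.002 in normalized μ units for spectra and
150 deg·cm²·dmol⁻¹ for Θ₂₂₂ (≈1% of a typical dynamic range). Recovery
tests run noiseless; the noise path is exercised separately.

What the generator does *not* emulate: instrument response and energy
resolution, multiple-scattering XANES structure, glitches and detector
deadtime, ΔCp ≠ 0 baselines, and aggregation-distorted melts. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under the stated model, not robustness to every artifact of real
beamline data.

## XANES processing

**Edge energy** is the abscissa of the maximum derivative, refined by a
parabola through the three surrounding derivative samples.

**Normalization** follows edge-step practice: a line fitted on
[E₀−150, E₀−30] eV is subtracted, a quadratic fitted on [E₀+50, E₀+300]
defines the step at E₀, and the post-edge is flattened to mean 1. The
unflattened step-normalized spectrum is retained alongside: flattening
extrapolates its quadratic outside the fit range, which is cosmetic for
XANES display but poisonous for background removal, so EXAFS extraction
uses the unflattened form.

**Pre-edge fitting** is staged because the [E₀−25, E₀−2] window rides the
rising edge: a line through the lower 60% of the window flags the peak
candidate (at least 5 eV below the window top), then a simultaneous
Gaussian + quadratic fit runs on [c₀−8, c₀+6] eV — the quadratic tracks
the curved edge tail a line cannot, keeping the fitted height approximately
linear in the true height. A feature is reported absent when its height is
under 3× the residual scatter or its width runs to the bound (a broad
"Gaussian" fitting the edge tail is not a pre-edge).

**LCF** minimizes Σ[t − f·a − (1−f)·b]² over f ∈ [0,1]; the optimum is the
closed form f* = Σ(t−b)(a−b)/Σ(a−b)², clipped. Components are linearly
interpolated onto the target grid; the default window [E₀−20, E₀+80] eV
covers the near-edge region where the two references differ most. Exactly
two components with complementary fractions are supported — the
construction the bound-fraction question calls for.

## EXAFS

**Wavenumber.** k = √(0.262468·(E−E₀)) with the standard 2mₑ/ħ² constant;
the Fermi shift re-references k′ = √(k² + 0.262468·ΔE_F) inside the model
rather than at extraction, so the fit can recover it.

**Scattering table.** The oxygen amplitude/phase/mean-free-path used by
both the generator and the fitter is the smooth parameterization
f(k) = 0.90·e^(−0.15k), φ(k) = π − 0.90k, λ(k) = 4 + 0.8k (k in Å⁻¹, λ in
Å). It is synthetic: the contract of the package is self-consistent
parameter recovery, not ab-initio phase shifts; user tables (4-column
text) override it. One consequence worth knowing: the linear phase makes
shells appear ~0.45 Å short in distance space, which informs the rbkg
discussion below.

**Background removal.** μ is resampled on a uniform k grid (Δk = 0.05)
starting at k_min = 1.5 Å⁻¹ — just past the edge jump, which no smooth
spline can follow and which nothing downstream uses. A cubic B-spline with
⌊2·Δk·rbkg/π⌋+1 coefficients (the information-theoretic count for
structure below rbkg) on uniform knots is fitted by linear least squares
to minimize the Fourier magnitude of the k²-weighted residual on
R ∈ [0, rbkg], with a weak (5%) data-tracking term regularizing the
directions the short-distance Fourier window cannot see. χ = μ − spline;
the edge step is already 1. With rbkg = 1.0 Å and the default table the
first apparent shell sits near 1.4–1.6 Å, comfortably above rbkg.

**Shell grouping.** Ligand distances sorted ascending are greedily
clustered: a new shell opens when a distance exceeds the running shell
mean by more than tol (default 0.1 Å); shell R is the member mean, N the
count, and rigid-group labels carry over from residue identity when a
shell is single-residue.

**Refinement.** Bounded trust-region least squares (single start,
tolerances 1e-12) on k²-weighted χ over k ∈ [3, 12] Å⁻¹. Released
parameters per the free mask: one radial offset per rigid group — the
distance-fit reading of treating coordinating residues as rigid bodies —
and/or ΔE_F. σ² stays fixed at 0.003 Å² unless explicitly freed, and
coordination numbers are never refined. Bounds keep radii in (1, 6) Å and
|ΔE_F| ≤ 15 eV. The misfit metric is
R = 100·Σ|k^w(χ_obs−χ_mod)| / Σ|k^w·χ_obs| — normalized by the
observation, hence asymmetric by construction.

## Melting analysis

Θ is Savitzky–Golay smoothed (window 11 points = 5.5 °C, order 3 — odd,
and narrower than the closest transition pair handled, 8 °C) and
differentiated by central differences. Candidate transitions are peaks of
|dΘ/dT| (sign-agnostic to ellipticity conventions) with prominence ≥5% of
the global maximum; the top two by prominence are kept, ties toward lower
temperature. A single peak is localized by 3-point quadratic
interpolation. When two peaks are retained their positions come from a
joint two-Gaussian fit of the derivative over the spanning window: the
derivative maxima of *overlapping* transitions pull toward each other (for
two ΔH = 400 kJ/mol transitions 8 °C apart the raw upper maximum sits
~0.6 °C low), and deconvolving the pair removes that bias; the fit falls
back to quadratic interpolation if it fails or wanders >2 °C from the
discrete peaks. ΔTm is first-Tm(with metal) − first-Tm(without), so
destabilization is negative. Reversibility compares heating and cooling
scans on their overlap against 5% of the dynamic range by default — the
quantitative reading of "no hysteresis".

Known bias: even a perfect derivative reader sits ~0.1 °C below Tm for a
single van't Hoff transition (the 1/T² factor skews the peak); this is
inherent to the first-derivative definition of Tm, not a numerical error.

## Pipeline

`pipeline.run` executes simulate → melt → xanes → exafs → report from a
YAML/dict config with one global seed; per-sample generator seeds derive
from it. Logging goes to stderr with stage timings; numeric outputs only
to files, with fixed formatting, so reruns are byte-identical. The report
joins Tm, ΔTm against each sample's metal-free partner, and the LCF bound
fraction; `rank_stability` orders metal-containing samples by first Tm,
ties broken by ΔTm (less destabilized first), then name. The demo
configuration names variants by the fragment actually measured (90-210)
even where sample tables elsewhere file them under the long-fragment
column; the `_90_` infix in the sample name is authoritative here.

## Problem sizes

Acceptance-style computations use the full experimental granularity: 1001
energy points for XANES (E₀±200/300 eV at 0.5 eV), ~1720-point μ(E) for
EXAFS extraction with 180 k-points in the fit window, and 151-point melts
(20–95 °C at 0.5 °C). These run in seconds; the round-trip property sweep
(20 random site models through generate → normalize → extract → refine)
dominates the test suite at a few seconds.

## Limitations

Single-scattering only; no Fourier-domain fitting; no coordination-number
or σ² refinement by default; two-component LCF only; at most two melting
transitions; the scattering table is synthetic, so absolute distances are
only meaningful within the self-consistent synthetic world — against
measured data one would substitute tabulated or computed phase shifts.
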