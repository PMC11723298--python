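# Methods

This note records the model, the numerical choices, and the open design
decisions behind `depfield`, at the level of detail a user needs to judge
what the computed numbers do and do not mean.

## 1. Device model and governing equations

The device is a parallel-plate microchannel of height `H`.  Its floor
carries interdigitated finger electrodes (alternating driven/grounded,
finger width `2w`, centre-to-centre pitch `L`, spacing `d = L − 2w`); its
lid is a planar grounded counter-electrode.  The fingers are long compared
with the channel height, so the field is modelled in the 2-D cross-section.
Mirror symmetry reduces the domain to one half-period: dimensionless
coordinates `x* = x/L ∈ [0,1]` (driven finger centre at 0, grounded finger
centre at 1) and `y* = y/H ∈ [0,1]` (lid at 0, electrode plane at 1).

The analysis is RMS electrostatics: at the MHz frequencies of interest the
medium behaves resistively on the device scale, the potential obeys the
Laplace equation, and all AC quantities are represented by their effective
values.  In dimensionless form

    ∂²φ/∂x*² + (L/H)² ∂²φ/∂y*² = 0,

with `φ = V_rms` on the driven finger (`0 ≤ x* ≤ w/L`, `y* = 1`), `φ = 0`
on the grounded finger and the lid, zero normal derivative on the two
symmetry planes `x* ∈ {0, 1}`, and — the crux — zero normal derivative over
the insulating gap (`w/L < x* < 1 − w/L`, `y* = 1`): no current enters the
substrate.  This last Neumann segment makes the problem a *mixed* boundary
value problem with no separable closed form.

Out of scope by construction: 3-D end effects of finite fingers, dielectric
passivation layers, Joule heating, and any coupling to fluid flow.  The
force model is the dipole (first-order) DEP approximation; field phase
effects (travelling-wave DEP) are not modelled.

## 2. Cell polarizability (Clausius–Mossotti module)

Complex permittivities use the physics convention `ε* = ε + σ/(jω) =
ε − jσ/ω`; spectra computed here are complex conjugates of the engineering
convention.  A live mammalian cell is modelled as a single-shell particle:
a conducting interior (effective permittivity `ε_c`, conductivity `σ_c`)
wrapped in a thin insulating membrane of capacitance per area `c_m`.  With
`a = d_c/2`, the membrane in series with the interior gives

    ε_p* = a c_m ε_c* / (a c_m + ε_c*),

and `β = (ε_p* − ε_l*)/(ε_p* + 2ε_l*)`.  Expanding in the four time
constants `τ_c* = c_m d_c / 2σ_c`, `τ_c = ε_c/σ_c`, `τ_l* = c_m d_c / 2σ_l`,
`τ_l = ε_l/σ_l` yields the rational form implemented in
`cm_single_shell(..., form="shell")`:

    β = [ ω²(τ_l τ_c* + τ_l τ_c − τ_l* τ_c) + jω(τ_l* − τ_l − τ_c* − τ_c) − 1 ]
        / [ −ω²(2τ_l τ_c* + τ_l* τ_c + 2τ_l τ_c) + jω(τ_l* + 2τ_l + 2τ_c* + 2τ_c) + 2 ].

Its DC limit is `β → −1/2` (a membrane-insulated particle looks like an
insulator at DC) and its high-frequency limit is the Maxwell–Wagner
contrast of the membrane-loaded interior.  The implementation is verified
against the independent two-phase route (`shell_effective_permittivity` +
`cm_two_phase`) to machine precision, and a property test checks
`−0.5 ≤ Re(β) ≤ 1` across the passive parameter space.

A second variant, `form="as-printed"`, reproduces a version of this formula
that circulates with typographically corrupted denominator signs (its DC
limit is `+1/2`, and near 8.5 MHz with typical assay parameters it returns
`Re(β) ≈ −1`, outside the physical band).  It exists only so the
discrepancy is documentable; nothing else uses it.

Defaults and parameters: cell diameter 15 µm (mammalian epithelial scale),
`c_m = 0.01 F/m²`, interior `50 ε₀` / `0.5 S/m`; medium `ε_l = 6.9e−10 F/m`
(≈ 78 ε₀, aqueous) and `σ_l = 1.0e−3 S/m` (isotonic mannitol-type assay
buffer — low conductivity keeps `Re(β)` near its positive plateau at MHz
frequencies and limits heating).  `peak_frequency` refines a 200-point
log-scan with bounded Brent search on log-frequency; ties resolve to the
lowest frequency.

## 3. The gap approximation and its calibration

The separable surrogate replaces the gap's Neumann condition with a
Dirichlet profile: an odd cubic in the stretched coordinate
`t = (x* − 1/2)/(1/2 − w/L) ∈ (−1, 1)`,

    φ(t; C) = (V_rms/π) [ π/2 − C t − (π/2 − C) t³ / s ].

Two members of this family are supported (`GapApproximation`):

* `s = 6` (**published form**, the package default for field work).  It is
  discontinuous at the gap edges — its edge limit is
  `(V/π)(π/2 + C + (π/2−C)/6) ≈ 0.78 V_rms` against the electrode's
  `V_rms`.  The discontinuity is deliberate and is *not* smoothed: it is
  part of the surrogate being characterized.
* `s = 1` (**edge-continuous form**).  It equals the electrode potentials
  exactly at both edges for *every* `C`, making `C` a pure shape parameter.

The canonical constant `C = 0.75480` is reconstructed by the calibration
module as a one-parameter linear least-squares fit (closed form — the
profile is linear in `C`) of the edge-continuous family to the ideal
conformal solution for the potential across a gap between coplanar
semi-infinite electrodes,

    φ_ref(t) = (V_rms/π) (π/2 − arcsin t).

That fit has the exact value

    C_opt = 123π/512 = 0.7547185…,

independent of every device dimension (the fit lives entirely in `t`) —
which is why a single constant serves all geometries.  The package treats
the printed fifth decimal (0.75480 vs 0.75472) as insignificant; the
default constant is kept at 0.75480 and the calibration reproduces it
within 1e−4.

A second reference, `reference="mixed-fd"`, fits the family to the gap
trace of the *finite-channel* mixed solution instead.  That fit is
geometry-dependent (`C_opt ≈ 0.69` at `H/L = 5`, `w/L = 0.25` for the
continuous family; ≈ 1.09 for the published family) because the grounded
lid skews and steepens the true trace — see §6.  Sampling for either
reference: 512 equispaced points strictly inside the gap, excluding one
grid cell next to each edge (the FD trace is contaminated there by the
edge singularity; the same window is applied to the conformal reference so
the two fits are comparable).

## 4. Fourier-series solution

With fully Dirichlet top data `f(x*)` the solution separates into the
cosine eigenbasis (`k_n = nπ`):

    φ = a₀ y* + 2 Σₙ aₙ cos(k_n x*) sinh(k_n (H/L) y*)/sinh(k_n H/L),
    a₀ = ∫₀¹ f = V_rms/2,      aₙ = ∫₀¹ f(x*) cos(k_n x*) dx*.

Normative definition and dual path.  The coefficients are *defined* as the
numerical projection of the boundary profile (`coefficients_quadrature`,
composite 10-point Gauss–Legendre per smooth piece, panel count scaled to
the top mode).  `coefficients_closed_form` evaluates the analytically
integrated projection of the piecewise constant/cubic/constant profile;
the two paths agree to relative 1e−9 for n ≤ 200 (tested), and even-order
coefficients vanish identically because the boundary data satisfy
`f(x*) + f(1−x*) = V_rms`.

Numerical stability.  `sinh(k_n H/L)` overflows beyond n of a few dozen at
`H/L = 5`; the ratio `sinh(k_n(H/L)y*)/sinh(k_n H/L)` is therefore
evaluated in exp-difference form (`exp(kA(y−1))` terms with an `expm1`
denominator) and the stored coefficients never carry the sinh factor.
Fields and `∇|E|²` come from term-wise analytic differentiation with the
`1/L`, `1/H` chain factors; evaluation on lattices is tensor-factored into
BLAS products, chunked to bound memory.

Series length.  The default is n = 10,000: boundary-profile reconstruction
then has mean absolute error < 0.5 % of `V_rms` outside ±0.005 of the two
profile discontinuities, and interior quantities are converged far beyond
measurement relevance (terms decay like `exp(−nπ(H/L)(1−y*))` away from the
electrode plane — at `y* ≤ 0.99` the sum is effectively a few hundred
terms).  Surface-averaged quantities (the parametric sweep) converge much
faster and use n = 2,000 (a doubling check holds the change under 1 %).
No Gibbs mitigation is applied anywhere: smoothing would silently alter
exactly the near-edge quantities this package exists to characterize.

Known evaluation caveat: *exactly on* `y* = 1` with the published
(discontinuous) profile, the term-wise differentiated field series does not
converge pointwise — partial sums ripple with O(1) amplitude that decays
with distance from the edges, a direct signature of the profile's jump.
The edge-continuous profile removes the jump (coefficients fall one power
faster) and its field is evaluable on the plane.  Interior evaluation
(`y* < 1`) is unconditionally stable for both.

## 5. Finite-difference oracle

The true mixed problem is solved independently of the series machinery:
second-order 5-point differences on an edge-aligned uniform lattice, with
Neumann sides/gap closed by second-order ghost reflection (corners where
Dirichlet meets Neumann take the Dirichlet value).  Grids satisfy
`ny − 1 = (H/L)(nx − 1)`, which makes the physical cells square and the
dimensionless stencil exactly isotropic.  The reference sizes are
721×3601 (≈ 2.6e6 nodes), with 1441×7201 (≈ 1.04e7) for the oracle's own
convergence check and 461×2301 (≈ 1.06e6) as the calibration-scale grid.

The linear systems are solved by an in-house geometric multigrid: V(2,2)
cycles, red–black Gauss–Seidel smoothing, full-weighting restriction,
bilinear prolongation, sparse-LU on the coarsest level (≤ 1e5 unknowns),
to relative residual 1e−10 — far below the discretization error the oracle
is used to measure, so algebraic error never enters the comparisons.  The
solver is verified against an independently assembled `scipy` sparse solve
(max deviation ~1e−13 V on test grids), against the exactly representable
uniform-lid solution `φ = V_rms y*`, and by a Richardson grid-doubling
study (observed interior order ≥ 1.5; the electrode-edge singularity
degrades the local order, as it must).  Discrete fields use
`numpy.gradient` (central interior, second-order one-sided at boundaries).

Oracle self-convergence, measured: the average relative |E| change between
the 2.6e6- and 1.04e7-node solutions, excluding one coarse cell around each
electrode edge, is **0.013 %** — comfortably inside the 0.15 % level the
verification protocol demands.

## 6. What the comparison shows — and its structural limit

Two distinct error sources separate cleanly:

* **Series truncation + discretization**: comparing the series against the
  FD solve of the *same* (Dirichlet-replaced) problem agrees to < 0.1 % of
  `V_rms` at interior points — the surrogate problem is solved essentially
  exactly.
* **The gap approximation itself**: comparing against the FD solve of the
  *true mixed* problem isolates the modelling error of the Dirichlet
  replacement.

Mirror symmetry is the right lens for the second item.  The
Dirichlet-replaced problem satisfies `φ(x*,y*) + φ(1−x*,y*) = V_rms·y*`
exactly (all-Dirichlet harmonic argument).  The true mixed problem does
*not*: the mirror transform breaks the gap's Neumann condition, and the
grounded lid draws flux asymmetrically — the converged mixed solution has
`φ(0.5, 1) ≈ 0.474 V_rms`, not `V_rms/2`.  An antisymmetric cubic profile
cannot represent that, so a few-percent potential error on the electrode
plane is intrinsic to the surrogate, not a tuning failure.

Measured at Type-A ratios (`H/L = 5`, `w/L = 0.25`), n = 10,000,
C = 0.75480 (published profile), 721×3601 mixed reference, sampling the
line `y* = 1` at the FD nodes with edge nodes ±1 excluded, under four
averaging rules (all reported by `error_report`; percentages):

| rule                                  | Δφ*   | ΔE*    |
|---------------------------------------|-------|--------|
| pointwise relative (floor 1e−3)       | 10.83 | 39.71  |
| scale-normalized (mean |Δ|/scale)     | 2.47  | 487.7  |
| mean-ratio (L1)                       | 5.06  | 52.90  |
| relative L2 (**default**)             | 7.04  | 95.39  |

The relative-L2 rule — the standard verification norm — is the documented
default; under it the potential comparison lands at **Δφ\* = 7.0 %**,
i.e. the few-percent accuracy level this construction is known for.

The field comparison along the surface line is a different matter, and the
package reports it honestly rather than defining it away: on the gap the
true solution has `E_y = 0` (that *is* the insulating boundary condition),
while the Dirichlet-replaced solution carries a nonzero normal field there
— a structural, solver-independent difference of order tens of percent
that dominates every surface-line average of |E*| (see the table).  Away
from the electrode plane the two solutions converge quickly: averaged over
the whole channel interior, the |E*| deviation is ≈ 5 % (mean-ratio) and
the φ* deviation ≈ 2.3 %.  Conclusion for users: treat series-derived
*fields on the gap segment of the electrode plane itself* as qualitative;
everywhere else — including the electrode surface, where cells actually
collect — the analytic field is accurate to a few percent.

## 7. Parametric study

`mean_surface_force` averages |F_DEP| over one full electrode period at a
fixed dimensionless height `y* = 1 − offset` (default offset 1e−3, i.e.
0.5 µm below the plane for a 500-µm channel), with ≥ 200 equispaced
samples; n = 2,000 terms per layout.  The continuum force diverges at the
electrode edges, so "on the surface" is necessarily a recipe: the offset
and segment are recorded in the result metadata.  Two recipe facts are
measured and tested rather than hidden:

* The *absolute* average is edge-dominated and offset-sensitive (halving
  the offset scales the published-profile average by ≈ 4× — its boundary
  jump makes the near-edge field ~1/r — and the continuous-profile average
  by < 2×).  The *relative structure* of the force map is offset-robust
  (log-map correlation > 0.99 between offsets), so every design conclusion
  drawn from the map survives the recipe.
* The averaging segment matters: averaging over the metal finger alone
  over-weights the edge peak as the finger narrows and makes the force
  appear width-dominated; averaging over the full patterned surface — the
  quantity relevant to a cell population settling onto the floor — yields
  the robust design finding.

That finding, reproduced on a 40×40 map of width `2w` and spacing `d` over
[5, 60] µm at `H = 500 µm`: the surface-averaged force **decreases
monotonically with spacing at fixed width** and is **more sensitive to
spacing than to width** (mean |∂F/∂d| > mean |∂F/∂w|).  Practical corollary
for ~15-µm cells: choose the spacing first (30–50 µm is the useful window);
the width is a secondary knob.

## 8. Degenerate inputs, tie-breaks, tolerances

* `DeviceGeometry` enforces `0 < 2w < L`, `H > 0`; `GapApproximation`
  enforces `0 < C < π/2` (outside, the cubic coefficient changes sign
  meaninglessly).
* `gap_potential` is defined on the *open* gap interval only;
  `mean_surface_force` rejects `offset = 0` (singular edge value).
* `fit_C` raises a rank error when every sample sits at the gap midpoint
  (the `C`-dependence vanishes there); it requires ≥ 10 samples.
* `peak_frequency`: flat spectra tie-break to the lowest frequency;
  default relative tolerance 1e−4 on log-frequency.
* Multigrid convergence: relative residual 1e−10 with an absolute floor at
  the equation scale, so an exact initial guess (uniform lid) terminates
  immediately; non-convergence raises with the achieved residual.
* `field_grid` marks `∇|E|²` and force values on the four boundary lines
  with NaN — the documented sentinel for "interior-only quantity".
* FD grids must be electrode-edge aligned (`(nx−1)·w/L` integral); the
  `FDGrid.for_geometry` factory constructs aligned, physically square
  lattices near a node budget.

## 9. Problem sizes and runtime

The verification pipeline (script `scripts/acceptance.py`) uses: 512-sample
calibration fit (instant), one 2.6e6-node and one 1.04e7-node multigrid
solve (≈ 5 s and ≈ 35 s on one CPU), an n = 10,000-term series, and a
40×40 sweep at n = 2,000 (≈ 1 min in the test suite).  These sizes put the
algebraic and sampling errors well below every tolerance quoted above while
keeping a full run in the minutes range.

## 10. Limitations

The model is 2-D, electrostatic (RMS), single-shell, dipole-order DEP, with
ideal electrodes (no passivation, no electrode polarization/double-layer
impedance, no Joule heating, no flow coupling).  The gap surrogate is
accurate for the potential to a few percent and for interior fields, but
its surface-line field on the gap violates the insulating condition by
construction (§6).  The calibration constant is exact for the ideal
conformal reference; for shallow channels (`H/L ≲ 1`) the finite-channel
trace departs further from that reference and a geometry-specific
`reference="mixed-fd"` recalibration is the better choice.
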