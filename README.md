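# depfield

Electric-field and dielectrophoretic-force modelling for parallel-plate
cell-separation devices whose floor carries interdigitated finger electrodes
and whose lid is a planar grounded counter-electrode.

Dielectrophoresis (DEP) moves polarizable particles along the gradient of a
nonuniform AC field.  For a spherical cell of diameter `d_c` suspended in a
medium of permittivity `ε_l`, the time-averaged force is

    F_DEP = 2π ε_l (d_c/2)³ Re(β) ∇|E|²,

where `β = (ε_c* − ε_l*)/(ε_c* + 2ε_l*)` is the Clausius–Mossotti factor of
the cell against the medium (complex permittivities `ε* = ε + σ/(jω)`).
Designing a trap therefore needs two ingredients this package computes:

1. **The cell's polarizability spectrum** — a single-shell model (conducting
   interior wrapped in a thin membrane of capacitance per area `c_m`) gives
   `Re(β)(f)` and the frequency that maximizes it (`depfield.cm`).
2. **The field map of the device** — the RMS electrostatic potential in the
   channel cross-section solves a Laplace problem that mixes Dirichlet
   (electrodes) and Neumann (insulating gap) conditions on the electrode
   plane.  Replacing the gap condition with a calibrated cubic potential
   profile makes the problem separable, giving a Fourier cosine series

       φ = a₀y* + 2 Σₙ aₙ cos(nπx*) · sinh(nπ(H/L)y*)/sinh(nπH/L)

   that can be differentiated term by term — so `E`, `∇|E|²` and `F_DEP`
   come out analytically smooth, where grid-based solvers oscillate near the
   electrode-edge singularities (`depfield.series`).

An independent finite-difference multigrid solver of the *true* mixed
problem (`depfield.fd`) quantifies the cost of the gap approximation; the
cubic's constant `C = 0.75480` is reconstructed by closed-form least squares
against the ideal conformal gap solution (`depfield.calibrate`, exact value
`123π/512`); and a width/spacing parametric study maps the surface-averaged
force over electrode layouts (`depfield.sweep`).

Who this is for: microfluidic-device designers sizing interdigitated
electrode arrays, and biophysicists estimating DEP trapping forces on
mammalian-scale cells.

## Worked example

```python
import depfield as df

# Type-A layout: 50-um fingers, 50-um gaps, 500-um channel, 10 Vpp drive
geom  = df.DeviceGeometry.from_width_spacing(50e-6, 50e-6, 500e-6)
drive = df.DriveSettings.from_vpp(10.0, f=8.5e6)     # V_rms = 3.5355 V

# cell polarizability (single-shell model, 15-um cell)
medium = df.MediumProperties(epsilon_l=6.9e-10, sigma_l=1.0e-3)
cell   = df.CellDielectricModel(d_c=15e-6, c_m=0.01,
                                epsilon_c_eff=50 * df.VACUUM_PERMITTIVITY,
                                sigma_c_eff=0.5)
f_peak = df.peak_frequency(cell, medium)             # 4.611e+05 Hz
beta   = df.cm_single_shell(cell, medium, f_peak)    # Re(beta) = 0.9671

# field solution and DEP force near the electrode edge
pref = df.dep_prefactor(medium, 15e-6, 0.98)         # 1.7924e-24 F m
sol  = df.build_solution(geom, drive, n_terms=10_000)
sol.potential(0.5, 0.9)                              # 1.5910 V
sol.electric_field(0.25, 0.99, normalized=True)      # E* = (9.743, -6.198)
sol.dep_force(pref, 0.25, 0.99)
# -> (-9.449e-10, 3.056e-09) N, normalized magnitude 1.78e4
```

The force points toward the electrode edge (positive DEP), is strongest in a
~20-µm layer above the electrode plane, and at the gap midline drops to a
local minimum — which is where adsorbed cells are observed to be sparsest in
devices of this class.

Calibrating the gap constant from scratch:

```python
df.calibrate_gap_constant(geom, drive).C_opt   # 0.754718  (= 123*pi/512)
```

A `depfield` command-line tool wraps the same functionality
(`cm-spectrum`, `solve`, `validate`, `fit-c`, `sweep`; see
`depfield --help` and the TOML config schema in `depfield.config`).

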