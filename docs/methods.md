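# Methods

## Model

The simulator solves the coupled electro-thermal ablation problem on a 2D
axisymmetric domain whose revolution about the catheter axis represents the
left-atrial posterior wall, the inserted ablation catheter, and (optionally)
an esophageal cooling device. Magnetic induction is neglected: at 500 kHz the
skin depth in tissue is far larger than the domain, so the electric problem
is quasi-static current conservation with complex conductivity
σ_c = σ + jωε₀ε_r. Displacement currents are retained because tissue
permittivity at this frequency is large enough that ωε₀ε_r (≈ 0.22 S/m for
ε_r = 8000) is comparable to σ.

Heat transport follows the Pennes bioheat equation with the time-averaged
Joule density ½ Re(J·E\*) as source. Convective transport is not resolved:
the blood pool is removed from the thermal unknowns and replaced by Robin
(film) conditions — h_t = 610 W/(m² K) on endocardial tissue and
h_e = 3346 W/(m² K) on blood-wetted catheter surfaces, both referenced to
37 °C — and the device coolant is a fixed-temperature sink (below). The
metabolic source is neglected and the blood perfusion rate defaults to zero:
no published value exists for this configuration and, over a 20 s ablation,
perfusion is a second-order effect. It can be enabled via `omega_b` in the
run configuration.

Thermal injury uses first-order Arrhenius kinetics
dα/dt = (1 − α) A e^{−ΔE/RT}, with A = 2.94·10³⁸ s⁻¹, ΔE = 2.596·10⁵ J/mol
for myocardium, esophagus and averaged thoracic tissue, and
A = 4.43·10¹⁶ s⁻¹, ΔE = 1.3·10⁵ J/mol for pericardial fat. Nodes on a
fat/non-fat interface use the non-fat constants. The fraction of damage is
θ_d = clamp(α, 0, 1), reported in percent.

### Lesion metrics

All reported metrics are read along the axial sampling line from the tip
contact plane through the tissue stack (sample spacing 0.02 mm, material
interfaces sampled exactly). The esophageal lesion depth is the distance from
the fat–esophagus interface to the deepest esophageal sample with
θ_d > 2 %, the crossing located by linear interpolation between bracketing
samples, clamped to [0, esophagus thickness]. Peak temperature is the line
maximum at the final output step.

## Geometry

z = 0 is the plane of the flat electrode face; layer interfaces are grid
planes. The electrode indents the endocardium by the insertion depth
(tip height / 25 = 160 µm), so the endocardial surface away from the tip sits
at z = +160 µm and exactly the nominal myocardium thickness lies beneath the
electrode along the axis — which keeps the sampling-line tissue span equal to
the sum of the layer thicknesses. A hemispherical electrode face was
prototyped during development and changed lesion metrics negligibly; the flat
face keeps every subdomain grid-aligned, making subdomain areas exact under
refinement.

Several extents are not physically constrained and are configuration
defaults chosen large enough that results are insensitive to them (checked by
direct variation): blood chamber height 20 mm (5→40 mm moves the 30 W peak
by < 1 °C), tissue radial extent 40 mm, and a thoracic padding of 80 mm that
truncates the open thorax and carries the grounded/insulated far-field
boundary. The cooling device is modelled as planar slabs: 0.5 mm silicone
wall, 11 mm water, 0.5 mm wall (≈ 12 mm total, the device diameter).

### Coolant treatment

The device water is held at T_water over the whole water layer, during both
the 5-minute precooling phase and ablation. This represents a high-flow,
well-mixed coolant: the real device exchanges water fast enough that the
layer is isothermal at the supply temperature, whereas a stagnant conductive
water layer could not even reach T_water within the precool by conduction
alone (diffusion length ≈ 12 mm for an 11 mm layer). The device wall remains
a conductive domain, so the esophagus sees the coolant only through 0.5 mm of
silicone.

## Discretization

**Mesh.** A structured tensor-product grid in (r, z), split into right
triangles, with every material interface on a grid line. Sizing is graded
geometrically away from the electrode: finest edge 0.11 mm (scaled to meet
the element target), growth 0.12 per unit distance away from the tip and
0.05 within the tissue stack, capped at 10 mm in the far field. The gentle
growth rates matter: the potential decays like 1/r, and aggressive
coarsening measurably pollutes the terminal impedance. A global scale factor
is bisected until the element count is within ~10 % of the target (default
8000). Right triangles make the P1 stiffness matrix an M-matrix, so the
implicit thermal step satisfies a discrete maximum principle — verified by a
property test with random bounded initial data.

At the default target, doubling the element count changes the initial
impedance by 0.8 % and halving the time step changes the 20 s / 30 W peak
temperature by < 0.1 K. The residual slow impedance drift under refinement
(≈ +0.7 %/doubling) comes from the inverse-square-root current singularity
at the electrode rim, which first-order elements resolve at O(h); it affects
the absolute impedance level, not temperatures, which are set by the
(conserved) total power.

**Electric solve.** P1 axisymmetric elements with exact 2πr weighting and
direct sparse factorization. All platinum-tip nodes are constrained to one
terminal potential (the metal is 10⁷× more conductive than tissue); external
boundaries are grounded; the axis and all other boundaries are natural
(zero-current). The unit-terminal solve is rescaled so ½ Re(V I\*) equals
the prescribed power; with the reaction-based terminal current this makes the
discrete dissipated power equal the prescribed power to round-off, which the
acceptance suite checks at every step.

**Thermal solve.** Backward Euler, internal step 0.1 s during ablation
(output every 1 s over 0–20 s), 5 s steps during the 300 s precool. Material
properties are evaluated at the previous step's element-mean temperature
(lagged linearization, no Newton iteration); the dt-halving test bounds the
error of this choice. Lumped mass and row-summed (lumped) Robin terms keep
the system an M-matrix. Temperature-dependent properties clamp to their
fitted ranges' endpoints — mandatory because 40–50 W runs exceed the 115 °C
upper end of the σ(T) fit. The printed σ(T) step at 105 °C (0.665 → 0.57
S/m) is kept as specified rather than smoothed; it acts as a strong negative
feedback that pins high-power peak temperatures near 110–120 °C.

**Electric–thermal–damage coupling.** The electric problem is re-solved
every internal step with σ evaluated at the current temperature (tissue σ
rises ~2 %/K, so the field redistributes during the first seconds). Damage is
integrated with the same 0.1 s step using the exact exponential update
α ← 1 − (1 − α) e^{−k̄ dt} with k̄ the average of the Arrhenius rate at the
old and new temperatures; at constant temperature this reproduces the closed
form 1 − e^{−kt} to < 10⁻⁶ relative (property-tested), and the rate's
exponential temperature sensitivity is why damage uses the fine step, not the
1 s output step.

## Verification

Three independent analytic oracles are built by `make_oracle_fixture`:
concentric hemispherical electrodes (impedance vs (1/a − 1/b)/2πσ, agreement
0.04 %), a 1D slab transient vs its Fourier series (< 1 % at t = 5 s), and
constant-temperature Arrhenius integration (< 10⁻⁶ relative). Monotonicity
properties (lesion depth non-decreasing in power, non-increasing as coolant
cools; device presence raising initial impedance; impedance falling during
ablation; thin-wall anatomy sustaining deeper esophageal injury) and bitwise
determinism of outputs are asserted over full-scale sweeps.

Problem sizes used by the test and acceptance runs are the package defaults
(≈ 8 000 elements, dt = 0.1 s, 20 s horizon); coarser ≈ 1 500-element meshes
and 2 s horizons are used only for plumbing tests whose assertions do not
depend on resolution.

## Known limitations

- No latent heat of vaporization: temperatures may exceed 100 °C (as in the
  modelled experiments); steam-pop dynamics are out of scope.
- No electrode irrigation, contact-force tissue deformation, or 3D
  (non-axisymmetric) anatomy; the device layers are planar slabs rather than
  curved tube walls.
- The blood pool is electrically present but thermally reduced to film
  coefficients; power deposited in blood (the majority at this geometry) is
  assumed swept away by flow.
- Absolute impedance is sensitive to unmodelled series resistance of the
  body return path, so the simulated level (~40 Ω initial) is lower than
  typical clinical readings; relative impedance behaviour (fall during
  heating, rise when the device is inserted) is the meaningful output.
- Sub-electrode peak temperature is intrinsically discretization-sensitive
  (thin boundary layers near the contact edge). Externally reported reference
  values for this configuration, digitized from figures and obtained on
  coarser unstructured meshes, run cooler at the peak and deeper in
  esophageal damage than this implementation's mesh-converged results; the
  acceptance suite records these comparisons at fixed tolerances, and the
  cases outside tolerance are knowingly reported as failures rather than
  tuned away. Device-effect differences (e.g. the peak-temperature reduction
  from inserting the device at body-temperature coolant) agree closely.
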