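# Methods

This note records the model assumptions, the numerical choices and the
default parameters behind `emsaxs`, and what the synthetic fixtures do and
do not demonstrate.

## Physical premise and its limits

TEM maps sample the Coulomb charge density of a particle; SAXS samples its
electron density. The method assumes the two are proportional, so that a
density threshold in the map defines the same surface a SAXS-visible
particle would have. Differences between electron and photon scattering
lengths (e.g. negative electron scattering lengths of ions) are ignored, and
the SAXS data are assumed extrapolated to zero concentration, so no
structure factor is modelled. Dummy atoms cut from the map are
indistinguishable, hence all share one Gaussian form factor
`F(q) = exp[−(qσ)²/2]` with σ = 1 Å — including the hydration waters, whose
amplitude is instead controlled by the fitted contrast factor `c_w`.

## Model generation

* Voxel indices are 0-based and a dummy atom sits exactly at
  `origin + index·voxel_size` — the map's own grid, no half-voxel offset.
* Origin resolution follows the MRC2014 recommendation: a non-zero ORIGIN
  record wins, otherwise `NXSTART·voxel_size` (per-file-axis starts are
  permuted to x, y, z first). `read_map(..., prefer_origin_record=False)`
  flips the precedence. The header RMS is never trusted; it is recomputed
  and a disagreement only warns.
* `stride` (default 1) takes every k-th grid point per axis; SAXS resolution
  rarely justifies stride > 2. The mass estimate always counts stride-1
  voxels, since striding changes sampling, not volume.
* Automatic scan bounds: the upper threshold is the map maximum; the lower
  is 0 for non-negative maps and one RMS for maps with negative values
  (negative EM density is noise). Note that for a non-negative map the
  lowest level admits *every* voxel; for large maps give `tmin` explicitly.
* Disconnected blobs are deliberately *not* filtered: porous or fragmented
  maps should be punished by χ², not silently cleaned up.

## Hydration shell

Waters are placed by rejection sampling: candidate points at random
directions around every surface voxel (a voxel with at least one of its six
face neighbours unselected), radius uniform in
`[shell_distance, shell_distance + placement_tolerance]`; a candidate is
rejected if any dummy atom is nearer than `shell_distance` (no interior
placement) or any accepted water nearer than `min_water_spacing`; acceptance
stops at `target_density × estimated area`. The area estimate is 2/3 of the
exposed voxel-face area, which corrects the 3/2 staircase bias of a
digitized smooth surface. Defaults, all overridable:

| parameter             | default | rationale |
|-----------------------|---------|-----------|
| `shell_distance`      | 3.0 Å   | carbon–water-oxygen van-der-Waals contact |
| `min_water_spacing`   | 2.8 Å   | water–water contact distance |
| `placement_tolerance` | 2.8 Å   | radial thickness of one molecular water layer |
| `target_density`      | 0.2 Å⁻² | approximate surface density of a monolayer |

With a vanishing radial thickness the 2.8 Å spacing cannot reach
0.2 waters/Å² (random sequential packing of disks saturates well below it);
one molecular layer of radial freedom is what makes the target density
attainable, which is why the tolerance defaults to the water diameter.
Hydration is deterministic given the seed; during a scan each level hydrates
with a child seed spawned from the run seed.

## Histograms and the Debye evaluation

Histograms store, per distance bin (default width 0.1 Å), the summed pair
weight `Σ 2wᵢwⱼ` and the weight×distance sum; the representative distance of
a bin is its centre of mass (weighted bins, default) or the midpoint. The
zero-distance self term `Σ wᵢ²` is kept separately, making the conservation
identity `self + Σ bins = (Σw)²` exact to rounding and the q = 0 limit
trivial. Because both stored moments are additive, onion-shell partial
histograms assemble *exactly*: the scan's incremental histogram equals a
from-scratch recomputation bin for bin (verified to 1e-9 relative in the
acceptance suite). Hydration components (pw, ww) are recomputed per level —
the water set changes with the surface, so the O(nm) reuse applies to the
map–map component only.

`sinc` is evaluated through numpy's implementation (exact at 0); the sphere
form factor used as an analytic oracle switches to its series
`1 − x²/10` below x = 0.01 to avoid cancellation. Pairwise work is streamed
in 512-row blocks so memory stays flat for maps of tens of thousands of
voxels.

## Fitting and the landscape

For each level the fit is `I_exp = a·(I_pp + c_w·I_pw + c_w²·I_ww) + b`:
(a, b) by the weighted least-squares closed form, `c_w` by grid search over
0…5 in steps of 0.05. The grid always contains 0, so adding hydration can
never worsen the optimum; a constant model curve raises a rank-deficiency
error. The reduced χ² uses n − 3 degrees of freedom — the scanned threshold
is a discrete model index, not a fitted parameter, which is the conservative
convention.

The threshold and `c_w` both control the effective particle size and are
therefore strongly correlated; together with the quantized voxel densities
this makes the raw landscape noisy, especially at small volumes where each
density step adds a surface-proportional batch of atoms. The landscape is
therefore smoothed with a centred moving average (default window 5 levels,
truncated at the ends, NaN-aware for empty-model levels) before minima are
located; both the raw minimum and the window-averaged χ² are reported, and
no interpolation between grid levels is performed. Equal smoothed minima
break towards the lower threshold (larger model). Empty-model levels are
recorded as missing, not as errors.

The mass axis converts thresholded volume at 1.35 g/cm³ (average protein
density). It is a labelling aid for selecting among multiple minima, not an
absolute measurement.

## Simulated data and phantoms

Simulated curves use the exact (unbinned) Debye sum over per-atom contrasts
`Z_eff − ρ_solvent·V_excl`, with Z_eff and displaced volumes from a bundled
residue table (20 amino acids + water; element-level fallback with warning)
and ρ_solvent = 0.334 e/Å³ by default. Per-point errors come from the
package's empirical error family

    σ(q) = (α + β·q^γ) · (I(q) + f·I(0)) / √k

with defaults α = 0.005, β = 0.3, γ = 1.5, f = 10⁻³, k = 1: a relative
error growing from ~0.5% at low q to ~10% at q = 0.5 Å⁻¹, plus a small
baseline floor so σ stays positive through form-factor minima, as in a real
buffer-subtracted measurement. Gaussian noise of this magnitude is drawn
reproducibly from the model's seed.

Phantom maps are geometric solids (ball, two-ball) or Gaussian-smeared
point depositions on a voxel grid. They are internally consistent fixtures,
not EM simulators: no CTF, no detector statistics, no map-processing
artefacts, no resolution anisotropy. Passing the round-trip tests therefore
shows the *pipeline* is faithful (a map whose surface matches the scattering
particle is recovered at the right threshold with χ²ᵣ ≈ 1), not that any
real microscope map will fit this well; real matched pairs typically land in
the low double digits of χ²ᵣ.

Standard round-trip conditions used by the tests and the acceptance script:
a ball of radius 16 Å on a 32³ grid of 2 Å voxels, smeared with a 2 Å
Gaussian (the generating surface then sits at the half-maximum density 0.5),
scanned over 40 levels down to 0.02 against 120 simulated points in
q = 0.01–0.3 Å⁻¹. The mismatch control replaces the curve by an equal-volume
two-ball particle separated by three sub-ball radii. These sizes keep a
full scan near ten seconds while leaving the shape information (several
sphere-form-factor oscillations) in the fitted q range.

## Known limitations

* For small or coarsely sampled particles (radius of a few voxels) the
  `c_w`–threshold degeneracy can produce a spurious global minimum at a much
  higher threshold: a small core plus a strong water shell can mimic the
  full particle. Inspecting the mass axis and the reported secondary minima
  resolves this; it is the documented reason the mass column exists.
* The binned-vs-exact Debye agreement (≲10⁻³ relative at 0.1 Å bins) is
  measured for q ≤ 0.5 Å⁻¹; wider q ranges need finer bins.
* Maps are assumed orthorhombic (cell angles 90°); exotic skewed-cell maps
  are not supported.
* `write_model_pdb` numbers residues modulo 9999 and relies on gemmi's
  serial handling for very large models; dummy models intended for
  visualization should use `stride` ≥ 2 anyway.
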