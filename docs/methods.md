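# Methods

## Scope and model

The package quantifies fractional Se occupancies at the belt-chalcogen sites
of the nitrogenase FeMo-cofactor from anomalous difference density maps, and
implements the assay-side computations that accompany such an experiment.
It operates strictly downstream of structure determination: site positions
and B-factors are taken from a refined model (here, from the synthetic
fixture), never searched for in the map. Space-group symmetry is not
expanded — all maps are P1 over the asymmetric unit, which is where the
quantification lives. mmCIF, anisotropic displacement parameters and
refinement-based occupancy fitting against structure factors are out of
scope.

## Forward model (synthetic scenes)

Each scattering species at a site contributes an isotropic Gaussian peak

    rho(r) = occ · f″ · (4π/B_eff)^{3/2} · exp(−4π² r² / B_eff),

in map units where the full-space integral of a full-occupancy peak equals
f″ in electrons. `B_eff = B_atom + B_blur` with
`B_blur(d) = (d / 1.6 Å)² · 9 Å²`, so peak widths grow with both the atomic
displacement parameter and the nominal map resolution d; at the default
d = 1.6 Å a B = 9 Å² atom renders with B_eff = 18 Å² (σ ≈ 0.48 Å). The model
ignores atomic form-factor shape, Friedel-pair statistics and solvent — only
relative integrated densities matter to the estimator, and shape systematics
cancel in the Fe-normalized ratios.

The fixture geometry is generic, not the true cofactor coordinates: what the
estimator is sensitive to is controlled exactly — two 7-Fe cofactor copies
(two stacked Fe triangles plus an apical Fe), each with a belt triangle of
three chalcogen sites 5.7 Å apart and ~2.2 Å Fe–chalcogen contacts; two 8-Fe
clusters (2.6 Å cube); 30 Fe total, all at unit occupancy; cluster copies
≥ 25 Å apart and every site ≥ 10 Å from a cell edge (default cell: 50 Å
orthorhombic P1 box). B-factors are drawn per scene from N(9.0, 0.4²) Å² for
Fe and N(9.9, 0.5²) Å² for chalcogen sites, the values characteristic of the
isotropically refined reference structures. A mixed belt site uses one
B-factor for both its Se and its S component. Optionally a single remote
low-occupancy Se site (0–20%) is placed 22 Å from cofactor copy 1.

Noise is i.i.d. Gaussian per voxel. The default RMS is 2% of the
full-occupancy Se peak height — the map statistic reported for the
experimental data this emulates. No noise correlation structure is modelled;
nothing anchors one. Consequently, passing recovery tests demonstrate the
estimator's behaviour under white map noise with exactly known site
positions and B's, not robustness to model error, correlated map artifacts
or mis-refined coordinates.

Default grid spacing is resolution/3 (0.533 Å at 1.6 Å). Maps are float32
(CCP4 mode 2), so file round trips are bit exact. Identical fixture
specifications (including seed) render bit-identical maps.

## Integration and the mode response

Site densities are sphere integrals of radius 1.0 Å. Two sampling rules:

* **voxel-sum** (default of `IntegrationConfig`): sum of voxels whose
  centers fall inside the sphere, × voxel volume, with periodic wrap.
  Whether the historical grid-map tooling summed voxels or interpolated is
  not documented; voxel-sum is this package's stated convention. At the
  default spacing its sphere-discretization error has ~1.7% per-site scatter
  (measured), which is why it is kept for map statistics but not preferred
  for estimation.
* **subgrid-trilinear**: trilinear resampling on a 4× subdivided grid before
  the same rule. Scatter drops below 0.3%; the interpolation loses a
  mode-systematic ~10% of peak mass, which cancels in calibrated ratios.

`quantify_scene` defaults to subgrid-trilinear; this is a deliberate
deviation of the estimation path from the plain voxel-sum default, chosen
because the recovery error budget (below) requires the low-variance mode.

Because the 1.0 Å sphere captures only part of a peak and the captured
fraction depends on B_eff, each measured density is divided by the
integration mode's **response** — the expected integrated signal per unit
peak mass at that B_eff, measured numerically by rendering a unit Gaussian
at the map's spacing and running the same integrator (averaged over eight
fixed sub-voxel offsets, cached). This one mechanism normalizes out the
B-dependent capture fraction (Se sites at B ≈ 9.9 Å² vs Fe references at
≈ 9.0 Å² differ by ~2.6% at default conditions), the trilinear mass loss and
the voxel-sum discretization mean, making the mixing formula exact for the
Gaussian model. Supplying no peak model disables the correction and gives
the plain D_norm ratio algebra.

No baseline is subtracted inside the sphere: an anomalous difference map is
taken as zero-mean away from anomalous scatterers. The B-factor cutoff for
reference selection exists but defaults to off, since the reference and
cofactor atoms have similar B values by construction.

## Estimation, uncertainty, diagnostics

Calibration is the mean and population CV of the 30 Fe reference densities;
CV > 4% logs a warning (reference-quality bound), CV > 15% is an error.
Belt sites use the mixed-chalcogen conversion
`p = (D_norm − r_S)/(r_Se − r_S)`, which assumes Se + S fractions sum to one.
A two-unknown (p_Se, p_S) decomposition from a single scalar is
underdetermined, so chalcogen loss is *not* decomposed: a genuinely vacant
site simply reports a low Se occupancy and the density deficit is left
unexplained (the CO-inhibited endpoint is represented exactly this way).
Isolated Se sites (the remote site) use free mode `p = D_norm / r_Se`.

Uncertainty is the quadrature combination of the calibration CV (propagated
through p) and the detection floor `rms / peak(full Se)`; the floor is also
the `below_detection` threshold. Estimates outside [0,1] by at most twice
their uncertainty are clamped with a `clamped` flag; further out they are
flagged `inconsistent` and left unclamped — out-of-range magnitudes are
diagnostic. The copy-to-copy deviation |p₁ − p₂| is computed per label and
reported as an empirical uncertainty check; the ~5-point anchor is treated
as occupancy percentage points.

**Cross-talk correction.** Neighboring peaks bleed into each other's spheres
(an Fe at 2.2 Å leaves ~0.3% of its mass inside a belt sphere at default
B_eff). A second pass subtracts each neighbor's predicted in-sphere mass —
closed form via the noncentral-χ²(3) radial CDF — using first-pass occupancy
estimates and the first-pass calibration as the unit scale (which keeps all
estimates invariant under rescaling the map), then recalibrates. Measured
error budget at default conditions, noiseless: ≤ 0.008 occupancy per copy
across planted fractions 0–1; under default noise the mean absolute
recovery error is ≈ 0.01 and the across-Fe CV ≈ 1.8% (trilinear) / ≈ 3.3%
(voxel-sum median over seeds).

## Time course

Each freeze-quench point is a scene quantified on both cofactor copies;
copies are averaged with equal weight and half their difference enters the
point's uncertainty in quadrature. Turnover normalization counts one
ethylene (from acetylene, a 2-electron substrate) as one turnover per
cofactor; converting product amount to turnovers requires the molar amount
of active sites (two per MoFe tetramer), which is a required input since it
depends on the protein molar mass. The series demands strictly increasing
turnover counts. Diagnostics flag any increase of total belt Se between
consecutive points beyond combined uncertainties (Se is only ever lost) and
report — as an observation, not an error — whether the earliest point shows
the 5A site ahead of 3A. No kinetic model is fit to the traces; the
default seven-point planted trajectory (turnovers 2–5361) is illustrative,
shaped to the qualitative migration behaviour, and is not a fitted or
published table.

## Kinetics

Dixon analysis fits unrestrained OLS lines of 1/v on inhibitor
concentration per substrate level and takes K_i as the negated **median** of
pairwise intersection abscissae (mean optional), with the MAD as dispersion;
near-parallel pairs (relative slope difference < 1e-6) are excluded with a
warning. Whether a reported ± on K_i should derive from replicate scatter or
fit covariance is ambiguous in general, so the fit exposes both the
intersection dispersion and the per-line statistics. Concentrations carry
explicit units and are normalized to μM internally. Velocities are taken as
product/time for fixed-time assays. The lag phase of an activity time course
is the x-intercept of the best steady-state suffix line (max R², ties to the
longer suffix), floored at zero. Relative activity is a ratio of condition
means with delta-method error propagation; the dose optimum is the
concentration with maximal mean product, ties broken downward, flagged when
it sits on the edge of the tested range.

The synthetic assay generators plant the reference values (K_i 410 μM and
12.7 mM; H₂ ratios 65% and 38%; CH₄ optimum 1 mM; specific activity
2350 nmol min⁻¹ mg⁻¹) on the published concentration grids with 3%
multiplicative replicate noise (triplicate gas-chromatography assays), so
the fits are exercised under realistic scatter; noiseless generation gives
exact recovery. Note the weak-inhibitor (KSCN) K_i is an extrapolation far
beyond the tested 0–4 mM range, so single realizations scatter by ~13%;
replicate medians are the stable quantity.

## Problem sizes and determinism

Default study conditions: 50 Å cell, 1.6 Å resolution, 0.533 Å grid
(94³ ≈ 8×10⁵ voxels), 36 sites, 2% noise. One scene renders and quantifies
in well under a second, so Monte-Carlo checks use 40–100 seeded replicates.
A single integer seed fans out to all stages through a fixed SeedSequence
derivation; re-running a pipeline config reproduces truth tables
byte-identically.

## Known limitations

* The Gaussian peak model is also the basis of the response and cross-talk
  corrections; on real maps (form factors, series-termination ripple,
  correlated noise) those corrections are approximations.
* Belt sites assume full chalcogen complement (Se + S = 1) in mixed mode;
  partial vacancy biases p_Se low by construction and is only surfaced as a
  density deficit.
* The S-residual mixing formula is this package's explicit formalization of
  a correction described only qualitatively for the original tooling.
* P1 only; no symmetry-related clash handling; no headspace gas-law
  corrections in the kinetics beyond fixed unit conversions.
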