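# Methods

## Binding-pocket definition and descriptors

The pocket of a protein–ligand complex is the set of protein residues
having at least one heavy atom whose center lies within a cutoff
(default 5.0 Å) of any ligand heavy atom. Distances are center-to-center,
not surface-to-surface: this is the simplest reproducible reading of a
distance-defined pocket and makes membership monotone in the cutoff.
Ligand atoms are never pocket members. Hydrogens are kept in the data
model but excluded from all distance, hull and SASA computations by
default, because structure predictors differ in whether they emit
hydrogens and heavy-atom-only results are comparable across sources.
Alternate locations are collapsed to the highest-occupancy conformer
(ties → earlier altloc letter) at parse time, so all geometry downstream
is single-conformer and deterministic.

Per model, five scalars are computed:

* **Volume and surface area** — of the convex hull of pocket heavy-atom
  centers (`scipy.spatial.ConvexHull`). The hull is a deliberate choice
  where several constructions (alpha shapes, grid cavities) would do: it
  is deterministic, dependency-light, and adequate for ranking pockets of
  closely related mutants. Fewer than 4 atoms or a coplanar set raises a
  degenerate-geometry error rather than returning 0.
* **Hydropathy** — unweighted mean of the Kyte–Doolittle index over
  pocket residues; nonstandard residues are skipped with a warning (they
  still contribute to the geometric descriptors), and a pocket with no
  scorable residue is an error.
* **SASA** — Shrake–Rupley with probe 1.4 Å and a per-element van der
  Waals table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown
  elements fall back to 1.70 Å with a warning). Quadrature points come
  from a deterministic Fibonacci sphere (default 960 points/atom,
  minimum 92), so values are bit-reproducible — no RNG anywhere in the
  descriptor path. Occlusion is evaluated against *all* heavy atoms of
  the model (protein and ligand), so atoms outside the pocket bury
  pocket atoms as they do physically. Against a 20 000-direction Monte
  Carlo quadrature and an independent library implementation, the
  960-point default agrees to well within 2 % on random clusters.
* **Dipole magnitude** — |Σᵢ qᵢ (rᵢ − r̄)| over pocket heavy atoms, with
  r̄ the geometric center of the pocket heavy atoms. Because a pocket may
  carry net charge, the dipole is origin-dependent in general; the origin
  convention is therefore fixed and recorded in every output row.
  Magnitudes are reported in e·Å and Debye (1 e·Å = 4.8032 D). Two
  bundled charge schemes are selectable and always recorded: **formal**
  (Asp/Glu −1 at the carboxylate carbon, Lys +1 at NZ, Arg +1 at CZ, His
  neutral, termini ignored) and **partial_table** (a coarse bundled
  per-(residue, atom) table covering backbone and polar/charged side
  chains; unlisted atoms count 0 with a warning). The formal scheme is
  the default; neither claims force-field accuracy — they rank pockets
  by polarity.

## Lifetime correlation

Structure predictors emit several models per protein (10 by default in
the synthetic study). For each descriptor and each model index m, the
Spearman coefficient ρₘ is computed across proteins against the lifetime
table; the association is summarized as mean ± sample sd over the model
indices. A value like ρ = −0.52 ± 0.17 is to be read this way: spread
over replicate predictions, not a standard error.

Significance is assessed separately by a nonparametric bootstrap in which
**proteins are the resampling unit** — they are the exchangeable
observations; models are replicate predictions of the same protein, so
each replicate resamples proteins with replacement and draws one model
index per resampled protein uniformly. The 95 % percentile interval
(simplest defensible choice; BCa was considered unnecessary at these n)
of ≥1000 replicates is reported; "significant" means the CI excludes 0.
Degenerate replicates (constant vectors) are discarded and counted; more
than half degenerate raises. Descriptors are assessed one at a time with
no multiplicity correction, matching how per-descriptor significance
bars are usually read.

Spearman itself is rank-then-Pearson with average ranks for ties
(`scipy.stats.rankdata`); constant vectors and n < 3 are errors, not
NaNs. The bootstrap is fully vectorized (rank and Pearson along the
replicate axis), making the 100-trial type-I calibration in the test
suite cheap.

## Phasor analysis

The transform uses bin-center time stamps; with edges the first-harmonic
coordinates acquire an O(ωΔt) phase bias, with centers the residual bias
is O((ωΔt)²) — negligible at 256 bins over 25 ns (ωΔt ≈ 0.025). The
repetition period defaults to 25 ns (40 MHz) but is a required
configuration item for any real dataset, as is the harmonic (default 1,
sufficient to unmix three components).

No IRF deconvolution is attempted. For instrument data the supported
path is phasor calibration: divide (as complex numbers) by the measured
phasor of a reference of known lifetime and multiply by its ideal
on-semicircle phasor. The simulator can blur decays with a Gaussian IRF
so this path is testable end to end.

Unmixing solves the exact 3×3 barycentric system for three references
(or projects onto the reference segment for two). Shot noise pushes
pixels outside the reference triangle; such points are projected to the
nearest triangle point, the projection distance is recorded per pixel as
a residual, and fractions are then clipped/renormalized — a hard failure
on out-of-triangle pixels would shred real images. Collinear references
raise. Pixels whose (optionally k×k sliding-window binned) total count
falls below the intensity threshold (default 100 photons, below which
lifetimes are meaningless) are masked. Component images split the
*unbinned* pixel intensity by the recovered fractions, so summed
component images reproduce the masked total-intensity image exactly.

The monoexponential estimator for cuvette-style decays maximizes the
Poisson likelihood of binned counts under a period-wrapped exponential
plus a flat background fraction (bounded [0, 0.5]), optimized in
(log τ, b) with L-BFGS-B; the standard error of τ̂ comes from the
observed information (numerical second derivative at the optimum). The
wrapped model matters at short periods, where the previous cycle's tail
raises the "baseline" in a τ-dependent way a truncated model misfits.

## Synthetic data: what it emulates and what it does not

**Decays** are drawn from the wrapped (periodic) exponential mixture —
matching TCSPC physics where late photons fold into the next cycle —
binned over exactly one period, with optional Gaussian IRF blur and
exact total photon counts. Poisson pixel statistics are the only noise
model; no detector afterpulsing, dead time, dark counts or additive
camera noise.

**Scenes** (default 128×128, 256 bins, 25 ns) mimic a three-organelle
cell: a perinuclear ring at 5.9 ns, an elliptical nucleus at 5.5 ns and
scattered dots at 1.4 ns — the measured lifetimes of the dye bound to
two tag mutants in cells and of the unbound dye. Labeled regions default
to 10⁴ mean photons/pixel, the photon regime in which fraction recovery
to ±0.05 is attainable; overlapping regions mix by photon budget and the
generator returns exact per-pixel fraction maps as ground truth. Region
boundaries are hard masks — no optical blur, scattering or background
autofluorescence — so passing tests demonstrate the unmixing math and
photon-statistics behavior, not robustness to optical artifacts.

**Structure sets** place a fixed flat dye-like ligand at the origin and
a shell of residues built from idealized amino-acid heavy-atom templates
with side chains pointing inward, tips at 4 Å radius (every residue is
within the 5 Å pocket by construction). One Arg(+)/Asp(−) pair at an
angular separation θ solving 2·(4 Å)·sin(θ/2) = |μ| realizes any target
dipole in [0, 8] e·Å *exactly* and net-neutrally (targets outside the
feasible range raise; a zero target uses a centrosymmetric four-residue
arrangement). Per-model Gaussian coordinate jitter (default 0.15 Å)
emulates predictor variability. The default study is 12 proteins × 10
models with target dipoles on a deterministic grid over 0.5–7.5 e·Å and
lifetimes τ = 6.5 − 0.5·|μ| + ε ns, ε ~ N(0, 0.15 ns) — spanning
roughly 2.6–6.3 ns, the window the dye exhibits across environments,
with the dipole–lifetime anticorrelation built in. These pseudo-proteins
have realistic bond lengths but no fold, secondary structure or packing;
they validate the descriptor/correlation machinery, not structural
biology.

## Numerical choices and degenerate inputs

* Pocket membership at the exact cutoff distance is inclusive (≤); the
  KD-tree path is verified against an all-pairs scan in the tests.
* Empty pockets warn and propagate as errors only when a descriptor is
  actually requested.
* Phasor lifetimes require g > 0 (phase) and modulus ≤ 1 (+1e-9 slack
  for rounding); the modulation radicand is clamped at 0.
* The ML fit requires ≥1000 total counts and raises with optimizer
  diagnostics on non-convergence; on a noiseless binned expectation it
  recovers τ to 1e-6.
* All generators accept either a seed or a Generator; identical seeds
  give bit-identical outputs, including the degenerate case where a
  zero-fraction mixture component must consume no randomness.

## Problem sizes

The bundled tests and the acceptance script run at desk scale: 10⁶
photons per decay, 128×128×256 image stacks, and 12×10 structure sets
with 960-point SASA quadrature — sizes chosen so a full validation run
completes in about a minute on a laptop core while keeping shot-noise
tolerances (2 % on lifetime recovery, 5 % on per-pixel fractions)
comfortably resolvable.

## Known limitations

* The hull-based volume/area is one of several defensible pocket
  constructions; absolute values are not comparable across construction
  choices, only rankings within one choice.
* Both charge schemes are coarse; comparing dipole magnitudes against
  values computed with a different charge model requires recording the
  scheme (the output tables always do).
* Unmixing supports at most three components at one harmonic;
  multi-harmonic blind unmixing is out of scope.
* No vendor raw formats (.ptu/.sdt): decays come as CSV, images as
  multi-page TIFF.
* The correlation arm deliberately stops at association (ρ, CI); it does
  not fit predictive lifetime models.
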