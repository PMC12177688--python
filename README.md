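# pocketflim

Analysis toolkit for environment-sensitive fluorophores bound to
self-labeling protein tags (HaloTag-style chemigenetic probes), built
around two questions:

1. **What about the protein pocket sets the dye's fluorescence
   lifetime?** Given predicted protein–ligand complexes (PDB/mmCIF,
   several models per protein), the package extracts the binding pocket —
   all amino acids with a heavy atom within 5 Å of the dye — and computes
   five descriptors per model: convex-hull **volume** and **surface
   area**, mean **Kyte–Doolittle hydropathy**, Shrake–Rupley
   **solvent-accessible surface area**, and the magnitude of the pocket
   **dipole moment** |Σᵢ qᵢ (rᵢ − r̄)| (e·Å). Each descriptor is
   correlated with measured lifetimes by Spearman's ρ, once per model
   index (reported as mean ± sd over models), with significance from a
   protein-level bootstrap 95 % percentile CI.

2. **Can species with different lifetimes be separated in images?**
   TCSPC decays and time-resolved image stacks are mapped to phasor
   coordinates g = Σcₖcos(ωtₖ)/Σcₖ, s = Σcₖsin(ωtₖ)/Σcₖ at
   ω = 2π·harmonic/T. Monoexponentials lie on the universal semicircle at
   g = 1/(1+ω²τ²), s = ωτ/(1+ω²τ²); mixtures combine linearly, so pixels
   containing up to three lifetime species are unmixed by solving
   [g; s; 1] = M·f for barycentric fractions. Phase/modulation lifetimes
   and a Poisson maximum-likelihood monoexponential fit (wrapped tail +
   flat background) are provided as estimators.

A first-class synthetic-data module generates every input with known
ground truth — wrapped-exponential photon decays, three-organelle FLIM
scenes, and pseudo-protein pocket sets with an exactly realized target
dipole and a built-in dipole→lifetime anticorrelation — so the whole
pipeline is testable offline.

Intended users: groups engineering lifetime-multiplexed probes who want
to rank tag mutants by pocket polarity, and FLIM users who want a small,
transparent phasor-unmixing implementation with simulators for method
validation.

## Worked example

`python examples/phasor_basics.py` — a 5.9 ns monoexponential decay with
10⁶ photons at a 25 ns repetition period:

```
true lifetime        : 5.900 ns
phasor (g, s)        : (0.3126, 0.4644)
phase lifetime       : 5.910 ns
modulation lifetime  : 5.890 ns
ML fit               : 5.893 +/- 0.007 ns
```

The phasor sits on the universal semicircle and all three estimators
agree with the generating lifetime to within shot noise (≈0.2 %). A phase
lifetime below the modulation lifetime would instead indicate a mixture.

`python examples/lifetime_correlation.py` — 12 synthetic proteins × 10
models whose lifetimes decrease with pocket dipole:

```
descriptor  rho_mean  rho_sd  ci_lo  ci_hi  significant
 volume_A3     0.357   0.053 -0.306  0.780        False
   area_A2     0.281   0.096 -0.379  0.765        False
hydropathy    -0.099   0.000 -0.684  0.564        False
   sasa_A2     0.065   0.093 -0.577  0.690        False
 dipole_eA    -0.992   0.002 -0.996 -0.887         True
```

Only the dipole is flagged significant (CI excluding 0) and negative —
the relation the generator builds in — while descriptors unrelated to
lifetime are correctly called n.s. The other examples cover pocket
descriptors on a single complex (`pocket_descriptors.py`) and
three-component image unmixing (`flim_unmixing.py`).

## Command line

A thin CLI wraps the same functions:

```sh
pocketflim simulate structures --n-proteins 12 --seed 1 --out synth/
pocketflim pocket correlate synth/SYN*.pdb --lifetimes synth/lifetimes.csv --out run/
pocketflim simulate decay --tau 5.9 --photons 1000000 --out decay.csv
pocketflim flim phasor decay.csv --period-ns 25 --fit
pocketflim flim unmix --stack scene.tif --ref-lifetime 5.9 --ref-lifetime 5.5 \
    --ref-lifetime 1.4 --out unmixed/
```

Every run writes its fully resolved config, seed and package version into
the output directory, so outputs are exactly regenerable.

## Layout

- `src/pocketflim/structure_io.py` — PDB/mmCIF reading/writing (gemmi),
  uniform atomic model, ligand selection
- `src/pocketflim/pocket.py` — pocket extraction + the five descriptors
- `src/pocketflim/lifetime_stats.py` — Spearman, per-model correlation,
  protein-level bootstrap
- `src/pocketflim/phasor.py` — phasor transform, lifetimes, calibration,
  2/3-component unmixing, Poisson ML fit
- `src/pocketflim/synthetic.py` — decay/scene/structure-set generators
- `src/pocketflim/pipeline.py`, `cli.py` — end-to-end runs + CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
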