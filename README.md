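# lcdphase

Coarse-grained phase-separation simulations and condensate analysis for
TDP-43 low-complexity-domain (LCD) phosphovariants.

TDP-43, the protein that aggregates in ALS and frontotemporal dementia, is
hyperphosphorylated on C-terminal serines of its LCD (residues 261–414) in
disease. `lcdphase` is a toolkit for asking, in silico and in quantitative
image/blot analysis, what those phosphogroups do to condensation:

* **Sequence/variant machinery** — the canonical 414-aa human TDP-43
  (UniProt Q13148) bundled as a fixture; phosphomimetic (S→D), control
  (S→A) and phosphoserine (S→pS) variants at the disease sites
  (2 = {S409, S410}, 5 = +{S379, S403, S404}, 12 = +{S373, S375, S387,
  S389, S393, S395, S407}); Henderson–Hasselbalch net charge with
  phosphoserine at −2.
* **A residue-level (HPS) force field** — hydrophobicity-scaled
  Ashbaugh–Hatch van der Waals term
  (Φ = LJ + (1−λᵢⱼ)ε for r ≤ 2^{1/6}σᵢⱼ, else λᵢⱼ·LJ), Debye–Hückel
  electrostatics Φ = qᵢqⱼe²·exp(−r/κ⁻¹)/(4πε₀Dr), harmonic bonds.
* **A Langevin slab simulator** — BAOAB integration, periodic boxes,
  neighbor lists, and the slab-coexistence protocol (compact equilibration →
  box extension along z → constant-volume production).
* **Phase analysis** — centered z-density profiles, dense/dilute coexistence
  concentrations, ΔG_trans = −RT·ln(c_dense/c_dilute), condensate detection,
  variant ranking by saturation concentration.
* **Contact & solvation analysis** — residue contact maps (fixed 4.5 Å or
  2^{1/6}σᵢⱼ rules, i±2 intra-chain exclusion), difference maps,
  type-resolved contact profiles, water-coordination histograms.
* **Wet-lab quantification formulas** — sedimentation S/(S+C) ratios, FRAP
  normalization I(t) = (ROI1−ROI3)/(ROI2−ROI3) with prebleach scaling and
  AUC, droplet segmentation with roundness = 4·area/(π·major_axis²) and the
  circularity ≥ 0.3 / area ≥ 3 px filters.
* **Seeded synthetic fixtures** for every analysis operator, each carrying
  its planted ground truth in a manifest.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from lcdphase import (
    net_charge, canonical_tdp43, build_variant, canonical_variant_spec,
    tdp43_lcd, make_forcefield, initialize_compact, run_langevin,
    slab_schedule, density_profile, compute_phase_metrics,
)

# 1. Net charges at pH 7.4 (elementary charges)
wt = canonical_tdp43()
for name in ("Wt", "12D", "12pS"):
    q = net_charge(build_variant(wt, canonical_variant_spec(name)))
    print(f"{name:>4}: {q:+.1f}")
```

prints

```
  Wt: -4.1
 12D: -16.1
12pS: -28.1
```

— the wild-type protein is mildly acidic; each phosphomimetic aspartate adds
one negative charge and each phosphoserine two, so full 12-site
phosphorylation quadruples the net negative charge, the electrostatic origin
of its weakened condensation.

```python
# 2. A reduced-scale slab run of the wild-type LCD (~2 min on one core)
ff = make_forcefield(cutoff_vdw=25.0, cutoff_elec=25.0)
seq = tdp43_lcd("Wt")                      # LCD aa. 261-414, 154 residues
cfg = initialize_compact(6, seq, ff, (90.0, 90.0, 90.0), seed=1)
params, schedule = slab_schedule(
    {"n_chains": 6, "box": (90.0, 90.0, 600.0), "sub_lz": 90.0,
     "equilibration_steps": 10_000, "production_steps": 30_000},
    seed=1, stride=5_000,
)
traj = run_langevin(cfg, ff, schedule)
masses = ff.params_for(traj.bead_codes)[0]
profile = density_profile(traj, masses, n_bins=60, discard_fraction=0.5)
m = compute_phase_metrics(profile, name="Wt", dense_halfwidth=40.0,
                          dilute_margin=150.0)
print(f"c_dense = {m.c_dense:.0f} mg/mL, condensate: {m.has_condensate}")
```

prints (numbers vary slightly with seed)

```
c_dense = 198 mg/mL, condensate: True
```

— the 154-residue LCD chains condense spontaneously into a dense slab of a
few hundred mg/mL coexisting with an essentially empty dilute phase, the
hallmark of liquid–liquid phase separation in this model. Comparing
variants (`"12A"`, `"12D"`, `"12pS"`) probes how phosphomimetic and
phospho charges shift this balance; see `docs/methods.md` for what the
reduced-scale runs do and do not resolve.

A CLI mirrors the library:

```bash
lcdphase build-variant 12D -o 12D.fasta
lcdphase simulate Wt --preset desk --seed 1 -o wt.npz
lcdphase analyze-phase wt.npz --plot profile.png
lcdphase quant-frap trace.csv --bleach-index 5
lcdphase quant-droplets image.tif -o droplets.csv
```

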