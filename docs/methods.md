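# Methods

`lcdphase` models how C-terminal phosphorylation and phosphomimetic
substitution weaken condensation of the TDP-43 low-complexity domain (LCD,
residues 261–414 of the 414-residue human protein). This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic fixtures do and do not demonstrate.

## Sequences, variants and net charge

The canonical human TDP-43 sequence (UniProt Q13148) is bundled as a FASTA
fixture. Variants substitute serines at the disease phosphosites, in
full-length numbering:

* 2 sites: S409, S410
* 5 sites: S379, S403, S404, S409, S410
* 12 sites: S373, S375, S379, S387, S389, S393, S395, S403, S404, S407,
  S409, S410

S→D ("2D"/"5D"/"12D") mimics the phospho-charge with aspartate (−1), S→A
("2A"/"5A"/"12A") removes the hydroxyl as a control, and S→pS ("5pS"/"12pS")
installs phosphoserine (charge −2).

Net charge uses Henderson–Hasselbalch fractional charges: acids contribute
−1/(1+10^(pKa−pH)), bases +1/(1+10^(pH−pKa)), plus the two termini.
"Physiological pH" is taken as 7.4. The default pKa set is the Putnam
"Protein Calculator v3.4" set (D 4.40, E 4.40, H 6.50, C 8.50, Y 10.00,
K 10.00, R 12.00, N-term 8.00, C-term 3.10). This choice is pinned by the
worked values the package reproduces (Wt −4.1, 12D −16.1, 12pS −28.1 at one
decimal); a common textbook set (shipped as `pka_textbook.csv`) yields −4.5
for the wild type and was therefore not adopted as the default.
Phosphoserine contributes exactly −2 in the default `FIXED_MINUS_2` mode —
the convention implied by the −4.1 → −28.1 arithmetic; a `HENDERSON` mode
(phosphate −1 with a second ionization, pKa2 = 5.96) is available. Whether
termini should be included is not settled by the worked values; they are
included by default and can be switched off.

Note one arithmetic consequence of the Putnam set: aspartate's fractional
charge at pH 7.4 is −0.999, so the 12D−Wt difference is −11.988 rather than
−12 exactly, while 12pS−Wt is −24 exactly by construction.

## The energy model

One bead per residue. Three terms, in package units (kJ/mol, Å, Da, ps):

* **Hydrophobicity-scaled van der Waals (Ashbaugh–Hatch).** With
  σᵢⱼ = (σᵢ+σⱼ)/2 and λᵢⱼ = (λᵢ+λⱼ)/2:
  Φ(r) = LJ(r) + (1−λᵢⱼ)ε for r ≤ 2^{1/6}σᵢⱼ, else λᵢⱼ·LJ(r), where
  LJ is the 12-6 potential of depth ε. Both branches equal −λᵢⱼ·ε at the
  switch, so Φ is continuous; λ = 0 retains the bare repulsive core.
* **Debye–Hückel electrostatics.** Φ = qᵢqⱼ e²/(4πε₀ D r) · exp(−r/κ⁻¹)
  with integer bead charges (D/E −1, K/R +1, H 0, phosphoserine −2).
  The screening length κ⁻¹ follows from temperature and ionic strength
  (≈9.9 Å at 310 K, 100 mM, D = 80).
* **Harmonic bonds.** ½k(r−r₀)² between consecutive residues.

Defaults: ε = 0.2 kcal/mol (0.8368 kJ/mol), k = 10 kJ/(mol·Å²), r₀ = 3.8 Å,
dielectric 80, ionic strength 100 mM, vdW cutoff 25 Å, electrostatic cutoff
35 Å. Nonbonded terms are truncated and shifted to zero at the cutoff during
dynamics (the scalar pair functions report the unshifted form by default so
the switch-point identity −λᵢⱼ·ε holds exactly). Bonded (i, i+1) pairs are
excluded from the nonbonded sum.

The per-residue parameters (mass, charge, σ, λ) for the 20 canonical
residues are the established hydrophobicity-scale (HPS) set. The
phosphoserine row combines the chemically fixed entries (charge −2, mass
167.06 Da = Ser + HPO₃) with package-chosen σ = 6.00 Å (serine core enlarged
by the phosphate) and λ = 0.14 (strongly hydrophilic, below aspartate's
0.378). The qualitative behavior of the 12pS variant is dominated by the −2
charge, not by the precise σ/λ values.

Correctness is defined by equality: the neighbor-list path must agree with
an all-pairs evaluation, and analytic forces with central differences of the
energy.

## Langevin dynamics and the slab protocol

BAOAB-split Langevin integration, timestep 10 fs, friction 0.01 ps⁻¹,
velocities from Maxwell–Boltzmann at the target temperature, a counter-based
(Philox) random stream seeded per run, periodic orthorhombic boxes with
minimum-image conventions, and a Verlet-skin (3 Å) neighbor list rebuilt on
a displacement trigger (cell list where the box admits ≥3 cells per
dimension, exact O(N²) scan otherwise — the two are defined to produce the
same pair set).

Slab protocol: chains are grown as self-avoiding walks (bond length r₀,
non-bonded separation ≥ 0.8·min σ) inside a compact sub-box, equilibrated,
then the box is extended along z and production runs at constant volume so
the dense slab coexists with its dilute phase. Box extension first makes
every chain whole across the old periodic boundary and then recenters the
condensate at the new midplane, so no bond is ever cut by the box change.

Two numerical guards keep the start of a run honest rather than explosive:
initial-overlap cores are relaxed during a short soft start (default 2000
steps) with per-bead force norms capped at 1000 kJ/mol/Å and a strong
thermostat (5 ps⁻¹) that drains the overlap heat; forces beyond 10⁶
kJ/mol/Å at any point raise a diagnostic error carrying the offending
configuration. With friction 0 and the soft start disabled the integrator
reduces to velocity Verlet and conserves energy (NVE check mode).

Presets: `desk` (50 chains × 154 residues, 160 × 160 × 1200 Å, 5×10⁵
equilibration + 2×10⁶ production steps) is the reduced-scale configuration
for a workstation; `paper` (100 chains, 212 × 212 × 2800 Å, ≥5.8 µs) is the
full-scale protocol and is cluster-scale — it is provided as configuration
only. Tests and the acceptance script use further-reduced systems (6–8
chains, 90–100 Å cross-section, 10⁴–10⁵ production steps, 25 Å cutoffs)
chosen so each run completes in minutes while the condensate observables
remain resolvable; these sizes are stated where used.

## Phase analysis

Per-frame z-density profiles are centered by locating the densest 100 Å
sliding window under the periodic wrap (coarse) and refining with the
mass-weighted mean displacement (exact, translation-equivariant), then
averaged; concentrations are in mg/mL (1 Da/Å³ = 1660.54 mg/mL), and the
profile integral reproduces the total bead mass — a conservation identity
the tests assert. c_dense is the mean over |z − L_z/2| ≤ 50 Å, c_dilute the
mean over |z − L_z/2| ≥ 250 Å (window sizes configurable; reduced boxes use
proportionally smaller windows). ΔG_trans = −RT ln(c_dense/c_dilute) with
R = 8.314 J/(mol·K). A condensate is declared when the peak bin is at least
10× the dilute mean (an all-zero dilute region with a nonzero peak counts as
condensed). Variant ranking sorts by ascending c_dilute — lower saturation
concentration means stronger condensation — with dissolved variants last and
ties (default 15% relative, a design parameter) reported as tiers rather
than silently broken. The first half of production is discarded as
equilibration by default.

## Contacts and solvation

Two contact rules: a fixed 4.5 Å cutoff (the rule used for explicit-solvent,
Martini-style condensate trajectories; this package analyzes such
trajectories but does not generate them) and the HPS rule
r < 2^{1/6}σᵢⱼ. Contacts are strict inequalities. Intra-chain pairs within
±2 residues are excluded (exclusion configurable) and flagged absent, not
zero; the diagonal remains meaningful for inter-chain contacts (residue i of
one chain touching residue i of another). Inter-chain probabilities count
each unordered chain pair per frame as one opportunity; intra-chain tallies
are kept separately and also exposed as a combined per-opportunity map,
because published condensate maps mix both. Difference maps are entrywise
and antisymmetric by construction. Type-resolved profiles tally contacts
from a residue selection by partner amino-acid type and normalize to 1
(an all-zero tally returns an explicitly flagged empty profile). Solvation
histograms count solvent particles within 5 Å (default) of selected
residues, per residue per frame.

## Wet-lab quantification formulas

* Sedimentation: S/(S+C) from supernatant and pellet band intensities
  (identical form for RIPA-soluble/insoluble fractions).
* FRAP: I(t) = (ROI1−ROI3)/(ROI2−ROI3), normalized to the mean of a
  configurable prebleach window (default 1 frame), making the prebleach
  level exactly 1; AUC by trapezoidal integration with interpolated
  endpoints.
* Droplets: difference-of-Gaussians bandpass (σ_small = 1 px, σ_large = 20
  px default — the named bandpass scale without a published kernel, so only
  scale-level properties are asserted), Otsu threshold (published thresholds
  were manual), connected components, then per-droplet area, major axis,
  roundness = 4·area/(π·major²) (the inverse aspect ratio; 1 for a circle,
  b/a for an ellipse) and circularity = 4π·area/perimeter². Both measures
  are computed because the filters need circularity (≥ 0.3) while the
  reported shape statistic is roundness; rows with area < 3 px are dropped.

## Synthetic fixtures

Every generator is a pure function of (parameters, seed) and serializes its
planted ground truth in a manifest; tests recover the truth through the
corresponding analysis operator rather than recomputing it.

* `make_tanh_slab` draws bead positions from a planted tanh coexistence
  profile by inverse-CDF sampling in z (uniform in x/y); the per-frame bead
  count is the profile mass over an abstract per-bead mass quantum, chosen
  small enough (with enough frames) that Poisson noise sits well inside the
  stated recovery tolerances. It validates the profile/coexistence
  machinery, not polymer physics: beads are unbonded sampling quanta.
* `make_planted_contact_traj` lays residues on a sparse grid (30 Å spacing)
  and moves listed chain-1 residues next to chain-0 partners at exact
  distances; the geometry is deliberately not bond-consistent (analysis
  fixture only, constructed with validation off).
* `make_solvated_frame` places exact water counts within the cutoff of each
  (well-separated) residue plus far-away distractors; rejection sampling is
  bounded and raises rather than degrading the planted counts.
* `make_frap_trace` builds ROI series whose normalized recovery is
  plateau·(1−exp(−rate·t)) plus optional Gaussian noise.
* `make_droplet_image` renders supersampled (4×) anti-aliased ellipses;
  expected roundness is semi-minor/semi-major.
* `make_random_lcd` draws sequences from a residue composition
  (multinomial, or exact counts via largest-remainder rounding).

Passing on these fixtures shows the operators invert their own generative
models exactly or within stated tolerances; it does not show that the
coarse-grained model reproduces any particular experimental number — the
model's claim is directional (which variants condense, and how the dilute
phase orders), not quantitative coexistence densities.

## Reduced-scale phase behavior: what is and is not claimed

The reduced systems run by the tests and the acceptance script (6–8 chains,
~10⁴–10⁵ steps ≈ 0.5–1 ns, 25 Å cutoffs) resolve the robust end of the
variant spectrum: 12A and Wt hold a clear density peak coexisting with an
essentially empty dilute phase, and the dilute-phase ordering
12A ≤ Wt ≤ 12D holds as ties at the few-chain scale, where c_dilute is
quantized at roughly one chain per dilute volume. Ties at 0 mg/mL are
expected and reported as ties.

Dissolution of the fully phosphorylated 12pS variant is *not* resolved at
this scale, and the package reports that honestly. Direct energy accounting
under the default parameterization (standard HPS residue set, ε = 0.2
kcal/mol, 100 mM screening, phosphoserine charge −2) gives a per-chain
condensate binding energy near −35 kT for 12pS — cohesion is van der
Waals-dominated, and the screened electrostatic penalty of the 24 phospho
charges amounts to only about +12 kT per chain — so 12pS remains condensed
over the nanoseconds accessible here, from condensed and from dispersed
starts alike. Discriminating 12pS from Wt in this family of models is a
microsecond, 50–100-chain computation (the `desk` and `paper` presets exist
for exactly that), and is additionally sensitive to the precise
phosphoserine σ/λ values, for which this package ships documented estimates
rather than a transcription of a published table. No quantitative
coexistence concentration is claimed at reduced scale.

## Known limitations

* Implicit solvent, integer charges, no pH coupling during dynamics: the
  net-charge calculator's fractional (Henderson–Hasselbalch) charges are a
  reporting concern only and deliberately not used by the force field.
* The phosphoserine σ/λ entries are package estimates (see above), not a
  transcription of a published table; the charge −2 is the load-bearing
  parameter.
* The Martini-style 4.5 Å contact rule is provided for analyzing externally
  produced explicit-solvent trajectories; the package does not simulate
  explicit solvent, so solvation analyses run on fixtures or imported
  frames.
* Slab coexistence at few-chain scale is subject to strong finite-size
  effects; interfacial fluctuations bias c_dilute upward and its
  quantization makes small differences between strongly condensing variants
  (12A vs Wt) unresolvable. The ranking machinery therefore reports ties
  explicitly.
* Single-platform determinism is guaranteed (seeded Philox streams,
  fixed-order reductions); bitwise identity across different CPU
  architectures is not.
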