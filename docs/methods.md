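# Methods

## The ternary-equilibrium model

A protein–protein interaction (PPI) stabilizer ("molecular glue") S
binds a receptor protein R and a ligand protein L, forming binary
complexes R·S and L·S and the ternary complex R·L·S:

    R + S  ⇌ RS     K_RS
    L + S  ⇌ LS     K_LS
    RS + L ⇌ RLS    K_LS/φ
    LS + R ⇌ RLS    K_RS/φ

`K_RS` and `K_LS` are dissociation constants (molar); the dimensionless
cooperativity factor φ multiplies the ternary association constant and
is applied identically on both association routes so the thermodynamic
cycle closes (detailed balance). Free energies convert to constants via
`K_D = exp(ΔΔG/RT)` with `R = 1.9872×10⁻³ kcal/(mol·K)`.

**Exact solver.** With the free stabilizer `[S_f]` fixed, receptor and
ligand conservation reduce to one quadratic whose positive root is
evaluated in a cancellation-free form; stabilizer conservation then
becomes a single monotone equation in `[S_f]`, bracketed on `[0, S_0]`
and solved with Brent's method (relative tolerance near machine
precision) plus one Newton polish. This yields guaranteed convergence
to the unique physical root; every returned state reconstructs the
totals to better than 10⁻⁶ relative (asserted internally) and 10⁻⁸ in
the test suite.

**Dilute closed form.** When the totals are negligible against the
binding scales,

    [RLS] = φ [R₀][L₀][S_f] / ((K_RS + [S_f])(K_LS + [S_f]))

which is unimodal in `[S_f]` (the hook effect: excess stabilizer
saturates the binary complexes), peaks at `[S_f] = √(K_RS·K_LS)`, and
gives the effective dissociation constant at the optimal dose

    K_RL,eff = [R₀][L₀]/[RLS_opt] = (√K_RS + √K_LS)²/φ.

The closed form was validated against an independent brute-force
mass-action oracle (dense log-grid scan in `[S_f]` with damped
fixed-point conservation, bisection polish); exact and closed-form
`[RLS]` agree to ≤0.1% in the dilute regime.

**What "dilute" means here.** The depletion correction scales with the
totals relative to *every* dissociation scale, including the
ternary-step constant `K/φ`. The package therefore defines the dilute
regime as `R₀, L₀ ≤ min(K_RS, K_LS)/(10³·max(1, φ))`; at φ = 10 and
totals of `min(K)/10³` the residual correction is genuinely at the
2×10⁻³ level and the 0.1% agreement would not hold.

**Optimal dose.** `[RLS]` is maximized over log-total-dose with a
bounded scalar search spanning ±30 natural-log units around
`√(K_RS·K_LS) + (R₀+L₀)/2`, wide enough to cover strong-depletion
regimes. A flat objective (degenerate constants) returns the left-most
maximizer with a warning flag.

**The −5 kcal/mol dual-binding threshold.** Scanning symmetric
per-partner energies at `[R₀] = [L₀] = 1 μM`, φ = 1, T = 298.15 K in
0.5 kcal/mol steps, −5 kcal/mol is the least-negative value whose
optimal-dose K_RL,eff crosses the millimolar/micromolar divide
(4·K_D(−5) ≈ 0.87 mM ≤ 1 mM, while 4·K_D(−4.5) ≈ 2.0 mM). The boundary
is a parameter (default 10⁻³ M) since the divide is a convention, and
the temperature of the thermodynamic model defaults to the 298.15 K
standard state (simulation-derived energies are typically produced at
310 K, but the standard-state convention is what the threshold
calibration uses); both are exposed.

Numerical range: constants derived from |ΔΔG| up to ~40 kcal/mol remain
finite in double precision because the dose search is centred on
`√(K_RS·K_LS)`; `K_RL,eff` is reported as `+inf` if `[RLS_opt]`
underflows.

## Energy-table aggregation and dual-binding scoring

Interaction free energies come from end-point (MM/GBSA-style)
post-processing of MD replicas, typically 5 independent replicas × 75
frames. Aggregation follows the replica convention: per-replica means
first; the reported mean is the mean of replica means, the reported
spread the sample (ddof = 1) standard deviation across replica means.
The balance term `|ΔΔG_RS − ΔΔG_LS|` is computed per frame and
aggregated the same way; this per-frame convention makes the balance
mean ≥ the difference of the printed means (Jensen), which is why
aggregated tables also expose `mean_gap = |mean − mean|` so either
convention can be inspected. A single replica reports sd 0 with a
flag. The total `ΔΔG_(RL)S` is an independent input column, never
recomputed as the sum of the per-partner terms (end-point totals are
not additive in that way).

Classification: a compound is *dual-binding* when its weaker-side
interaction `max(ΔΔG_RS, ΔΔG_LS)` is ≤ −5 kcal/mol (the equilibrium
threshold above); otherwise it is an *allosteric candidate* — possibly
still a stabilizer, via conformational pre-organization of one partner,
which only long stabilizer-free simulations can confirm and which this
package does not attempt. The boundary comparison is inclusive (≤) for
classification and strict (<) for the candidate-selection window
(weaker side < −15 kcal/mol, balance < 10 kcal/mol), matching the
"lower than / smaller than" reading of the window; both are
configurable.

On the curated 18-complex benchmark (`dualbind.benchmark`), this rule
flags exactly four allosteric candidates (A1-b/3m51, B2/2o98, B4/4mdk,
B5/1kkq) — compounds that bury little or no surface against the ligand
protein yet stabilize the pair.

## Geometry

* **Contacts.** An atom and a pocket probe are in contact when their
  distance is strictly below the sum of their radii. Radii: H 1.2,
  C 1.7, N 1.55, O 1.52, F 1.47, B 1.92, P 1.8, S 1.8 Å. Chlorine uses
  1.75 Å by default; a 0.2 Å legacy value — physically implausible, it
  would suppress every Cl contact — is available behind
  `literal_chlorine` only for strict reproduction of older counts.
  Unknown elements fall back to a configurable default with a warning.
* **Interface residues.** A residue is interfacial when any of its
  atoms is within 5 Å (inclusive) of any partner atom; evaluated with a
  KD-tree but identical to the all-pairs double loop (property-tested).
* **SASA.** Shrake–Rupley point counting with a deterministic Fibonacci
  sphere lattice (default 960 points/atom, probe 1.4 Å), so results are
  bit-stable; hydrogens are excluded by default (conventional SASA)
  though they participate in contact computations. Accuracy: ≤2% vs the
  analytic single-sphere area at 960 points; ≤1% vs a 10⁴-point
  evaluation for overlapping pairs.
* **BSA.** `BSA_RS = (SASA(R) + SASA(S) − SASA(R∪S))/2`, components in
  isolation; the ratio `BSA_LS/BSA_RS` is a quick geometric gauge of
  dual binding (≈1 balanced, ≈0 receptor-only, undefined when the
  stabilizer does not touch the receptor).
* **Superposition / iRMSD.** Kabsch SVD with the determinant fix
  (proper rotations only); degenerate (collinear) point sets are
  rejected. Interface RMSD superposes the selected interface atoms
  (heavy-atom default; backbone selection available) onto the reference
  and reports the post-fit RMSD, with an optional sliding-window mean
  whose width in frames the caller derives from the trajectory spacing
  (e.g. 2 ns worth of frames).

## Pockets

Pockets are consumed from cavity-detection output: probe spheres
(polar/apolar) in a documented PQR-style dialect, with externally
supplied pocket/drug scores in a sidecar TSV. Nothing re-detects or
re-scores cavities, and pocket volumes are an input series. One contact
rule is used everywhere (atoms vs probes, strictly-below radius sum):
the *interface-pocket* criterion requires at least m distinct atoms
from each protein side in probe contact (m ∈ {5, 10, 20} by default);
the *ligand coverage fraction* is the fraction of stabilizer atoms
(hydrogens included when present) touching ≥1 probe, each atom counted
once; the *accommodation fraction* of a volume series is the fraction
of frames with pocket volume ≥ the stabilizer's molecular volume.

## Discovery pipeline

Stages: pocket intake and ranking → property pre-filter (molecular
weight 375–425 Da, LogP 2–4.5, complexity ≤ 700 — the window typical of
known interface stabilizers; compounds above the complexity bound are
hard to parameterize for simulation) → optional uniform sub-sampling →
docking through an adapter (external command template, or a score
table; per-compound failure isolation; resumable via a provenance
ledger) → score cut (keep ≤ −6 kcal/mol, "better" meaning more
negative) → dual-binding evaluation of the survivors. Filter criteria
apply in the declared order weight → LogP → complexity, which affects
only audit attribution. One master seed feeds all randomized stages
through per-stage seeds derived by stage-name hash (kept below 2³¹);
identical config + seed reproduces every artifact.

## Synthetic fixtures: what they do and do not show

The fixture generators produce schematic inputs with planted ground
truth: lattice "proteins" whose interface membership is unambiguous by
construction, probe sets that touch exactly the planted atoms, Gaussian
frame energies around planted means (with realized per-replica means
recorded in the manifest, so aggregation is checked against realized
values), and compound rosters with exact planted pass counts. Every
generator re-verifies its plant by brute force before writing, and all
fixtures are byte-stable under a fixed seed.

The candidate-selection check uses a synthetic 50-compound roster with
34 planted dual binders — margins placed an order of magnitude above
the frame noise so the plant cannot flip — standing in for a docked
screening shortlist of that size and composition.

These fixtures exercise *contracts*, not physics: passing tests show
the equilibrium algebra, counting rules, aggregation conventions and
pipeline plumbing are correct, but say nothing about force-field
accuracy, real pocket geometry, conformational flexibility or the
predictive power of docking scores — all of which live in the external
tools this package orchestrates.

## Problem sizes and defaults used in the shipped checks

Solver validation uses 100 random parameter sets (K log-uniform over
10⁻⁹–10⁻¹ M, totals 10⁻⁸–10⁻³ M, φ ∈ {0.1, 1, 10}) against a
3000-point oracle grid; the geometry brute-force comparisons use 10³
random contact pairs and ~10²-atom fixtures; the pipeline check runs a
200-compound roster. These sizes make the full suite run in seconds
while leaving every code path exercised.

## Known limitations

* One stabilizer species per system; no binding kinetics; no fitting of
  K or φ to dose–response data.
* The equilibrium model assumes well-mixed dilute solution mass action;
  activity coefficients and crowding are ignored.
* SASA uses a single radii table (the contact table) rather than a
  force-field-specific set; absolute areas therefore differ slightly
  from other implementations, though BSA differences largely cancel.
* PDB parsing covers standard fixed-width records (multi-model
  supported); no mmCIF, no trajectory formats.
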