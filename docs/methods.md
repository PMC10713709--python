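# Methods

`conjscan` models and book-keeps the chemoselective conjugation of
[Cp*Rh(H₂O)₃]²⁺ with aromatic amino-acid side-chain mimetics — p-cresol
(`pC`, a tyrosine mimic), 3-methylindole (`3MI`, tryptophan) and toluene
(`T`, phenylalanine). The reaction of interest is the ligand exchange

    EC  =  [Cp*Rh(H₂O)₃]²⁺ · X   ⟶   PA  =  [Cp*Rh(η⁶-X)]²⁺ + 3 H₂O

from the non-covalent encounter complex (EC) to the η⁶ product adduct
(PA). The package has three layers: a coarse-grained biased-dynamics
simulator that reproduces the *statistical shape* of such trajectories, a
coordination/hapticity analyzer, and the fragment pair-interaction-energy
(PIE) and thermochemistry bookkeeping that turns per-frame energies into
selectivity statements. Units are fixed throughout: Å, ps, kcal/mol, K.

## Toy exchange simulator (`toy_exchange_sim`)

The simulator is deliberately minimal: a Rh site capped by a single Cp*
pseudo-site (lumped mass 135.2 amu), three explicit waters (O + 2 H),
and one rigid-ish aromatic ligand built from ring sites (6 carbons for the
arene; a fused 6+5 ring system with a pyrrolic N for the indole; a
phenolic O–H for p-cresol). It is *not* a quantitative surrogate for the
electronic-structure potential it stands in for; its role is to generate
trajectories whose coordination statistics exercise every downstream
analysis.

Interactions (all smooth, all with analytic forces, verified against
finite differences to 1e-8):

* **Bonded terms.** Harmonic springs hold each water together and tie Cp*
  to Rh; a full pairwise distance network over the ligand keeps it nearly
  rigid without rigid-body dynamics (neighbor bonds 400, braces 120, long
  braces 40 kcal/mol/Å²).
* **Rh–water wells.** Morse wells, depth 16 kcal/mol, width 2.6 Å⁻¹,
  minimum 2.10 Å — deep enough that a 50-ps thermal run never carries a
  water past the 2.5 Å "bound" threshold, shallow enough that the
  metadynamics bias empties them within tens of ps.
* **Rh–arene attraction, capacity-gated.** Each ring atom feels a Morse
  attraction to Rh (5 kcal/mol per site) multiplied by a smooth gate
  σ((occ₀ − occ_w)/w) on the *water occupancy* of the metal: with three
  waters bound the arene is effectively shut out; each departure opens
  roughly another third of the full strength. Symmetrically, the water
  wells are throttled by the ring-contact occupancy down to a 5 % floor,
  so an η⁶ arene blocks re-aquation without forbidding the occasional
  re-binding event. These gates are this model's expression of the metal's
  finite coordination capacity (Cp* + 6 further electrons' worth of
  ligands); their cross-derivatives are included in the forces, so the
  potential remains strictly conservative.
* **Heteroatom anchor.** The phenolic O (and pyrrolic N) carries its own
  longer-ranged Morse attraction to Rh (6 kcal/mol, 1.6 Å⁻¹), throttled
  while the aquo shell is complete. Because it is longer-ranged than the
  ring attraction and opens at a laxer gate, the O–Rh contact typically
  forms *before* the first η² ring contact — the designed analogue of the
  OH group anticipating the first water replacement.
* **Hydrogen bonds.** A Morse term between ligand donor-H (phenol OH,
  indole NH) and water oxygens, and between water H and the phenolic O
  (which is donor *and* acceptor; the NH is donor-only). Water–water
  hydrogen bonding carries no potential term: early versions included it
  and the cooperative tugs it produced were the main source of spurious
  water detachment in unbiased controls. The geometric H-bond *analysis*
  is independent of this choice.
* **Soft repulsions** (A·exp(−r/ρ)) between molecules, strongest between
  water oxygens and ring atoms (the steric competition for the metal
  face), and a **log-Fermi spherical wall**
  V = Σᵢ k_B·T·ln(1 + exp(β(rᵢ − R))), β = 6 Å⁻¹, R = 9 Å, which keeps
  dissociated molecules in the simulation volume. The 9 Å default leaves
  the bulky indole room to tumble without being pressed into the aquo
  shell.

**Dynamics.** Langevin (BAOAB) at 298.15 K, friction 1 ps⁻¹ as the
implicit-solvent stand-in, timestep 2 fs with hydrogen masses
repartitioned to 2 amu for stability. With zero friction and zero
temperature the propagator reduces exactly to velocity Verlet, which the
test suite uses to check energy conservation from a relaxed structure
(`minimize_energy`, L-BFGS on the model potential, mirrors the protocol
of minimizing representative snapshots).

**Metadynamics bias.** The collective variable is the Cartesian RMSD
(optimal-superposition) of the three water oxygens; reference snapshots
are deposited every 50 fs and the bias is
V = Σⱼ k·exp(−α·RMSD(x, refⱼ)²) with k = k_push·|cv| and α = 0.9 Å⁻²,
k_push = 0.05 in the model's reduced energy unit (one unit = 30 kcal/mol,
the `energy_scale` mapping, i.e. 4.5 kcal/mol per Gaussian). One subtlety
is load-bearing: an RMSD over the three oxygens *alone* is invariant
under rigid motion of the O-triad, so a bias on it could never push the
waters off the metal — it would only reshape their triangle. The bias
therefore superposes on the CV set augmented with the Rh position, so
radial escape registers on the CV. The prefactor still counts only the
three genuine CV atoms.

Numerical choices for the bias: distances to all references are evaluated
with a closed-form (trigonometric) eigenvalue solution of the 3×3
correlation matrices, with the Kabsch reflection correction — no
per-reference LAPACK calls; rotation matrices (needed for the analytic
gradient, an envelope-theorem expression) are computed by batched SVD
only for references with α·d² < 9, the rest being dynamically negligible;
the bias force is refreshed every 5 steps (10 fs) and immediately after
each deposition. These choices change trajectories only at the level of
the thermostat noise.

**Calibration.** Force-field constants are invented, and their defaults
were chosen once so that, at the documented bias parameters, the model
shows the three qualitative behaviours the analysis layers are built to
detect: (i) stepwise loss of all three waters within 100 ps of biased
dynamics, with occasional re-binding and η⁶ formation after η²; (ii)
intact [Cp*Rh(H₂O)₃]²⁺ throughout 50-ps unbiased controls; (iii) for the
phenol ligand, O–Rh anchoring preceding the first η² contact in most
runs. Timescales compress relative to the reference behaviour (first
water typically leaves within ~1–3 ps rather than ~10), which is
acceptable for a model whose purpose is exercising the analyzers.

## Mock PIE tables

`generate_mock_pie_table` fabricates five-fragment PIE/EDA records from a
trajectory's coordination states: the X–scaffold pair is drawn around a
hapticity-dependent mean (−5 unbound, −35 κ¹/η¹, −60 η², −75 η³, −90 η⁴,
−110 η⁵, −125 kcal/mol η⁶), bound waters around −25, expelled waters
around 0, the remaining pairs around −1. The five EDA components are
drawn as fixed signed shares of the total (E_ct 40 %, E_disp 12 %
attractive; E_ex −20 %, E_solv −8 %, i.e. repulsive for a negative total)
plus noise, with the electrostatic term absorbing the remainder so the
decomposition closes *exactly* on every record. The scaffold charge Q₃
falls from +2.0 in proportion to the X-pair charge-transfer magnitude
(anti-correlation built in, mirroring charge transfer from the arene),
with the ligand fragment carrying the complementary charge.

What this generator emulates: the segment structure (means by
coordination class), the closure identity, the Q₃/CT coupling, and
seed-reproducibility. What it does not: correlated noise between pairs,
three-body redistribution between fragments, basis-set or embedding
artifacts, or any genuine electronic response. Passing tests therefore
demonstrate that the *bookkeeping* is correct on data of the right shape,
not that desk-scale simulation reproduces quantum-chemical PIEs.

## Coordination analysis (`coordination`)

Distance criteria, read strictly: a ring C or N is bound to Rh below
3.0 Å, a phenolic or water O below 2.5 Å; equality is unbound (the
boundary convention is declared, not derivable — published criteria say
"below"). Hapticity is the bound-atom count of the dominant ring;
bicyclic ligands are book-kept per ring with ties broken toward the
phenyl ring, and the label records the dominant ring (e.g. `η2(pyrrole)`).
A bound heteroatom alone is κ¹; a heteroatom plus exactly two ring
carbons yields the composite `η3(O,C1,C2)` motif reported for the phenol,
any other simultaneous combination is labelled κ¹+ηⁿ. The water-O
threshold (2.5 Å) follows the phenolic value by chemical analogy.

Event detection debounces transitions: a change at frame *i* is emitted
only if the series does not revert past the new value within the next
`min_dwell` frames (default 3). This suppresses single-frame flicker
while still resolving a fast monotone cascade (3→2→1→0) into one event
per step; each event records the step magnitude so replaying
release/rebind events over the initial count reconstructs the series.
Hydrogen bonds use conventional geometric criteria — donor–acceptor
< 3.5 Å and D–H···A angle > 120° — since no criteria are published for
this system.

## Energetics and thermochemistry (`fmo_energetics`, `thermo`)

The five-fragment scheme is fixed: id 1 [Cp*Rh]²⁺, ids 2–4 the waters,
id 5 the ligand X. The merged fragmentation variant folds the H-bonded
water's atoms into fragment X, keeping id 5, so the ligand–complex
interaction energy E^INT = Σᵢ PIE(X, i) is unchanged in form. Per frame,
TPIE = Σ_{i>j} PIEᵢⱼ, and ΔTPIE = TPIE_PA − TPIE_EC estimates the
exchange enthalpy because no covalent bond is broken. Missing pair
records raise; treating them as zeros would silently corrupt TPIE.
η⁶-segment statistics use the sample (n−1) standard deviation — the
convention behind published ± values is unstated, and the choice is
documented rather than inferred. Explicit-water trends are least-squares
lines in the water count (two points reduce to interpolation); crossings
of two ligands' lines are solved analytically and flagged when they fall
outside the observed 0–3 range.

G and H assemble as G = E_sol + G_therm, H = E_sol + H_therm; reaction
deltas are products-minus-reactants sums; the summary table reports ΔG,
ΔH, ΔTPIE with relative columns against a reference reaction (default
the most exergonic, configurable). All inputs are taken as kcal/mol —
an explicit `hartree_to_kcal` (627.5095) is provided, nothing converts
implicitly. One bookkeeping caveat: the published summary table's last
relative TPIE entry (7.6) sits one rounding unit below the difference of
its own printed absolutes (−17.4 + 25.1 = 7.7); the package computes
correct arithmetic and its tests compare to the printed column at printed
precision. The estimator-vs-ΔH comparison reports per-reaction offsets
(≈ −10 kcal/mol), their mean, and the worst relative-column discrepancy
(0.9 kcal/mol from the printed absolutes), comfortably inside the
1 kcal/mol agreement claim.

## Pipeline and problem sizes

`run_pipeline` chains simulate → subsample (1 ps) → coordination → mock
energetics → report for each ligand × replicate (default 2 replicates,
mirroring the two-run protocol), with one derived seed per run and a
manifest (config hash, seeds, version) sufficient to reproduce the bundle
byte-for-byte.

Sizes used by the shipped checks: behavioural statistics use five biased
100-ps runs and five unbiased 50-ps controls of the phenol system
(~30–40 s per biased run on one core); segment-statistic recovery uses
n = 100 frames at noise sd 1.5 kcal/mol; property suites use dense random
five-fragment tables and brute-force enumeration oracles.

## Known limitations

* The toy potential has no electronic structure: absolute energies,
  PIE magnitudes and barrier heights are not comparable to
  quantum-chemistry values; only coordination *statistics* are meant to
  be faithful.
* The Cp* ligand is one pseudo-site: ring–Cp* steric detail (e.g. methyl
  clashes raising exchange-repulsion at η⁶) appears in the mock EDA
  shares, not in the dynamics.
* Metadynamics convergence (free-energy estimates from deposited bias) is
  out of scope; the bias is used only as a driving protocol.
* The XYZ reader assumes well-formed blocks and parses only a `t=` time
  token; exotic comment-line conventions pass through as metadata-free
  frames with caller-supplied spacing.
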