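# Methods

This note documents the models, numerical choices and validation strategy
behind phtitra, and what the synthetic round-trip tests do and do not show
about real constant-pH trajectories.

## Titration analysis

**State classification.**  A frame of a titratable site is a pure
deprotonated state when λ ≥ 0.8, a pure protonated state when λ ≤ 0.2, and
in either case the tautomer coordinate (when the residue has one:
carboxylates, histidine) must lie outside the open mixed band
(0.2, 0.8).  All other frames are discarded and counted as such — the
partition N_deprot + N_prot + N_discarded = N_total is asserted on every
call.  The cut-offs are a `StateCutoffs` value and fully configurable;
boundary frames (λ exactly 0.8 or 0.2) count as pure.  Residues with a
single titratable site have no χ and the purity condition is vacuous.

**Fractions and fitting.**  Sᵢ = N_deprot/(N_deprot+N_prot) per pH;
discarded frames never enter the denominator, and a pH at which no pure
state was observed is dropped from the fit with a logged warning rather
than interpolated.  The generalized Henderson–Hasselbalch curve
S(pH) = 1/(1+10^{n(pKa−pH)}) is fitted by bounded trust-region least
squares (`scipy.optimize.least_squares`) on (pKa, n), with n ∈ [1e−3, 10]
and pKa ∈ [−10, 24]; initialisation is pKa at the pH of the point nearest
S = 0.5 and n = 1, which is reliable for this monotone two-parameter
family.  Tolerances are set to machine-level (1e−14) since each fit costs
microseconds.  Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹.  By construction the fitted curve passes through 0.5 at the
fitted pKa; the package exposes this as an exact self-consistency check.

**Identifiability guard.**  When every observed fraction exceeds 0.95 (or
falls below 0.05) the midpoint lies outside the simulated pH grid and the
two parameters are not identifiable; the result then carries a one-sided
bound (the grid edge) with `ph_range_flag` set to `below_grid` /
`above_grid` and `converged = False` — never an extrapolated point
estimate.

**Weighting.**  Fits are unweighted by default; `fit(weighted=True)`
weights each pH point by its pure-state count (square-root weights in the
residual).  With the equal per-pH sampling used throughout the tests the
two give indistinguishable estimates; the option matters when replicas of
unequal length are pooled.

**Per-replica vs pooled.**  Both modes are supported: pool by
concatenating records per pH before counting, or fit each replica's
fractions separately and compare.  The pipeline defaults to pooling
(concatenation), the simpler and better-sampled estimator.

**Reference pKa table.**  ΔpKa is the fitted pKa minus a model-pentapeptide
reference for the residue type.  The shipped defaults (Asp 4.0, Glu 4.4,
His 6.5) are editable placeholders for whichever model-compound set a
study uses; load study-specific values from YAML.  Tests never rely on the
default numbers.

## H-bond networks

**Angle convention.**  The angular criterion is the deviation from
donor–H···acceptor linearity, i.e. 180° − θ(D,H,A); a perfectly linear
bond scores 0°.  A criterion of "angle below 20°" can only be meant this
way: the internal D–H–A angle of a real H-bond is always near 180°.

**Detection.**  Donor and acceptor heavy atoms are resolved from a
per-residue-type chemistry table that follows the protonation state
(protonated carboxylates gain a hydroxyl donor, deprotonated ones are
acceptor-only, neutral histidine donates on its single protonated ring
nitrogen).  States are supplied per residue instance; the default is
deprotonated carboxylates and the Nδ histidine tautomer.  Hydrogens are
attached geometrically (within 1.25 Å of the donor heavy atom, same
residue), so H naming conventions are irrelevant; a donor without a
resolvable hydrogen is skipped with a log entry.  Candidate pairs come
from a k-d tree query at the distance cutoff (3.5 Å default).

**Water bridges.**  Per frame, a breadth-first search runs from each
protein group through the water–water H-bond graph to depth ≤ 3; a pair of
groups is bridged when the search reaches a water adjacent to the second
group, and the minimal water count per pair is recorded.  Each (pair,
frame) counts once regardless of how many distinct paths exist, because
occupancy is defined per pair and per frame.  Correctness of this search
is tested against an independent brute-force enumeration of all ordered
water tuples on dozens of random small systems.

**Occupancy and graphs.**  Occupancy = 100 × (frames with the connection)
/ (frames analysed); direct and water-bridged occupancies are tracked
separately, as are the "all groups" and "side chains only" scopes.  Three
residue-level graph sets are built — (1) backbone + side chains with
bridges, (2) side chains with bridges, (3) side-chain direct only — with
canonical thresholds per angle criterion (10/50, 10/25, 10/15 percent at
20°/60°).  A (set, angle, threshold) triple that contradicts the canonical
mapping is rejected unless explicitly overridden.  Nodes are residues;
whether an atom is backbone or side chain is decided by atom name.  Edges
are undirected: donating and accepting are not distinguished.  Replicas
are pooled by concatenation (counts and frame totals add); per-replica
analyses are just separate calls.

**Frame selection.**  First/last/stride subsampling is a configuration
option applied before analysis, not hard-coded.

## Backbone conformation

**Dihedrals.**  φ = C(i−1)–N(i)–CA(i)–C(i) and ψ = N(i)–CA(i)–C(i)–N(i+1),
computed per frame with biotite's dihedral primitive; angles at termini or
across missing atoms are NaN and propagate as "undefined", never as 0.

**PAD.**  Per residue, each defined torsion sample is mapped to a unit
vector; φ and ψ are centred on their own circular means (so a rigid
residue scores 0 wherever its basin lies), and the pooled mean resultant
length R̄ — equal to the average of the two per-angle resultant lengths —
gives PAD = (180/π)·√(−2 ln R̄), capped at 180°.  The cap is reached
exactly for angles equally spaced around the circle (R̄ = 0).  The metric
is monotone in dispersion, invariant to frame order and to duplicating the
ensemble, and is exposed behind `pad_from_resultant` so φ-only or ψ-only
variants can be substituted; which torsion combination the original
dispersion metric used is not fixed by our sources, and the joint (φ, ψ)
form was chosen as the symmetric default.

**Helix assignment.**  A residue is helical in a frame iff φ ∈ [−100°,
−30°], ψ ∈ [−67°, −7°] and it belongs to a run of ≥ 4 consecutive
in-window residues; helical content is the percentage of helical
residue-frames.  This is a deliberately simple dihedral-window assignment,
not a re-implementation of pattern-based secondary-structure codes; it is
exact on ideal geometry and adequate for trend statements (helix shortens
or persists), but it will disagree with STRIDE/DSSP near helix ends.

## Synthetic generators

**Titration records.**  At each pH, each frame is first assigned a
category: mid-λ (probability `mid_lambda_fraction`), mixed-χ
(`mixed_chi_fraction`), otherwise pure.  Pure frames are deprotonated with
probability S(pH) from the ground-truth (pKa, n); their λ is uniform on
the matching cut-off band ([0.8, 1.0] or [0.0, 0.2]) rather than a point
mass, so the band logic is genuinely exercised, and χ is uniform on
[0, 0.15] or [0.85, 1.0].  Mid-λ frames draw λ uniformly on [0.25, 0.75]
— strictly inside the discard band, so the generator's bookkeeping of
injected impurities matches the classifier's discarded tally frame-exactly.
Draws are independent by default; an optional two-state Markov mode with a
flip-scale parameter lengthens dwell times at an unchanged stationary law,
for stressing the cumulative-fraction convergence diagnostic.  Everything
derives from one `numpy` Generator seeded by the spec.

**Toy ensembles.**  Backbones are built by internal-coordinate (NeRF)
construction from ideal α-helix torsions (φ = −57°, ψ = −47°) inside the
helix span (extended elsewhere), with i.i.d. Gaussian noise of the
requested σ on every defined torsion, vectorised across frames.  Amide
hydrogens and carbonyl oxygens are placed in the peptide plane so backbone
i→i−4 H-bonds emerge naturally.  Engineered contacts are realised as
collinear chains (donor heavy atom + H, 0–3 waters, acceptor) with 2.9 Å
heavy-atom spacing and zero angular deviation; per frame a Bernoulli draw
at the target occupancy decides whether the chain (minus the anchored
donor atom) is displaced 12 Å outward, which breaks the donor link while
keeping the topology constant across the model stack.  Chains of distinct
contacts extend along directions rotated 137° apart around the helix axis
so they cannot cross-link.  A contact whose atoms the chemistry table
cannot interpret (e.g. a hydroxyl donor on alanine) is rejected as
unrealizable.

**What the round trips show — and don't.**  Recovering (pKa, n) from the
generator demonstrates the counting/fitting chain is unbiased under the
generator's assumptions: two-state sampling that actually follows the
Hill law, no λ autocorrelation (unless enabled), equal frames per pH.
Real CpHMD data violate all three to some degree (finite sampling,
correlated λ dynamics, conformation-coupled titration), so the synthetic
tolerances (mean |ΔpKa| ≤ 0.1 at 10⁴ frames/pH) are a floor on method
error, not an estimate of production accuracy.  Likewise the toy
ensembles have exact geometry and isolated contacts; they validate the
detection logic and threshold bookkeeping, not force-field realism or
solvent structure.

## Problem sizes and runtime

The validation suite uses 10⁴ samples per pH × 5 pH values × 20 seeded
datasets for parameter recovery, 50 random small systems (≤ 12 groups,
≤ 15 waters) for the brute-force graph oracle, and 2 000-frame toy
ensembles for occupancy thresholds — sizes at which the binomial noise on
a 50% occupancy is ± 3% (3σ) and the whole suite completes in seconds on
one core.

## Known limitations

* PDB coordinate precision (3 decimals) bounds round-trip fidelity at
  ~10⁻³ Å; distances for reporting are rounded half-up to one decimal.
* Residue-level group ids are `RESNAME+RESID` without the chain id;
  multi-chain systems with colliding numbering need re-numbering first.
* The worked-example distance checks on the deposited NMR ensemble (PDB
  entry 1RON) require the user to supply `data/1RON.pdb`; the file is not
  redistributed.
* Only geometric H-bond criteria are implemented — no energetic scoring,
  π or C–H···O interactions.
* mmCIF and compressed trajectory formats (DCD/XTC) are out of scope;
  convert to multi-model PDB first.
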