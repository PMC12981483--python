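# phtitra

Post-processing for **constant-pH molecular dynamics (CpHMD)** of peptides
and small proteins: titration-curve pKa estimation from λ-dynamics output,
geometric hydrogen-bond / water-bridge network graphs, and backbone
fluctuation metrics — together with synthetic generators that produce every
input with known ground truth, so the whole pipeline can be validated
quantitatively.

## Who this is for

CpHMD engines propagate, for every titratable site *i*, a continuous
titration coordinate λᵢ (1 = deprotonated, 0 = protonated) and, for
carboxylates and histidine, a tautomer coordinate χᵢ.  Turning those raw
trajectories into residue pKa values, pH-dependent interaction networks and
flexibility profiles involves a series of filtering and fitting choices that
are easy to get subtly wrong.  This package implements that analysis chain
as a tested library with a thin CLI.

## The model

Per-frame states are classified with band cut-offs: a frame is
**deprotonated** when λ ≥ 0.8, **protonated** when λ ≤ 0.2, and in both
cases the tautomer must be pure (χ < 0.2 or χ > 0.8); everything else —
intermediate λ or mixed tautomers — is **discarded**, never folded into a
state.  The deprotonated fraction at one pH is

    Sᵢ = N_deprot,i / (N_deprot,i + N_prot,i)

and the fractions across the simulated pH grid are fitted to the
generalized Henderson–Hasselbalch (Hill) curve

    Sᵢ(pH) = 1 / (1 + 10^{n (pKa,i − pH)})

by bounded nonlinear least squares; the pKa is the pH at which Sᵢ = 0.5
(exactly, by construction), and n is the Hill coefficient.  ΔpKa is the
shift against a model-pentapeptide reference table.  Partial charges of a
titrating group interpolate linearly: q_α(λ) = λ q_α^d + (1−λ) q_α^p.

H-bonds use standard geometric criteria — donor/acceptor heavy-atom
distance ≤ 3.5 Å, deviation from donor–H···acceptor linearity below 20°
(strict) or 60° (permissive) — and water bridges are paths through 1–3
mutually H-bonded waters.  Edge occupancy is the percentage of frames in
which the connection exists; three residue-level graph sets are built
(backbone+side chain incl. bridges; side chains incl. bridges; side-chain
direct only) with canonical occupancy thresholds per angle criterion
(set 1: 10%/50%, set 2: 10%/25%, set 3: 10%/15% at 20°/60°).

Backbone flexibility is summarised per residue by a circular dispersion of
the (φ, ψ) torsions (PAD, 0° for rigid, capped at 180°), and helicity by a
simplified α-window dihedral assignment with a minimum run of 4 residues.

## Worked example

```python
import phtitra as pt

# synthetic λ-records with known ground truth: pKa 4.0, Hill 1.0
spec = pt.SyntheticSpec(pka_true=4.0, hill_true=1.0, n_samples_per_ph=20000, seed=1)
sim = pt.simulate_titration_records(spec)
res = pt.TitrationModel.from_records(sim.records).fit()
print(res.summary())
print(f"delta_pKa: {pt.pka_shift(res, pt.ReferencePKaTable.default()):+.4f}")
```

prints

```
Titration curve fit (generalized Henderson-Hasselbalch)
========================================================
residue:        ASP6
n pH points:    5
converged:      True
pH range flag:  in_range
pKa:            3.9993  (se 0.0011)
Hill n:         1.0036  (se 0.0027)
residual norm:  0.00125366
delta_pKa: -0.0007
```

The fitted pKa recovers the generator's ground truth (4.0) to three decimal
places from 20 000 sampled frames per pH; the near-zero ΔpKa says the
fitted value sits at the reference pKa for aspartate.  The same round trip
works for the structural side:

```python
toy = pt.build_toy_ensemble(pt.ToyStructureSpec(
    sequence="ASAAADAAAS", n_frames=500, dihedral_noise_sigma=6.0,
    engineered_contacts=(
        pt.EngineeredContact(2, "OG", 6, "OD1", n_waters=1, target_occupancy=60.0),
    ),
    seed=1))
occ = pt.analyze_ensemble(toy.ensemble)
for e in pt.graph_edges(occ, pt.GraphSpec(pt.GraphSet.SIDECHAIN_WATER, 60)):
    print(e.group_a, e.group_b, e.kind, e.min_waters_observed, f"{e.occupancy:.1f}%")
```

```
ASP6 SER2 water_bridged 1 58.2%
```

— the single engineered one-water bridge, recovered at its realised
occupancy (60% target, Bernoulli-sampled over 500 frames), and nothing
else above the side-chain graph threshold.

## Command line

```
phtitra simulate | titrate | hbonds | conf | run | measure
```

e.g. `phtitra measure ensemble.pdb S22:OG R19:O` prints the distance between
the Ser22 hydroxyl oxygen and the Arg19 backbone carbonyl oxygen of model 1,
rounded half-up to one decimal.  `phtitra run --config run.yaml` executes
titrate → hbonds → conf and writes CSV tables, GraphML networks and a
deterministic run manifest.

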