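# igxlink

Structural analysis of chemical cross-linking mass spectrometry (XL-MS)
data: mapping identified residue-pair cross-links onto 3D structures of
(homo-)oligomeric assemblies, validating them against the linker-imposed
distance cutoff, using them as restraints for rigid-body modelling of a
mobile domain, and quantifying inter-domain motions between two
conformations.

It is written for structural biologists and proteomics researchers who have
a table of identified cross-links (e.g. from an in-gel or in-solution
DSS/DSSO experiment) and one or more atomic structures, and who want the
downstream structural analysis — not the spectral search — done
reproducibly.

## What it computes

**Shortest-combination distance mapping.** In an oligomer a residue-pair
link (i, j) maps onto many chain combinations: both residues on one chain,
or split across any pair of chains. For a structure with chains
*c₁ … c_n*, the distance representing the link is

```
d(i, j) = min over chain pairs (c_a, c_b) of ‖ Cα(c_a, i) − Cα(c_b, j) ‖
```

A link is *over-length* when d(i, j) exceeds the maximal Cα–Cα span the
cross-linker chemistry allows (30 Å for DSS/DSSO-class lysine reagents).
Links are filtered by replicate evidence (kept when seen in ≥ 2 of 3
replicates), histogrammed in half-open 5 Å bins, and compared across
conditions by directional set overlap.

**Restraint-driven rigid-body modelling.** Inter-body cross-links become
flat-bottom harmonic restraints (target 17 ± 2 Å, hard window 3–30 Å). An
exhaustive scan over a quasi-uniform orientation set × translation grid
counts, for every k, the clash-free poses consistent with ≥ k restraints
(the accessible interaction space, N_k); local derivative-free refinement
then minimises

```
E = Σ_k ( max(0, |d_k − μ_k| − σ_k) / σ_k )²   +   soft clash penalty
```

and ranks solutions by (E, clash count, RMS deviation from the restraint
targets). Solvent accessibility for choosing docking-active residues is
computed with a deterministic Shrake–Rupley quadrature; candidate models
are compared by the fraction of cross-linked pairs inside a 40 Å contact
map.

**Domain-motion analysis.** Kabsch least-squares superposition, the
rotation angle θ = arccos((tr R − 1)/2), inter-domain angle/centroid
displacement after anchor-domain alignment, superposition-independent
difference distance matrices, and contour-length feasibility of flexible
linkers (3.4–4.0 Å per residue).

**Synthetic data with planted truth.** Every stage runs without downloads:
Cn-symmetric ring oligomers of self-avoiding Cα bead chains, multidomain
chains with extended linkers, and cross-link tables with a planted
true/decoy distance split and per-replicate detection noise.

## Worked example

```python
from igxlink import (SimSpec, make_ring_oligomer, simulate_crosslinks,
                     deduplicate_and_filter, map_table, distance_summary,
                     AnalysisConfig)

spec = SimSpec(seed=8, n_subunits=7, n_residues_per_chain=120,
               ring_radius=34.0, n_links=40)
ring = make_ring_oligomer(spec)
table, truth = simulate_crosslinks(ring, spec)
print(f"simulated {len(truth)} unique links, {len(table)} replicate observations")

cfg = AnalysisConfig()            # 30 A threshold, 5 A bins, 2-of-3 replicates
kept = deduplicate_and_filter(table, cfg)
mapped = map_table(kept, ring, cfg)
s = distance_summary(mapped, cfg)
print(f"{s.n_unique} unique links mapped, {s.n_overlength} over 30 A, "
      f"mean Ca-Ca distance {s.mean_distance:.1f} A")
for left in sorted(s.histogram):
    print(f"  [{left:4.0f},{left + s.bin_width:4.0f}) A : {s.histogram[left]}")
```

prints

```
simulated 40 unique links, 102 replicate observations
33 unique links mapped, 0 over 30 A, mean Ca-Ca distance 14.3 A
  [   5,  10) A : 8
  [  10,  15) A : 11
  [  15,  20) A : 11
  [  20,  25) A : 3
```

Seven of the 40 planted links were dropped by the 2-of-3 replicate filter
(each link is detected per replicate with probability 0.8); none of the
mapped links is over-length because no decoys were planted, and the mean
distance reflects lysine pairs bridged inside and between the ring's
subunits.

The same pipeline runs from the shell:

```bash
igx simulate --out run/ --seed 8
igx map --out run/ --structure run/simulated.pdb --links run/simulated_links.tsv
igx report run/ --plots
```

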