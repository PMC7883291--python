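# Methods

This note records the models, conventions and numerical choices behind
`igxlink`, and what the synthetic studies do and do not demonstrate.

## Cross-link mapping

**Identity and canonical form.** A cross-link is a residue pair
((protein_a, pos_a), (protein_b, pos_b)) with spectral-count, replicate and
condition metadata. Identity is order-insensitive: endpoints are sorted
lexicographically, and a table drops exact duplicate rows within one
replicate. Positions are 1-based full-sequence (UniProt/FASTA) numbering;
structures use author numbering, reconciled by an explicit per-chain
integer offset. When a FASTA is available the offset is derived by exact
subsequence matching of the chain sequence, and ambiguity or mismatch is an
error — the package never guesses a numbering.

**Shortest-combination rule.** For homo-oligomers every chain combination
of a link is enumerated: both residues on one chain, or split across any
unordered chain pair (for a split pair the smaller of the two residue
placements is taken). The minimum over all combinations represents the link
in histograms and statistics. Enumerating *all* pairs rather than
"neighbouring subunits" needs no adjacency definition and gives the same
minimum for ring geometries, where the nearest chain pair is always
enumerated. Self-links (a residue to itself) are meaningful only across
chains; their same-chain placement is skipped, and they are excluded from
distance statistics but reported separately. Unmapped links (missing
residue or Cα) are kept with a reason, never dropped.

**Thresholds and bins.** The over-length threshold defaults to 30 Å — the
maximal Cα–Cα span bridgeable by DSS/DSSO-class lysine reagents (11.4 Å
spacer plus two lysine side chains plus backbone flexibility); both
reagents are treated identically. Histograms use half-open bins
[k·w, (k+1)·w) with w = 5 Å by default (the bin width is presentation, not
inference, and is configurable). Replicate filtering keeps a link observed
in ≥ `min_replicates` (default 2) distinct replicates; the filtered table
stays replicate-resolved so the filter is idempotent, and spectral counts
are summed wherever unique links are consumed.

**Overlap statistics** are computed at the residue-pair level (not the
peptide-pair level, which would require spectral information out of scope
here) and reported directionally: |A∩B|/|A| is "the share of A's links also
found in B". Both directions are returned.

## Solvent accessibility and contact maps

SASA uses the Shrake–Rupley method with a deterministic golden-spiral
quadrature (default 960 points, probe 1.4 Å). The package operates on Cα
bead models, so each residue is one bead of effective radius 3.0 Å — a
stand-in for the side-chain envelope chosen so that surface beads of a
compact globule score high and core beads near zero. Relative accessibility
is the bead SASA over the isolated-bead SASA (4π(r+probe)²), bounded by 1;
full-atom reference tables (Gly-X-Gly maxima, as used by Naccess-style
tools) would differ slightly and would be the right reference for full-atom
inputs. The quadrature is exactly translation-invariant and
rotation-invariant only to the sphere-sampling error (≲1% of the sphere
area at 960 points); an independent implementation (biotite's) agrees to
the same order in the test suite. Docking-active residues are those with
relative accessibility ≥ 0.40, alongside the cross-linked residues.

Contact maps are Cα–Cα distance matrices with a boolean mask below a
threshold (default 40 Å, the radius used for contact-map comparison of
candidate models; whether published contact analyses use Cα–Cα or
heavy-atom minima is often unstated — Cα–Cα is chosen and declared). The
map-overlap score is the fraction of unique cross-linked residue pairs
whose cell is in contact: published contact-map agreement scores are not
reproduced verbatim, but any monotone overlap measure ranks candidate
models identically, which is its only use here. Difference distance
matrices Δ(i,j) = d_A(i,j) − d_B(i,j) are superposition-independent and
antisymmetric; the ±20 Å clip is applied at display time only.

## Restraints, interaction-space scan, docking

A cross-link bridging the fixed and mobile bodies becomes a flat-bottom
harmonic restraint: target mean 17 Å and spread 2 Å between lysine Cα
atoms (the expected bridged distance of a DSS-class reagent), with hard
satisfaction bounds [3, 30] Å. Links internal to one body are excluded and
counted.

The accessible-interaction-space scan enumerates a deterministic
quasi-uniform orientation set (Shoemake's uniform-quaternion map driven by
a Halton sequence; default 576 orientations) crossed with a cubic
mobile-centroid grid (default 2 Å spacing) over a shell sized from both
body radii plus the largest restraint upper bound. Grid points that cannot
geometrically satisfy any restraint (triangle inequality on the anchor
lever arms) are pruned first; clash checks (any inter-body Cα pair closer
than 3.0 Å) run only where the bodies' bounding spheres can touch. The scan
reports N_k — clash-free poses consistent with ≥ k restraints — and a
diversity-filtered list of best poses.

Docking refines start poses by Powell minimisation (derivative-free, hence
deterministic for fixed starts) of the flat-bottom energy plus a soft
quadratic clash penalty, followed by a harmonic polish toward the exact
targets that is kept only if it does not leave the flat-bottom optimum.
Poses are ranked by (energy, clash count, RMS deviation from targets) — the
RMS discriminates inside the zero-energy plateau, implementing "best
agreement with the distance restraints" — and clustered greedily at 5 Å
mobile-body RMSD. Refinement is guaranteed never to worsen the restraint
energy relative to its own start (the start is kept otherwise). A
complementary start generator enumerates orientations and solves each
orientation's optimal translation by least squares, which removes the
translation-grid resolution limit; model selection among full candidate
models is lexicographic on (higher contact-map overlap, lower restraint
RMS), ties reported and broken by input order.

## Domain motions

Superposition is the SVD form of the Kabsch algorithm with the standard
determinant sign fix (never a reflection); degenerate (collinear) sets are
rejected. The rotation angle of a proper rotation is
arccos((trace − 1)/2), clamped to [−1, 1]. Published superposition tools do
not fully specify their angle convention, so one self-consistent convention
is declared: the alternative structure is aligned on the *anchor* domain;
the inter-domain angle is the residual rotation of the *moving* domain in
that frame, and the displacement is the distance between the moving
domain's centroids in the same frame. Identical inputs give exactly (0, 0).

Linker feasibility compares the Euclidean gap with the contour-length band
n × [3.4, 4.0] Å; a gap is feasible iff it does not exceed the upper bound.
Deriving n from an inclusive residue range is off-by-one-prone (a quoted
range may include a flanking residue), so that path warns and asks the user
to confirm the counting convention.

## Synthetic data

The generators emulate the *statistical and geometric* structure of a
cross-linking experiment, not its chemistry or spectra.

* **Ring oligomers**: one compact self-avoiding Cα walk (3.8 Å steps,
  3.0 Å exclusion, confined to a ball whose radius follows n^(1/3);
  confinement is eased slightly if a long walk jams) replicated by
  rotations of 360°/n — exact Cn symmetry. Default 7 subunits of 120
  residues at ring radius 34 Å, chosen so chains approach to a few Å
  without clashing. Lysine-like sites are a random 1-in-12 subset of
  positions (the typical lysine frequency in globular proteins), identical
  across subunits.
* **Multidomain chains**: compact domains grown sequentially, each walk
  avoiding all previously placed beads (the chain cannot interpenetrate
  itself — this also guarantees the built conformation is clash-free as a
  docking ground truth), joined by extended linkers pointing away from the
  built body.
* **Cross-link tables**: true links drawn uniformly without replacement
  from lysine-like pairs whose shortest-combination distance is ≤ 30 Å,
  decoys from pairs beyond it (`decoy_fraction` of the emitted links);
  each link is detected independently per replicate with `detect_prob`
  (default 0.8 — reproducible detection with occasional dropouts) and
  carries a small Poisson spectral count. Decoy planting requires geometry
  with > 30 Å pairs, i.e. elongated or multidomain fixtures — on a compact
  ring every residue pair has a short combination somewhere, which is
  exactly why over-length links in rings indicate co-occurring states
  rather than geometry.
* **Planted docking problems**: two domains in direct contact; 8 restraints
  whose targets are the exact true distances (spread 1.0 Å — the study
  validates pose recovery, so the restraint sharpness is an instrument
  setting; with a ±2 Å flat bottom the pose can drift more than the 5 Å
  recovery radius along soft directions, which a Jacobian analysis of the
  8×6 distance-to-pose sensitivity makes explicit). Some mobile anchors
  carry two partners: one-to-one anchor pairings admit discrete alternative
  embeddings of the distance graph (the inverse-kinematics multiplicity),
  whereas shared anchors trilaterate the pose essentially uniquely —
  mirroring real cross-link sets, where one lysine links to several
  partners. Anchor draws are screened by the smallest singular value of the
  distance Jacobian (≥ 0.45) so the planted problem is identifiable.

The random-number contract: every generator consumes
`numpy.random.default_rng(seed)` in a fixed documented order, so a fixed
seed is bit-reproducible across runs and platforms.

Passing these studies shows the *computational* pipeline is correct and
self-consistent: distances, counts and overlaps match planted truth, and
pose/motion recovery works when the restraints determine the answer. It
does not validate identification quality of real search engines, chemistry
biases of real cross-linkers, or full-atom sterics — bead-level clashes and
accessibility are coarse surrogates.

## Problem sizes and determinism

Default test and acceptance problem sizes — rings of 3–7 × 30–150 residues,
two-body docking with 60–70-bead domains, scans of 96–288 orientations at
3–4 Å grid spacing, 20-seed recovery studies — were chosen so the full
suite completes in a few minutes on one CPU while leaving each statistical
check enough samples for a binomial confidence interval. All pipeline
outputs are deterministic given the archived configuration and seed; the
run manifest records inputs, seeds and per-stage record counts.

## Known limitations

* Cα-only: no side-chain geometry, no atomic clash detection, no
  solvent-exclusion subtleties; the 3.0 Å bead radius and 3.0 Å clash
  criterion are coarse surrogates.
* The flat-bottom restraint is a convenience potential, not a calibrated
  cross-linker length distribution.
* The scan's orientation set is quasi-uniform, not an exact SO(3) grid;
  "one orientation step" is therefore a statistical, not worst-case,
  resolution.
* Contact-map overlap is a ranking surrogate, not a published score.
* Real-data numbering reconciliation handles exact subsequence matches
  only; indels between construct and deposited structure require a manual
  offset.
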