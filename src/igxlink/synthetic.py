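"""Synthetic structures and cross-link tables with known ground truth.

Every downstream stage of the pipeline (mapping, accessibility, docking,
motion analysis) can be exercised on fixtures from this module without any
external download.  Two structural archetypes are generated:

* Cn-symmetric ring oligomers of identical compact Cα-bead chains — the
  statistical shape of a chaperonin-like homo-oligomer, where one residue
  pair maps onto many intra- and inter-chain combinations.
* Single chains of compact globular domains joined by extended linkers —
  the shape of a multidomain protein with a mobile domain on a flexible
  tether.

Cross-link tables are planted with known truth: "true" links are drawn from
lysine-like residue pairs whose shortest Cα–Cα combination is at most
``max_true_dist`` (default 30 Å, the spacer-arm-derived cutoff for
DSS/DSSO-class reagents), decoys from pairs beyond it, and each link is
detected independently per replicate with probability ``detect_prob``.

Random-number contract: every generator takes its stream from
``numpy.random.default_rng(seed)`` and draws in a fixed documented order, so
a fixed seed gives bit-identical output across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Chain, CrossLink, CrossLinkTable, StructureModel

#: Virtual Cα–Cα bond length of the bead model, Å.
BOND_LENGTH = 3.8
#: Minimum bead separation enforced by the self-avoiding walk, Å.
MIN_BEAD_DIST = 3.0

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


class GenerationError(Exception):
    pass


class OverlapError(GenerationError):
    pass


@dataclass
class SimSpec:
    """Parameters of one simulated experiment.

    Defaults mimic a mid-size ring oligomer cross-linked in triplicate:
    lysines at roughly 1 in 12 positions (the typical lysine frequency in
    globular proteins), a 30 Å true-link cutoff, and per-replicate detection
    at 0.8 — reproducibly detected links with occasional dropouts.
    """

    seed: int = 0
    n_subunits: int = 7
    n_residues_per_chain: int = 120
    ring_radius: float = 34.0
    linkable_fraction: float = 1.0 / 12.0
    max_true_dist: float = 30.0
    decoy_fraction: float = 0.0
    n_replicates: int = 3
    detect_prob: float = 0.8
    n_links: int = 40
    protein_id: str = "SYNPROT"
    condition: str = "sim"

    def __post_init__(self) -> None:
        for name in ("linkable_fraction", "decoy_fraction", "detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class PlantedLink:
    """Ground-truth record for one emitted cross-link."""

    key: tuple[str, int, str, int]
    min_distance: float      # shortest Cα–Cα combination on the source structure
    is_decoy: bool           # planted above max_true_dist
    replicates: tuple[int, ...]  # replicates in which the link was detected


# --------------------------------------------------------------------------
# bead-chain construction

def _compact_saw(n: int, rng: np.random.Generator,
                 confine_radius: float | None = None,
                 obstacles: np.ndarray | None = None,
                 confine_center: np.ndarray | None = None,
                 max_restarts: int = 200) -> np.ndarray:
    """Self-avoiding random walk of ``n`` beads with 3.8 Å steps, confined
    to a ball around its start so the chain is globular rather than
    extended.  ``obstacles`` (coordinates in the walk's frame, which starts
    at the origin) are avoided at the same minimum bead distance.  The
    returned walk starts at the origin."""
    if confine_radius is None:
        confine_radius = max(1.9 * n ** (1 / 3) + 2.5, 7.0)
    center = np.zeros(3) if confine_center is None \
        else np.asarray(confine_center, float)
    obs_tree = cKDTree(obstacles) if obstacles is not None and len(obstacles) \
        else None
    for attempt in range(max_restarts):
        # if the walk keeps jamming, ease the confinement a little — long
        # chains need slightly lower density to remain buildable
        if attempt and attempt % 50 == 0:
            confine_radius *= 1.1
        pts = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _attempt in range(60):
                v = rng.normal(size=3)
                v *= BOND_LENGTH / np.linalg.norm(v)
                cand = pts[i - 1] + v
                if np.linalg.norm(cand - center) > confine_radius:
                    continue
                if i >= 2:
                    d2 = np.sum((pts[: i - 1] - cand) ** 2, axis=1)
                    if np.min(d2) < MIN_BEAD_DIST ** 2:
                        continue
                if obs_tree is not None and \
                        obs_tree.query(cand)[0] < MIN_BEAD_DIST:
                    continue
                pts[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise GenerationError(f"could not build a compact {n}-bead chain")


def _rotation_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _make_chain(cid: str, coords: np.ndarray, aas: list[str]) -> Chain:
    return Chain(chain_id=cid,
                 resnums=np.arange(1, len(coords) + 1),
                 aas=list(aas),
                 coords=coords)


def _linkable_aas(n_res: int, fraction: float, rng: np.random.Generator) -> list[str]:
    """Mark a random subset of positions as lysine-like ('K'), rest 'A'."""
    n_link = max(0, round(fraction * n_res))
    pos = rng.choice(n_res, size=n_link, replace=False) if n_link else np.array([], int)
    aas = ["A"] * n_res
    for p in pos:
        aas[p] = "K"
    return aas


def make_ring_oligomer(spec: SimSpec) -> StructureModel:
    """Cn-symmetric ring of identical compact bead chains.

    One chain is built as a confined self-avoiding walk, translated to
    ``ring_radius`` on the x-axis, and replicated by rotations of 360°/n
    about the z-axis — exact Cn symmetry by construction.  Identical
    lysine-like positions are marked in every chain (homo-oligomer).
    """
    rng = np.random.default_rng(spec.seed)
    proto = _compact_saw(spec.n_residues_per_chain, rng)
    proto = proto - proto.mean(axis=0)
    aas = _linkable_aas(spec.n_residues_per_chain, spec.linkable_fraction, rng)
    proto = proto + np.array([spec.ring_radius, 0.0, 0.0])

    if spec.n_subunits > len(_CHAIN_IDS):
        raise GenerationError(f"at most {len(_CHAIN_IDS)} subunits supported")
    chains: dict[str, Chain] = {}
    for k in range(spec.n_subunits):
        R = _rotation_z(2.0 * np.pi * k / spec.n_subunits)
        cid = _CHAIN_IDS[k]
        chains[cid] = _make_chain(cid, proto @ R.T, aas)

    model = StructureModel(
        model_id=f"ring{spec.n_subunits}",
        chains=chains,
        chain_proteins={cid: spec.protein_id for cid in chains},
    )
    if spec.n_subunits > 1:
        # adjacent chains must not interpenetrate
        ids = list(chains)
        for a, b in zip(ids, ids[1:] + ids[:1]):
            ca, cb = chains[a].coords, chains[b].coords
            if a == b:
                continue
            dmin = cKDTree(ca).query(cb)[0].min()
            if dmin < MIN_BEAD_DIST:
                raise OverlapError(
                    f"ring_radius {spec.ring_radius} too small: chains {a}/{b} "
                    f"approach to {dmin:.2f} Å"
                )
    return model


def make_multidomain_chain(
    domain_lengths: list[int],
    linker_lengths: list[int],
    seed: int = 0,
    linkable_fraction: float = 1.0 / 12.0,
    protein_id: str = "SYNMULTI",
) -> tuple[StructureModel, list]:
    """Rigid globular bead domains joined by extended linkers.

    Domains are compact self-avoiding walks; linkers are straight segments
    at 3.8 Å per step along +x, so consecutive domains are well separated.
    Returns the single-chain structure and the per-domain residue ranges as
    :class:`~igxlink.rigidmodel.DomainDefinition` objects (linkers included
    as their own definitions, named ``linker1`` ...).
    """
    from .rigidmodel import DomainDefinition

    if len(linker_lengths) != len(domain_lengths) - 1:
        raise GenerationError(
            "need exactly one linker length per adjacent domain pair"
        )
    if any(l <= 0 for l in domain_lengths):
        raise GenerationError("zero-length domain in specification")
    if any(l < 0 for l in linker_lengths):
        raise GenerationError("negative linker length")

    rng = np.random.default_rng(seed)
    coords_parts: list[np.ndarray] = []
    defs: list[DomainDefinition] = []
    cursor = np.zeros(3)
    res_start = 1
    for i, dlen in enumerate(domain_lengths):
        # the walk avoids every previously placed part: the chain must not
        # interpenetrate itself
        placed = np.vstack(coords_parts) if coords_parts else None
        obstacles = placed - cursor if placed is not None else None
        # grow the new domain outward, away from what is already built
        r_conf = max(1.9 * dlen ** (1 / 3) + 2.5, 7.0)
        if placed is None:
            center = None
            outward = np.array([1.0, 0.0, 0.0])
        else:
            outward = cursor - placed.mean(axis=0)
            outward = outward / max(np.linalg.norm(outward), 1e-9)
            center = 0.55 * r_conf * outward
        dom = _compact_saw(dlen, rng, confine_radius=r_conf,
                           obstacles=obstacles, confine_center=center) + cursor
        coords_parts.append(dom)
        defs.append(DomainDefinition(name=f"domain{i + 1}",
                                     ranges=[(res_start, res_start + dlen - 1)]))
        res_start += dlen
        cursor = dom[-1]
        if i < len(linker_lengths):
            llen = linker_lengths[i]
            # extended linker pointing away from everything built so far
            built = np.vstack(coords_parts)
            u = cursor - built.mean(axis=0)
            u = u / max(np.linalg.norm(u), 1e-9)
            if llen:
                steps = np.arange(1, llen + 1)[:, None] * (BOND_LENGTH * u)
                linker = cursor + steps
                coords_parts.append(linker)
                defs.append(DomainDefinition(
                    name=f"linker{i + 1}",
                    ranges=[(res_start, res_start + llen - 1)]))
                res_start += llen
                cursor = linker[-1]
            cursor = cursor + BOND_LENGTH * u

    coords = np.vstack(coords_parts)
    aas = _linkable_aas(len(coords), linkable_fraction, rng)
    chain = _make_chain("A", coords, aas)
    model = StructureModel(model_id="multidomain",
                           chains={"A": chain},
                           chain_proteins={"A": protein_id})
    return model, [d for d in defs if d.name.startswith("domain")] + \
                  [d for d in defs if d.name.startswith("linker")]


# --------------------------------------------------------------------------
# cross-link simulation

def _min_combination_distances(model: StructureModel,
                               positions: np.ndarray) -> np.ndarray:
    """Shortest Cα–Cα distance over all chain combinations for every pair of
    sequence positions (same-chain placement excluded when i == j)."""
    coords = np.stack([ch.coords for ch in model.chains.values()])  # (C, n, 3)
    sel = coords[:, positions - 1, :]                               # (C, L, 3)
    C, L, _ = sel.shape
    # (C, C, L, L) distances between position i on chain c1 and j on c2
    diff = sel[:, None, :, None, :] - sel[None, :, None, :, :]
    d = np.sqrt(np.sum(diff ** 2, axis=-1))
    inter = d.copy()
    same = np.arange(C)
    inter[same, same, :, :] = np.inf          # drop same-chain combos
    dmin_inter = inter.min(axis=(0, 1))       # (L, L)
    intra = d[same, same, :, :].min(axis=0)   # (L, L) same-chain combos
    np.fill_diagonal(intra, np.inf)           # i==j intra is degenerate
    return np.minimum(dmin_inter, intra) if C > 1 else np.where(
        np.eye(L, dtype=bool), np.inf, intra)


def simulate_crosslinks(
    model: StructureModel, spec: SimSpec,
) -> tuple[CrossLinkTable, list[PlantedLink]]:
    """Plant cross-links on a structure and emit a replicate-resolved table.

    True links are drawn uniformly (without replacement) from lysine-like
    position pairs whose shortest combination distance is ≤ ``max_true_dist``;
    a ``decoy_fraction`` share of the emitted links comes from pairs above
    the cutoff.  Each link is detected independently in each replicate with
    ``detect_prob``; links detected nowhere stay in the truth record with an
    empty replicate tuple.
    """
    rng = np.random.default_rng(spec.seed + 1)
    first_chain = next(iter(model.chains.values()))
    positions = np.array([int(r) for r, a in
                          zip(first_chain.resnums, first_chain.aas) if a == "K"])
    if len(positions) < 2:
        raise GenerationError("structure has fewer than 2 linkable residues")

    dmin = _min_combination_distances(model, positions)
    iu, ju = np.triu_indices(len(positions))
    pair_pos = np.stack([positions[iu], positions[ju]], axis=1)
    pair_d = dmin[iu, ju]
    finite = np.isfinite(pair_d)
    pair_pos, pair_d = pair_pos[finite], pair_d[finite]

    true_mask = pair_d <= spec.max_true_dist
    true_pool = np.flatnonzero(true_mask)
    decoy_pool = np.flatnonzero(~true_mask)
    if len(true_pool) == 0:
        raise GenerationError(
            f"no linkable pair within {spec.max_true_dist} Å; cannot plant true links"
        )

    n_decoy = round(spec.decoy_fraction * spec.n_links)
    n_true = spec.n_links - n_decoy
    if n_true > len(true_pool):
        raise GenerationError(
            f"requested {n_true} true links but only {len(true_pool)} eligible pairs"
        )
    if n_decoy > len(decoy_pool):
        raise GenerationError(
            f"requested {n_decoy} decoy links but only {len(decoy_pool)} "
            f"pairs beyond {spec.max_true_dist} Å"
        )
    chosen_true = rng.choice(true_pool, size=n_true, replace=False)
    chosen_decoy = rng.choice(decoy_pool, size=n_decoy, replace=False)

    links: list[CrossLink] = []
    truth: list[PlantedLink] = []
    p = spec.protein_id
    for idx, is_decoy in [(i, False) for i in chosen_true] + \
                         [(i, True) for i in chosen_decoy]:
        pos_a, pos_b = int(pair_pos[idx, 0]), int(pair_pos[idx, 1])
        detected = tuple(
            r + 1 for r in range(spec.n_replicates)
            if rng.random() < spec.detect_prob
        )
        key = CrossLink(p, pos_a, p, pos_b).key
        truth.append(PlantedLink(key=key, min_distance=float(pair_d[idx]),
                                 is_decoy=is_decoy, replicates=detected))
        for rep in detected:
            links.append(CrossLink(
                protein_a=p, pos_a=pos_a, protein_b=p, pos_b=pos_b,
                csm_count=int(rng.poisson(2.0)) + 1,
                replicate=rep, condition=spec.condition,
            ))
    table = CrossLinkTable(links=links,
                           provenance=f"simulated(seed={spec.seed})")
    return table, truth


# --------------------------------------------------------------------------
# planted docking problems

def _farthest_point_sample(coords: np.ndarray, k: int,
                           rng: np.random.Generator) -> list[int]:
    """Greedy farthest-point subset: spreads anchors over the body."""
    from scipy.spatial.distance import cdist
    idx = [int(rng.integers(len(coords)))]
    while len(idx) < k:
        d = cdist(coords, coords[idx]).min(axis=1)
        idx.append(int(np.argmax(d)))
    return idx


def planted_docking_problem(
    seed: int,
    n_restraints: int = 8,
    fixed_len: int = 60,
    mobile_len: int = 70,
    sd: float = 1.0,
):
    """Two rigid bodies in a known relative pose plus restraints at truth.

    Builds a two-domain chain whose domains touch (2-residue linker), then
    derives ``n_restraints`` inter-body distance restraints whose targets
    equal the true distances.  Anchors are farthest-point sampled on *both*
    bodies: with anchors clustered on one side, distance restraints leave a
    free rotation about the cluster and the pose is unrecoverable — spread
    anchors pin the pose.  The identity pose is the ground truth, so a
    docking result's translation norm is directly the centroid-recovery
    error.

    Returns (fixed Body, mobile Body, restraints).
    """
    from scipy.spatial.distance import cdist

    from .rigidmodel import Body, DistanceRestraint

    # zero-length linker: the domains sit in direct contact, giving anchor
    # pairs across the whole 5-28 Å range (good triangulation geometry)
    model, domains = make_multidomain_chain(
        [fixed_len, mobile_len], [0], seed=seed, linkable_fraction=0.5)
    fixed = Body.from_structure(model, domains[0])
    mobile = Body.from_structure(model, domains[1])
    rng = np.random.default_rng(seed + 10_007)
    D = cdist(fixed.coords, mobile.coords)

    # Each mobile anchor gets links to two different fixed partners: a
    # one-to-one anchor pairing leaves discrete alternative embeddings of
    # the distance graph (multiple 6-DOF solutions), whereas two partners
    # per anchor trilaterate it onto a circle and the rigid body onto an
    # essentially unique pose.  Cross-link sets in practice show the same
    # pattern — one lysine links to several partners on the other body.
    best_set: list[DistanceRestraint] | None = None
    best_sigma = -1.0
    n_mob_anchors = max(3, n_restraints - 2)
    for _draw in range(12):
        mob_sel = _farthest_point_sample(mobile.coords, n_mob_anchors, rng)
        pairs: list[tuple[int, int]] = []
        used_fixed: list[int] = []
        for j in mob_sel:
            cand = np.flatnonzero((D[:, j] > 5.0) & (D[:, j] < 28.0))
            if cand.size == 0:
                cand = np.array([int(np.argmin(D[:, j]))])
            if used_fixed:
                spread = cdist(fixed.coords[cand],
                               fixed.coords[used_fixed]).min(axis=1)
                order = np.argsort(-spread)
            else:
                order = rng.permutation(cand.size)
            for k in order[:2]:
                if len(pairs) < n_restraints:
                    pairs.append((int(cand[k]), int(j)))
                    used_fixed.append(int(cand[k]))
        restraints = []
        for i, j in pairs[:n_restraints]:
            target = float(np.clip(D[i, j], 4.5, 29.0))
            restraints.append(DistanceRestraint(
                residue_i=int(fixed.resnums[i]),
                residue_j=int(mobile.resnums[j]),
                target_mean=target, sd=sd,
            ))
        sigma = _pose_stiffness(fixed, mobile, restraints)
        if sigma > best_sigma:
            best_sigma, best_set = sigma, restraints
        if sigma >= 0.45:
            break
    return fixed, mobile, best_set


def _pose_stiffness(fixed, mobile, restraints) -> float:
    """Smallest singular value of the restraint-distance Jacobian w.r.t.
    the 6 pose degrees of freedom at the true pose.

    A small value means the restraint set leaves a soft direction along
    which the mobile body can move without violating any distance — such a
    planted problem is not identifiable and is rejected by the generator.
    """
    c = mobile.centroid
    idx_i = fixed.index_of([r.residue_i for r in restraints])
    idx_j = mobile.index_of([r.residue_j for r in restraints])
    f = fixed.coords[idx_i]
    m = mobile.coords[idx_j]
    u = m - f
    d = np.linalg.norm(u, axis=1)
    u = u / d[:, None]
    lever = m - c
    J = np.zeros((len(restraints), 6))
    J[:, 3:] = u
    for a in range(3):
        ax = np.zeros(3)
        ax[a] = 1.0
        J[:, a] = np.einsum("kj,kj->k", u, np.cross(ax, lever))
    return float(np.linalg.svd(J, compute_uv=False)[-1])
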