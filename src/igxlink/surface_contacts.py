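"""Solvent accessibility, active-residue selection, contact maps, and
difference distance matrices.

SASA is computed with the Shrake–Rupley method: each atom is surrounded by
a deterministic golden-spiral quadrature of points on its solvent-expanded
sphere, and the accessible area is the fraction of points not buried inside
any neighbour's expanded sphere.  The package works on Cα bead models, so
each residue is one bead with an effective radius (default 3.0 Å) that
stands in for the missing side chain; relative accessibility is the bead's
SASA over the SASA of an isolated bead, which makes a fully exposed residue
score ~1 and a core residue ~0.  (With full-atom reference tables relative
values can slightly exceed 1 at termini; the bead reference is bounded by 1
by construction.)

Contact maps are Cα–Cα distance matrices with a boolean mask at a
threshold (default 40 Å — the "contact relationship" radius used for
ranking models against cross-link data).  The map-overlap score is the
fraction of unique cross-linked residue pairs falling inside the contact
mask: a monotone surrogate for published contact-map agreement scores,
sufficient for ranking candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import CrossLink, StructureModel

#: Effective bead radius for Cα-only models, Å.
CA_BEAD_RADIUS = 3.0
#: Water-probe radius, Å.
PROBE_RADIUS = 1.4


class SurfaceError(Exception):
    pass


# --------------------------------------------------------------------------
# Shrake–Rupley SASA

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


@dataclass
class AccessibilityProfile:
    """Per-residue absolute SASA (Å²) and relative accessibility."""

    residues: list[tuple[str, int, str]]   # (chain_id, resnum, aa)
    sasa: np.ndarray                       # (n,) Å²
    relative: np.ndarray                   # (n,) fraction of isolated-bead SASA
    probe_radius: float
    n_points: int
    bead_radius: float

    def as_dict(self) -> dict[tuple[str, int], float]:
        """(chain, resnum) → relative accessibility."""
        return {(c, r): float(v) for (c, r, _), v in
                zip(self.residues, self.relative)}


def shrake_rupley_sasa(
    structure: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    bead_radius: float = CA_BEAD_RADIUS,
) -> AccessibilityProfile:
    """Shrake–Rupley solvent-accessible surface area on a Cα bead model.

    Deterministic: the point quadrature is a fixed golden spiral, so the
    same structure always yields the same profile.  Residues without a Cα
    are skipped.
    """
    residues: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    for cid, chain in structure.chains.items():
        for resnum, aa, xyz in zip(chain.resnums, chain.aas, chain.coords):
            if np.any(np.isnan(xyz)):
                continue
            residues.append((cid, int(resnum), aa))
            coords.append(xyz)
    if not coords:
        raise SurfaceError("structure has no atoms with coordinates")
    xyz = np.asarray(coords)
    n = len(xyz)
    r_exp = bead_radius + probe
    pts = sphere_points(n_points) * r_exp           # template shell

    tree = cKDTree(xyz)
    sphere_area = 4.0 * np.pi * r_exp ** 2
    sasa = np.empty(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(xyz[i], 2.0 * r_exp) if j != i]
        if not neigh:
            sasa[i] = sphere_area
            continue
        shell = xyz[i] + pts                        # (m, 3)
        d2 = cdist(shell, xyz[neigh], "sqeuclidean")
        exposed = np.all(d2 > r_exp ** 2, axis=1)
        sasa[i] = sphere_area * exposed.mean()
    return AccessibilityProfile(
        residues=residues, sasa=sasa, relative=sasa / sphere_area,
        probe_radius=probe, n_points=n_points, bead_radius=bead_radius,
    )


def select_active_residues(
    profile: AccessibilityProfile,
    cutoff: float = 0.40,
    candidates: set[tuple[str, int]] | None = None,
) -> set[tuple[str, int]]:
    """Residues with relative accessibility ≥ cutoff, within a candidate set.

    These are the solvent-accessible "active" residues used (together with
    cross-linked residues) to drive information-based docking.
    """
    rel = profile.as_dict()
    if candidates is None:
        candidates = set(rel)
    else:
        candidates = set(candidates)
    if not candidates:
        raise SurfaceError("empty candidate residue set")
    return {key for key in candidates if key in rel and rel[key] >= cutoff}


# --------------------------------------------------------------------------
# contact maps

@dataclass
class ContactMap:
    """Pairwise Cα distance matrix with a boolean contact mask."""

    residues_a: list[tuple[str, int]]
    residues_b: list[tuple[str, int]]
    distances: np.ndarray      # (na, nb) Å, NaN where a Cα is absent
    mask: np.ndarray           # (na, nb) bool, distance < threshold
    threshold: float
    symmetric: bool

    def index_a(self) -> dict[tuple[str, int], int]:
        return {k: i for i, k in enumerate(self.residues_a)}

    def index_b(self) -> dict[tuple[str, int], int]:
        return {k: i for i, k in enumerate(self.residues_b)}


def _residue_coords(structure: StructureModel) -> tuple[list, np.ndarray]:
    keys, xyz = [], []
    for cid, chain in structure.chains.items():
        for resnum, c in zip(chain.resnums, chain.coords):
            keys.append((cid, int(resnum)))
            xyz.append(c)
    return keys, np.asarray(xyz, dtype=float).reshape(-1, 3)


def contact_map(
    struct_a: StructureModel,
    struct_b: StructureModel | None = None,
    threshold: float = 40.0,
) -> ContactMap:
    """Full Cα–Cα distance matrix plus a ``distance < threshold`` mask.

    With a single structure the map is the symmetric self-map (diagonal 0).
    Rows/columns of residues lacking a Cα carry NaN distances and are
    masked out.
    """
    keys_a, xyz_a = _residue_coords(struct_a)
    symmetric = struct_b is None
    keys_b, xyz_b = (keys_a, xyz_a) if symmetric else _residue_coords(struct_b)
    if not keys_a or not keys_b:
        raise SurfaceError("empty residue set; cannot build a contact map")
    d = cdist(xyz_a, xyz_b)
    mask = np.where(np.isnan(d), False, d < threshold)
    return ContactMap(residues_a=keys_a, residues_b=keys_b,
                      distances=d, mask=mask,
                      threshold=threshold, symmetric=symmetric)


def map_overlap_score(
    cmap: ContactMap,
    links: "set[tuple[str, int, str, int]] | list[CrossLink]",
    resolver=None,
) -> float:
    """Fraction of unique cross-linked residue pairs inside the contact mask.

    ``links`` is a set of canonical link keys or a list of
    :class:`CrossLink`.  ``resolver`` maps a (protein, position) endpoint to
    candidate (chain, resnum) axis keys; by default the position is taken as
    the residue number on every chain axis (single-protein maps).  A pair
    counts as in-contact if *any* of its chain-combination cells is within
    contact (the shortest-combination convention).  Links touching no axis
    cell at all are excluded; if none is mappable the score is undefined.
    """
    if not isinstance(links, (set, frozenset)):
        links = {ln.key for ln in links}
    if resolver is None:
        idx_a = cmap.index_a()
        idx_b = cmap.index_b()

        def resolver(protein: str, pos: int, axis_index: dict) -> list[int]:
            return [i for (c, r), i in axis_index.items() if r == pos]
    else:
        idx_a = cmap.index_a()
        idx_b = cmap.index_b()

    n_mappable = 0
    n_contact = 0
    for (pa, ra, pb, rb) in sorted(links):
        ia = resolver(pa, ra, idx_a)
        ib = resolver(pb, rb, idx_b)
        cells = [(i, j) for i in ia for j in ib]
        if cmap.symmetric:
            cells += [(j, i) for i in ia for j in ib
                      if 0 <= j < cmap.mask.shape[0] and 0 <= i < cmap.mask.shape[1]]
        cells = [(i, j) for (i, j) in cells
                 if not np.isnan(cmap.distances[i, j])]
        if not cells:
            continue
        n_mappable += 1
        if any(cmap.mask[i, j] for (i, j) in cells):
            n_contact += 1
    if n_mappable == 0:
        raise SurfaceError("no link mappable onto the contact map; score undefined")
    return n_contact / n_mappable


# --------------------------------------------------------------------------
# difference distance matrix

def difference_distance_matrix(
    coords_a: np.ndarray, coords_b: np.ndarray,
) -> np.ndarray:
    """Signed difference of intra-molecular distance matrices.

    ``Δ(i, j) = d_A(i, j) − d_B(i, j)`` over two matched Cα sets; being
    built from internal distances it is invariant to any rigid-body motion
    of either set and antisymmetric under operand swap.  Raw values are
    returned; use :func:`clip_for_display` for rendering.
    """
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    if coords_a.shape != coords_b.shape:
        raise SurfaceError(
            f"matched coordinate sets differ in shape: "
            f"{coords_a.shape} vs {coords_b.shape}"
        )
    return cdist(coords_a, coords_a) - cdist(coords_b, coords_b)


def clip_for_display(ddm: np.ndarray, limit: float = 20.0) -> np.ndarray:
    """Clip a difference distance matrix to ±limit for rendering only."""
    return np.clip(ddm, -limit, limit)
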