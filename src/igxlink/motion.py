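"""Quantify conformational differences between two structures.

The toolkit is the classical rigid-body one: least-squares (Kabsch)
superposition of matched Cα sets, the rotation angle of a proper rotation
matrix, inter-domain rotation/displacement between two conformations, and a
contour-length feasibility check for flexible linkers.

Angle/displacement convention (one self-consistent choice, since published
tools differ): the alternative structure is superposed onto the reference
using the *anchor* domain's Cα atoms; the inter-domain rotation angle is
then the rotation angle of the residual superposition of the *moving*
domain in that anchor-aligned frame, and the displacement is the distance
between the moving domain's centroids in the same frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rigidmodel import DomainDefinition
from .structio import StructureModel


class SuperpositionError(Exception):
    pass


class PairingError(Exception):
    pass


@dataclass
class SuperpositionResult:
    """Optimal least-squares rigid transform mapping mobile onto reference.

    Applying ``x @ rotation.T + translation`` to the mobile set yields the
    stated RMSD against the reference.
    """

    rotation: np.ndarray     # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_ref: np.ndarray,
                     coords_mobile: np.ndarray) -> SuperpositionResult:
    """Optimal least-squares superposition of two matched Cα sets.

    Uses the SVD form of the Kabsch algorithm with the standard sign fix so
    the returned rotation is always proper (det +1, never a reflection).
    Requires at least 3 non-collinear points.
    """
    P = np.asarray(coords_ref, float).reshape(-1, 3)
    Q = np.asarray(coords_mobile, float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise SuperpositionError(
            f"matched sets differ in size: {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise SuperpositionError("need at least 3 matched points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    # degenerate geometry: all points (near-)collinear leaves the rotation
    # about the line undetermined
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise SuperpositionError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, in degrees in [0, 180].

    ``θ = arccos((trace − 1) / 2)``, clamped for numerical safety.
    """
    R = np.asarray(R, float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6) \
            or np.linalg.det(R) < 0:
        raise SuperpositionError("input is not a proper orthonormal rotation")
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _domain_coords(structure: StructureModel, domain: DomainDefinition,
                   chain_id: str | None = None) -> dict[int, np.ndarray]:
    chains = ([structure.chains[chain_id]] if chain_id
              else list(structure.chains.values()))
    out: dict[int, np.ndarray] = {}
    for chain in chains:
        for rn, xyz in zip(chain.resnums, chain.coords):
            rn = int(rn)
            if rn in domain and not np.any(np.isnan(xyz)) and rn not in out:
                out[rn] = xyz
    return out


def _matched(struct_ref: StructureModel, struct_alt: StructureModel,
             domain: DomainDefinition,
             chain_id: str | None) -> tuple[np.ndarray, np.ndarray]:
    a = _domain_coords(struct_ref, domain, chain_id)
    b = _domain_coords(struct_alt, domain, chain_id)
    common = sorted(set(a) & set(b))
    missing = sorted((set(a) ^ set(b)))
    if len(common) < 3:
        raise PairingError(
            f"domain {domain.name!r}: only {len(common)} residues matched in "
            f"both structures (unmatched: {missing[:10]}{'...' if len(missing) > 10 else ''})"
        )
    return (np.array([a[r] for r in common]),
            np.array([b[r] for r in common]))


def interdomain_motion(
    struct_ref: StructureModel,
    struct_alt: StructureModel,
    anchor_domain: DomainDefinition,
    moving_domain: DomainDefinition,
    chain_id: str | None = None,
) -> tuple[float, float]:
    """Rotation angle (°) and centroid displacement (Å) of a moving domain
    between two conformations, after aligning on an anchor domain.

    The alternative structure is superposed onto the reference using the
    anchor domain's Cα atoms; the angle is the residual rotation of the
    moving domain in that frame, the displacement the centroid shift.
    Identical structures give (0, 0) for any domain pair.
    """
    ref_anchor, alt_anchor = _matched(struct_ref, struct_alt,
                                      anchor_domain, chain_id)
    sup = kabsch_superpose(ref_anchor, alt_anchor)
    ref_mov, alt_mov = _matched(struct_ref, struct_alt,
                                moving_domain, chain_id)
    alt_mov_aligned = sup.transform(alt_mov)
    residual = kabsch_superpose(ref_mov, alt_mov_aligned)
    angle = rotation_angle(residual.rotation)
    displacement = float(np.linalg.norm(
        ref_mov.mean(axis=0) - alt_mov_aligned.mean(axis=0)))
    return angle, displacement


@dataclass
class LinkerFeasibility:
    gap: float
    contour_min: float
    contour_max: float
    feasible: bool
    n_residues: int


def linker_feasibility(
    end_xyz: np.ndarray,
    start_xyz: np.ndarray,
    n_linker_residues: int,
    per_residue_min: float = 3.4,
    per_residue_max: float = 4.0,
) -> LinkerFeasibility:
    """Can an n-residue flexible linker span the gap between two points?

    The contour length of a peptide of n residues is between
    ``n × per_residue_min`` and ``n × per_residue_max`` (3.4–4.0 Å per
    residue); the gap is feasible iff it does not exceed the maximal
    contour length.
    """
    if n_linker_residues < 1:
        raise ValueError("linker must have at least one residue")
    gap = float(np.linalg.norm(np.asarray(end_xyz, float)
                               - np.asarray(start_xyz, float)))
    cmin = n_linker_residues * per_residue_min
    cmax = n_linker_residues * per_residue_max
    return LinkerFeasibility(gap=gap, contour_min=cmin, contour_max=cmax,
                             feasible=gap <= cmax,
                             n_residues=n_linker_residues)


def linker_residue_count(domain: DomainDefinition) -> int:
    """Number of residues in a linker domain definition.

    Counts positions inclusively.  Note the off-by-one trap: a linker
    bounded by flanking domains at positions s-1 and e+1 spans the range
    [s, e], i.e. e − s + 1 residues, whereas a range quoted inclusive of one
    flank has one residue more — a warning flags ranges so users can verify
    the counting convention.
    """
    n = domain.n_residues
    warnings.warn(
        f"linker {domain.name!r}: counting {n} residue(s) from inclusive "
        f"range(s) {domain.ranges}; verify the counting convention — a "
        "quoted range may include a flanking residue",
        stacklevel=2,
    )
    return n
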