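"""Restraint construction, accessible-interaction-space scanning, and
restraint-guided rigid-body docking of a mobile body against a fixed body.

The model is deliberately coarse: both bodies are Cα bead sets, a
cross-link between them becomes a flat-bottom harmonic distance restraint
(target 17 ± 2 Å between lysine Cα atoms, hard satisfaction window
3–30 Å), and the mobile body moves as a rigid unit.  The scan enumerates a
deterministic quasi-uniform set of orientations crossed with a translation
grid and reports, for every k, the number of clash-free poses consistent
with at least k restraints — the accessible interaction space.  Docking
then refines the best scan poses by derivative-free local minimisation of
the restraint energy plus a soft clash penalty, clusters the solutions by
mobile-body RMSD, and ranks them by (restraint energy, clash count).

Pose convention: a :class:`RigidPose` rotates the mobile body about its own
centroid and then translates it, ``x' = R (x − c) + c + t`` with ``c`` the
mobile centroid.  The translation therefore *is* the centroid displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structio import CrossLink


class RestraintError(Exception):
    pass


class ScanError(Exception):
    pass


class DockingError(Exception):
    pass


# --------------------------------------------------------------------------
# domain definitions and restraints

@dataclass
class DomainDefinition:
    """A named set of inclusive residue intervals in full-sequence numbering."""

    name: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.ranges)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping ranges in domain {self.name!r}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in spans:
            if e < s:
                raise ValueError(f"empty range ({s},{e}) in domain {self.name!r}")

    def __contains__(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.ranges)

    @property
    def residues(self) -> list[int]:
        out: list[int] = []
        for s, e in sorted(self.ranges):
            out.extend(range(s, e + 1))
        return out

    @property
    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom harmonic distance restraint derived from a cross-link.

    Zero energy inside ``target_mean ± sd``; the hard bounds
    ``[lower_bound, upper_bound]`` define satisfaction during the scan.
    """

    residue_i: int            # fixed body, full-sequence numbering
    residue_j: int            # mobile body
    target_mean: float = 17.0
    sd: float = 2.0
    upper_bound: float = 30.0
    lower_bound: float = 3.0

    def __post_init__(self) -> None:
        if not (self.lower_bound < self.target_mean < self.upper_bound):
            raise ValueError(
                "restraint bounds must satisfy lower < mean < upper; got "
                f"[{self.lower_bound}, {self.target_mean}, {self.upper_bound}]"
            )
        if self.sd <= 0:
            raise ValueError("restraint sd must be > 0")


def build_restraints(
    links: "list[CrossLink] | set[tuple[str, int, str, int]]",
    fixed_domain: DomainDefinition,
    mobile_domain: DomainDefinition,
    target_mean: float = 17.0,
    sd: float = 2.0,
    upper_bound: float = 30.0,
    lower_bound: float = 3.0,
) -> tuple[list[DistanceRestraint], list[tuple[int, int]]]:
    """One restraint per link bridging the fixed and mobile bodies.

    Links with both endpoints inside one body are excluded and returned as
    the second element (position pairs).  Zero inter-body links is an error:
    without restraints the scan and the docking are unconstrained.
    """
    if not isinstance(links, (set, frozenset)):
        keys = {ln.key for ln in links}
    else:
        keys = set(links)
    restraints: list[DistanceRestraint] = []
    excluded: list[tuple[int, int]] = []
    for (pa, ra, pb, rb) in sorted(keys):
        in_fixed = (ra in fixed_domain, rb in fixed_domain)
        in_mobile = (ra in mobile_domain, rb in mobile_domain)
        if in_fixed[0] and in_mobile[1]:
            restraints.append(DistanceRestraint(
                residue_i=ra, residue_j=rb, target_mean=target_mean,
                sd=sd, upper_bound=upper_bound, lower_bound=lower_bound))
        elif in_fixed[1] and in_mobile[0]:
            restraints.append(DistanceRestraint(
                residue_i=rb, residue_j=ra, target_mean=target_mean,
                sd=sd, upper_bound=upper_bound, lower_bound=lower_bound))
        else:
            excluded.append((ra, rb))
    if not restraints:
        raise RestraintError(
            f"no inter-body link between {fixed_domain.name!r} and "
            f"{mobile_domain.name!r} ({len(excluded)} intra-body link(s) excluded)"
        )
    return restraints, excluded


# --------------------------------------------------------------------------
# rigid poses

def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has det -1 (reflection)")
    return R


@dataclass
class RigidPose:
    """Rotation + translation of the mobile body (about its own centroid)."""

    rotation: np.ndarray                  # (3, 3) proper orthonormal
    translation: np.ndarray               # (3,) Å, equals centroid displacement
    n_satisfied: int = 0
    restraint_energy: float = float("nan")
    clash_count: int = 0

    def __post_init__(self) -> None:
        self.rotation = _check_rotation(self.rotation)
        self.translation = np.asarray(self.translation, float).reshape(3)

    def apply(self, coords: np.ndarray, centroid: np.ndarray | None = None) -> np.ndarray:
        coords = np.asarray(coords, float)
        c = coords.mean(axis=0) if centroid is None else np.asarray(centroid, float)
        return (coords - c) @ self.rotation.T + c + self.translation

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def quasi_uniform_rotations(n: int = 576) -> np.ndarray:
    """Deterministic quasi-uniform sample of SO(3) as (n, 3, 3) matrices.

    Uses Shoemake's mapping from the unit cube to unit quaternions driven
    by a Halton sequence — reproducible across runs and platforms, and
    asymptotically uniform on the rotation group.
    """
    if n < 1:
        raise ValueError("need at least one orientation")

    def halton(index: np.ndarray, base: int) -> np.ndarray:
        out = np.zeros_like(index, dtype=float)
        f = 1.0
        i = index.astype(int).copy()
        while np.any(i > 0):
            f /= base
            out += f * (i % base)
            i //= base
        return out

    idx = np.arange(1, n + 1)
    u1 = halton(idx, 2)
    u2 = halton(idx, 3)
    u3 = halton(idx, 5)
    # Shoemake: uniform unit quaternions from three uniforms
    q = np.stack([
        np.sqrt(1.0 - u1) * np.sin(2.0 * np.pi * u2),
        np.sqrt(1.0 - u1) * np.cos(2.0 * np.pi * u2),
        np.sqrt(u1) * np.sin(2.0 * np.pi * u3),
        np.sqrt(u1) * np.cos(2.0 * np.pi * u3),
    ], axis=1)
    w, x, y, z = q[:, 3], q[:, 0], q[:, 1], q[:, 2]
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


# --------------------------------------------------------------------------
# coordinate bundles

@dataclass
class Body:
    """Residue-numbered Cα coordinates of one rigid body."""

    resnums: np.ndarray        # (n,) int, full-sequence numbering
    coords: np.ndarray         # (n, 3) Å

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, int)
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.resnums) != len(self.coords):
            raise ValueError("resnums and coords length mismatch")
        self._index = {int(r): i for i, r in enumerate(self.resnums)}

    def __len__(self) -> int:
        return len(self.resnums)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def radius(self) -> float:
        return float(np.linalg.norm(self.coords - self.centroid, axis=1).max())

    def index_of(self, resnums: list[int], label: str = "body") -> np.ndarray:
        missing = [r for r in resnums if r not in self._index]
        if missing:
            raise RestraintError(
                f"restraint residue(s) {missing} missing from {label}"
            )
        return np.array([self._index[r] for r in resnums], int)

    @classmethod
    def from_structure(cls, structure, domain: DomainDefinition | None = None,
                       chain_id: str | None = None) -> "Body":
        """Extract a body from a structure, optionally limited to a domain."""
        resnums, coords = [], []
        chains = ([structure.chains[chain_id]] if chain_id
                  else list(structure.chains.values()))
        for chain in chains:
            for rn, xyz in zip(chain.resnums, chain.coords):
                if np.any(np.isnan(xyz)):
                    continue
                if domain is not None and int(rn) not in domain:
                    continue
                resnums.append(int(rn))
                coords.append(xyz)
        if not resnums:
            raise RestraintError("no residues selected for the body")
        return cls(resnums=np.array(resnums), coords=np.array(coords))


# --------------------------------------------------------------------------
# restraint energy

def restraint_energy(
    pose: RigidPose,
    restraints: list[DistanceRestraint],
    fixed: Body,
    mobile: Body,
) -> tuple[float, np.ndarray]:
    """Flat-bottom harmonic restraint energy of a pose.

    ``E = Σ_k ((max(0, |d_k − mean| − sd)) / sd)²`` over restraints; zero iff
    every distance lies within ``mean ± sd``.  Returns the energy and the
    per-restraint distances.
    """
    if not restraints:
        raise RestraintError("no restraints given")
    idx_i = fixed.index_of([r.residue_i for r in restraints], "fixed body")
    idx_j = mobile.index_of([r.residue_j for r in restraints], "mobile body")
    moved = pose.apply(mobile.coords, centroid=mobile.centroid)
    d = np.linalg.norm(fixed.coords[idx_i] - moved[idx_j], axis=1)
    mean = np.array([r.target_mean for r in restraints])
    sd = np.array([r.sd for r in restraints])
    viol = np.maximum(0.0, np.abs(d - mean) - sd) / sd
    return float(np.sum(viol ** 2)), d


def count_clashes(fixed: Body, mobile_coords: np.ndarray,
                  clash_dist: float = 3.0) -> int:
    """Number of mobile beads closer than ``clash_dist`` to any fixed bead."""
    tree = cKDTree(fixed.coords)
    d, _ = tree.query(mobile_coords)
    return int(np.sum(d < clash_dist))


# --------------------------------------------------------------------------
# accessible interaction space scan

@dataclass
class ScanResult:
    """Outcome of the exhaustive rotation × translation scan."""

    n_consistent: np.ndarray       # (K+1,) N_k = clash-free poses with >= k satisfied
    n_by_exact_k: np.ndarray       # (K+1,) clash-free poses with exactly k satisfied
    n_total_poses: int             # rotations x surviving grid points
    n_clash_free: int
    best_poses: list[RigidPose]    # top poses by (satisfied desc, energy asc)
    grid_spacing: float
    n_orientations: int


def accessible_interaction_scan(
    fixed: Body,
    mobile: Body,
    restraints: list[DistanceRestraint],
    n_orientations: int = 576,
    grid_spacing: float = 2.0,
    clash_dist: float = 3.0,
    max_best: int = 32,
    rotations: np.ndarray | None = None,
    max_radius: float | None = None,
) -> ScanResult:
    """Exhaustive rigid-body scan of the accessible interaction space.

    Orientations come from :func:`quasi_uniform_rotations`; mobile-centroid
    positions from a cubic grid (spacing ``grid_spacing``) over a shell
    around the fixed body sized from both body radii plus the largest
    restraint upper bound.  Grid points that cannot geometrically satisfy
    any restraint are pruned before rotations are tried.  Per pose the
    number of restraints with distance inside their hard bounds is counted
    and poses with any inter-body clash are rejected.
    """
    if not restraints:
        raise ScanError("scan requires at least one restraint")
    K = len(restraints)
    idx_i = fixed.index_of([r.residue_i for r in restraints], "fixed body")
    idx_j = mobile.index_of([r.residue_j for r in restraints], "mobile body")
    lower = np.array([r.lower_bound for r in restraints])
    upper = np.array([r.upper_bound for r in restraints])

    if rotations is None:
        rotations = quasi_uniform_rotations(n_orientations)
    else:
        rotations = np.asarray(rotations, float)
        n_orientations = len(rotations)

    c_m = mobile.centroid
    mobile_rel = mobile.coords - c_m                      # (n, 3)
    anchor_len = np.linalg.norm(mobile_rel[idx_j], axis=1)  # (K,)
    f_anchor = fixed.coords[idx_i]                        # (K, 3)

    # candidate centroid grid over a shell around the fixed body
    c_f = fixed.centroid
    reach = fixed.radius() + mobile.radius() + float(upper.max())
    if max_radius is not None:
        reach = min(reach, float(max_radius))
    ax = np.arange(-reach, reach + grid_spacing / 2, grid_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + c_f

    # prune: a centroid can satisfy restraint k only if the sphere of the
    # anchor's lever arm intersects the [lower, upper] annulus around f_k
    d_anchor = np.linalg.norm(grid[:, None, :] - f_anchor[None, :, :], axis=2)
    feasible_any = np.any(
        (d_anchor >= (lower - anchor_len)[None, :]) &
        (d_anchor <= (upper + anchor_len)[None, :]), axis=1)
    grid = grid[feasible_any]
    if len(grid) == 0:
        raise ScanError("translation grid too tight: no feasible centroid")

    rotated = np.einsum("mij,nj->mni", rotations, mobile_rel)  # (m, n, 3)
    rot_anchor = rotated[:, idx_j, :]                          # (m, K, 3)

    mean = np.array([r.target_mean for r in restraints])
    sd = np.array([r.sd for r in restraints])
    clash2 = clash_dist ** 2
    fx = fixed.coords
    G, M = len(grid), len(rotations)

    # restraint satisfaction and flat-bottom energy for every grid x rotation
    sat = np.empty((G, M), dtype=np.int32)
    energy = np.empty((G, M))
    gchunk = max(1, int(4_000_000 // max(1, M * K)))
    for s in range(0, G, gchunk):
        g = grid[s:s + gchunk]                                    # (gc, 3)
        d = np.linalg.norm(
            rot_anchor[None, :, :, :] + g[:, None, None, :]
            - f_anchor[None, None, :, :], axis=-1)                # (gc, M, K)
        sat[s:s + gchunk] = ((d >= lower) & (d <= upper)).sum(axis=-1)
        viol = np.maximum(0.0, np.abs(d - mean) - sd) / sd
        energy[s:s + gchunk] = np.sum(viol ** 2, axis=-1)

    # clash detection only where the bounding spheres can touch;
    # |p - f|^2 = |p|^2 + |f|^2 - 2 p.f via one GEMM per grid point
    clash = np.zeros((G, M), dtype=bool)
    contact_reach = fixed.radius() + mobile.radius() + clash_dist
    near = np.linalg.norm(grid - c_f, axis=1) <= contact_reach
    fx2 = np.einsum("ij,ij->i", fx, fx)
    n_mob = len(mobile)
    for gi in np.flatnonzero(near):
        pts = (rotated + grid[gi]).reshape(-1, 3)                 # (M*n, 3)
        d2 = (np.einsum("ij,ij->i", pts, pts)[:, None] + fx2[None, :]
              - 2.0 * (pts @ fx.T))
        clash[gi] = (d2 < clash2).any(axis=1).reshape(M, n_mob).any(axis=1)

    ok = ~clash
    n_clash_free = int(ok.sum())
    if n_clash_free == 0:
        raise ScanError("no clash-free pose in the scan (grids too tight)")
    counts_exact = np.bincount(sat[ok].ravel(), minlength=K + 1)

    # top clash-free poses by (satisfied desc, energy asc), kept diverse:
    # a pose only enters the list if it differs from every kept pose by at
    # least one grid step in translation or a clear rotation angle, so the
    # best set seeds distinct basins rather than one basin's neighbours
    flat_ok = ok.ravel()
    order = np.lexsort((energy.ravel(), -sat.ravel()))
    order = order[flat_ok[order]]
    best_poses: list[RigidPose] = []
    for f in order:
        if len(best_poses) >= max_best:
            break
        gi, mi = divmod(int(f), M)
        t = grid[gi] - c_m
        R = rotations[mi]
        distinct = True
        for p in best_poses:
            if np.linalg.norm(p.translation - t) >= grid_spacing:
                continue
            cos_ang = (np.trace(p.rotation.T @ R) - 1.0) / 2.0
            if np.degrees(np.arccos(np.clip(cos_ang, -1, 1))) < 15.0:
                distinct = False
                break
        if distinct:
            best_poses.append(RigidPose(
                rotation=R.copy(), translation=t,
                n_satisfied=int(sat[gi, mi]),
                restraint_energy=float(energy[gi, mi]),
                clash_count=0))
    n_consistent = np.array([counts_exact[k:].sum() for k in range(K + 2)][:K + 1])
    return ScanResult(
        n_consistent=n_consistent,
        n_by_exact_k=counts_exact,
        n_total_poses=len(grid) * len(rotations),
        n_clash_free=n_clash_free,
        best_poses=best_poses,
        grid_spacing=grid_spacing,
        n_orientations=len(rotations),
    )


# --------------------------------------------------------------------------
# rigid-body docking

def rotation_grid_starts(
    fixed: Body,
    mobile: Body,
    restraints: list[DistanceRestraint],
    n_orientations: int = 192,
    n_starts: int = 12,
) -> list[RigidPose]:
    """Start poses from an orientation grid with per-orientation optimal
    translation.

    For every quasi-uniform orientation the translation minimising the
    harmonic restraint misfit is solved by least squares (3 unknowns, one
    residual per restraint) — unlike a translation grid this has no spatial
    resolution limit, so an orientation within the grid's angular step of
    the truth yields a start inside the true basin.  The best ``n_starts``
    orientations by harmonic misfit are returned (clashes are left to the
    docking stage's penalty).
    """
    from scipy.optimize import least_squares

    if not restraints:
        raise DockingError("need at least one restraint")
    idx_i = fixed.index_of([r.residue_i for r in restraints], "fixed body")
    idx_j = mobile.index_of([r.residue_j for r in restraints], "mobile body")
    f_anchor = fixed.coords[idx_i]
    mean_t = np.array([r.target_mean for r in restraints])
    sd_t = np.array([r.sd for r in restraints])
    c_m = mobile.centroid
    mob_rel = mobile.coords - c_m
    rotations = quasi_uniform_rotations(n_orientations)

    scored: list[tuple[float, int, np.ndarray]] = []
    for mi, R in enumerate(rotations):
        anchors = mob_rel[idx_j] @ R.T + c_m            # anchors at t = 0

        def residuals(t: np.ndarray, anchors=anchors) -> np.ndarray:
            d = np.linalg.norm(f_anchor - (anchors + t), axis=1)
            return (d - mean_t) / sd_t

        t0 = (f_anchor - anchors).mean(axis=0)
        sol = least_squares(residuals, t0, method="lm", max_nfev=60)
        scored.append((float(np.sum(sol.fun ** 2)), mi, sol.x))
    scored.sort(key=lambda s: (s[0], s[1]))
    return [RigidPose(rotation=rotations[mi].copy(), translation=t,
                      restraint_energy=misfit)
            for misfit, mi, t in scored[:n_starts]]


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    Kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * Kx + (1 - np.cos(theta)) * (Kx @ Kx)


def _soft_clash_penalty(fixed_tree: cKDTree, coords: np.ndarray,
                        clash_dist: float) -> float:
    d, _ = fixed_tree.query(coords, distance_upper_bound=clash_dist)
    close = d[np.isfinite(d)]
    if close.size == 0:
        return 0.0
    return float(np.sum(((clash_dist - close) / clash_dist) ** 2))


@dataclass
class DockResult:
    poses: list[RigidPose]         # ranked by (restraint_energy, clash_count)
    clusters: list[list[int]]      # indices into ``poses`` per RMSD cluster
    per_start: list[dict]          # diagnostics per start pose


def rigid_dock(
    fixed: Body,
    mobile: Body,
    restraints: list[DistanceRestraint],
    start_poses: list[RigidPose],
    clash_dist: float = 3.0,
    clash_weight: float = 10.0,
    cluster_rmsd: float = 5.0,
    maxiter: int = 400,
    early_stop_energy: float | None = 1e-9,
) -> DockResult:
    """Refine start poses by local minimisation of the docking objective.

    The objective is the flat-bottom restraint energy plus a soft quadratic
    clash penalty.  Minimisation is derivative-free (Powell) over a 6-vector
    (rotation-vector delta, translation delta) relative to each start, hence
    deterministic for fixed starts.  If refinement would raise the pure
    restraint energy above its start value the start pose is kept instead.
    Solutions are clustered greedily by mobile-body RMSD and ranked by
    (restraint energy, clash count).
    """
    if not start_poses:
        raise DockingError("no start poses given")
    fixed_tree = cKDTree(fixed.coords)
    c_m = mobile.centroid
    mob_rel = mobile.coords - c_m
    idx_i = fixed.index_of([r.residue_i for r in restraints], "fixed body")
    idx_j = mobile.index_of([r.residue_j for r in restraints], "mobile body")
    f_anchor = fixed.coords[idx_i]
    mean_t = np.array([r.target_mean for r in restraints])
    sd_t = np.array([r.sd for r in restraints])

    refined: list[RigidPose] = []
    rms_final: list[float] = []
    per_start: list[dict] = []
    n_converged = 0
    for start in start_poses:
        R0, t0 = start.rotation, start.translation

        def _distances_and_coords(x: np.ndarray):
            R = _rotvec_to_matrix(x[:3]) @ R0
            coords = mob_rel @ R.T + c_m + t0 + x[3:]
            d = np.linalg.norm(f_anchor - coords[idx_j], axis=1)
            return d, coords

        def objective(x: np.ndarray) -> float:
            d, coords = _distances_and_coords(x)
            viol = np.maximum(0.0, np.abs(d - mean_t) - sd_t) / sd_t
            return float(np.sum(viol ** 2)) + clash_weight * \
                _soft_clash_penalty(fixed_tree, coords, clash_dist)

        def harmonic(x: np.ndarray) -> float:
            # inside the flat bottom the energy gives no pull, so this
            # polish stage draws the pose toward the exact targets
            d, coords = _distances_and_coords(x)
            return float(np.sum(((d - mean_t) / sd_t) ** 2)) + \
                clash_weight * _soft_clash_penalty(fixed_tree, coords, clash_dist)

        res = minimize(objective, np.zeros(6), method="Powell",
                       options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-8})
        res2 = minimize(harmonic, res.x, method="Powell",
                        options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-8})
        # keep the polish only if it does not leave the flat-bottom optimum
        if objective(res2.x) <= objective(res.x) + 1e-9:
            res.x = res2.x
        R = _rotvec_to_matrix(res.x[:3]) @ R0
        # re-orthonormalise accumulated numerical drift
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:
            u[:, -1] *= -1
            R = u @ vt
        cand = RigidPose(rotation=R, translation=t0 + res.x[3:])
        e_cand, d_cand = restraint_energy(cand, restraints, fixed, mobile)
        e_start, _ = restraint_energy(start, restraints, fixed, mobile)
        if e_cand > e_start:           # refinement must not worsen the restraints
            cand = RigidPose(rotation=R0.copy(), translation=t0.copy())
            e_cand, d_cand = e_start, None
        coords = cand.apply(mobile.coords, centroid=c_m)
        cand.restraint_energy = e_cand
        cand.clash_count = count_clashes(fixed, coords, clash_dist)
        d_final = restraint_energy(cand, restraints, fixed, mobile)[1]
        cand.n_satisfied = int(sum(
            r.lower_bound <= dd <= r.upper_bound
            for r, dd in zip(restraints, d_final)))
        refined.append(cand)
        rms_final.append(float(np.sqrt(np.mean((d_final - mean_t) ** 2))))
        # once a clash-free pose sits essentially exactly on every
        # restraint target, no further start can rank higher
        if early_stop_energy is not None and cand.clash_count == 0 \
                and e_cand <= early_stop_energy \
                and rms_final[-1] <= 0.2 * float(np.min(sd_t)):
            n_converged += bool(res.success)
            per_start.append({"success": bool(res.success),
                              "n_evaluations": int(res.nfev),
                              "final_objective": float(res.fun),
                              "early_stop": True})
            break
        n_converged += bool(res.success)
        per_start.append({"success": bool(res.success),
                          "n_evaluations": int(res.nfev),
                          "final_objective": float(res.fun)})
    if n_converged == 0:
        raise DockingError(
            f"optimizer converged on none of {len(start_poses)} starts; "
            f"diagnostics: {per_start}"
        )

    # rank by (energy, clash), breaking flat-bottom ties by the RMS
    # deviation from the restraint targets: inside the zero-energy plateau
    # the RMS still measures agreement with the restraints
    order = sorted(range(len(refined)),
                   key=lambda i: (round(refined[i].restraint_energy, 9),
                                  refined[i].clash_count, rms_final[i]))
    poses = [refined[i] for i in order]

    # greedy RMSD clustering on the ranked list
    placed = [p.apply(mobile.coords, centroid=c_m) for p in poses]
    clusters: list[list[int]] = []
    for i, coords in enumerate(placed):
        for cluster in clusters:
            rep = placed[cluster[0]]
            rmsd = float(np.sqrt(np.mean(np.sum((coords - rep) ** 2, axis=1))))
            if rmsd < cluster_rmsd:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    return DockResult(poses=poses, clusters=clusters, per_start=per_start)


# --------------------------------------------------------------------------
# model selection

@dataclass
class SelectionResult:
    best_index: int
    table: list[dict]
    tie: bool


def select_model(
    candidates: list[tuple[Body, Body]],
    restraints: list[DistanceRestraint],
    contact_threshold: float = 40.0,
) -> SelectionResult:
    """Rank candidate (fixed, placed-mobile) models against the restraints.

    Each candidate is scored by (a) the map-overlap fraction — the share of
    restraint residue pairs whose Cα–Cα distance is below the contact
    threshold — and (b) the RMS deviation of restraint distances from their
    target mean.  Best is lexicographic: higher overlap, then lower RMS.
    Ties are reported and broken by stable input order.
    """
    if not candidates:
        raise DockingError("no candidate models to select from")
    rows: list[dict] = []
    for i, (fixed, mobile) in enumerate(candidates):
        _, d = restraint_energy(RigidPose.identity(), restraints, fixed, mobile)
        rms = float(np.sqrt(np.mean(
            (d - np.array([r.target_mean for r in restraints])) ** 2)))
        overlap = float(np.mean(d < contact_threshold))
        rows.append({"candidate": i, "overlap_score": overlap,
                     "restraint_rms": rms,
                     "mean_restraint_distance": float(d.mean())})
    order = sorted(range(len(rows)),
                   key=lambda i: (-rows[i]["overlap_score"],
                                  rows[i]["restraint_rms"], i))
    best = order[0]
    tie = len(order) > 1 and (
        rows[order[1]]["overlap_score"] == rows[best]["overlap_score"]
        and rows[order[1]]["restraint_rms"] == rows[best]["restraint_rms"])
    return SelectionResult(best_index=best, table=rows, tie=tie)
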