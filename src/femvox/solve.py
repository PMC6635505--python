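"""Displacement-controlled nonlinear FE solution of the voxel model.

Small-strain, 8-node hexahedral elements with 2×2×2 Gauss integration on an
axis-aligned voxel grid.  Loading mimics the one-legged-stance experiment: a
reference node at the mean position of the cranial-most plate layer is
rigidly coupled to that layer, its vertical translation is prescribed
(default −5 mm compression) while its horizontal translations and all
rotations are free (the experimental axle bearing); the distal shaft nodes
are fully fixed.  The nonlinear material response (scalar damage) is solved
per displacement increment by a damped secant fixed-point iteration with
adaptive increment halving, using one sparse direct factorization per
iteration.

All voxel elements share one geometry, so each element stiffness is a
weighted sum of eight precomputed per-Gauss-point unit matrices with weights
E·(1 − D) — assembly is a few einsums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, splu

from .material import MaterialParams, damage_stress_update, stiffness_matrix
from .mesh import (EmbeddingConfig, HexMesh, MATERIAL_BONE, MATERIAL_PU,
                   MATERIAL_STEEL)

__all__ = [
    "BoundaryConditions",
    "LoadDisplacementCurve",
    "DamageField",
    "SolverError",
    "hex_gauss_data",
    "make_boundary_conditions",
    "assemble",
    "solve_nonlinear",
]

_GP = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
               dtype=float) / np.sqrt(3.0)
_CORNER_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


class SolverError(RuntimeError):
    pass


def hex_gauss_data(spacing) -> tuple[np.ndarray, float]:
    """B matrices (8 gp, 6, 24) and integration weight (detJ, weight 1) for an
    axis-aligned hexahedron with edge lengths ``spacing``."""
    hx, hy, hz = (float(s) for s in np.broadcast_to(spacing, (3,)))
    detJ = hx * hy * hz / 8.0
    B = np.zeros((8, 6, 24))
    for g, (xi, eta, zeta) in enumerate(_GP):
        for a in range(8):
            sx, sy, sz = _CORNER_SIGNS[a]
            dNdx = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta) * 2.0 / hx
            dNdy = 0.125 * (1 + sx * xi) * sy * (1 + sz * zeta) * 2.0 / hy
            dNdz = 0.125 * (1 + sx * xi) * (1 + sy * eta) * sz * 2.0 / hz
            c = 3 * a
            B[g, 0, c + 0] = dNdx
            B[g, 1, c + 1] = dNdy
            B[g, 2, c + 2] = dNdz
            B[g, 3, c + 1] = dNdz
            B[g, 3, c + 2] = dNdy
            B[g, 4, c + 0] = dNdz
            B[g, 4, c + 2] = dNdx
            B[g, 5, c + 0] = dNdy
            B[g, 5, c + 1] = dNdx
    return B, detJ


@dataclass
class LoadDisplacementCurve:
    displacement: np.ndarray  # mm, 0 → prescribed (negative = compression)
    reaction: np.ndarray  # kN, vertical reaction at the reference point
    truncated: bool = False

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"displacement_mm": self.displacement,
                      "force_kN": self.reaction}).to_csv(path, index=False)


@dataclass
class DamageField:
    """Per-element mean damage per recorded increment, rows = increments."""

    D: np.ndarray  # (n_increments + 1, n_elements) float32

    def peak_increment(self, curve: LoadDisplacementCurve) -> int:
        return int(np.argmax(np.abs(curve.reaction)))


@dataclass
class BoundaryConditions:
    """Fixed dofs + rigid coupling of a node set to a reference point.

    The reference point sits at the mean position of the coupled nodes; its
    vertical (z) translation is prescribed, the remaining 5 rigid-body dofs
    are free.  ``extra_prescribed`` allows plain per-dof Dirichlet values for
    benchmark problems.
    """

    fixed_dofs: np.ndarray
    coupled_nodes: np.ndarray | None
    reference_point: np.ndarray | None
    prescribed_displacement: float = -5.0
    extra_prescribed: dict[int, float] = field(default_factory=dict)


def make_boundary_conditions(
    mesh: HexMesh, prescribed_displacement: float = -5.0
) -> BoundaryConditions:
    """Stance BCs: distal bottom node layer fully fixed; cranial-most plate
    node layer rigidly coupled to a reference point with prescribed vertical
    displacement."""
    sz = mesh.spacing[2]
    plate_el = np.flatnonzero(mesh.material == MATERIAL_STEEL)
    if len(plate_el) == 0:
        raise SolverError("mesh has no identifiable cranial steel plate")
    plate_nodes = np.unique(mesh.elements[plate_el])
    z = mesh.nodes[:, 2]
    z_top = z[plate_nodes].max()
    coupled = plate_nodes[z[plate_nodes] > z_top - 0.5 * sz]
    z_bot = z.min()
    bottom_nodes = np.flatnonzero(z < z_bot + 0.5 * sz)
    fixed = (3 * bottom_nodes[:, None] + np.arange(3)[None, :]).ravel()
    ref = mesh.nodes[coupled].mean(axis=0)
    return BoundaryConditions(
        fixed_dofs=fixed,
        coupled_nodes=coupled,
        reference_point=ref,
        prescribed_displacement=prescribed_displacement,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class _Model:
    """Precomputed structures: per-gp unit stiffness, dof maps, transform T."""

    def __init__(self, mesh: HexMesh, params: MaterialParams,
                 embedding: EmbeddingConfig | None = None,
                 distal_elastic_layers: int = 0):
        self.mesh = mesh
        self.params = params
        emb = embedding or EmbeddingConfig()
        self.B, self.detJ = hex_gauss_data(mesh.spacing)

        # per-element undamaged modulus and strengths; PU/steel never damage
        n_e = mesh.n_elements
        self.E = np.empty(n_e)
        self.nu = np.empty(n_e)
        bone = mesh.material == MATERIAL_BONE
        rho = np.where(np.isnan(mesh.rho), 1.0, mesh.rho)
        self.E[bone] = params.E0 * rho[bone] ** params.p_exp
        self.nu[bone] = params.nu
        pu = mesh.material == MATERIAL_PU
        steel = mesh.material == MATERIAL_STEEL
        self.E[pu], self.nu[pu] = emb.E_pu, emb.nu_pu
        self.E[steel], self.nu[steel] = emb.E_steel, emb.nu_steel
        self.can_damage = bone.copy()
        if distal_elastic_layers > 0:
            # distal shaft sits inside the experimental embedding; keep those
            # element layers elastic so the clamped boundary cannot damage
            zc = mesh.element_centers()[:, 2]
            z0 = mesh.nodes[:, 2].min()
            self.can_damage &= zc > z0 + distal_elastic_layers * mesh.spacing[2]
        self.syc = np.where(bone, params.strength(rho, tension=False), np.inf)
        self.syt = np.where(bone, params.strength(rho, tension=True), np.inf)

        # per-gp unit stiffness per distinct Poisson ratio
        self.Kgp_by_nu: dict[float, np.ndarray] = {}
        for nu in np.unique(self.nu):
            C = stiffness_matrix(1.0, float(nu))
            Kgp = np.einsum("gci,cd,gdj->gij", self.B, C, self.B) * self.detJ
            self.Kgp_by_nu[float(nu)] = Kgp
        self.nu_group = {float(nu): np.flatnonzero(self.nu == nu)
                         for nu in np.unique(self.nu)}

        self.edofs = (3 * mesh.elements[:, :, None]
                      + np.arange(3)[None, None, :]).reshape(n_e, 24)
        self.rows = np.repeat(self.edofs, 24, axis=1).ravel()
        self.cols = np.tile(self.edofs, (1, 24)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def stiffness(self, D: np.ndarray) -> sparse.csr_matrix:
        """Secant stiffness with per-gp damage D (n_e, 8)."""
        w = self.E[:, None] * (1.0 - D)  # (n_e, 8)
        data = np.zeros((self.mesh.n_elements, 24, 24))
        for nu, idx in self.nu_group.items():
            Kgp = self.Kgp_by_nu[nu]
            data[idx] = np.einsum("eg,gij->eij", w[idx], Kgp)
        K = sparse.coo_matrix((data.ravel(), (self.rows, self.cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        return K

    def strains(self, u: np.ndarray) -> np.ndarray:
        """Gauss-point strains (n_e, 8, 6) from the full dof vector."""
        ue = u[self.edofs]  # (n_e, 24)
        return np.einsum("gck,ek->egc", self.B, ue)

    def damage_update(self, eps: np.ndarray, D_committed: np.ndarray) -> np.ndarray:
        """Trial damage from strains, floored by the committed history."""
        n_e = self.mesh.n_elements
        flat = eps.reshape(n_e * 8, 6)
        E = np.repeat(self.E, 8)
        syc = np.repeat(self.syc, 8)
        syt = np.repeat(self.syt, 8)
        _, D_new, _ = damage_stress_update(flat, D_committed.ravel(), E, syc, syt,
                                           self.params)
        D_new = D_new.reshape(n_e, 8)
        D_new[~self.can_damage] = 0.0
        return D_new

    def internal_force(self, eps: np.ndarray, D: np.ndarray) -> np.ndarray:
        """Global internal force from per-gp strains and damage (secant law)."""
        n_e = self.mesh.n_elements
        flat = eps.reshape(n_e * 8, 6)
        E = np.repeat(self.E, 8)
        nu = np.repeat(self.nu, 8)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        stress = np.empty_like(flat)
        tr = flat[:, :3].sum(axis=1)
        stress[:, :3] = (lam * tr)[:, None] + 2 * mu[:, None] * flat[:, :3]
        stress[:, 3:] = mu[:, None] * flat[:, 3:]
        stress *= (1.0 - D.reshape(n_e * 8))[:, None]
        sg = stress.reshape(n_e, 8, 6)
        fe = np.einsum("gck,egc->ek", self.B, sg) * self.detJ  # (n_e, 24)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f


def assemble(
    mesh: HexMesh,
    params: MaterialParams,
    D: np.ndarray | None = None,
    embedding: EmbeddingConfig | None = None,
) -> sparse.csr_matrix:
    """Assembled global secant stiffness (symmetric sparse, 3 dof/node).

    ``D`` is per-gp damage (n_e, 8); omitted = undamaged.  Raises on a
    structurally disconnected mesh only at solve time (factorization).
    """
    model = _Model(mesh, params, embedding)
    if D is None:
        D = np.zeros((mesh.n_elements, 8))
    return model.stiffness(np.asarray(D, dtype=float))


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


def _build_transform(model: _Model, bcs: BoundaryConditions):
    """Sparse T with u_full = T @ q, q = [free dofs..., master dofs].

    Fixed dofs get zero rows.  If a rigid coupling is present, the last six
    reduced dofs are the master translations/rotations (ux, uy, uz, rx, ry,
    rz) and the prescribed dof is the master uz; otherwise prescribed values
    come from ``extra_prescribed``.
    """
    ndof = model.ndof
    fixed = np.zeros(ndof, dtype=bool)
    fixed[np.asarray(bcs.fixed_dofs, dtype=int)] = True
    slave = np.zeros(ndof, dtype=bool)
    if bcs.coupled_nodes is not None:
        cd = (3 * np.asarray(bcs.coupled_nodes)[:, None] + np.arange(3)).ravel()
        slave[cd] = True
    if (fixed & slave).any():
        raise SolverError("fixed and coupled dof sets overlap")
    regular = ~(fixed | slave)
    reg_ids = np.flatnonzero(regular)
    n_reg = len(reg_ids)
    n_master = 6 if bcs.coupled_nodes is not None else 0
    nred = n_reg + n_master

    rows = [reg_ids]
    cols = [np.arange(n_reg)]
    vals = [np.ones(n_reg)]
    if bcs.coupled_nodes is not None:
        ref = np.asarray(bcs.reference_point, dtype=float)
        r = model.mesh.nodes[np.asarray(bcs.coupled_nodes)] - ref  # (m, 3)
        m = len(r)
        base = n_reg
        # u_s = u_m + theta × r_s  (small rotations)
        for comp in range(3):
            rows.append(3 * np.asarray(bcs.coupled_nodes) + comp)
            cols.append(np.full(m, base + comp))
            vals.append(np.ones(m))
        # rotation contributions: (theta × r)_x = ty*rz - tz*ry, etc.
        cross = {
            0: [(4, r[:, 2]), (5, -r[:, 1])],
            1: [(3, -r[:, 2]), (5, r[:, 0])],
            2: [(3, r[:, 1]), (4, -r[:, 0])],
        }
        for comp, terms in cross.items():
            for master_off, coef in terms:
                rows.append(3 * np.asarray(bcs.coupled_nodes) + comp)
                cols.append(np.full(m, base + master_off))
                vals.append(coef)
    T = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, nred)).tocsr()

    prescribed: dict[int, float] = {}
    if bcs.coupled_nodes is not None:
        prescribed[n_reg + 2] = 1.0  # master uz carries the load factor
    for dof, val in bcs.extra_prescribed.items():
        if fixed[dof] or slave[dof]:
            raise SolverError("extra prescribed dof is fixed or coupled")
        red = int(np.searchsorted(reg_ids, dof))
        prescribed[red] = val
    return T, prescribed, n_reg


def solve_nonlinear(
    mesh: HexMesh,
    params: MaterialParams,
    bcs: BoundaryConditions,
    n_increments: int = 50,
    tol: float = 1e-6,
    d_tol: float = 1e-7,
    max_iter: int = 60,
    max_halvings: int = 4,
    dD_max: float = 0.2,
    embedding: EmbeddingConfig | None = None,
    distal_elastic_layers: int = 2,
    verbose: bool = False,
) -> tuple[LoadDisplacementCurve, DamageField]:
    """Incremental solution to the full prescribed displacement.

    Per increment, the damage fixed point is iterated with the secant
    stiffness; an increment that fails to converge is halved, up to
    ``max_halvings`` levels, after which the run is returned truncated
    (flagged on the curve).  Damage growth per increment is rate-limited to
    ``dD_max`` per integration point (a viscous-delay-style regularization
    that keeps the displacement-controlled solution from jumping over the
    quasi-static post-peak branch at localization).  The solver is
    deterministic.
    """
    if n_increments < 1:
        raise SolverError("need at least one increment")
    model = _Model(mesh, params, embedding,
                   distal_elastic_layers=distal_elastic_layers)
    T, prescribed, n_reg = _build_transform(model, bcs)
    nred = T.shape[1]
    pres_ids = np.array(sorted(prescribed.keys()), dtype=int)
    pres_scale = np.array([prescribed[i] for i in pres_ids])
    free = np.setdiff1d(np.arange(nred), pres_ids)
    u_total = bcs.prescribed_displacement

    D_committed = np.zeros((mesh.n_elements, 8))
    disp = [0.0]
    reac = [0.0]
    D_hist = [np.zeros(mesh.n_elements, dtype=np.float32)]
    truncated = False

    targets = list(u_total * (np.arange(1, n_increments + 1) / n_increments))
    current = 0.0
    halvings = 0
    force_scale = 0.0
    linsolver = _LinearSolver()
    while targets:
        target = targets[0]
        ok, reaction, D_committed_new, n_iter = _solve_step(
            model, T, free, pres_ids, pres_scale, target, D_committed,
            tol, d_tol, max_iter, dD_max, linsolver, force_scale)
        force_scale = max(force_scale, abs(reaction))
        if ok:
            targets.pop(0)
            D_committed = D_committed_new
            current = target
            disp.append(target)
            reac.append(reaction / 1000.0)  # N → kN
            D_hist.append(D_committed.mean(axis=1).astype(np.float32))
            halvings = 0
            if verbose:
                print(f"  u = {target:+.3f} mm  F = {reaction / 1000.0:+.4f} kN"
                      f"  ({n_iter} iterations)")
        else:
            if halvings >= max_halvings:
                truncated = True
                break
            mid = 0.5 * (current + target)
            targets.insert(0, mid)
            halvings += 1

    curve = LoadDisplacementCurve(
        displacement=np.array(disp), reaction=np.array(reac), truncated=truncated)
    return curve, DamageField(D=np.array(D_hist))


class _LinearSolver:
    """Direct factorization, reused as a CG preconditioner while it stays
    effective; refactorized when the damaged system drifts too far."""

    def __init__(self, refactor_above: int = 12, maxiter: int = 30):
        self.lu = None
        self.refactor_above = refactor_above
        self.maxiter = maxiter

    def _factor(self, Kff: sparse.csc_matrix):
        try:
            self.lu = splu(Kff)
        except RuntimeError as exc:
            raise SolverError(
                "singular system — the mesh likely contains a floating "
                f"(disconnected) region: {exc}") from exc

    def solve(self, Kff: sparse.csc_matrix, rhs: np.ndarray) -> np.ndarray:
        if self.lu is not None:
            count = 0

            def cb(_):
                nonlocal count
                count += 1

            M = LinearOperator(Kff.shape, self.lu.solve)
            x, info = cg(Kff, rhs, M=M, rtol=1e-12, atol=0.0,
                         maxiter=self.maxiter, callback=cb)
            if info == 0:
                if count > self.refactor_above:
                    self._factor(Kff)  # stale preconditioner; refresh for next
                return x
        self._factor(Kff)
        return self.lu.solve(rhs)


def _solve_step(model, T, free, pres_ids, pres_scale, load, D_committed,
                tol, d_tol, max_iter, dD_max=1.0, linsolver=None,
                force_scale=0.0):
    """One displacement increment.

    Returns (converged, vertical reaction N, damage, iterations used)."""
    D = D_committed.copy()
    D_cap = np.minimum(D_committed + dD_max, 1.0 - 1e-12)
    q = np.zeros(T.shape[1])
    q[pres_ids] = pres_scale * load
    reaction = 0.0
    linsolver = linsolver or _LinearSolver()
    for it in range(max_iter):
        K = model.stiffness(D)
        Kr = (T.T @ K @ T).tocsc()
        Kff = Kr[np.ix_(free, free)].tocsc()
        Kfp = Kr[np.ix_(free, pres_ids)]
        rhs = -Kfp @ (pres_scale * load)
        q[free] = linsolver.solve(Kff, rhs)
        u = T @ q
        eps = model.strains(u)
        # monotone iterate bounded by the rate cap: guarantees convergence of
        # the fixed point even when capped points would otherwise flip-flop
        D_new = np.maximum(D, np.minimum(model.damage_update(eps, D_committed),
                                         D_cap))
        dmax = float(np.max(np.abs(D_new - D))) if D.size else 0.0
        # equilibrium residual with the updated damage: f_int = f_int(ε, D_new)
        f_red = T.T @ model.internal_force(eps, D_new)
        reaction = float(f_red[pres_ids].sum())
        res = float(np.linalg.norm(f_red[free]))
        scale = max(abs(reaction), force_scale, 1e-8)
        D = D_new
        if dmax < d_tol and res <= tol * scale:
            return True, reaction, D, it + 1
    return False, reaction, D, max_iter
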