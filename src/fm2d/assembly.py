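"""Assembly of the coupled membrane / two-phase flow saddle system.

One implicit Euler step couples, in a single linear solve, the bulk
Navier-Stokes momentum balance (P2 velocity U, P1 pressure P), three
incompressibility-type constraints -- bulk divergence, a single scalar
"virtual element" constraint <U, omega>^h = 0 paired with the multiplier
P_sing that conserves the enclosed area, and the surface inextensibility
<grad_s . (pi_ell U), chi_k> = 0 paired with the surface pressure P_Gamma --
and the bending mechanics on the membrane: the Dziuk curvature relation
between the new vertex positions X and the curvature vector kappa, and the
linearised first variation of the bending energy giving the force F_Gamma.

Unknown layout (velocity first, all velocity degrees of freedom including
Dirichlet ones, eliminated at solve time):

    [ U (2*n_p2) | P (n_p1) | lambda (0/1) | P_sing (1) | P_Gamma (K) |
      kappa (2K) | dX (2K) | F_Gamma (2K) ]

lambda is the pressure-mean multiplier, present only when the whole boundary
is Dirichlet.  The block layout follows the saddle structure

    [ B     C   ]  with  C = (C_Omega, D_Omega, S_{Gamma,Omega}),
    [ C^T   0   ]

extended by the three membrane rows (velocity/vertex coupling, curvature,
force), and admits the Schur reduction onto (U, P~) used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import sparse

from .bulkmesh import ElementClassification, InterfaceClipping
from .interface import (InterfaceMesh, segment_normals, vertex_normals_omega,
                        vertex_weights)
from .spaces import TaylorHood, TRI_QUAD, EDGE_QUAD

__all__ = ["PhysicalParams", "SurfaceOperators", "SaddleSystem", "assemble_full"]


@dataclass
class PhysicalParams:
    """Physical and discretisation parameters.

    Densities may vanish (quasi-static limits); viscosities must be
    positive; ``alpha`` is the bending rigidity, ``tau`` the time step and
    ``ell`` the order (1 or 2) of the interface interpolation of the bulk
    velocity in the surface terms.  ``g`` is the Dirichlet velocity data and
    ``f`` the volume force, both callables of point arrays (or None for 0).
    """

    rho_minus: float = 1.0
    rho_plus: float = 1.0
    mu_minus: float = 1.0
    mu_plus: float = 1.0
    rho_gamma: float = 1.0
    mu_gamma: float = 1.0
    alpha: float = 1.0
    tau: float = 1e-3
    ell: int = 1
    g: Optional[Callable] = None
    f: Optional[Callable] = None

    def __post_init__(self):
        if min(self.mu_minus, self.mu_plus) <= 0:
            raise ValueError("bulk viscosities must be positive")
        if min(self.rho_minus, self.rho_plus, self.rho_gamma) < 0:
            raise ValueError("densities must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("bending rigidity must be positive")
        if self.tau <= 0:
            raise ValueError("time step must be positive")
        if self.ell not in (1, 2):
            raise ValueError("ell must be 1 or 2")


def _kron2(mat: sparse.spmatrix) -> sparse.csr_matrix:
    """Expand a node-indexed operator to interleaved 2-vector DOFs."""
    return sparse.kron(mat, sparse.eye(2), format="csr")


def _interleave(vec2: np.ndarray) -> np.ndarray:
    """(n, 2) nodal vectors -> flat interleaved DOF vector (2n,)."""
    return np.ascontiguousarray(vec2).ravel()


def _deinterleave(flat: np.ndarray) -> np.ndarray:
    return flat.reshape(-1, 2)


# ---------------------------------------------------------------------------
# surface operators (membrane-only matrices)
# ---------------------------------------------------------------------------


class SurfaceOperators:
    """All membrane matrices for the current polygon.

    ``M`` is the lumped mass (diagonal), ``A`` the P1 stiffness; ``B_div``
    is the divergence-divergence block printed in the matrix formulation,
    whose (k,l) 2x2 block is <grad_s . (chi_l e_j), grad_s . (chi_k e_i)>;
    for plane curves it is symmetric, so the Willmore-variation combination
    Z = B - B* - R collapses to -B_div.  ``A_weighted(kappa)`` is the
    |kappa|^2-weighted stiffness that carries the 1/2<|kappa|^2, grad_s .
    chi>^h term of the energy variation onto the vertex positions.
    """

    def __init__(self, gamma: InterfaceMesh):
        self.gamma = gamma
        self.K = gamma.n_vertices
        self.h = gamma.segment_lengths()
        self.w = vertex_weights(gamma)
        self.nu = segment_normals(gamma)
        self.omega = vertex_normals_omega(gamma)
        self.tang = gamma.tangents()
        i, j = gamma.seg_start, gamma.seg_end
        inv_h = 1.0 / self.h
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        vals = np.concatenate([inv_h, inv_h, -inv_h, -inv_h])
        self.A_scalar = sparse.csr_matrix((vals, (rows, cols)), shape=(self.K, self.K))
        self.M_diag = self.w  # scalar lumped mass
        self._seg_pattern = (i, j)

    @property
    def M(self) -> sparse.csr_matrix:
        return sparse.diags(np.repeat(self.w, 2), format="csr")

    @property
    def A(self) -> sparse.csr_matrix:
        return _kron2(self.A_scalar)

    def _weighted_stiffness(self, coef: np.ndarray) -> sparse.csr_matrix:
        """Scalar stiffness with per-segment coefficient ``coef/h``."""
        i, j = self._seg_pattern
        c = coef / self.h
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        vals = np.concatenate([c, c, -c, -c])
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.K, self.K))

    @property
    def B_div(self) -> sparse.csr_matrix:
        """Divergence-divergence block: per segment (tau tau^T)/h on the
        usual +/- stiffness pattern."""
        i, j = self._seg_pattern
        t = self.tang
        blocks = np.einsum("ja,jb->jab", t, t) / self.h[:, None, None]
        rows, cols, vals = [], [], []
        for (r, c, s) in ((i, i, 1.0), (j, j, 1.0), (i, j, -1.0), (j, i, -1.0)):
            for a in range(2):
                for b in range(2):
                    rows.append(2 * r + a)
                    cols.append(2 * c + b)
                    vals.append(s * blocks[:, a, b])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(2 * self.K, 2 * self.K))

    @property
    def Z(self) -> sparse.csr_matrix:
        """Willmore-variation combination B - B* - R; equals -B_div for
        plane curves, where the divergence-divergence block is symmetric."""
        return (-self.B_div).tocsr()

    def A_weighted(self, kappa: np.ndarray) -> sparse.csr_matrix:
        """Stiffness weighted by the mean of |kappa|^2/4 at the segment
        endpoints; vanishes when kappa does."""
        i, j = self._seg_pattern
        k2 = np.sum(np.asarray(kappa, float) ** 2, axis=1)
        coef = 0.25 * (k2[i] + k2[j])
        return _kron2(self._weighted_stiffness(coef))

    def bending_force_rhs(self, kappa: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Right-hand side of the force row: Z kappa^m + A_kappa X^m."""
        zk = self.Z @ _interleave(np.asarray(kappa, float))
        ax = self.A_weighted(kappa) @ _interleave(np.asarray(x, float))
        return zk + ax


# ---------------------------------------------------------------------------
# interface-bulk coupling
# ---------------------------------------------------------------------------


# 2-point Gauss on [0,1] (exact for cubics); used on membrane segments where
# the quadratic interface interpolant makes integrands quadratic in arclength.
_SG = 0.5 * (1.0 - 1.0 / np.sqrt(3.0)), 0.5 * (1.0 + 1.0 / np.sqrt(3.0))


class CouplingOperators:
    """Blocks coupling the bulk velocity space to membrane fields.

    Every interface integral in the scheme involves the interface interpolant
    pi_ell of the bulk velocity, so only point evaluations of the P2 basis at
    membrane vertices (and, for ell = 2, segment midpoints) are needed; the
    integrands are then polynomials on whole segments and integrate exactly.
    """

    def __init__(self, space: TaylorHood, surf: SurfaceOperators,
                 clipping: InterfaceClipping, ell: int):
        self.space = space
        self.surf = surf
        self.ell = ell
        self.E = space.evaluation_matrix(clipping.vertex_host, clipping.vertex_bary)
        self.E_mid = (space.evaluation_matrix(clipping.mid_host, clipping.mid_bary)
                      if ell == 2 else None)

    # -- lumped vertex pairing M_{Gamma,Omega} ------------------------------
    @property
    def M_go(self) -> sparse.csr_matrix:
        """(2 n_p2, 2K): <chi_k e_s, pi_1(phi_i e_r)>^h = w_k phi_i(q_k)
        delta_rs."""
        WE = self.E.multiply(self.surf.w[:, None]).T.tocsr()
        return _kron2(WE)

    # -- single volume-constraint column ------------------------------------
    @property
    def D_col(self) -> np.ndarray:
        """-<phi_i e_r, omega>^h as one column over velocity DOFs."""
        w_omega = self.surf.w[:, None] * self.surf.omega
        return -_interleave(self.E.T @ w_omega)

    # -- surface inextensibility S_{Gamma,Omega} ----------------------------
    @property
    def S(self) -> sparse.csr_matrix:
        """(2 n_p2, K): <chi_l, grad_s . (pi_ell phi_i e_r)>.

        For ell = 1 each segment contributes tau_r (phi(q_end) -
        phi(q_start))/2 to both endpoint columns; for ell = 2 the quadratic
        interpolant adds the midpoint values with the exact weights
        (-5/6, 2/3, 1/6) against the start hat and (-1/6, -2/3, 5/6)
        against the end hat.
        """
        g = self.surf.gamma
        i, j = g.seg_start, g.seg_end
        t = self.surf.tang
        K, n2 = g.n_vertices, self.space.n_p2
        if self.ell == 1:
            diff = self.E[j] - self.E[i]            # (J, n_p2)
            parts = [(diff, 0.5, i), (diff, 0.5, j)]
            contributions = []
            for mat, coef, cols in parts:
                for r in range(2):
                    scaled = mat.multiply((coef * t[:, r])[:, None]).tocoo()
                    contributions.append((scaled, r, cols))
        else:
            Ea, Eb, Ec = self.E[i], self.E[j], self.E_mid
            start_comb = (-5.0 / 6.0) * Ea + (2.0 / 3.0) * Ec + (1.0 / 6.0) * Eb
            end_comb = (-1.0 / 6.0) * Ea + (-2.0 / 3.0) * Ec + (5.0 / 6.0) * Eb
            contributions = []
            for mat, cols in ((start_comb.tocsr(), i), (end_comb.tocsr(), j)):
                for r in range(2):
                    scaled = mat.multiply(t[:, r][:, None]).tocoo()
                    contributions.append((scaled, r, cols))
        rows_all, cols_all, vals_all = [], [], []
        for scaled, r, colmap in contributions:
            rows_all.append(2 * scaled.col + r)       # velocity DOF
            cols_all.append(colmap[scaled.row])       # surface vertex
            vals_all.append(scaled.data)
        return sparse.csr_matrix(
            (np.concatenate(vals_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(2 * n2, K))

    # -- Boussinesq-Scriven surface viscosity -------------------------------
    def surface_viscous(self, mu_gamma: float) -> sparse.csr_matrix:
        """2 mu_Gamma <D_s(pi_ell u), D_s(pi_ell xi)>: for plane curves
        D_s(v) = (tau . dv/ds) tau tau^T, so the form is a weighted sum of
        tangential stretch rates."""
        g = self.surf.gamma
        i, j = g.seg_start, g.seg_end
        t = self.surf.tang
        h = self.surf.h
        n2 = self.space.n_p2
        if mu_gamma == 0.0:
            return sparse.csr_matrix((2 * n2, 2 * n2))
        if self.ell == 1:
            diff = (self.E[j] - self.E[i]).multiply((1.0 / h)[:, None]).tocsr()
            comps = [diff.multiply(t[:, r][:, None]).tocsr() for r in range(2)]
            Bop = self._tangential_rate_op(comps)
            return (2.0 * mu_gamma) * (Bop.T @ sparse.diags(h) @ Bop)
        # ell = 2: two Gauss points per segment, derivative of the 1D
        # quadratic through (start, mid, end)
        Ea, Eb, Ec = self.E[i].tocsr(), self.E[j].tocsr(), self.E_mid.tocsr()
        mats = []
        wts = []
        for tg in _SG:
            da, dc, db = 4 * tg - 3.0, 4.0 - 8 * tg, 4 * tg - 1.0
            deriv = (da * Ea + dc * Ec + db * Eb).multiply((1.0 / h)[:, None]).tocsr()
            comps = [deriv.multiply(t[:, r][:, None]).tocsr() for r in range(2)]
            mats.append(self._tangential_rate_op(tuple(comps)))
            wts.append(0.5 * h)
        Bop = sparse.vstack(mats)
        W = sparse.diags(np.concatenate(wts))
        return (2.0 * mu_gamma) * (Bop.T @ W @ Bop)

    def _tangential_rate_op(self, comps) -> sparse.csr_matrix:
        """Combine per-component segment operators into one operator on
        interleaved velocity DOFs: row_j(u) = sum_r comps[r][j, i] u[2i+r]."""
        c0 = comps[0].tocoo()
        c1 = comps[1].tocoo()
        rows = np.concatenate([c0.row, c1.row])
        cols = np.concatenate([2 * c0.col, 2 * c1.col + 1])
        vals = np.concatenate([c0.data, c1.data])
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(c0.shape[0], 2 * self.space.n_p2))

    def surface_inertia(self, rho_gamma_over_tau: float) -> sparse.csr_matrix:
        """(rho_Gamma / tau) <pi_1 u, pi_1 xi>^h."""
        if rho_gamma_over_tau == 0.0:
            n = 2 * self.space.n_p2
            return sparse.csr_matrix((n, n))
        M = self.E.T @ sparse.diags(self.surf.w) @ self.E
        return rho_gamma_over_tau * _kron2(M.tocsr())


# ---------------------------------------------------------------------------
# bulk operators
# ---------------------------------------------------------------------------


def bulk_mass(space: TaylorHood, coef: np.ndarray) -> sparse.csr_matrix:
    """Scalar P2 mass matrix with a piecewise-constant coefficient."""
    lam, wq = TRI_QUAD
    vals, _ = space.p2_at(lam)
    elem = np.einsum("q,qi,qj->ij", wq, vals, vals)  # same on every triangle
    scale = coef * space.area
    conn = space.p2_conn
    rows = np.repeat(conn, 6, axis=1).ravel()
    cols = np.tile(conn, (1, 6)).ravel()
    data = (scale[:, None, None] * elem[None]).ravel()
    n = space.n_p2
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def bulk_viscous(space: TaylorHood, mu: np.ndarray) -> sparse.csr_matrix:
    """2 (mu D(u), D(xi)) on interleaved vector DOFs."""
    lam, wq = TRI_QUAD
    _, grads = space.p2_at(lam)  # (nt, nq, 6, 2)
    # K1[i,j] = int grad phi_j . grad phi_i ; K2[(i,r),(j,s)] = int d_r phi_j d_s phi_i
    K1 = np.einsum("q,tqia,tqja,t->tij", wq, grads, grads, mu * space.area)
    K2 = np.einsum("q,tqis,tqjr,t->tirjs", wq, grads, grads, mu * space.area)
    nt = space.mesh.n_triangles
    elem = np.zeros((nt, 6, 2, 6, 2))
    for r in range(2):
        elem[:, :, r, :, r] += K1
    elem += K2
    conn = space.p2_conn
    dof = (2 * conn[:, :, None] + np.arange(2)[None, None, :]).reshape(nt, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 2 * space.n_p2
    return sparse.csr_matrix((elem.reshape(nt, 12, 12).ravel(), (rows, cols)),
                             shape=(n, n))


def bulk_convection(space: TaylorHood, rho: np.ndarray,
                    W: np.ndarray) -> sparse.csr_matrix:
    """Antisymmetrised convection linearised at the old velocity W:
    (1/2) rho [((W.grad) u) . xi - ((W.grad) xi) . u], as a scalar operator
    expanded to both components."""
    lam, wq = TRI_QUAD
    vals, grads = space.p2_at(lam)
    conn = space.p2_conn
    Wq = np.einsum("qi,tid->tqd", vals, W[conn])  # (nt, nq, 2)
    N = np.einsum("q,tqd,tqjd,qi,t->tij", wq, Wq, grads, vals, rho * space.area)
    elem = 0.5 * (N - np.transpose(N, (0, 2, 1)))
    rows = np.repeat(conn, 6, axis=1).ravel()
    cols = np.tile(conn, (1, 6)).ravel()
    n = space.n_p2
    scal = sparse.csr_matrix((elem.ravel(), (rows, cols)), shape=(n, n))
    return _kron2(scal)


def boundary_outflow(space: TaylorHood, rho_plus: float,
                     W: np.ndarray) -> sparse.csr_matrix:
    """(1/2) rho_+ <W.n, u . xi> on the stress-free boundary part."""
    n = 2 * space.n_p2
    info = space.neumann_boundary_edges()
    if info is None or rho_plus == 0.0:
        return sparse.csr_matrix((n, n))
    pair, midnode, normal, length = info
    gp, gw = EDGE_QUAD
    # 1D quadratic trace shape functions at the Gauss points
    N = np.stack([(1 - gp) * (1 - 2 * gp), gp * (2 * gp - 1), 4 * gp * (1 - gp)], axis=1)
    nodes = np.column_stack([pair, midnode])  # (ne, 3)
    Wn = np.einsum("qi,eid,ed->eq", N, W[nodes], normal)  # (ne, nq)
    elem = 0.5 * rho_plus * np.einsum("q,eq,qi,qj,e->eij", gw, Wn, N, N, length)
    rows = np.repeat(nodes, 3, axis=1).ravel()
    cols = np.tile(nodes, (1, 3)).ravel()
    scal = sparse.csr_matrix((elem.ravel(), (rows, cols)),
                             shape=(space.n_p2, space.n_p2))
    return _kron2(scal)


def bulk_divergence(space: TaylorHood) -> sparse.csr_matrix:
    """C with entries -(psi_n, d_r phi_j): momentum gets +C P, continuity is
    C^T U = 0 (both carry the same minus sign, keeping the saddle symmetric)."""
    lam, wq = TRI_QUAD
    _, grads = space.p2_at(lam)
    p1_vals = lam  # P1 shapes are the barycentric coordinates
    elem = -np.einsum("q,tqjr,qn,t->tjrn", wq, grads, p1_vals, space.area)
    conn2 = space.p2_conn
    conn1 = space.mesh.triangles
    nt = space.mesh.n_triangles
    dof = (2 * conn2[:, :, None] + np.arange(2)[None, None, :]).reshape(nt, 12)
    rows = np.repeat(dof, 3, axis=1).ravel()
    cols = np.tile(conn1, (1, 12)).ravel()
    return sparse.csr_matrix(
        (elem.reshape(nt, 12, 3).ravel(), (rows, cols)),
        shape=(2 * space.n_p2, space.n_p1))


def pressure_mean_vector(space: TaylorHood) -> np.ndarray:
    """Vector of integrals of the P1 pressure basis (for the zero-mean
    multiplier when the whole boundary is Dirichlet)."""
    out = np.zeros(space.n_p1)
    contrib = np.repeat(space.area[:, None] / 3.0, 3, axis=1)
    np.add.at(out, space.mesh.triangles.ravel(), contrib.ravel())
    return out


# ---------------------------------------------------------------------------
# the full system
# ---------------------------------------------------------------------------


@dataclass
class SaddleSystem:
    """Assembled one-step system plus the metadata needed to solve it."""

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    slices: dict
    fixed_dofs: np.ndarray
    fixed_vals: np.ndarray
    # pieces for the Schur path and for residual reporting
    B: sparse.csr_matrix
    C_all: sparse.csr_matrix          # velocity x (P, lambda, P_sing, P_Gamma)
    M_go: Optional[sparse.csr_matrix]
    surf: Optional[SurfaceOperators]
    coupling: Optional["CouplingOperators"]
    b_u: np.ndarray
    r_force: Optional[np.ndarray]     # Z kappa^m + A_kappa X^m
    params: PhysicalParams
    space: TaylorHood

    @property
    def n_unknowns(self) -> int:
        return self.matrix.shape[0]

    def export_matrixmarket(self, prefix) -> None:
        """Dump the system for external verification: ``<prefix>.mtx`` (the
        block matrix), ``<prefix>_rhs.mtx`` and a plain-text sidecar
        ``<prefix>_layout.txt`` describing the unknown layout and the
        Dirichlet-fixed velocity degrees of freedom."""
        from scipy.io import mmwrite
        prefix = str(prefix)
        mmwrite(prefix + ".mtx", self.matrix.tocoo())
        mmwrite(prefix + "_rhs.mtx", self.rhs.reshape(-1, 1))
        with open(prefix + "_layout.txt", "w") as fh:
            fh.write("block layout (start stop), interleaved xy components\n")
            for name, sl in self.slices.items():
                fh.write(f"{name} {sl.start} {sl.stop}\n")
            fh.write(f"n_fixed_velocity_dofs {len(self.fixed_dofs)}\n")
            fh.write(" ".join(map(str, self.fixed_dofs.tolist())) + "\n")


def assemble_full(space: TaylorHood,
                  classification: Optional[ElementClassification],
                  gamma: Optional[InterfaceMesh],
                  clipping: Optional[InterfaceClipping],
                  params: PhysicalParams,
                  U_old: Optional[np.ndarray] = None,
                  surf_vel_old: Optional[np.ndarray] = None,
                  kappa_old: Optional[np.ndarray] = None,
                  cache: Optional[dict] = None) -> SaddleSystem:
    """Assemble the coupled system for one time step.

    ``U_old`` are nodal values (n_p2, 2) of the previous velocity on this
    mesh (already transferred); ``surf_vel_old`` the previous membrane
    velocity at the membrane vertices (for the surface inertia history);
    ``kappa_old`` the pushforward curvature.  With ``gamma=None`` the system
    reduces to single-phase (Navier-)Stokes.  ``cache`` (a dict owned by the
    caller) holds the matrices that depend only on (mesh, rho, mu) --
    viscous, mass, divergence -- and is reused while those are unchanged.
    """
    n2 = space.n_p2
    nu_dofs = 2 * n2
    unsteady = classification is not None and (
        params.rho_minus > 0 or params.rho_plus > 0)
    rho = classification.rho if classification is not None else np.zeros(space.mesh.n_triangles)
    mu = classification.mu if classification is not None else np.full(space.mesh.n_triangles, params.mu_plus)

    if cache is None:
        cache = {}
    if not (cache.get("space") is space
            and np.array_equal(cache.get("rho"), rho)
            and np.array_equal(cache.get("mu"), mu)):
        cache.clear()
        cache.update(space=space, rho=rho.copy(), mu=mu.copy())
        cache["visc"] = bulk_viscous(space, mu)
        cache["M_rho2"] = _kron2(bulk_mass(space, rho / params.tau)) if unsteady else None
        cache["C"] = bulk_divergence(space)

    B = cache["visc"]
    b_u = np.zeros(nu_dofs)
    if U_old is None:
        U_old = np.zeros((n2, 2))
    if unsteady:
        M_rho2 = cache["M_rho2"]
        B = B + M_rho2
        b_u += M_rho2 @ _interleave(U_old)
        B = B + bulk_convection(space, rho, U_old)
        B = B + boundary_outflow(space, params.rho_plus, U_old)
    if params.f is not None:
        f_nodal = space.interpolate(params.f)
        M_one = bulk_mass(space, np.ones(space.mesh.n_triangles))
        b_u += _kron2(M_one) @ _interleave(f_nodal)

    C = cache["C"]
    with_mean = len(space.mesh.domain.neumann_faces) == 0
    cols = [C]
    if with_mean:
        # the zero-mean multiplier couples to the pressure only
        cols.append(sparse.csr_matrix((nu_dofs, 1)))

    surf = coupling = None
    r_force = None
    if gamma is not None:
        surf = SurfaceOperators(gamma)
        coupling = CouplingOperators(space, surf, clipping, params.ell)
        B = B + coupling.surface_inertia(params.rho_gamma / params.tau)
        B = B + coupling.surface_viscous(params.mu_gamma)
        if surf_vel_old is not None and params.rho_gamma > 0:
            b_u += (params.rho_gamma / params.tau) * (
                coupling.M_go @ _interleave(surf_vel_old))
        cols.append(sparse.csr_matrix(coupling.D_col).T)
        cols.append(coupling.S)
        K = gamma.n_vertices
    else:
        K = 0

    C_all = sparse.hstack(cols, format="csr")
    n_press = C_all.shape[1]

    # global layout
    off = {}
    pos = 0
    for name, size in (("u", nu_dofs), ("press", n_press), ("kappa", 2 * K),
                       ("dx", 2 * K), ("force", 2 * K)):
        off[name] = slice(pos, pos + size)
        pos += size
    n_total = pos

    blocks_row = []
    # momentum row
    mom = [B, C_all]
    if K:
        mom += [None, None, (-params.alpha) * coupling.M_go]
    blocks_row.append(mom)
    # constraint row (C^T u = 0) with the pressure-mean tie for lambda
    zero_pp = sparse.csr_matrix((n_press, n_press))
    if with_mean:
        mvec = pressure_mean_vector(space)
        # lambda is the last pressure-type unknown before P_sing/P_Gamma:
        # order inside "press": [P (n_p1), lambda, P_sing?, P_Gamma?]
        lam_idx = space.n_p1
        rowlam = sparse.lil_matrix((n_press, n_press))
        rowlam[lam_idx, :space.n_p1] = mvec
        rowlam[:space.n_p1, lam_idx] = mvec[:, None]
        zero_pp = rowlam.tocsr()
    cons = [C_all.T, zero_pp]
    if K:
        cons += [None, None, None]
    blocks_row.append(cons)
    if K:
        Mg = surf.M
        Ag = surf.A
        # vertex-velocity coupling row
        blocks_row.append([coupling.M_go.T, None, None, (-1.0 / params.tau) * Mg, None])
        # curvature row
        blocks_row.append([None, None, Mg, Ag, None])
        # force row
        blocks_row.append([None, None, -Ag, None, Mg])

    matrix = sparse.bmat(blocks_row, format="csr")
    rhs = np.zeros(n_total)
    rhs[off["u"]] = b_u
    if K:
        x_flat = _interleave(gamma.vertices)
        rhs[off["dx"]] = -(surf.A @ x_flat)
        kap = np.zeros((K, 2)) if kappa_old is None else np.asarray(kappa_old, float)
        r_force = surf.bending_force_rhs(kap, gamma.vertices)
        rhs[off["force"]] = r_force

    # Dirichlet data
    dir_nodes = space.dirichlet_nodes()
    fixed = np.sort(np.concatenate([2 * dir_nodes, 2 * dir_nodes + 1]))
    if params.g is not None:
        gvals = np.asarray(params.g(space.p2_coords[dir_nodes]), float)
    else:
        gvals = np.zeros((len(dir_nodes), 2))
    fixed_vals = _interleave(gvals)

    return SaddleSystem(
        matrix=matrix, rhs=rhs, slices=off, fixed_dofs=fixed,
        fixed_vals=fixed_vals, B=B, C_all=C_all,
        M_go=coupling.M_go if K else None, surf=surf, coupling=coupling,
        b_u=b_u, r_force=r_force, params=params, space=space)
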