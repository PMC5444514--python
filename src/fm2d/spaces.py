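"""Taylor-Hood P2/P1 spaces on a bulk triangulation.

Velocity: continuous piecewise quadratic vectors with degrees of freedom at
triangle vertices and edge midpoints; pressure: continuous piecewise linear
at vertices.  Vector degrees of freedom are interleaved, ``dof = 2*node + r``
for component r.  Dirichlet data is imposed by symmetric elimination: the
full system is assembled over all velocity unknowns and the fixed rows and
columns are sliced out, with the lifting moved to the right-hand side.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .bulkmesh import BulkMesh

__all__ = ["TaylorHood", "TRI_QUAD", "EDGE_QUAD"]

# Dunavant 7-point rule on the reference triangle, exact for degree 5.
_w1, _w2 = 0.1259391805448272, 0.1323941527885062
_a1, _b1 = 0.7974269853530873, 0.1012865073234563
_a2, _b2 = 0.0597158717897698, 0.4701420641051151
TRI_QUAD = (
    np.array([
        [1 / 3, 1 / 3, 1 / 3],
        [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
        [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
    ]),
    np.array([0.225, _w1, _w1, _w1, _w2, _w2, _w2]),
)

# 4-point Gauss-Legendre on [0, 1], exact for degree 7 (boundary edge terms).
_gp = np.array([0.069431844202974, 0.330009478207572,
                0.669990521792428, 0.930568155797026])
_gw = np.array([0.173927422568727, 0.326072577431273,
                0.326072577431273, 0.173927422568727])
EDGE_QUAD = (_gp, _gw)


def p2_shape(lam: np.ndarray):
    """P2 shape functions and barycentric gradients at barycentric points.

    ``lam`` has shape (nq, 3); returns values (nq, 6) and d/dlambda
    (nq, 6, 3).  Node order: 3 vertices, then midpoints of edges
    (0,1), (1,2), (2,0).
    """
    l0, l1, l2 = lam[:, 0], lam[:, 1], lam[:, 2]
    vals = np.stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ], axis=1)
    z = np.zeros_like(l0)
    dl = np.stack([
        np.stack([4 * l0 - 1, z, z], axis=1),
        np.stack([z, 4 * l1 - 1, z], axis=1),
        np.stack([z, z, 4 * l2 - 1], axis=1),
        np.stack([4 * l1, 4 * l0, z], axis=1),
        np.stack([z, 4 * l2, 4 * l1], axis=1),
        np.stack([4 * l2, z, 4 * l0], axis=1),
    ], axis=1)
    return vals, dl


def p1_shape(lam: np.ndarray):
    return lam, np.broadcast_to(np.eye(3), (lam.shape[0], 3, 3))


class TaylorHood:
    """P2 velocity / P1 pressure space bookkeeping on one mesh."""

    def __init__(self, mesh: BulkMesh):
        self.mesh = mesh
        edges, tri_edges = mesh.edge_arrays()
        self.n_p1 = mesh.n_vertices
        self.n_p2 = mesh.n_vertices + len(edges)
        # element connectivity: 6 P2 nodes per triangle
        self.p2_conn = np.hstack([mesh.triangles, mesh.n_vertices + tri_edges])
        self.p2_coords = np.vstack([
            mesh.vertices, 0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])])
        # geometry: barycentric gradients dlambda/dx, constant per triangle
        p = mesh.tri_coords()
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        self.area = 0.5 * det
        gl1 = np.stack([d2[:, 1], -d2[:, 0]], axis=1) / det[:, None]
        gl2 = np.stack([-d1[:, 1], d1[:, 0]], axis=1) / det[:, None]
        self.grad_lam = np.stack([-gl1 - gl2, gl1, gl2], axis=1)  # (nt, 3, 2)

    # -- basis evaluation ---------------------------------------------------
    def p2_at(self, lam: np.ndarray):
        """Values and physical gradients of the 6 P2 basis functions at
        barycentric points ``lam`` (nq, 3), per triangle.

        Returns vals (nq, 6) and grads (nt, nq, 6, 2).
        """
        vals, dl = p2_shape(lam)
        grads = np.einsum("qia,tad->tqid", dl, self.grad_lam)
        return vals, grads

    def eval_p2_function(self, coeffs: np.ndarray, hosts: np.ndarray,
                         bary: np.ndarray) -> np.ndarray:
        """Point values of a P2 function (scalar (n_p2,) or vector
        (n_p2, 2) coefficients) at located points."""
        vals, _ = p2_shape(bary)
        conn = self.p2_conn[hosts]  # (np, 6)
        c = coeffs[conn]
        if c.ndim == 2:
            return np.einsum("pi,pi->p", vals, c)
        return np.einsum("pi,pid->pd", vals, c)

    def interpolate(self, fn) -> np.ndarray:
        """Nodal P2 interpolant of a callable fn(points (n,2)) -> (n,) or
        (n, 2)."""
        return np.asarray(fn(self.p2_coords), float)

    def evaluation_matrix(self, hosts: np.ndarray, bary: np.ndarray) -> sparse.csr_matrix:
        """Sparse (n_points, n_p2) matrix of P2 basis point values."""
        vals, _ = p2_shape(bary)
        conn = self.p2_conn[hosts]
        rows = np.repeat(np.arange(len(hosts)), 6)
        return sparse.csr_matrix(
            (vals.ravel(), (rows, conn.ravel())), shape=(len(hosts), self.n_p2))

    # -- boundary handling ----------------------------------------------------
    def dirichlet_nodes(self) -> np.ndarray:
        """P2 node indices on the Dirichlet part of the boundary.

        A boundary edge is stress-free only if both endpoints and its
        midpoint lie on a declared stress-free face; otherwise Dirichlet.
        """
        mesh = self.mesh
        edges, _ = mesh.edge_arrays()
        bidx = mesh.boundary_edges()
        be = edges[bidx]
        mids = 0.5 * (mesh.vertices[be[:, 0]] + mesh.vertices[be[:, 1]])
        neumann = (mesh.domain.on_neumann(mesh.vertices[be[:, 0]])
                   & mesh.domain.on_neumann(mesh.vertices[be[:, 1]])
                   & mesh.domain.on_neumann(mids))
        dir_edges = bidx[~neumann]
        nodes = np.unique(np.concatenate([
            edges[dir_edges].ravel(), mesh.n_vertices + dir_edges]))
        return nodes

    def neumann_boundary_edges(self):
        """(edge vertex pair, midpoint-node, outward normal, length) arrays
        for the stress-free part of the boundary."""
        mesh = self.mesh
        edges, tri_edges = mesh.edge_arrays()
        bidx = mesh.boundary_edges()
        be = edges[bidx]
        mids = 0.5 * (mesh.vertices[be[:, 0]] + mesh.vertices[be[:, 1]])
        neumann = (mesh.domain.on_neumann(mesh.vertices[be[:, 0]])
                   & mesh.domain.on_neumann(mesh.vertices[be[:, 1]])
                   & mesh.domain.on_neumann(mids))
        sel = bidx[neumann]
        if len(sel) == 0:
            return None
        pair = edges[sel]
        midnode = mesh.n_vertices + sel
        tang = mesh.vertices[pair[:, 1]] - mesh.vertices[pair[:, 0]]
        length = np.linalg.norm(tang, axis=1)
        tang = tang / length[:, None]
        normal = np.c_[tang[:, 1], -tang[:, 0]]
        # orient outward: the normal must point away from the barycenter of
        # the (unique) triangle owning each boundary edge
        owner_tri = np.empty(len(sel), np.int64)
        for i, e in enumerate(sel):
            owner_tri[i] = np.nonzero((tri_edges == e).any(axis=1))[0][0]
        bc = self.mesh.barycenters()[owner_tri]
        emid = 0.5 * (mesh.vertices[pair[:, 0]] + mesh.vertices[pair[:, 1]])
        flip = np.einsum("ed,ed->e", normal, emid - bc) < 0
        normal[flip] *= -1.0
        return pair, midnode, normal, length
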