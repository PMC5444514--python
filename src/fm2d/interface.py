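"""Parametric polygonal interface: geometry, surface calculus, transport.

The membrane is tracked as a closed, simple, counterclockwise polygon
``Gamma`` with vertices ``q_k`` and segments ``sigma_j`` joining consecutive
vertices.  Scalar/vector fields on the membrane are either continuous
piecewise linear (one value per vertex, the hat basis ``chi_k``) or piecewise
constant (one value per segment).  The counterclockwise orientation makes the
per-segment normal ``nu`` (tangent rotated by -90 degrees) point out of the
enclosed region ``Omega_-`` into ``Omega_+``.

Mass lumping replaces the P1 surface mass matrix by the diagonal of vertex
weights ``w_k`` (half the summed lengths of the two adjacent segments); it is
what makes the curvature initialisation and the scalar transport diagonal,
and it underlies the mesh-quality and conservation mechanisms of the flow
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing
from scipy.special import ellipeinc

from .errors import GeometryError

__all__ = [
    "InterfaceMesh",
    "make_shape",
    "segment_normals",
    "vertex_normals_omega",
    "vertex_weights",
    "inner_product",
    "surface_gradient_p1",
    "surface_divergence_p1",
    "curvature_init",
    "diagnostics",
    "pushforward",
    "transport_scalar",
]


@dataclass
class InterfaceMesh:
    """Closed oriented polygon with implicit connectivity.

    ``vertices`` has shape (K, 2); segment ``j`` joins vertex ``j`` to vertex
    ``(j + 1) % K``, so the number of segments equals the number of vertices.
    """

    vertices: np.ndarray
    check_simple: bool = field(default=True)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("interface needs at least 3 plane points")
        self.vertices = v
        if np.min(self.segment_lengths()) <= 0.0:
            raise GeometryError("zero-length interface segment")
        if self.enclosed_area() < 0.0:  # enforce counterclockwise
            self.vertices = v[::-1].copy()
        if self.check_simple and not self.is_simple():
            raise GeometryError("interface polygon is self-intersecting")

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0]

    @property
    def seg_start(self) -> np.ndarray:
        return np.arange(self.n_vertices)

    @property
    def seg_end(self) -> np.ndarray:
        return (np.arange(self.n_vertices) + 1) % self.n_vertices

    def segment_vectors(self) -> np.ndarray:
        v = self.vertices
        return np.roll(v, -1, axis=0) - v

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def segment_midpoints(self) -> np.ndarray:
        v = self.vertices
        return 0.5 * (v + np.roll(v, -1, axis=0))

    def tangents(self) -> np.ndarray:
        """Unit tangents in traversal direction, one per segment."""
        e = self.segment_vectors()
        return e / self.segment_lengths()[:, None]

    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def enclosed_area(self) -> float:
        """Signed shoelace area (positive for counterclockwise)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))

    def is_simple(self) -> bool:
        return bool(LinearRing(self.vertices).is_simple)

    def moved(self, new_vertices: np.ndarray, check_simple: bool = False) -> "InterfaceMesh":
        """Same connectivity, new vertex positions (pure vertex motion)."""
        return InterfaceMesh(np.asarray(new_vertices, float), check_simple=check_simple)


# ---------------------------------------------------------------------------
# shape generation
# ---------------------------------------------------------------------------


def _equal_chords(point_of_s, total_length, n, rtol=1e-12, max_iter=2000):
    """Place n points on a closed curve so the n chords have equal length.

    ``point_of_s`` maps arclength positions (vectorised, s in [0, L)) to
    points.  Starting from equal-arclength spacing, the arclength increments
    are rescaled by (target chord / current chord) until the chord spread is
    below ``rtol`` relative; the first point stays at s = 0.  On shapes with
    varying curvature equal arclength alone leaves an O((L/n)^2 kappa^2)
    chord spread, which this fixed point removes.
    """
    ds = np.full(n, total_length / n)
    for _ in range(max_iter):
        s = np.concatenate(([0.0], np.cumsum(ds)))[:-1]
        pts = point_of_s(s)
        h = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        spread = (h.max() - h.min()) / h.mean()
        if spread < rtol:
            break
        ds = ds * (h.mean() / h)
        ds *= total_length / ds.sum()
    return pts


def _circle(center, radius, n):
    t = 2.0 * np.pi * np.arange(n) / n
    return np.c_[center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]


def _ellipse(center, axes, n):
    """Equal-chord polygon on an ellipse with full axis lengths ``axes``.

    Work with z(u) = (small*cos u, big*sin u), whose speed is
    big*sqrt(1 - m sin^2 u) with m = 1 - (small/big)^2, so the arclength is
    the incomplete elliptic integral big*E(u | m) -- exact via scipy.  The
    inverse u(s) is obtained by Newton iteration.  If the long axis should
    lie along x, rotate the result by -90 degrees (orientation preserving).
    """
    a, b = 0.5 * axes[0], 0.5 * axes[1]
    big, small = (a, b) if a >= b else (b, a)
    m = 1.0 - (small / big) ** 2
    total = float(big * ellipeinc(2.0 * np.pi, m))

    def p_of_s(s):
        u = 2.0 * np.pi * s / total  # initial guess, exact for a circle
        for _ in range(30):
            speed = big * np.sqrt(1.0 - m * np.sin(u) ** 2)
            du = (big * ellipeinc(u, m) - s) / speed
            u = u - du
            if np.max(np.abs(du)) < 1e-15:
                break
        return np.c_[small * np.cos(u), big * np.sin(u)]

    pts = _equal_chords(p_of_s, total, n)
    if a >= b:
        pts = pts[:, ::-1] * np.array([1.0, -1.0])
    return pts + np.asarray(center, float)


def _arc_chain_point_factory(pieces):
    """Vectorised arclength parameterisation of a chain of line/arc pieces.

    Each piece is ("line", p0, p1) or ("arc", center, radius, ang0, ang1)
    with the arc traversed from ang0 to ang1 (either direction).  Returns
    (point_of_s, total_length).
    """
    lengths = []
    for piece in pieces:
        if piece[0] == "line":
            lengths.append(float(np.linalg.norm(np.subtract(piece[2], piece[1]))))
        else:
            _, _, r, a0, a1 = piece
            lengths.append(abs(a1 - a0) * r)
    lengths = np.array(lengths)
    offsets = np.concatenate(([0.0], np.cumsum(lengths)))
    total = float(offsets[-1])

    def point_of_s(s):
        s = np.asarray(s, float)
        idx = np.clip(np.searchsorted(offsets, s, side="right") - 1, 0, len(pieces) - 1)
        out = np.empty((s.size, 2))
        for i, piece in enumerate(pieces):
            mask = idx == i
            if not mask.any():
                continue
            t = (s[mask] - offsets[i]) / lengths[i]
            if piece[0] == "line":
                p0 = np.asarray(piece[1], float)
                p1 = np.asarray(piece[2], float)
                out[mask] = p0 + t[:, None] * (p1 - p0)
            else:
                _, c, r, a0, a1 = piece
                ang = a0 + t * (a1 - a0)
                out[mask] = np.asarray(c, float) + r * np.c_[np.cos(ang), np.sin(ang)]
        return out

    return point_of_s, total


def _stadium(width, length, n):
    """Capsule with total bounding box ``length`` x ``width``: a rectangle of
    size (length - width) x width capped by two semicircles of radius
    width/2, traversed counterclockwise from the bottom-left."""
    r = 0.5 * width
    straight = length - width
    if straight <= 0:
        raise GeometryError("stadium length must exceed its width")
    hx = 0.5 * straight
    pieces = [
        ("line", (-hx, -r), (hx, -r)),
        ("arc", (hx, 0.0), r, -0.5 * np.pi, 0.5 * np.pi),
        ("line", (hx, r), (-hx, r)),
        ("arc", (-hx, 0.0), r, 0.5 * np.pi, 1.5 * np.pi),
    ]
    p_of_s, total = _arc_chain_point_factory(pieces)
    return _equal_chords(p_of_s, total, n)


def _letter_c(r_inner, r_outer, opening_angle, n, center=(0.0, 0.0)):
    """Open annulus (a 'C'): outer arc, semicircular cap, inner arc, cap.
    The gap of half-angle ``opening_angle/2`` is centred on the +x axis."""
    if not (0.0 < r_inner < r_outer):
        raise GeometryError("need 0 < r_inner < r_outer")
    if not (0.0 < opening_angle < 2.0 * np.pi):
        raise GeometryError("opening angle must lie in (0, 2*pi)")
    rc = 0.5 * (r_inner + r_outer)   # centreline radius of the tube
    w = 0.5 * (r_outer - r_inner)    # tube half-width
    a0 = 0.5 * opening_angle
    a1 = 2.0 * np.pi - a0
    cx, cy = center
    cap_hi = (cx + rc * np.cos(a1), cy + rc * np.sin(a1))
    cap_lo = (cx + rc * np.cos(a0), cy + rc * np.sin(a0))
    # caps turn through pi about the tube-centreline endpoints
    pieces = [
        ("arc", (cx, cy), r_outer, a0, a1),
        ("arc", cap_hi, w, a1, a1 + np.pi),
        ("arc", (cx, cy), r_inner, a1, a0),
        ("arc", cap_lo, w, a0 + np.pi, a0 + 2.0 * np.pi),
    ]
    p_of_s, total = _arc_chain_point_factory(pieces)
    return _equal_chords(p_of_s, total, n)


_EQUIDISTRIBUTION_RTOL = 1e-10


def make_shape(name: str, n_vertices: int, **params) -> InterfaceMesh:
    """Generate an equidistributed closed polygon sampling a named shape.

    Supported shapes (all counterclockwise):

    ``circle(center, radius)``; ``ellipse(center, axes)`` with full axis
    lengths; ``stadium(width, length)`` -- a tube of total bounding box
    ``length`` x ``width`` realised as a rectangle with two semicircular
    caps; ``letter_c(r_inner, r_outer, opening_angle)``.

    Segment lengths are equal to within 1e-10 relative tolerance.
    """
    if n_vertices < 3:
        raise GeometryError("need at least 3 vertices")
    name = name.lower()
    if name == "circle":
        center = params.get("center", (0.0, 0.0))
        radius = float(params.get("radius", 1.0))
        if radius <= 0:
            raise GeometryError("circle radius must be positive")
        pts = _circle(center, radius, n_vertices)
    elif name == "ellipse":
        center = params.get("center", (0.0, 0.0))
        axes = params.get("axes", (1.0, 1.0))
        if min(axes) <= 0:
            raise GeometryError("ellipse axes must be positive")
        pts = _ellipse(center, np.asarray(axes, float), n_vertices)
    elif name == "stadium":
        width = float(params.get("width", 0.2))
        length = float(params.get("length", 1.5))
        if width <= 0 or length <= 0:
            raise GeometryError("stadium dimensions must be positive")
        pts = _stadium(width, length, n_vertices)
    elif name == "letter_c":
        pts = _letter_c(
            float(params.get("r_inner", 0.3)),
            float(params.get("r_outer", 0.6)),
            float(params.get("opening_angle", 0.5 * np.pi)),
            n_vertices,
            center=params.get("center", (0.0, 0.0)),
        )
    else:
        raise GeometryError(f"unknown shape {name!r}")
    mesh = InterfaceMesh(pts)
    h = mesh.segment_lengths()
    if (h.max() - h.min()) / h.mean() > _EQUIDISTRIBUTION_RTOL * n_vertices:
        raise GeometryError("shape generator failed to equidistribute")
    return mesh


# ---------------------------------------------------------------------------
# surface calculus
# ---------------------------------------------------------------------------


def segment_normals(gamma: InterfaceMesh) -> np.ndarray:
    """Per-segment unit normal: tangent rotated by -90 deg, pointing into
    the exterior phase for a counterclockwise polygon.  Shape (J, 2)."""
    t = gamma.tangents()
    return np.c_[t[:, 1], -t[:, 0]]


def vertex_weights(gamma: InterfaceMesh) -> np.ndarray:
    """Mass-lumped vertex measures w_k = |support of chi_k| / 2."""
    h = gamma.segment_lengths()
    return 0.5 * (h + np.roll(h, 1))


def vertex_normals_omega(gamma: InterfaceMesh) -> np.ndarray:
    """Length-weighted average of the two adjacent segment normals.

    omega_k = (sum_{j in Theta_k} |sigma_j| nu_j) / (sum |sigma_j|); it is the
    test direction that makes the discrete enclosed-area conservation
    mechanism work, because the lumped pairing with any P1 field against
    ``w * nu`` and ``w * omega`` coincide.
    """
    nu = segment_normals(gamma)
    h = gamma.segment_lengths()
    num = h[:, None] * nu
    num = num + np.roll(num, 1, axis=0)
    den = h + np.roll(h, 1)
    return num / den[:, None]


def inner_product(gamma: InterfaceMesh, eta, zeta, mode: str = "full") -> float:
    """L2 inner product of two surface fields on the polygon.

    P1 fields are arrays of shape (K,) or (K, 2); P0 fields (J,) or (J, 2).
    ``full`` integrates exactly (the integrand is piecewise quadratic at
    most); ``lumped`` uses the vertex rule sum_k w_k eta(q_k).zeta(q_k),
    with one-sided limits for P0 arguments (i.e. the trapezoid value per
    segment).
    """
    eta = np.asarray(eta, float)
    zeta = np.asarray(zeta, float)
    K = gamma.n_vertices
    h = gamma.segment_lengths()

    def per_vertex(a):  # (K,) pairs of one-sided values per segment end
        if a.shape[0] == K:
            return a[gamma.seg_start], a[gamma.seg_end]
        return a, a  # P0: same value at both ends (one-sided limits)

    if eta.shape != zeta.shape and eta.shape[0] != zeta.shape[0]:
        # allow P0 vs P1 mixes, but vector-ness must agree
        if (eta.ndim != zeta.ndim):
            raise ValueError("mismatched field shapes")
    a0, a1 = per_vertex(eta)
    b0, b1 = per_vertex(zeta)

    def dot(x, y):
        return x * y if x.ndim == 1 else np.sum(x * y, axis=1)

    if mode == "lumped":
        return float(np.sum(0.5 * h * (dot(a0, b0) + dot(a1, b1))))
    if mode == "full":
        # exact Simpson on each segment for (at most) quadratic integrands
        am, bm = 0.5 * (a0 + a1), 0.5 * (b0 + b1)
        return float(np.sum(h / 6.0 * (dot(a0, b0) + 4.0 * dot(am, bm) + dot(a1, b1))))
    raise ValueError(f"unknown mode {mode!r}")


def surface_gradient_p1(gamma: InterfaceMesh, field: np.ndarray) -> np.ndarray:
    """Per-segment surface gradient of a P1 field.

    For a scalar field returns (J, 2): (difference quotient) * unit tangent.
    For a vector field returns (J, 2, 2) applied componentwise, with
    ``out[j, i]`` the surface gradient of component i on segment j.
    """
    field = np.asarray(field, float)
    h = gamma.segment_lengths()
    t = gamma.tangents()
    diff = field[gamma.seg_end] - field[gamma.seg_start]
    if field.ndim == 1:
        return (diff / h)[:, None] * t
    return (diff / h[:, None])[:, :, None] * t[:, None, :]


def surface_divergence_p1(gamma: InterfaceMesh, field: np.ndarray) -> np.ndarray:
    """Per-segment surface divergence of a P1 vector field: tangential
    stretch rate tau . d(field)/ds."""
    h = gamma.segment_lengths()
    t = gamma.tangents()
    diff = field[gamma.seg_end] - field[gamma.seg_start]
    return np.sum(diff * t, axis=1) / h


def p1_stiffness_action(gamma: InterfaceMesh, field: np.ndarray) -> np.ndarray:
    """Action of the P1 surface stiffness matrix on a (K,) or (K,2) field:
    row k of <grad_s field, grad_s chi_k>."""
    h = gamma.segment_lengths()
    diff = (np.asarray(field, float)[gamma.seg_end] - field[gamma.seg_start])
    flux = diff / (h[:, None] if diff.ndim == 2 else h)
    out = np.zeros_like(np.asarray(field, float))
    np.subtract.at(out, gamma.seg_start, flux)
    np.add.at(out, gamma.seg_end, flux)
    return out  # row k: sum over adjacent segments of (field_k - field_nb)/h


def curvature_init(gamma: InterfaceMesh) -> np.ndarray:
    """Discrete curvature vector: lumped solve of
    <kappa, eta>^h + <grad_s id, grad_s eta> = 0 for all P1 eta.

    With lumping the system is diagonal: kappa_k = -(A_Gamma X)_k / w_k.
    Sign convention: kappa is negative where the enclosed phase is locally
    convex (kappa = -1/R on a counterclockwise circle of radius R).
    """
    w = vertex_weights(gamma)
    return -p1_stiffness_action(gamma, gamma.vertices) / w[:, None]


def diagnostics(gamma: InterfaceMesh) -> dict:
    """Geometric scalars: length, enclosed area, reduced area
    a_r = 4*pi*area/length^2 (1 for a circle), and the element ratio
    r_a = max|sigma| / min|sigma| (mesh quality, 1 when equidistributed)."""
    if not gamma.is_simple():
        raise GeometryError("interface polygon is self-intersecting")
    h = gamma.segment_lengths()
    length = float(h.sum())
    area = gamma.enclosed_area()
    return {
        "length": length,
        "enclosed_area": area,
        "a_r": 4.0 * np.pi * area / length**2,
        "r_a": float(h.max() / h.min()),
    }


def pushforward(field: np.ndarray) -> np.ndarray:
    """Vertex-indexed transfer of a field between two interfaces of identical
    connectivity: values are copied label-for-label (only the geometry the
    field lives on changes)."""
    return np.array(field, float, copy=True)


def transport_scalar(psi: np.ndarray, gamma_old: InterfaceMesh,
                     gamma_new: InterfaceMesh) -> np.ndarray:
    """Advect a P1 scalar with the interface, conserving its lumped integral:
    <psi_new, chi_k>^h_new = <psi_old, chi_k>^h_old, i.e.
    psi_new_k = psi_old_k * w_old_k / w_new_k.

    A uniform initial field stays uniform exactly when local lengths are
    preserved, which is the fingerprint of discrete local inextensibility.
    """
    if gamma_old.n_vertices != gamma_new.n_vertices:
        raise GeometryError("connectivity mismatch in transport")
    w_old = vertex_weights(gamma_old)
    w_new = vertex_weights(gamma_new)
    if np.min(w_new) <= 0.0:
        raise GeometryError("zero vertex weight on target interface")
    return np.asarray(psi, float) * w_old / w_new
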