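"""Scalar diagnostics and file output.

The discrete energy after a step is

    E^h = E^h_kin + (alpha/2) <kappa^{m+1}, kappa^{m+1}>^h_{Gamma^m},
    E^h_kin = (1/2) ||(rho^m)^(1/2) U^{m+1}||^2
            + (rho_Gamma/2) <U^{m+1}, U^{m+1}>^h_{Gamma^m};

for driven-free runs (g = 0, f = 0) it is the Lyapunov quantity of the
scheme.  The reduced area a_r = 4 pi area / length^2 and the element ratio
r_a = max|sigma| / min|sigma| characterise shape and mesh quality; the
reduced volume v_r (its three-dimensional analogue) is provided as a
formula on given (surface area, volume) numbers for reference only.

Outputs are plain text: a diagnostics CSV in full double precision, legacy
ASCII VTK files for the bulk grid (velocity, density, viscosity, element
label) and for the membrane polyline (curvature magnitude, surface
pressure, transported marker), and a per-snapshot interface CSV.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable

import numpy as np

from .assembly import bulk_mass, _kron2, _interleave
from .interface import InterfaceMesh, vertex_weights

__all__ = ["discrete_energy", "conservation_report", "reduced_volume",
           "OutputWriter", "write_interface_csv", "read_interface_csv",
           "write_diagnostics_csv", "read_diagnostics_csv",
           "write_vtk_bulk", "write_vtk_interface"]

CSV_COLUMNS = ["t", "length", "area", "energy", "kinetic", "a_r", "r_a",
               "psi_min", "psi_max", "res_div", "res_inext", "res_omega",
               "p_sing"]


def discrete_energy(space, rho_elements, U, gamma: InterfaceMesh, kappa,
                    rho_gamma: float, alpha: float):
    """(total energy, kinetic part) from bulk velocity and curvature."""
    u_flat = _interleave(np.asarray(U, float))
    M = _kron2(bulk_mass(space, np.asarray(rho_elements, float)))
    kin = 0.5 * float(u_flat @ (M @ u_flat))
    if rho_gamma > 0:
        hosts, bary = space.mesh.locate(gamma.vertices)
        u_g = space.eval_p2_function(np.asarray(U, float), hosts, bary)
        w = vertex_weights(gamma)
        kin += 0.5 * rho_gamma * float(np.sum(w * np.sum(u_g**2, axis=1)))
    w = vertex_weights(gamma)
    bend = 0.5 * alpha * float(np.sum(w * np.sum(np.asarray(kappa, float)**2, axis=1)))
    return kin + bend, kin


def conservation_report(history: Iterable[dict], domain_area: float | None = None):
    """Maximum relative drifts of interface length and phase areas.

    Returns a dict with drifts as fractions (multiply by 100 for percent).
    The complement-phase drift requires the (fixed) total domain area.
    """
    hist = list(history)
    if len(hist) < 2:
        raise ValueError("need at least two records")
    L0 = hist[0]["length"]
    A0 = hist[0]["area"]
    dl = max(abs(r["length"] - L0) for r in hist) / abs(L0)
    da = max(abs(r["area"] - A0) for r in hist) / abs(A0)
    out = {"length_drift": dl, "area_drift": da,
           "max_r_a": max(r["r_a"] for r in hist)}
    if domain_area is not None:
        C0 = domain_area - A0
        out["complement_drift"] = max(
            abs((domain_area - r["area"]) - C0) for r in hist) / abs(C0)
    return out


def reduced_volume(surface_area: float, volume: float) -> float:
    """v_r = 6 sqrt(pi) V / A^(3/2): 1 for a sphere (3D shape number;
    formula-only utility, no 3D geometry in this package)."""
    return 6.0 * np.sqrt(np.pi) * volume / surface_area**1.5


# ---------------------------------------------------------------------------
# plain-text writers (full double precision for determinism checks)
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def write_diagnostics_csv(path, history: Iterable[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in history:
            writer.writerow([_FMT % rec[c] for c in CSV_COLUMNS])


def read_diagnostics_csv(path) -> list:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        cols = next(reader)
        return [dict(zip(cols, map(float, row))) for row in reader]


def write_interface_csv(path, gamma: InterfaceMesh) -> None:
    """x,y per vertex; the closing edge back to the first vertex is
    implied."""
    np.savetxt(path, gamma.vertices, delimiter=",", header="x,y",
               comments="", fmt=_FMT)


def read_interface_csv(path) -> InterfaceMesh:
    return InterfaceMesh(np.loadtxt(path, delimiter=",", skiprows=1))


def write_vtk_bulk(path, mesh, classification=None, U=None, space=None) -> None:
    """Legacy ASCII VTK unstructured grid with optional cell data (density,
    viscosity, classification label) and point velocity (P1 part)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfm2d bulk mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} 0\n")
        nt = mesh.n_triangles
        fh.write(f"CELLS {nt} {4 * nt}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {nt}\n")
        fh.write("5\n" * nt)
        if classification is not None:
            fh.write(f"CELL_DATA {nt}\n")
            for name, arr in (("rho", classification.rho),
                              ("mu", classification.mu),
                              ("label", classification.labels)):
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in arr) + "\n")
        if U is not None:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write("VECTORS velocity double\n")
            for ux, uy in np.asarray(U)[:mesh.n_vertices]:
                fh.write(f"{ux:.17g} {uy:.17g} 0\n")


def write_vtk_interface(path, gamma: InterfaceMesh, point_data=None) -> None:
    """Legacy ASCII VTK polyline of the closed membrane polygon."""
    K = gamma.n_vertices
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfm2d interface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {K} double\n")
        for x, y in gamma.vertices:
            fh.write(f"{x:.17g} {y:.17g} 0\n")
        fh.write(f"LINES 1 {K + 2}\n")
        fh.write(" ".join([str(K + 1)] + [str(i) for i in range(K)] + ["0"]) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {K}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in np.asarray(arr)) + "\n")


class OutputWriter:
    """Per-run output directory: diagnostics CSV plus periodic snapshots."""

    def __init__(self, directory):
        self.dir = str(directory)
        os.makedirs(self.dir, exist_ok=True)

    def snapshot(self, sim) -> None:
        st = sim.state
        tag = f"{st.step:06d}"
        write_interface_csv(os.path.join(self.dir, f"interface_{tag}.csv"), st.gamma)
        sol = getattr(sim, "_last_solution", None)
        pdata = {"kappa_mag": np.linalg.norm(st.kappa, axis=1), "psi": st.psi}
        if sol is not None and len(sol.P_gamma):
            pdata["p_gamma"] = sol.P_gamma
        write_vtk_interface(os.path.join(self.dir, f"interface_{tag}.vtk"),
                            st.gamma, pdata)
        if st.space is not None:
            write_vtk_bulk(os.path.join(self.dir, f"bulk_{tag}.vtk"),
                           st.space.mesh, U=st.U, space=st.space)

    def finalize(self, sim) -> None:
        write_diagnostics_csv(os.path.join(self.dir, "diagnostics.csv"),
                              sim.state.history)
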