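"""Time evolution: mesh adaptation, assembly, solve, interface advection.

One step of the scheme, starting from the membrane polygon Gamma^m, the
previous velocity U^m and the pushforward curvature kappa^m:

1. rebuild the adapted bulk mesh around Gamma^m and transfer U^m onto it by
   pointwise P2 interpolation;
2. classify elements and clip the membrane against the triangles;
3. assemble and solve the coupled saddle system for (U^{m+1}, pressures,
   kappa^{m+1}, dX^{m+1}, F^{m+1});
4. move the membrane vertices, Gamma^{m+1} = X^m + dX^{m+1} (equivalently
   q_k + tau * U^{m+1}(q_k)); transport the marker field Psi and push the
   curvature and membrane velocity forward label-for-label;
5. record diagnostics (energies, conservation quantities, mesh quality,
   constraint residuals).

Everything is deterministic: identical inputs reproduce identical states
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import assemble_full, _interleave
from .bulkmesh import (BAND_MARGIN, build_adaptive_mesh,
                       classify_elements, clip_interface)
from .errors import GeometryError
from .interface import (InterfaceMesh, curvature_init, diagnostics,
                        pushforward, transport_scalar, vertex_weights)
from .presets import ScenarioPreset, get_preset
from .solver import CachedDirectSolver, solve_schur
from .spaces import TaylorHood

log = logging.getLogger("fm2d.stepper")

__all__ = ["FlowState", "Simulation"]


@dataclass
class FlowState:
    """Complete state at time level m."""

    step: int
    t: float
    gamma: InterfaceMesh
    kappa: np.ndarray          # (K, 2), on gamma's connectivity
    psi: np.ndarray            # (K,) transported marker, starts at 1
    surf_vel: np.ndarray       # (K, 2) membrane velocity history
    U: Optional[np.ndarray]    # (n_p2, 2) on `space`
    space: Optional[TaylorHood]
    history: list = field(default_factory=list)


class Simulation:
    """Driver for one scenario at one discretisation."""

    def __init__(self, preset: ScenarioPreset | str, n_fine: int, n_coarse: int,
                 tau: float, k_gamma: int, ell: int = 1,
                 solver: str = "direct", check_every: int = 10,
                 param_overrides: Optional[dict] = None):
        if isinstance(preset, str):
            preset = get_preset(preset)
        self.preset = preset
        self.n_fine, self.n_coarse = n_fine, n_coarse
        self.params = preset.physical_params(tau, ell, **(param_overrides or {}))
        if ell == 2 and self.params.rho_gamma > 0:
            import warnings
            warnings.warn(
                "quadratic interface interpolation with positive membrane "
                "density is outside the stability theory", stacklevel=2)
        if ell == 1 and k_gamma % 2 == 0:
            import warnings
            warnings.warn(
                "even vertex count admits a checkerboard surface-pressure "
                "mode with linear interface interpolation; use K = 2^k + 1",
                stacklevel=2)
        self.k_gamma = k_gamma
        self.solver = solver
        self.check_every = check_every
        self._direct = CachedDirectSolver()
        self._asm_cache = {}
        # adapted mesh kept while the membrane stays well inside the
        # refinement band; see _current_mesh
        self._mesh = None
        self._space = None
        self._gamma_at_build = None
        self.state = self._initialize()

    # -- setup --------------------------------------------------------------
    def _initialize(self) -> FlowState:
        gamma = self.preset.make_interface(self.k_gamma)
        if not self.preset.domain.contains(gamma.vertices).all():
            raise GeometryError("initial interface is not inside the domain")
        kappa = curvature_init(gamma)
        psi = np.ones(gamma.n_vertices)
        if self.preset.u0 is not None:
            surf_vel = np.asarray(self.preset.u0(gamma.vertices), float)
        else:
            surf_vel = np.zeros((gamma.n_vertices, 2))
        geo = diagnostics(gamma)
        w = vertex_weights(gamma)
        # bulk kinetic energy at t=0 is not recorded (no mesh yet); for the
        # relaxation scenarios used in the energy-decay checks u0 = 0 anyway
        kin0 = 0.5 * self.params.rho_gamma * float(
            np.sum(w * np.sum(surf_vel**2, axis=1)))
        bend0 = 0.5 * self.params.alpha * float(
            np.sum(w * np.sum(kappa**2, axis=1)))
        rec0 = {
            "t": 0.0, "length": geo["length"], "area": geo["enclosed_area"],
            "a_r": geo["a_r"], "r_a": geo["r_a"],
            "energy": kin0 + bend0, "kinetic": kin0,
            "psi_min": 1.0, "psi_max": 1.0,
            "res_div": 0.0, "res_inext": 0.0, "res_omega": 0.0,
            "p_sing": 0.0,
        }
        return FlowState(step=0, t=0.0, gamma=gamma, kappa=kappa, psi=psi,
                         surf_vel=surf_vel, U=None, space=None,
                         history=[rec0])

    def _velocity_on(self, space: TaylorHood) -> np.ndarray:
        """U^m on the (new) mesh: the P2 interpolant of u0 initially, the
        pointwise interpolant of the previous finite element velocity
        afterwards."""
        st = self.state
        if st.U is None:
            if self.preset.u0 is None:
                return np.zeros((space.n_p2, 2))
            return np.asarray(self.preset.u0(space.p2_coords), float)
        hosts, bary = st.space.mesh.locate(space.p2_coords)
        return st.space.eval_p2_function(st.U, hosts, bary)

    def _current_mesh(self, gamma: InterfaceMesh):
        """Adapted mesh for the current membrane position.

        The refinement band extends BAND_MARGIN * h_f beyond one element
        diameter around the membrane, so the mesh remains admissible until
        some vertex has moved a comparable distance; rebuilding only then
        also lets the solver reuse its factorisation in between.
        """
        h_f = self.preset.domain.mesh_size(self.n_fine)
        if self._mesh is not None:
            moved = float(np.max(np.linalg.norm(
                gamma.vertices - self._gamma_at_build, axis=1)))
            if moved <= 0.2 * BAND_MARGIN * h_f:
                return self._mesh, self._space, False
        self._mesh = build_adaptive_mesh(self.preset.domain, gamma,
                                         self.n_fine, self.n_coarse)
        self._space = TaylorHood(self._mesh)
        self._gamma_at_build = gamma.vertices.copy()
        return self._mesh, self._space, True

    # -- one step -----------------------------------------------------------
    def step(self) -> FlowState:
        st = self.state
        par = self.params
        gamma = st.gamma
        mesh, space, rebuilt = self._current_mesh(gamma)
        clip = clip_interface(mesh, gamma)
        cls = classify_elements(mesh, gamma, par.rho_minus, par.rho_plus,
                                par.mu_minus, par.mu_plus, clip)
        needs_uold = (par.rho_minus > 0 or par.rho_plus > 0)
        if needs_uold:
            same_mesh = st.space is space
            U_old = st.U if (same_mesh and st.U is not None) \
                else self._velocity_on(space)
        else:
            U_old = None
        system = assemble_full(space, cls, gamma, clip, par, U_old=U_old,
                               surf_vel_old=st.surf_vel, kappa_old=st.kappa,
                               cache=self._asm_cache)
        sol = solve_schur(system) if self.solver == "schur" \
            else self._direct.solve(system)

        # energies are evaluated on Gamma^m with the new velocity/curvature
        w = system.surf.w
        kin = 0.0
        if needs_uold or par.rho_gamma > 0:
            u_flat = _interleave(sol.U)
            if needs_uold:
                # tau * (mass with rho/tau) = mass with rho
                M_rho2 = self._asm_cache["M_rho2"]
                kin = 0.5 * par.tau * float(u_flat @ (M_rho2 @ u_flat))
            u_at_gamma = system.coupling.E @ sol.U
            kin += 0.5 * par.rho_gamma * float(np.sum(w * np.sum(u_at_gamma**2, axis=1)))
        bend = 0.5 * par.alpha * float(np.sum(w * np.sum(sol.kappa**2, axis=1)))

        new_vertices = gamma.vertices + sol.dX
        if not self.preset.domain.contains(new_vertices).all():
            raise GeometryError("membrane vertex left the domain")
        check = self.check_every > 0 and (st.step + 1) % self.check_every == 0
        gamma_new = gamma.moved(new_vertices, check_simple=check)
        psi_new = transport_scalar(st.psi, gamma, gamma_new)
        surf_vel_new = system.coupling.E @ sol.U  # pi_1 U^{m+1} at the labels

        geo = diagnostics(gamma_new) if check else _geo_quick(gamma_new)
        rec = {
            "t": st.t + par.tau,
            "length": geo["length"], "area": geo["enclosed_area"],
            "a_r": geo["a_r"], "r_a": geo["r_a"],
            "energy": kin + bend, "kinetic": kin,
            "psi_min": float(psi_new.min()), "psi_max": float(psi_new.max()),
            "res_div": sol.report.div_residual,
            "res_inext": sol.report.inext_residual,
            "res_omega": sol.report.omega_residual,
            "p_sing": sol.P_sing,
        }
        history = st.history + [rec]
        log.debug("step %d t=%.4f len=%.8f area=%.8f r_a=%.6f E=%.6g "
                  "res=(%.1e,%.1e,%.1e)%s", st.step + 1, rec["t"],
                  rec["length"], rec["area"], rec["r_a"], rec["energy"],
                  rec["res_div"], rec["res_inext"], rec["res_omega"],
                  " [remesh]" if rebuilt else "")
        self.state = FlowState(
            step=st.step + 1, t=st.t + par.tau, gamma=gamma_new,
            kappa=pushforward(sol.kappa), psi=psi_new,
            surf_vel=surf_vel_new, U=sol.U, space=space, history=history)
        self._last_solution = sol
        return self.state

    # -- run ----------------------------------------------------------------
    def run(self, T: float, output_every: int = 0, output_dir=None,
            progress: bool = False):
        """March to final time T; optionally write snapshots every
        ``output_every`` steps (and at the end)."""
        n_steps = int(round(T / self.params.tau))
        writer = None
        if output_dir is not None:
            from .diagnostics import OutputWriter
            writer = OutputWriter(output_dir)
        for m in range(n_steps):
            self.step()
            if writer is not None and (
                    (output_every and self.state.step % output_every == 0)
                    or m == n_steps - 1):
                writer.snapshot(self)
            if progress and (m + 1) % 50 == 0:
                r = self.state.history[-1]
                print(f"  step {m + 1}/{n_steps}  t={r['t']:.3f} "
                      f"len={r['length']:.6f} area={r['area']:.6f} "
                      f"r_a={r['r_a']:.5f}", flush=True)
        if writer is not None:
            writer.finalize(self)
        return self.state


def _geo_quick(gamma: InterfaceMesh) -> dict:
    h = gamma.segment_lengths()
    length = float(h.sum())
    area = gamma.enclosed_area()
    return {"length": length, "enclosed_area": area,
            "a_r": 4.0 * np.pi * area / length**2,
            "r_a": float(h.max() / h.min())}
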