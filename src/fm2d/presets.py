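"""Scenario presets for the two-dimensional membrane experiments.

Each preset bundles the flow domain, its boundary split, the Dirichlet data
g and initial velocity u0, the physical parameters and the initial membrane
shape:

* ``shear_a`` / ``shear_b``: lid-driven shear on (-2,2)^2 with g = (z2, 0)
  on top/bottom and stress-free sides; initial ellipse with axis lengths 1
  and 2.5 (reduced area 0.745); bending rigidity 0.05; viscosity contrast 1
  (tank treading) or 10 (tumbling).
* ``constriction``: quasi-static (rho = 0) Poiseuille inflow through a
  narrowed channel; initial elongated tube of total dimension 0.2 x 1.5
  (reduced area 0.351) placed upright in the inlet channel; alpha = 0.1;
  membrane density 0 or 15 (inertial variant).
* ``letter_C``: relaxation of a C-shaped membrane in (-1,1)^2 with no-slip
  walls, all parameters unity (membrane density 0 by default).
* ``relax_circle``: a centred circle with zero data -- a discrete
  stationary state used as a sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .assembly import PhysicalParams
from .bulkmesh import DomainSpec
from .errors import ConfigError
from .interface import InterfaceMesh, make_shape

__all__ = ["ScenarioPreset", "get_preset", "PRESETS"]


@dataclass
class ScenarioPreset:
    name: str
    domain: DomainSpec
    shape: dict                       # make_shape arguments (minus K)
    params: dict                      # PhysicalParams fields (minus tau/ell)
    g: Optional[Callable] = None
    u0: Optional[Callable] = None
    shape_transform: Optional[Callable] = None

    def make_interface(self, k_gamma: int) -> InterfaceMesh:
        shape_args = dict(self.shape)
        name = shape_args.pop("name")
        mesh = make_shape(name, k_gamma, **shape_args)
        if self.shape_transform is not None:
            mesh = mesh.moved(self.shape_transform(mesh.vertices))
        return mesh

    def physical_params(self, tau: float, ell: int, **overrides) -> PhysicalParams:
        kw = dict(self.params)
        kw.update(overrides)
        return PhysicalParams(tau=tau, ell=ell, g=self.g, **kw)


def _shear_g(pts):
    return np.c_[pts[:, 1], np.zeros(len(pts))]


def _shear_u0(pts):
    s = pts[:, 1]
    eta = np.sign(s) * 4.0 * np.maximum(np.abs(s) - 1.5, 0.0)
    return np.c_[eta, np.zeros(len(pts))]


def _poiseuille_g(pts):
    # inflow profile on the left face only; no-slip on the other walls
    out = np.zeros((len(pts), 2))
    left = pts[:, 0] <= -2.0 + 1e-9
    out[left, 0] = 1.0 - pts[left, 1] ** 2
    return out


def _shear_preset(mu_minus: float, name: str) -> ScenarioPreset:
    dom = DomainSpec(
        rectangles=((-2.0, 2.0, -2.0, 2.0),),
        neumann_faces=((-2.0, -2.0, -2.0, 2.0), (2.0, 2.0, -2.0, 2.0)))
    return ScenarioPreset(
        name=name, domain=dom,
        shape={"name": "ellipse", "axes": (1.0, 2.5)},
        params=dict(rho_minus=1.0, rho_plus=1.0, mu_minus=mu_minus,
                    mu_plus=1.0, rho_gamma=1.0, mu_gamma=1.0, alpha=0.05),
        g=_shear_g, u0=_shear_u0)


def _constriction_preset(rho_gamma: float, name: str) -> ScenarioPreset:
    dom = DomainSpec(
        rectangles=((-2.0, -1.0, -1.0, 1.0), (-1.0, 1.0, -0.5, 0.5),
                    (1.0, 2.0, -1.0, 1.0)),
        neumann_faces=((2.0, 2.0, -1.0, 1.0),))

    def upright_at_inlet(v):
        rot = np.c_[-v[:, 1], v[:, 0]]    # rotate 90 deg: long axis along y
        return rot + np.array([-1.5, 0.0])

    return ScenarioPreset(
        name=name, domain=dom,
        shape={"name": "stadium", "width": 0.2, "length": 1.5},
        params=dict(rho_minus=0.0, rho_plus=0.0, mu_minus=1.0, mu_plus=1.0,
                    rho_gamma=rho_gamma, mu_gamma=1.0, alpha=0.1),
        g=_poiseuille_g, u0=None, shape_transform=upright_at_inlet)


def _letter_c_preset() -> ScenarioPreset:
    dom = DomainSpec(rectangles=((-1.0, 1.0, -1.0, 1.0),))
    return ScenarioPreset(
        name="letter_C", domain=dom,
        shape={"name": "letter_c", "r_inner": 0.3, "r_outer": 0.6,
               "opening_angle": 0.5 * np.pi},
        params=dict(rho_minus=1.0, rho_plus=1.0, mu_minus=1.0, mu_plus=1.0,
                    rho_gamma=0.0, mu_gamma=1.0, alpha=1.0))


def _relax_circle_preset() -> ScenarioPreset:
    dom = DomainSpec(rectangles=((-2.0, 2.0, -2.0, 2.0),))
    return ScenarioPreset(
        name="relax_circle", domain=dom,
        shape={"name": "circle", "radius": 0.8},
        params=dict(rho_minus=1.0, rho_plus=1.0, mu_minus=1.0, mu_plus=1.0,
                    rho_gamma=1.0, mu_gamma=1.0, alpha=1.0))


PRESETS = {
    "shear_a": lambda: _shear_preset(1.0, "shear_a"),
    "shear_b": lambda: _shear_preset(10.0, "shear_b"),
    "constriction": lambda: _constriction_preset(0.0, "constriction"),
    "constriction_inertia": lambda: _constriction_preset(15.0, "constriction_inertia"),
    "letter_C": _letter_c_preset,
    "relax_circle": _relax_circle_preset,
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
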