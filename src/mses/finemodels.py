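"""Shipped fine-model implementations.

The multiscale Hamiltonian is agnostic to what the fine model is, so the
package ships three interchangeable implementations of the fine-model
contract (energy + exact forces + per-dof masses):

* :class:`Analytic1D` — one-dimensional analytic potentials in natural
  units (k_B = 1), used for closed-form and quadrature-verified tests;
* :class:`BeadSpringModel` — a bead-spring chain system with structure-based
  (Go-like) native contacts, harmonic bonds/angles and excluded volume;
  the "rugged, slow" surrogate for an atomistic complex;
* :func:`enm_fine_model` — an elastic-network fine model built by the CG
  machinery, for fine/CG pairs of matched resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import AMU_TO_SIM
from .energetics import CGModelEvaluator
from .cgforge import CGModel


class Analytic1D:
    """A 1D potential in natural units; coordinates have shape (1,)."""

    def __init__(
        self,
        potential: Callable[[float], float],
        force: Callable[[float], float],
        mass: float = 1.0,
        name: str = "analytic-1d",
    ):
        self.potential = potential
        self.force = force
        self.masses = np.array([mass], dtype=float)
        self.name = name
        self.reference = np.zeros(1)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = float(np.asarray(coords).ravel()[0])
        return self.potential(x), np.array([self.force(x)])


def harmonic_1d(a: float, mass: float = 1.0) -> Analytic1D:
    """V(x) = (a/2) x^2."""
    if a <= 0:
        raise ValueError("curvature a must be positive")
    return Analytic1D(lambda x: 0.5 * a * x * x, lambda x: -a * x, mass, f"harmonic(a={a})")


def double_well_1d(h: float, mass: float = 1.0) -> Analytic1D:
    """V(x) = h (x^2 - 1)^2: two minima at x = +-1 separated by barrier h."""
    if h <= 0:
        raise ValueError("barrier height must be positive")
    return Analytic1D(
        lambda x: h * (x * x - 1.0) ** 2,
        lambda x: -4.0 * h * x * (x * x - 1.0),
        mass,
        f"double-well(h={h})",
    )


def enm_fine_model(model: CGModel, mass_amu: float = 110.0) -> CGModelEvaluator:
    """An elastic-network fine model at C-alpha-like bead masses."""
    return CGModelEvaluator(model, mass=mass_amu)


# ---------------------------------------------------------------------------
# Bead-spring Go-like model

@dataclass
class BeadSpringModel:
    """Bead chains with native-contact attraction and excluded volume.

    Energy terms (kcal/mol, A):
      bonds     (k_b/2)(r - r0)^2 along each chain
      angles    (k_a/2)(theta - theta0)^2 on consecutive chain triples
      contacts  eps[(r0/r)^12 - 2(r0/r)^6] per native pair (Go-like)
      repulsion eps_rep (sigma/r)^12 for every non-excluded pair

    Native contacts are read off the reference geometry at build time, so
    the reference is a near-minimum and thermal motion at 300 K explores
    marginally stable binding, which is the regime of interest.
    """

    reference: np.ndarray  # (n, 3)
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray  # (nb,)
    angles: np.ndarray  # (na, 3) int
    angle_theta0: np.ndarray  # (na,)
    contacts: np.ndarray  # (nc, 2) int
    contact_r0: np.ndarray  # (nc,)
    bond_k: float = 20.0  # kcal/mol/A^2
    angle_k: float = 2.0  # kcal/mol/rad^2
    contact_eps: float | np.ndarray = 0.5  # kcal/mol, scalar or per-contact
    rep_sigma: float = 4.0  # A
    rep_eps: float = 1.0  # kcal/mol
    bead_mass_amu: float = 110.0
    # soft spherical confinement (finite-concentration mimic enabling
    # rebinding); radius None disables it
    confine_center: np.ndarray | None = None
    confine_radius: float | None = None
    confine_k: float = 1.0  # kcal/mol/A^2

    _rep_pairs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.reference)
        self.contact_eps = np.broadcast_to(
            np.asarray(self.contact_eps, dtype=float), (len(self.contacts),)
        ).copy()
        excluded = set()
        for i, j in self.bonds:
            excluded.add((min(i, j), max(i, j)))
        for i, j, k in self.angles:
            excluded.add((min(i, k), max(i, k)))
            excluded.add((min(i, j), max(i, j)))
            excluded.add((min(j, k), max(j, k)))
        for i, j in self.contacts:
            excluded.add((min(i, j), max(i, j)))
        pairs = [
            (i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in excluded
        ]
        self._rep_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.masses = np.full(n * 3, self.bead_mass_amu * AMU_TO_SIM)

    @property
    def n_beads(self) -> int:
        return len(self.reference)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(-1, 3)
        energy = 0.0
        forces = np.zeros_like(x)

        def pair_accumulate(idx, dV_dr, diff, r):
            grad = (dV_dr / r)[:, None] * diff
            np.add.at(forces, idx[:, 0], -grad)
            np.add.at(forces, idx[:, 1], grad)

        if len(self.bonds):
            diff = x[self.bonds[:, 0]] - x[self.bonds[:, 1]]
            r = np.linalg.norm(diff, axis=1)
            energy += float(np.sum(0.5 * self.bond_k * (r - self.bond_r0) ** 2))
            pair_accumulate(self.bonds, self.bond_k * (r - self.bond_r0), diff, r)

        if len(self.angles):
            i, j, k = self.angles[:, 0], self.angles[:, 1], self.angles[:, 2]
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
            dtheta = theta - self.angle_theta0
            energy += float(np.sum(0.5 * self.angle_k * dtheta**2))
            # dcos/dri, dcos/drk; dtheta/dx = -dcos/dx / sin
            hu = u / nu[:, None]
            hv = v / nv[:, None]
            dcos_di = (hv - cos_t[:, None] * hu) / nu[:, None]
            dcos_dk = (hu - cos_t[:, None] * hv) / nv[:, None]
            coef = (self.angle_k * dtheta / sin_t)[:, None]  # -dV/dcos * (-1) bookkeeping below
            f_i = coef * dcos_di
            f_k = coef * dcos_dk
            np.add.at(forces, i, f_i)
            np.add.at(forces, k, f_k)
            np.add.at(forces, j, -(f_i + f_k))

        if len(self.contacts):
            diff = x[self.contacts[:, 0]] - x[self.contacts[:, 1]]
            r = np.linalg.norm(diff, axis=1)
            s6 = (self.contact_r0 / r) ** 6
            energy += float(np.sum(self.contact_eps * (s6 * s6 - 2.0 * s6)))
            dV_dr = (12.0 * self.contact_eps / r) * (s6 - s6 * s6)
            pair_accumulate(self.contacts, dV_dr, diff, r)

        if len(self._rep_pairs):
            diff = x[self._rep_pairs[:, 0]] - x[self._rep_pairs[:, 1]]
            r = np.linalg.norm(diff, axis=1)
            s12 = (self.rep_sigma / r) ** 12
            energy += float(np.sum(self.rep_eps * s12))
            dV_dr = -12.0 * self.rep_eps * s12 / r
            pair_accumulate(self._rep_pairs, dV_dr, diff, r)

        if self.confine_radius is not None:
            diff = x - self.confine_center
            d = np.linalg.norm(diff, axis=1)
            excess = np.maximum(d - self.confine_radius, 0.0)
            energy += float(np.sum(0.5 * self.confine_k * excess**2))
            mask = excess > 0
            if np.any(mask):
                forces[mask] -= (
                    self.confine_k * excess[mask] / d[mask]
                )[:, None] * diff[mask]

        return energy, forces

    def minimized(self, coords: np.ndarray | None = None, maxiter: int = 300) -> np.ndarray:
        """Local energy minimisation (L-BFGS) of a configuration; relaxes
        build-time clashes before dynamics."""
        from scipy.optimize import minimize

        x0 = (self.reference if coords is None else np.asarray(coords, dtype=float)).ravel()

        def fun(xf):
            e, f = self.energy_forces(xf.reshape(-1, 3))
            return e, -f.ravel()

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
        return res.x.reshape(-1, 3)
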