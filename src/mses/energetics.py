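"""Energies and analytic forces for the multiscale Hamiltonian.

The total potential is

    V = V_fine(r_fine) + V_cg(r_cg) + V_couple(r_fine, r_cg; k)

with the coupling acting on a K-vector of collective variables chi on each
side:

    V_couple = k * |chi_fine(r_fine) - chi_cg(r_cg)|^2 .

chi is a projection onto a small shared space (typically the K selected
inter-group site-pair distances); the coupling is harmonic in the CV
mismatch and vanishes identically at k = 0, which is what makes the
zero-coupling replica an unbiased sample of the fine model.

All forces are exact negative gradients (chain rule through the pair
distances); ``gradient_check`` verifies any evaluator against central
finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .cgforge import CGModel


class LJSingularityError(ZeroDivisionError):
    """Two LJ-interacting sites coincide (r = 0)."""


# ---------------------------------------------------------------------------
# Collective variables

@dataclass(frozen=True)
class ChiVector:
    values: np.ndarray  # (K,) pair distances, A
    pair_list: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.pair_list):
            raise ValueError("values/pair_list length mismatch")


class CollectiveVariable(Protocol):
    """Differentiable projection of coordinates onto a K-vector."""

    def values(self, coords: np.ndarray) -> np.ndarray: ...

    def force_contribution(self, coords: np.ndarray, dv_dchi: np.ndarray) -> np.ndarray:
        """Return -d(V)/d(coords) given dV/dchi (chain rule)."""
        ...

    def __len__(self) -> int: ...


@dataclass(frozen=True)
class PairDistanceCV:
    """chi_i = |x[a_i] - x[b_i]| for K site pairs on an (n, 3) model."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def values(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        a = np.array([p[0] for p in self.pairs])
        b = np.array([p[1] for p in self.pairs])
        return np.linalg.norm(coords[a] - coords[b], axis=1)

    def force_contribution(self, coords: np.ndarray, dv_dchi: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        a = np.array([p[0] for p in self.pairs])
        b = np.array([p[1] for p in self.pairs])
        diff = coords[a] - coords[b]
        r = np.linalg.norm(diff, axis=1)
        safe_r = np.where(r > 0, r, 1.0)
        grad = (dv_dchi / safe_r)[:, None] * diff  # dV/dx_a per pair
        np.add.at(forces, a, -grad)
        np.add.at(forces, b, grad)
        return forces


@dataclass(frozen=True)
class CartesianCV:
    """chi = the coordinates themselves (flattened); used by analytic toys."""

    n_components: int

    def __len__(self) -> int:
        return self.n_components

    def values(self, coords: np.ndarray) -> np.ndarray:
        flat = np.asarray(coords, dtype=float).ravel()
        if flat.size != self.n_components:
            raise ValueError("coordinate size mismatch")
        return flat.copy()

    def force_contribution(self, coords: np.ndarray, dv_dchi: np.ndarray) -> np.ndarray:
        return (-np.asarray(dv_dchi, dtype=float)).reshape(np.shape(coords))


def chi_project(coords: np.ndarray, pairs: Sequence[tuple[int, int]]) -> ChiVector:
    """Project coordinates onto the K pair distances."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"pair ({i}, {j}) out of range for {n} sites")
    cv = PairDistanceCV(tuple((int(i), int(j)) for i, j in pairs))
    return ChiVector(cv.values(coords), cv.pairs)


# ---------------------------------------------------------------------------
# Coupling term

@dataclass(frozen=True)
class CouplingSpec:
    """The shared CV space and coupling constant tying the two models."""

    cv_fine: CollectiveVariable
    cv_cg: CollectiveVariable
    k_mmcg: float = 0.0  # kcal/mol/A^2

    def __post_init__(self) -> None:
        if len(self.cv_fine) != len(self.cv_cg):
            raise ValueError(
                f"CV dimension mismatch: {len(self.cv_fine)} vs {len(self.cv_cg)}"
            )
        if self.k_mmcg < 0:
            raise ValueError("k_mmcg must be non-negative")

    @property
    def K(self) -> int:
        return len(self.cv_fine)

    def with_k(self, k: float) -> "CouplingSpec":
        return CouplingSpec(self.cv_fine, self.cv_cg, k)


def pair_coupling_spec(
    pairs_fine: Sequence[tuple[int, int]],
    pairs_cg: Sequence[tuple[int, int]],
    k_mmcg: float = 0.0,
) -> CouplingSpec:
    """Coupling on aligned inter-group distance pairs of the two models."""
    if len(pairs_fine) != len(pairs_cg):
        raise ValueError("pair lists must be the same length")
    return CouplingSpec(
        PairDistanceCV(tuple(map(tuple, pairs_fine))),
        PairDistanceCV(tuple(map(tuple, pairs_cg))),
        k_mmcg,
    )


def coupling_mismatch(
    coords_fine: np.ndarray, coords_cg: np.ndarray, spec: CouplingSpec
) -> float:
    """B = |chi_fine - chi_cg|^2 in A^2, the k-free CV mismatch."""
    d = spec.cv_fine.values(coords_fine) - spec.cv_cg.values(coords_cg)
    return float(d @ d)


def coupling_energy_forces(
    coords_fine: np.ndarray,
    coords_cg: np.ndarray,
    spec: CouplingSpec,
    k: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """V_couple = k |chi_fine - chi_cg|^2 with exact forces on both models.

    At k = 0 energy and forces are exactly zero.  Forces follow the chain
    rule: dV/dchi_fine = 2 k (chi_fine - chi_cg), and each CV distributes
    its gradient onto the sites it is built from.
    """
    kk = spec.k_mmcg if k is None else k
    if kk < 0:
        raise ValueError("coupling constant must be non-negative")
    if kk == 0.0:
        return 0.0, np.zeros_like(np.asarray(coords_fine, dtype=float)), np.zeros_like(
            np.asarray(coords_cg, dtype=float)
        )
    diff = spec.cv_fine.values(coords_fine) - spec.cv_cg.values(coords_cg)
    energy = float(kk * diff @ diff)
    f_fine = spec.cv_fine.force_contribution(coords_fine, 2.0 * kk * diff)
    f_cg = spec.cv_cg.force_contribution(coords_cg, -2.0 * kk * diff)
    return energy, f_fine, f_cg


# ---------------------------------------------------------------------------
# CG model energy

def _pair_arrays(terms, attr_names):
    idx = np.array([t.site_pair for t in terms], dtype=int).reshape(-1, 2)
    cols = [np.array([getattr(t, a) for t in terms], dtype=float) for a in attr_names]
    return idx, cols


def cg_energy_forces(model: CGModel, coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Total CG energy (ENM + LJ + boundary) and analytic forces.

    ENM: E = (k/2)(r - r0)^2.  LJ: E = eps[(rm/r)^12 - 2(rm/r)^6], minimum
    -eps at r = rm.  Boundary: E = (kb/2)(r - onset)^2 for r > onset else 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_sites, 3):
        raise ValueError(f"expected coords shape {(model.n_sites, 3)}, got {coords.shape}")
    energy = 0.0
    forces = np.zeros_like(coords)

    def accumulate(idx: np.ndarray, dV_dr: np.ndarray, diff: np.ndarray, r: np.ndarray) -> None:
        grad = (dV_dr / r)[:, None] * diff  # dV/dx_i
        np.add.at(forces, idx[:, 0], -grad)
        np.add.at(forces, idx[:, 1], grad)

    if model.enm_terms:
        idx, (r0, k) = _pair_arrays(model.enm_terms, ("rest_length", "force_constant"))
        diff = coords[idx[:, 0]] - coords[idx[:, 1]]
        r = np.linalg.norm(diff, axis=1)
        energy += float(np.sum(0.5 * k * (r - r0) ** 2))
        accumulate(idx, k * (r - r0), diff, np.where(r > 0, r, 1.0))

    if model.lj_terms:
        idx, (eps, rm) = _pair_arrays(model.lj_terms, ("epsilon", "r_min"))
        diff = coords[idx[:, 0]] - coords[idx[:, 1]]
        r = np.linalg.norm(diff, axis=1)
        if np.any(r == 0.0):
            raise LJSingularityError("coincident sites in an LJ pair")
        s6 = (rm / r) ** 6
        energy += float(np.sum(eps * (s6 * s6 - 2.0 * s6)))
        dV_dr = (12.0 * eps / r) * (s6 - s6 * s6)
        accumulate(idx, dV_dr, diff, r)

    if model.boundary_terms:
        idx, (onset, kb) = _pair_arrays(model.boundary_terms, ("onset", "force_constant"))
        diff = coords[idx[:, 0]] - coords[idx[:, 1]]
        r = np.linalg.norm(diff, axis=1)
        excess = np.maximum(r - onset, 0.0)
        energy += float(np.sum(0.5 * kb * excess**2))
        accumulate(idx, kb * excess, diff, np.where(r > 0, r, 1.0))

    return energy, forces


class CGModelEvaluator:
    """FineModel-style wrapper so a CG model can serve as a fine model too."""

    def __init__(self, model: CGModel, mass: float | None = None):
        from .constants import AMU_TO_SIM

        self.model = model
        m_amu = model.site_mass if mass is None else mass
        self.masses = np.full(model.n_sites * 3, m_amu * AMU_TO_SIM)
        self.reference = model.reference_coordinates.copy()

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return cg_energy_forces(self.model, coords)


# ---------------------------------------------------------------------------
# Fine-model contract and total decomposition

class FineModel(Protocol):
    """Energy-and-forces evaluator over its own coordinates.

    Implementations must return forces that are the exact negative gradient
    of the energy (finite-difference testable via ``gradient_check``) and
    expose per-degree-of-freedom masses in simulation units.
    """

    masses: np.ndarray

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]: ...


@dataclass(frozen=True)
class EnergyDecomposition:
    v_mm: float
    v_cg: float
    v_mmcg: float

    @property
    def total(self) -> float:
        return self.v_mm + self.v_cg + self.v_mmcg


def total_mses_energy(
    fine_model: FineModel,
    coords_fine: np.ndarray,
    cg_model: CGModel | "FineModel",
    coords_cg: np.ndarray,
    spec: CouplingSpec,
) -> EnergyDecomposition:
    """Decompose the total multiscale energy into its three terms."""
    v_mm, _ = fine_model.energy_forces(coords_fine)
    if isinstance(cg_model, CGModel):
        v_cg, _ = cg_energy_forces(cg_model, coords_cg)
    else:
        v_cg, _ = cg_model.energy_forces(coords_cg)
    v_mmcg, _, _ = coupling_energy_forces(coords_fine, coords_cg, spec)
    return EnergyDecomposition(v_mm=float(v_mm), v_cg=float(v_cg), v_mmcg=float(v_mmcg))


# ---------------------------------------------------------------------------
# Verification

def gradient_check(
    energy_forces: Callable[[np.ndarray], tuple[float, np.ndarray]],
    coords: np.ndarray,
    step: float = 1e-5,
) -> float:
    """Max relative deviation of analytic forces from central differences.

    The relative scale is the larger of the numerical force magnitude and
    1, so near-zero components are compared absolutely.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    coords = np.asarray(coords, dtype=float)
    _, analytic = energy_forces(coords)
    flat = coords.ravel()
    worst = 0.0
    for i in range(flat.size):
        bump = np.zeros_like(flat)
        bump[i] = step
        e_plus, _ = energy_forces((flat + bump).reshape(coords.shape))
        e_minus, _ = energy_forces((flat - bump).reshape(coords.shape))
        numeric = -(e_plus - e_minus) / (2.0 * step)
        denom = max(1.0, abs(numeric))
        worst = max(worst, abs(numeric - analytic.ravel()[i]) / denom)
    return worst
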