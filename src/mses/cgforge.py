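"""Coarse-grained force-field builder.

The CG model is a C-alpha bead model with three term classes:

* intra-group elastic network (ENM): harmonic springs, E = (k/2)(r - r0)^2,
  between all same-group bead pairs closer than a cutoff in the reference
  structure (defaults k = 0.75 kcal/mol/A^2, cutoff 12 A, strict '<');
* inter-group structure-based 6-12 Lennard-Jones attraction on bead pairs
  within 15 A (inclusive) in the reference, with the minimum placed at the
  reference distance and depth epsilon = 0.03 kcal/mol;
* a soft harmonic outer boundary per LJ pair, zero below its onset
  (r_min + 12 A by default, k = 5 kcal/mol/A^2), preventing unbounded
  separation of the two groups.

At the reference coordinates every ENM spring is at rest, every LJ pair at
its minimum and every boundary term inactive, so the reference is a local
minimum of the CG energy by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structmodel import SiteSet, Structure, select_sites

ENM_FORCE_CONSTANT = 0.75  # kcal/mol/A^2
ENM_CUTOFF = 12.0  # A
LJ_SELECT_CUTOFF = 15.0  # A, inclusive
LJ_EPSILON = 0.03  # kcal/mol
BOUNDARY_OFFSET = 12.0  # A beyond the LJ minimum
BOUNDARY_FORCE_CONSTANT = 5.0  # kcal/mol/A^2
CG_SITE_MASS = 1.0e4  # amu; heavy beads for adiabatic separation


class UnboundModelError(ValueError):
    """No inter-group pair qualifies for an LJ term: the model has no
    attraction holding the groups together."""


@dataclass(frozen=True)
class ENMTerm:
    site_pair: tuple[int, int]
    rest_length: float  # A
    force_constant: float  # kcal/mol/A^2


@dataclass(frozen=True)
class LJTerm:
    site_pair: tuple[int, int]
    epsilon: float  # kcal/mol
    r_min: float  # A


@dataclass(frozen=True)
class BoundaryTerm:
    site_pair: tuple[int, int]
    onset: float  # A
    force_constant: float  # kcal/mol/A^2


@dataclass
class CGModel:
    """Coarse-grained sites, reference coordinates and interaction terms."""

    labels: tuple[tuple[str, int], ...]  # (chain, residue_number) per site
    reference_coordinates: np.ndarray  # (n, 3) A
    group_assignment: np.ndarray  # (n,) integer group per site
    enm_terms: list[ENMTerm] = field(default_factory=list)
    lj_terms: list[LJTerm] = field(default_factory=list)
    boundary_terms: list[BoundaryTerm] = field(default_factory=list)
    site_mass: float = CG_SITE_MASS  # amu

    def __post_init__(self) -> None:
        n = len(self.labels)
        for term in (*self.enm_terms, *self.lj_terms, *self.boundary_terms):
            i, j = term.site_pair
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"term indexes out of range: {term}")
        if len(self.lj_terms) != len(self.boundary_terms):
            raise ValueError("each LJ term requires a matching boundary term")

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    @property
    def is_free(self) -> bool:
        """True for a single-group model with no inter-group terms."""
        return not self.lj_terms


def build_enm(
    coords: np.ndarray,
    groups: Sequence[int],
    cutoff: float = ENM_CUTOFF,
    k: float = ENM_FORCE_CONSTANT,
) -> list[ENMTerm]:
    """One harmonic term per same-group pair with reference distance < cutoff."""
    if cutoff <= 0 or k <= 0:
        raise ValueError("cutoff and k must be positive")
    coords = np.asarray(coords, dtype=float)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        if np.sum(groups == g) < 2:
            warnings.warn(f"group {g} has fewer than 2 sites; no ENM terms for it")
    dm = squareform(pdist(coords))
    terms: list[ENMTerm] = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if groups[i] == groups[j] and dm[i, j] < cutoff:
                terms.append(ENMTerm((i, j), float(dm[i, j]), k))
    return terms


def build_interchain_lj(
    coords: np.ndarray,
    groups: Sequence[int],
    select_cutoff: float = LJ_SELECT_CUTOFF,
    epsilon: float = LJ_EPSILON,
    boundary_offset: float = BOUNDARY_OFFSET,
    boundary_k: float = BOUNDARY_FORCE_CONSTANT,
) -> tuple[list[LJTerm], list[BoundaryTerm]]:
    """Structure-based inter-group attraction.

    One 6-12 LJ term per cross-group pair at reference distance <= the
    selection cutoff (minimum at the reference distance), each paired with a
    soft harmonic boundary starting boundary_offset beyond the minimum.
    """
    if select_cutoff <= 0:
        raise ValueError("select_cutoff must be positive")
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {len(uniq)}")
    coords = np.asarray(coords, dtype=float)
    dm = squareform(pdist(coords))
    lj: list[LJTerm] = []
    bnd: list[BoundaryTerm] = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if groups[i] != groups[j] and dm[i, j] <= select_cutoff:
                r0 = float(dm[i, j])
                lj.append(LJTerm((i, j), epsilon, r0))
                bnd.append(BoundaryTerm((i, j), r0 + boundary_offset, boundary_k))
    if not lj:
        raise UnboundModelError(
            f"no cross-group pair within {select_cutoff} A: model would be unbound"
        )
    return lj, bnd


def assemble_cg_model(
    structure: Structure,
    chain_groups: Sequence[Sequence[str]],
    enm_cutoff: float = ENM_CUTOFF,
    enm_k: float = ENM_FORCE_CONSTANT,
    lj_select_cutoff: float = LJ_SELECT_CUTOFF,
    lj_epsilon: float = LJ_EPSILON,
    boundary_offset: float = BOUNDARY_OFFSET,
    boundary_k: float = BOUNDARY_FORCE_CONSTANT,
    site_mass: float = CG_SITE_MASS,
    atom_name: str = "CA",
) -> CGModel:
    """Build a complete CG model from a structure.

    chain_groups assigns chains to groups, e.g. ``[["A", "B"], ["C"]]``
    for a two-chain receptor bound by a one-chain ligand.  A single group
    yields a "free" model with ENM terms only.
    """
    labels: list[tuple[str, int]] = []
    coords: list[np.ndarray] = []
    assignment: list[int] = []
    for g, chains in enumerate(chain_groups):
        for chain in chains:
            sites = select_sites(structure, chain=chain, atom_name=atom_name)
            xyz = structure.coordinates[list(sites.indices)]
            labels.extend(sites.labels)
            coords.append(xyz)
            assignment.extend([g] * len(sites))
    ref = np.vstack(coords)
    groups = np.asarray(assignment)
    enm = build_enm(ref, groups, cutoff=enm_cutoff, k=enm_k)
    if len(chain_groups) == 1:
        lj: list[LJTerm] = []
        bnd: list[BoundaryTerm] = []
    else:
        lj, bnd = build_interchain_lj(
            ref, groups, select_cutoff=lj_select_cutoff, epsilon=lj_epsilon,
            boundary_offset=boundary_offset, boundary_k=boundary_k,
        )
    return CGModel(
        labels=tuple(labels), reference_coordinates=ref, group_assignment=groups,
        enm_terms=enm, lj_terms=lj, boundary_terms=bnd, site_mass=site_mass,
    )


# ---------------------------------------------------------------------------
# Serialization (human-readable, diffable)

def write_cg_model(model: CGModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# CG model: {model.n_sites} sites, mass {model.site_mass} amu\n")
        fh.write("[sites]\n")
        fh.write("# index\tchain\tresidue\tgroup\tx\ty\tz\n")
        for i, ((chain, resnum), g, xyz) in enumerate(
            zip(model.labels, model.group_assignment, model.reference_coordinates)
        ):
            fh.write(f"{i}\t{chain}\t{resnum}\t{g}\t{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}\n")
        fh.write("[enm]\n# i\tj\trest_length\tk\n")
        for t in model.enm_terms:
            fh.write(f"{t.site_pair[0]}\t{t.site_pair[1]}\t{t.rest_length:.6f}\t{t.force_constant:g}\n")
        fh.write("[lj]\n# i\tj\tr_min\tepsilon\n")
        for t in model.lj_terms:
            fh.write(f"{t.site_pair[0]}\t{t.site_pair[1]}\t{t.r_min:.6f}\t{t.epsilon:g}\n")
        fh.write("[boundary]\n# i\tj\tonset\tk\n")
        for t in model.boundary_terms:
            fh.write(f"{t.site_pair[0]}\t{t.site_pair[1]}\t{t.onset:.6f}\t{t.force_constant:g}\n")


def read_cg_model(path: str | Path) -> CGModel:
    labels: list[tuple[str, int]] = []
    coords: list[list[float]] = []
    groups: list[int] = []
    enm: list[ENMTerm] = []
    lj: list[LJTerm] = []
    bnd: list[BoundaryTerm] = []
    mass = CG_SITE_MASS
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "mass" in line:
                    mass = float(line.split("mass")[1].split("amu")[0])
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            parts = line.split("\t")
            if section == "sites":
                labels.append((parts[1], int(parts[2])))
                groups.append(int(parts[3]))
                coords.append([float(parts[4]), float(parts[5]), float(parts[6])])
            elif section == "enm":
                enm.append(ENMTerm((int(parts[0]), int(parts[1])), float(parts[2]), float(parts[3])))
            elif section == "lj":
                lj.append(LJTerm((int(parts[0]), int(parts[1])), float(parts[3]), float(parts[2])))
            elif section == "boundary":
                bnd.append(BoundaryTerm((int(parts[0]), int(parts[1])), float(parts[2]), float(parts[3])))
    return CGModel(
        labels=tuple(labels), reference_coordinates=np.asarray(coords, dtype=float),
        group_assignment=np.asarray(groups), enm_terms=enm, lj_terms=lj,
        boundary_terms=bnd, site_mass=mass,
    )
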