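"""Structure handling: PDB I/O, site selection, superposition, RMSD, contacts.

This is the geometric substrate for both model building (coarse-grained
sites are selected here) and ensemble analysis (RMSD collective variables,
inter-molecular contact maps).  Coordinates are in Angstrom throughout.
Residue numbers are kept 1-based as in the PDB file; internal site indices
are 0-based positions into ``Structure.atoms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist


class PDBFormatError(ValueError):
    """An ATOM/HETATM record could not be parsed (names the line number)."""


class ModelNotFoundError(KeyError):
    """The requested MODEL index is absent from the file."""


class EmptySelectionError(ValueError):
    """A site selection matched no atoms."""


class InsufficientPointsError(ValueError):
    """Fewer than three points supplied for a rigid superposition."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: tuple[float, float, float]
    element: str = ""


@dataclass
class Structure:
    """An ordered list of atoms from one PDB MODEL."""

    atoms: list[AtomRecord]
    model_index: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Angstrom."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class SiteSet:
    """Ordered references into a Structure, e.g. the C-alpha trace."""

    indices: tuple[int, ...]
    labels: tuple[tuple[str, int], ...]  # (chain_id, residue_number) per site

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom


# ---------------------------------------------------------------------------
# PDB I/O

_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM record; return None for skipped altlocs."""
    altloc = line[16:17]
    if altloc not in (" ", "", "A"):
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable PDB record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    coords = (x, y, z)
    if not all(np.isfinite(coords)):
        raise PDBFormatError(f"non-finite coordinates at line {lineno}")
    return AtomRecord(serial, name, residue_name, chain_id, residue_number, coords, element)


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read one MODEL from a PDB file.

    ATOM and HETATM records are parsed; alternate locations other than 'A'
    (or blank) are dropped; insertion codes are ignored.  Files without
    MODEL records are treated as a single model 1.
    """
    path = Path(path)
    models: dict[int, list[AtomRecord]] = {}
    current = 1
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                seen_model_record = True
                try:
                    current = int(line.split()[1])
                except (IndexError, ValueError) as exc:
                    raise PDBFormatError(f"bad MODEL record at line {lineno}") from exc
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    models.setdefault(current, []).append(atom)
    if not seen_model_record and models and model != 1 and model not in models:
        raise ModelNotFoundError(f"file has no MODEL records; only model 1 exists, requested {model}")
    if model not in models:
        raise ModelNotFoundError(f"model {model} not found in {path} (available: {sorted(models)})")
    return Structure(models[model], model_index=model)


def _format_atom_line(a: AtomRecord) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.coordinates
    return (
        f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id:1.1s}"
        f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2.2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            fh.write(_format_atom_line(a) + "\n")
        fh.write("END\n")


def write_trajectory_pdb(
    template: Structure, frames: Sequence[np.ndarray], path: str | Path
) -> None:
    """Write coordinate frames as a multi-MODEL PDB using template identities."""
    with open(path, "w") as fh:
        for i, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for atom, xyz in zip(template.atoms, np.asarray(frame, dtype=float)):
                rec = AtomRecord(
                    atom.serial, atom.name, atom.residue_name, atom.chain_id,
                    atom.residue_number, tuple(xyz), atom.element,
                )
                fh.write(_format_atom_line(rec) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_table(frames: Sequence[np.ndarray], path: str | Path) -> None:
    """Write frames as a delimited table: frame, site, x, y, z."""
    with open(path, "w") as fh:
        fh.write("frame\tsite\tx\ty\tz\n")
        for f, frame in enumerate(frames):
            for s, (x, y, z) in enumerate(np.asarray(frame, dtype=float)):
                fh.write(f"{f}\t{s}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


# ---------------------------------------------------------------------------
# Selection

def select_sites(
    structure: Structure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_name: str = "CA",
    include_water: bool = False,
) -> SiteSet:
    """Select atoms by chain, inclusive residue-number range and atom name.

    Waters are excluded by default; sites are returned in file order, which
    for a well-formed chain is residue order.  Raises EmptySelectionError
    rather than returning a silent empty set.
    """
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"residue range low > high: {residue_range}")
    indices: list[int] = []
    labels: list[tuple[str, int]] = []
    for i, a in enumerate(structure.atoms):
        if a.name != atom_name:
            continue
        if not include_water and a.residue_name in _WATER_NAMES:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        indices.append(i)
        labels.append((a.chain_id, a.residue_number))
    if not indices:
        raise EmptySelectionError(
            f"no atoms match chain={chain!r} range={residue_range} name={atom_name!r}"
        )
    return SiteSet(tuple(indices), tuple(labels))


# ---------------------------------------------------------------------------
# Superposition and RMSD

def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body fit (Kabsch) of mobile onto reference.

    Returns the proper rotation R (det = +1, reflections excluded) and
    translation t minimising RMSD(mobile @ R.T + t, reference), together
    with the minimal RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 points for a rigid fit, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (mobile - mu_m).T @ (reference - mu_r)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid transform to a coordinate array."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def fit_rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_sites: SiteSet | Sequence[int],
    measure_sites: SiteSet | Sequence[int],
) -> float:
    """RMSD on measure_sites after superposing on fit_sites only.

    The rigid fit is computed from fit_sites; that single transform is then
    applied to the whole frame and the RMSD is evaluated over measure_sites
    with no re-fit.  This is the standard "fit on core, measure on the
    moving part" collective variable for relative domain motion.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit_idx = list(fit_sites.indices if isinstance(fit_sites, SiteSet) else fit_sites)
    mes_idx = list(measure_sites.indices if isinstance(measure_sites, SiteSet) else measure_sites)
    res = superpose(frame[fit_idx], reference[fit_idx])
    moved = apply_transform(frame[mes_idx], res)
    return float(np.sqrt(np.mean(np.sum((moved - reference[mes_idx]) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Contacts

def contacts_between(
    group_a: np.ndarray, group_b: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """All pairs (i in A, j in B) with distance strictly below cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    group_a = np.asarray(group_a, dtype=float).reshape(-1, 3)
    group_b = np.asarray(group_b, dtype=float).reshape(-1, 3)
    if group_a.size == 0 or group_b.size == 0:
        return []
    dm = cdist(group_a, group_b)
    ii, jj = np.nonzero(dm < cutoff)
    return [(int(i), int(j)) for i, j in zip(ii, jj)]


# ---------------------------------------------------------------------------
# Cross-structure comparison

def common_site_labels(a: SiteSet, b: SiteSet) -> list[tuple[str, int]]:
    """Labels present in both site sets, in the order of the first."""
    in_b = set(b.labels)
    return [lab for lab in a.labels if lab in in_b]


def cross_crystal_rmsd(
    path_a: str | Path,
    path_b: str | Path,
    selections: Iterable[tuple[str | None, tuple[int, int] | None]] = ((None, None),),
    atom_name: str = "CA",
) -> float:
    """RMSD between two crystal structures over their shared C-alpha atoms.

    Sites are matched by (chain, residue number) across the two files within
    the given (chain, residue_range) selections, then superposed with the
    Kabsch fit.  The matched-atom set is selection-sensitive; pass explicit
    selections to control which residues enter the fit.
    """
    sa = read_structure(path_a)
    sb = read_structure(path_b)

    def collect(s: Structure) -> dict[tuple[str, int], int]:
        table: dict[tuple[str, int], int] = {}
        for chain, rng in selections:
            try:
                sites = select_sites(s, chain=chain, residue_range=rng, atom_name=atom_name)
            except EmptySelectionError:
                continue
            for idx, lab in zip(sites.indices, sites.labels):
                table.setdefault(lab, idx)
        return table

    ta, tb = collect(sa), collect(sb)
    shared = [lab for lab in ta if lab in tb]
    if len(shared) < 3:
        raise InsufficientPointsError(f"only {len(shared)} shared sites between structures")
    ca = sa.coordinates[[ta[lab] for lab in shared]]
    cb = sb.coordinates[[tb[lab] for lab in shared]]
    return superpose(ca, cb).rmsd
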