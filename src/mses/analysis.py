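"""Ensemble observables: free-energy surfaces, basins, binding modes,
contact probabilities, linker geometry, exchange statistics, convergence.

Free energies are reported in kJ/mol (converted from the internal
kcal/mol) and min-shifted so the most populated bin sits at zero; bins
never visited are unreachable (+inf), not zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .constants import KB_KCAL, KCAL_TO_KJ
from .sampler import ExchangeEvent
from .structmodel import contacts_between


@dataclass
class FESGrid:
    """2D binned free-energy surface over two collective variables."""

    cv_names: tuple[str, str]
    edges_x: np.ndarray
    edges_y: np.ndarray
    free_energy: np.ndarray  # kJ/mol, +inf where unvisited
    counts: np.ndarray
    temperature: float  # K

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])

    def to_table(self, path: str | Path) -> None:
        """cv1_center, cv2_center, free_energy_kJ_mol, count (blank = unreachable)."""
        with open(path, "w") as fh:
            fh.write(f"{self.cv_names[0]}_center\t{self.cv_names[1]}_center\tfree_energy_kJ_mol\tcount\n")
            for i, cx in enumerate(self.centers_x):
                for j, cy in enumerate(self.centers_y):
                    f = self.free_energy[i, j]
                    fstr = f"{f:.6f}" if np.isfinite(f) else ""
                    fh.write(f"{cx:.4f}\t{cy:.4f}\t{fstr}\t{int(self.counts[i, j])}\n")

    def plot(self, path: str | Path, levels: int = 20) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        masked = np.ma.masked_invalid(self.free_energy.T)
        pc = ax.pcolormesh(self.edges_x, self.edges_y, masked, shading="auto", cmap="viridis")
        fig.colorbar(pc, ax=ax, label="free energy (kJ/mol)")
        ax.set_xlabel(self.cv_names[0])
        ax.set_ylabel(self.cv_names[1])
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


class BindingMode(enum.Enum):
    BIDENTATE = "bidentate"
    MONODENTATE_DISTAL = "monodentate_distal"
    MONODENTATE_PROXIMAL = "monodentate_proximal"
    UNBOUND = "unbound"


DEFAULT_CG_CONTACT_CUTOFF = 8.0  # A, C-alpha bead surrogate for the 4 A heavy-atom rule
DEFAULT_BIN_WIDTH = 0.25  # A on RMSD axes


def fes_2d(
    samples: np.ndarray,
    bins: int | tuple[np.ndarray, np.ndarray] | float = DEFAULT_BIN_WIDTH,
    temperature: float = 300.0,
    cv_names: tuple[str, str] = ("cv1", "cv2"),
) -> FESGrid:
    """F(bin) = -k_B T ln(count/total) over a 2D histogram, in kJ/mol.

    ``bins`` may be an integer (bins per axis), a float (bin width in CV
    units) or a pair of explicit edge arrays.  The surface is shifted so
    its occupied minimum is 0; empty bins are +inf (unreachable).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) == 0:
        raise ValueError("samples must be a non-empty (n, 2) array")
    if isinstance(bins, tuple):
        edges_x, edges_y = (np.asarray(e, dtype=float) for e in bins)
    elif isinstance(bins, float):
        edges_x = _width_edges(samples[:, 0], bins)
        edges_y = _width_edges(samples[:, 1], bins)
    else:
        edges_x = np.linspace(samples[:, 0].min(), samples[:, 0].max() + 1e-12, bins + 1)
        edges_y = np.linspace(samples[:, 1].min(), samples[:, 1].max() + 1e-12, bins + 1)
    counts, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges_x, edges_y))
    total = counts.sum()
    with np.errstate(divide="ignore"):
        f_kcal = -KB_KCAL * temperature * np.log(counts / total)
    f_kj = f_kcal * KCAL_TO_KJ
    f_kj -= np.min(f_kj[counts > 0])
    f_kj[counts == 0] = np.inf
    return FESGrid(cv_names, edges_x, edges_y, f_kj, counts.astype(int), temperature)


def _width_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width + width * 0.5
    return np.arange(lo, hi + width, width)


def reweight_fes(grid: FESGrid) -> np.ndarray:
    """Boltzmann-invert a FES back to bin probabilities (round-trip check)."""
    kt_kj = KB_KCAL * grid.temperature * KCAL_TO_KJ
    with np.errstate(over="ignore"):
        p = np.where(np.isfinite(grid.free_energy), np.exp(-grid.free_energy / kt_kj), 0.0)
    return p / p.sum()


def basin_probability(
    samples: np.ndarray, predicate: Callable[[np.ndarray], np.ndarray | bool]
) -> float:
    """Fraction of samples inside a region defined by a total predicate.

    The predicate may be vectorised (returning a boolean array for an
    (n, d) input) or act on single samples.
    """
    samples = np.asarray(samples)
    try:
        mask = np.asarray(predicate(samples))
        if mask.shape != (len(samples),):
            raise TypeError
    except TypeError:
        mask = np.array([bool(predicate(s)) for s in samples])
    return float(np.mean(mask))


def classify_binding_mode(
    coords: np.ndarray,
    binder_sites: Sequence[int],
    distal_sites: Sequence[int],
    proximal_sites: Sequence[int],
    cutoff: float = DEFAULT_CG_CONTACT_CUTOFF,
) -> BindingMode:
    """Bidentate iff the binder contacts both domains; monodentate iff one."""
    binder_set = set(binder_sites)
    if binder_set & set(distal_sites) or binder_set & set(proximal_sites):
        raise ValueError("site sets must be disjoint")
    coords = np.asarray(coords, dtype=float)
    touches_distal = bool(
        contacts_between(coords[list(binder_sites)], coords[list(distal_sites)], cutoff)
    )
    touches_proximal = bool(
        contacts_between(coords[list(binder_sites)], coords[list(proximal_sites)], cutoff)
    )
    if touches_distal and touches_proximal:
        return BindingMode.BIDENTATE
    if touches_distal:
        return BindingMode.MONODENTATE_DISTAL
    if touches_proximal:
        return BindingMode.MONODENTATE_PROXIMAL
    return BindingMode.UNBOUND


def bidentate_fraction(
    frames: np.ndarray,
    binder_sites: Sequence[int],
    distal_sites: Sequence[int],
    proximal_sites: Sequence[int],
    cutoff: float = DEFAULT_CG_CONTACT_CUTOFF,
) -> float:
    """Fraction of frames classified bidentate."""
    modes = [
        classify_binding_mode(f, binder_sites, distal_sites, proximal_sites, cutoff)
        for f in frames
    ]
    return float(np.mean([m is BindingMode.BIDENTATE for m in modes]))


def contact_probability(
    frames: np.ndarray, pair: tuple[int, int], cutoff: float
) -> float:
    """Fraction of frames in which the site pair is closer than cutoff."""
    frames = np.asarray(frames, dtype=float)
    i, j = pair
    d = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
    return float(np.mean(d < cutoff))


def linker_length(frame: np.ndarray, site_a: int, site_b: int) -> float:
    """d_linker: the Euclidean span between the two linker anchor sites."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    if not (0 <= site_a < n and 0 <= site_b < n):
        raise IndexError(f"anchor sites ({site_a}, {site_b}) out of range for {n} sites")
    return float(np.linalg.norm(frame[site_a] - frame[site_b]))


def acceptance_stats(
    events: Sequence[ExchangeEvent],
) -> tuple[float, dict[tuple[int, int], float]]:
    """Overall and per-neighbour-pair mean swap acceptance from the log."""
    if not events:
        raise ValueError("empty exchange log")
    per_pair: dict[tuple[int, int], list[bool]] = {}
    for e in events:
        per_pair.setdefault(e.rung_pair, []).append(e.accepted)
    pair_rates = {p: float(np.mean(v)) for p, v in sorted(per_pair.items())}
    overall = float(np.mean([e.accepted for e in events]))
    return overall, pair_rates


def effective_sample_size(series: np.ndarray, max_lag: int | None = None) -> float:
    """n / (1 + 2 sum of autocorrelations), with a monotone cut-off window.

    Used to turn correlated time-series into honest standard errors; the
    sum is truncated at the first non-positive autocorrelation.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise ValueError("series too short")
    y = y - y.mean()
    denom = float(y @ y)
    if denom == 0.0:
        return float(n)
    max_lag = max_lag or n // 2
    tau = 1.0
    for lag in range(1, max_lag):
        c = float(y[:-lag] @ y[lag:]) / denom
        if c <= 0.0:
            break
        tau += 2.0 * c
    return n / tau


def variance_standard_error(series: np.ndarray) -> float:
    """Standard error of the sample variance of a (correlated) series,
    using the Gaussian formula Var(s^2) ~ 2 sigma^4 / n_eff."""
    y = np.asarray(series, dtype=float).ravel()
    n_eff = effective_sample_size(y)
    return float(np.var(y) * np.sqrt(2.0 / max(n_eff - 1.0, 1.0)))


def convergence_metric(
    samples: np.ndarray, bins: int = 20
) -> float:
    """Split-half Jensen-Shannon divergence (bits) of the 2D CV histogram.

    0 for identical halves, 1 bit for disjoint distributions; values below
    ~0.05 bits indicate the two halves sample the same surface.
    1D sample arrays are treated as a single-CV histogram.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 2 samples per half")
    first, second = samples[: n // 2], samples[n // 2 :]
    lo = samples.min(axis=0)
    hi = samples.max(axis=0) + 1e-12
    edges = [np.linspace(lo[d], hi[d], bins + 1) for d in range(samples.shape[1])]
    p, _ = np.histogramdd(first, bins=edges)
    q, _ = np.histogramdd(second, bins=edges)
    p = p.ravel() / p.sum()
    q = q.ravel() / q.sum()
    return float(jensenshannon(p, q, base=2) ** 2)
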