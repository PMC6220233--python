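"""Thermostatted dynamics and Hamiltonian replica exchange.

A campaign couples R fine replicas, each assigned one rung of a
coupling-constant ladder (rung 0 carries k = 0 and yields the unbiased
target ensemble), to an accelerated coarse-grained copy.  In the default
adiabatic mode a single heavy, hot CG trajectory drives all replicas and
feels no counterforce; a fully symmetric mode (one CG per replica, forces
both ways, one temperature) exists for exactness tests, since the
adiabatic scheme is an approximation.

Exchanges between neighbouring rungs m, n use the Metropolis criterion

    p_mn = min(1, exp(Delta_mn)),
    Delta_mn = beta (k_m - k_n)(B_m - B_n),

where B = |chi_fine - chi_cg|^2 is the k-free CV mismatch of the replica
currently at the rung.  Swapping the k assignments of the two replicas
changes the total energy by -(k_m - k_n)(B_m - B_n), so this is detailed
balance for the swap move.

Dynamics use the BAOAB splitting of Langevin dynamics; with zero friction
the integrator reduces to velocity Verlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .constants import AMU_TO_SIM, KB_KCAL
from .energetics import CouplingSpec, FineModel, coupling_energy_forces, coupling_mismatch


class DivergenceError(RuntimeError):
    """Coordinates became non-finite during propagation."""


class StateCorruptionError(RuntimeError):
    """Replica/rung bookkeeping lost its one-to-one invariant."""


# ---------------------------------------------------------------------------
# Thermostat / integrator

@dataclass(frozen=True)
class ThermostatSpec:
    """Langevin thermostat parameters.

    With ``units="real"``: temperatures in K, friction in 1/ps, timestep in
    fs, and k_B T in kcal/mol.  With ``units="natural"``: the temperature
    fields are k_B T directly, friction and timestep in reciprocal/plain
    natural time units (k_B = 1).
    """

    temperature_fine: float = 300.0
    temperature_cg: float = 1000.0
    friction: float = 1.0
    timestep: float = 2.0
    units: Literal["real", "natural"] = "real"

    def __post_init__(self) -> None:
        if self.temperature_fine <= 0 or self.temperature_cg <= 0:
            raise ValueError("temperatures must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")

    @property
    def kt_fine(self) -> float:
        return KB_KCAL * self.temperature_fine if self.units == "real" else self.temperature_fine

    @property
    def kt_cg(self) -> float:
        return KB_KCAL * self.temperature_cg if self.units == "real" else self.temperature_cg

    @property
    def gamma(self) -> float:
        """Friction in reciprocal timestep-units (1/fs for real units)."""
        return self.friction * 1e-3 if self.units == "real" else self.friction

    @property
    def beta_fine(self) -> float:
        return 1.0 / self.kt_fine


def maxwell_velocities(masses: np.ndarray, kt: float, rng: np.random.Generator) -> np.ndarray:
    """Per-dof Maxwell-Boltzmann velocities for the given masses and k_B T."""
    return rng.standard_normal(masses.shape) * np.sqrt(kt / masses)


def langevin_step(
    x: np.ndarray,
    v: np.ndarray,
    forces: np.ndarray,
    masses: np.ndarray,
    kt: float,
    gamma: float,
    dt: float,
    force_fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One BAOAB Langevin step; returns (x, v, forces, energy) at t + dt.

    ``forces`` must be the forces at the input coordinates.  With gamma = 0
    (and hence no noise) this is exactly velocity Verlet.  Coordinates and
    velocities are flat per-dof arrays matching ``masses``.
    """
    v = v + 0.5 * dt * forces / masses
    x = x + 0.5 * dt * v
    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kt / masses)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    energy, f_new = force_fn(x)
    v = v + 0.5 * dt * f_new / masses
    return x, v, f_new, energy


def propagate(
    x: np.ndarray,
    v: np.ndarray,
    n_steps: int,
    masses: np.ndarray,
    kt: float,
    gamma: float,
    dt: float,
    force_fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    rng: np.random.Generator | None,
    path_out: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run n_steps of BAOAB; optionally record the coordinate path."""
    _, forces = force_fn(x)
    energy = 0.0
    for s in range(n_steps):
        x, v, forces, energy = langevin_step(x, v, forces, masses, kt, gamma, dt, force_fn, rng)
        if path_out is not None:
            path_out[s] = x
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"non-finite coordinates at step {s + 1}")
    return x, v, energy


def run_plain(
    model: FineModel,
    thermostat: ThermostatSpec,
    n_steps: int,
    seed: int,
    x0: np.ndarray,
    record_every: int = 10,
) -> np.ndarray:
    """Plain (single-replica, uncoupled) Langevin sampling of a fine model."""
    rng = np.random.default_rng(seed)
    masses = model.masses
    x = np.asarray(x0, dtype=float).ravel().copy()
    shape = np.shape(x0)
    v = maxwell_velocities(masses, thermostat.kt_fine, rng)

    def force_fn(xf: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = model.energy_forces(xf.reshape(shape))
        return e, np.asarray(f, dtype=float).ravel()

    _, forces = force_fn(x)
    samples = []
    for s in range(n_steps):
        x, v, forces, _ = langevin_step(
            x, v, forces, masses, thermostat.kt_fine, thermostat.gamma,
            thermostat.timestep, force_fn, rng,
        )
        if (s + 1) % record_every == 0:
            samples.append(x.reshape(shape).copy())
    if not samples:
        raise ValueError("n_steps too small for record_every")
    return np.array(samples)


# ---------------------------------------------------------------------------
# Ladder and exchange moves

@dataclass(frozen=True)
class Ladder:
    k_values: tuple[float, ...]

    def __post_init__(self) -> None:
        k = self.k_values
        if not k or k[0] != 0.0:
            raise ValueError("ladder must start at exactly k = 0")
        if any(b <= a for a, b in zip(k, k[1:])):
            raise ValueError("ladder must be strictly increasing")
        if any(v < 0 for v in k):
            raise ValueError("ladder values must be non-negative")

    def __len__(self) -> int:
        return len(self.k_values)

    def __getitem__(self, i: int) -> float:
        return self.k_values[i]


@dataclass(frozen=True)
class ExchangeEvent:
    iteration: int
    rung_pair: tuple[int, int]
    delta: float
    accepted: bool
    draw: float


@dataclass
class ReplicaState:
    coords: np.ndarray  # flat per-dof
    velocities: np.ndarray
    rung: int
    mismatch: float = 0.0  # B = |chi_fine - chi_cg|^2, A^2

    def __post_init__(self) -> None:
        if self.mismatch < 0:
            raise ValueError("mismatch must be non-negative")


def exchange_delta(k_m: float, k_n: float, b_m: float, b_n: float, beta: float) -> float:
    """Delta_mn = beta (k_m - k_n)(B_m - B_n); antisymmetric in (m, n)."""
    if b_m < 0 or b_n < 0:
        raise ValueError("mismatch values must be non-negative")
    return beta * (k_m - k_n) * (b_m - b_n)


def exchange_probability(delta: float) -> float:
    """min(1, exp(Delta)), overflow-safe."""
    if delta >= 0.0:
        return 1.0
    return math.exp(delta)


def attempt_exchanges(
    replicas: Sequence[ReplicaState],
    ladder: Ladder,
    parity: int,
    beta: float,
    rng: np.random.Generator,
    iteration: int = 0,
) -> list[ExchangeEvent]:
    """Metropolis swap attempts on neighbour rung pairs of one parity.

    Pairs (m, m+1) with m = parity, parity+2, ... are each tested once;
    accepted pairs swap the k (rung) assignments of the two replicas.
    """
    if parity not in (0, 1):
        raise ValueError("parity must be 0 (even) or 1 (odd)")
    by_rung: dict[int, ReplicaState] = {}
    for rep in replicas:
        if rep.rung in by_rung:
            raise StateCorruptionError(f"two replicas assigned to rung {rep.rung}")
        by_rung[rep.rung] = rep
    if set(by_rung) != set(range(len(ladder))):
        raise StateCorruptionError("replica/rung assignment is not a bijection")
    events: list[ExchangeEvent] = []
    for m in range(parity, len(ladder) - 1, 2):
        n = m + 1
        rep_m, rep_n = by_rung[m], by_rung[n]
        delta = exchange_delta(ladder[m], ladder[n], rep_m.mismatch, rep_n.mismatch, beta)
        draw = float(rng.random())
        accepted = draw < exchange_probability(delta)
        if accepted:
            rep_m.rung, rep_n.rung = n, m
        events.append(ExchangeEvent(iteration, (m, n), delta, accepted, draw))
    return events


# ---------------------------------------------------------------------------
# Campaign

@dataclass
class CampaignConfig:
    ladder: Ladder
    thermostat: ThermostatSpec = field(default_factory=ThermostatSpec)
    exchange_interval: int = 10_000  # steps between exchange attempts
    n_iterations: int = 10_000
    seed: int = 0
    mode: Literal["adiabatic", "symmetric"] = "adiabatic"
    record_all_rungs: bool = False
    log_energies: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if self.exchange_interval <= 0:
            raise ValueError("exchange_interval must be positive")


def campaign_accounting(
    config: CampaignConfig, n_simulations: int = 1
) -> dict[str, float]:
    """Wall-clock-free bookkeeping of simulated time.

    Per-simulation duration = iterations x exchange interval x timestep;
    aggregate = replicas x duration x number of independent simulations.
    Times in ns and us for real units, plain time units otherwise.
    """
    dt = config.thermostat.timestep
    interval_time = config.exchange_interval * dt  # fs (real units)
    per_sim = config.n_iterations * interval_time
    aggregate = len(config.ladder) * per_sim * n_simulations
    if config.thermostat.units == "real":
        return {
            "exchange_interval_ps": interval_time / 1e3,
            "per_simulation_ns": per_sim / 1e6,
            "aggregate_us": aggregate / 1e9,
            "n_replicas": float(len(config.ladder)),
            "n_simulations": float(n_simulations),
        }
    return {
        "exchange_interval_time": interval_time,
        "per_simulation_time": per_sim,
        "aggregate_time": aggregate,
        "n_replicas": float(len(config.ladder)),
        "n_simulations": float(n_simulations),
    }


@dataclass
class CampaignResult:
    config: CampaignConfig
    rung0_samples: np.ndarray  # (n_iterations, *coord_shape)
    exchange_events: list[ExchangeEvent]
    rung_history: np.ndarray  # (n_iterations, R): rung of each replica
    energy_log: np.ndarray  # rows: iteration, replica, k, v_mm, v_cg, v_mmcg, total
    samples_by_rung: np.ndarray | None  # (n_iterations, R, *coord_shape)
    final_replicas: list[ReplicaState]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            directory / "energy_log.tsv", self.energy_log, delimiter="\t",
            header="iteration\treplica\tk_mmcg\tv_mm\tv_cg\tv_mmcg\ttotal", comments="",
        )
        with open(directory / "exchange_log.tsv", "w") as fh:
            fh.write("iteration\trung_m\trung_n\tdelta\taccepted\tdraw\n")
            for e in self.exchange_events:
                fh.write(
                    f"{e.iteration}\t{e.rung_pair[0]}\t{e.rung_pair[1]}\t"
                    f"{e.delta:.8g}\t{int(e.accepted)}\t{e.draw:.8g}\n"
                )
        np.savetxt(directory / "rung_history.tsv", self.rung_history, fmt="%d", delimiter="\t")
        flat = self.rung0_samples.reshape(len(self.rung0_samples), -1)
        np.savetxt(directory / "rung0_samples.tsv", flat, delimiter="\t")


def run_campaign(
    config: CampaignConfig,
    fine_model: FineModel,
    cg_model: FineModel,
    coupling: CouplingSpec,
    x_fine0: np.ndarray | None = None,
    x_cg0: np.ndarray | None = None,
) -> CampaignResult:
    """Run a replica-exchange campaign over the coupling ladder.

    Adiabatic mode: a single CG trajectory is propagated at the (hot) CG
    temperature with no counterforce from the fine replicas; each fine
    replica feels the coupling force toward the time-matched CG
    configuration at its rung's k.  Symmetric mode: each replica carries
    its own CG copy at the fine temperature with forces acting both ways
    (exact joint canonical sampling; used for validation).

    The rung-0 replica's configurations, recorded once per iteration, form
    the unbiased target ensemble.  Fully reproducible from ``config.seed``.
    """
    ladder = config.ladder
    R = len(ladder)
    th = config.thermostat
    shape_f = np.shape(x_fine0 if x_fine0 is not None else fine_model.reference)
    shape_c = np.shape(x_cg0 if x_cg0 is not None else cg_model.reference)
    x0f = np.asarray(
        x_fine0 if x_fine0 is not None else fine_model.reference, dtype=float
    ).ravel()
    x0c = np.asarray(
        x_cg0 if x_cg0 is not None else cg_model.reference, dtype=float
    ).ravel()

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(R + 2)
    rep_rngs = [np.random.default_rng(c) for c in children[:R]]
    cg_rng = np.random.default_rng(children[R])
    ex_rng = np.random.default_rng(children[R + 1])

    def fine_force(xflat: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = fine_model.energy_forces(xflat.reshape(shape_f))
        return e, np.asarray(f, dtype=float).ravel()

    def cg_force(xflat: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = cg_model.energy_forces(xflat.reshape(shape_c))
        return e, np.asarray(f, dtype=float).ravel()

    replicas = [
        ReplicaState(
            coords=x0f.copy(),
            velocities=maxwell_velocities(fine_model.masses, th.kt_fine, rep_rngs[i]),
            rung=i,
        )
        for i in range(R)
    ]
    if config.mode == "adiabatic":
        cg_states = [
            ReplicaState(
                coords=x0c.copy(),
                velocities=maxwell_velocities(cg_model.masses, th.kt_cg, cg_rng),
                rung=0,
            )
        ]
    else:
        cg_states = [
            ReplicaState(
                coords=x0c.copy(),
                velocities=maxwell_velocities(cg_model.masses, th.kt_fine, rep_rngs[i]),
                rung=i,
            )
            for i in range(R)
        ]

    interval = config.exchange_interval
    n_it = config.n_iterations
    rung0_samples = np.empty((n_it,) + shape_f)
    rung_history = np.empty((n_it, R), dtype=int)
    samples_by_rung = (
        np.empty((n_it, R) + shape_f) if config.record_all_rungs else None
    )
    energy_rows: list[tuple] = []
    events: list[ExchangeEvent] = []
    beta = th.beta_fine

    cg_path = np.empty((interval, x0c.size))

    for it in range(n_it):
        if config.mode == "adiabatic":
            cg = cg_states[0]
            try:
                cg.coords, cg.velocities, _ = propagate(
                    cg.coords, cg.velocities, interval, cg_model.masses,
                    th.kt_cg, th.gamma, th.timestep, cg_force, cg_rng,
                    path_out=cg_path,
                )
            except DivergenceError as exc:
                raise DivergenceError(f"CG copy diverged at iteration {it}: {exc}") from exc
            for idx, rep in enumerate(replicas):
                k = ladder[rep.rung]
                x, v = rep.coords, rep.velocities
                _, forces = fine_force(x)
                if k > 0.0:
                    _, fc, _ = coupling_energy_forces(
                        x.reshape(shape_f), cg_path[0].reshape(shape_c), coupling, k
                    )
                    forces = forces + fc.ravel()
                rng_i = rep_rngs[idx]
                for s in range(interval):
                    xc_now = cg_path[s]

                    def force_fn(xf: np.ndarray) -> tuple[float, np.ndarray]:
                        e, f = fine_force(xf)
                        if k > 0.0:
                            ec, ff, _ = coupling_energy_forces(
                                xf.reshape(shape_f), xc_now.reshape(shape_c), coupling, k
                            )
                            return e + ec, f + ff.ravel()
                        return e, f

                    x, v, forces, _ = langevin_step(
                        x, v, forces, fine_model.masses, th.kt_fine, th.gamma,
                        th.timestep, force_fn, rng_i,
                    )
                if not np.all(np.isfinite(x)):
                    raise DivergenceError(
                        f"replica {idx} (rung {rep.rung}) diverged at iteration {it}"
                    )
                rep.coords, rep.velocities = x, v
                rep.mismatch = coupling_mismatch(
                    x.reshape(shape_f), cg.coords.reshape(shape_c), coupling
                )
        else:  # symmetric
            for idx, (rep, cgr) in enumerate(zip(replicas, cg_states)):
                k = ladder[rep.rung]
                xf, vf = rep.coords, rep.velocities
                xc, vc = cgr.coords, cgr.velocities
                rng_i = rep_rngs[idx]
                _, ff = fine_force(xf)
                _, fc = cg_force(xc)
                if k > 0.0:
                    _, cf, cc = coupling_energy_forces(
                        xf.reshape(shape_f), xc.reshape(shape_c), coupling, k
                    )
                    ff = ff + cf.ravel()
                    fc = fc + cc.ravel()
                for _s in range(interval):
                    # half-kick + drift + O for both sub-systems, then joint
                    # force refresh: equivalent to BAOAB on the joint system.
                    vf = vf + 0.5 * th.timestep * ff / fine_model.masses
                    vc = vc + 0.5 * th.timestep * fc / cg_model.masses
                    xf = xf + 0.5 * th.timestep * vf
                    xc = xc + 0.5 * th.timestep * vc
                    if th.gamma > 0.0:
                        c1 = math.exp(-th.gamma * th.timestep)
                        vf = c1 * vf + np.sqrt(
                            (1 - c1 * c1) * th.kt_fine / fine_model.masses
                        ) * rng_i.standard_normal(vf.shape)
                        vc = c1 * vc + np.sqrt(
                            (1 - c1 * c1) * th.kt_fine / cg_model.masses
                        ) * rng_i.standard_normal(vc.shape)
                    xf = xf + 0.5 * th.timestep * vf
                    xc = xc + 0.5 * th.timestep * vc
                    _, ff = fine_force(xf)
                    _, fc = cg_force(xc)
                    if k > 0.0:
                        _, cf, cc = coupling_energy_forces(
                            xf.reshape(shape_f), xc.reshape(shape_c), coupling, k
                        )
                        ff = ff + cf.ravel()
                        fc = fc + cc.ravel()
                    vf = vf + 0.5 * th.timestep * ff / fine_model.masses
                    vc = vc + 0.5 * th.timestep * fc / cg_model.masses
                if not (np.all(np.isfinite(xf)) and np.all(np.isfinite(xc))):
                    raise DivergenceError(
                        f"replica {idx} (rung {rep.rung}) diverged at iteration {it}"
                    )
                rep.coords, rep.velocities = xf, vf
                cgr.coords, cgr.velocities = xc, vc
                rep.mismatch = coupling_mismatch(
                    xf.reshape(shape_f), xc.reshape(shape_c), coupling
                )

        events.extend(
            attempt_exchanges(replicas, ladder, it % 2, beta, ex_rng, iteration=it)
        )

        by_rung = {rep.rung: i for i, rep in enumerate(replicas)}
        rung0_samples[it] = replicas[by_rung[0]].coords.reshape(shape_f)
        for i, rep in enumerate(replicas):
            rung_history[it, i] = rep.rung
        if samples_by_rung is not None:
            for rung, i in by_rung.items():
                samples_by_rung[it, rung] = replicas[i].coords.reshape(shape_f)
        if config.log_energies:
            if config.mode == "adiabatic":
                v_cg_shared, _ = cg_force(cg_states[0].coords)
            for i, rep in enumerate(replicas):
                k = ladder[rep.rung]
                v_mm, _ = fine_force(rep.coords)
                xc = cg_states[0].coords if config.mode == "adiabatic" else cg_states[i].coords
                v_cg = v_cg_shared if config.mode == "adiabatic" else cg_force(xc)[0]
                v_mmcg = k * rep.mismatch
                energy_rows.append(
                    (it, i, k, v_mm, v_cg, v_mmcg, v_mm + v_cg + v_mmcg)
                )

    energy_log = (
        np.array(energy_rows, dtype=float) if energy_rows else np.empty((0, 7))
    )
    return CampaignResult(
        config=config,
        rung0_samples=rung0_samples,
        exchange_events=events,
        rung_history=rung_history,
        energy_log=energy_log,
        samples_by_rung=samples_by_rung,
        final_replicas=replicas,
    )
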