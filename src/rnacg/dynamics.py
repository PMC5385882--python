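"""Minimization, Langevin/NVE dynamics, simulated annealing, RMSD and
energy-vs-RMSD landscapes.

Internal MD units: Å, ps, amu, kcal/mol (accelerations convert through
``KCAL_TO_MD``).  The integrator is velocity Verlet; the thermostat is
the BAOAB splitting of Langevin dynamics with friction 1/ps by default,
which keeps configurational sampling accurate at the large timesteps the
soft coarse-grained potential allows.  All stochastic entry points take
an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import KB, KCAL_TO_MD
from .energy import EnergyBreakdown, EnergyModel
from .topology import CGStructure


@dataclass
class MDState:
    positions: np.ndarray      # (N, 3) Å
    velocities: np.ndarray     # (N, 3) Å/ps
    masses: np.ndarray         # (N,) amu
    time: float = 0.0          # ps

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol."""
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities ** 2)) / KCAL_TO_MD

    def kinetic_temperature(self) -> float:
        ndof = 3 * len(self.masses)
        return 2.0 * self.kinetic_energy() / (ndof * KB)


@dataclass
class Trajectory:
    times: list = field(default_factory=list)         # ps
    frames: list = field(default_factory=list)        # (N,3) arrays
    energies: list = field(default_factory=list)      # EnergyBreakdown
    kinetic: list = field(default_factory=list)       # kcal/mol
    final_state: MDState | None = None

    def append(self, t, x, e, ke):
        self.times.append(t)
        self.frames.append(x.copy())
        self.energies.append(e)
        self.kinetic.append(ke)


@dataclass
class AnnealingSchedule:
    """Temperature ladder for annealing runs.

    The default reproduces the published protocol: ten 5 ns stages at
    298, 400, 1000, 900, 800, 700, 600, 500, 400, 298 K with a 1 fs
    timestep and snapshots every 10 ps (50 ns, 5000 snapshots).  A
    ``scale`` factor shortens every duration (and the snapshot interval)
    proportionally for desk-scale runs.
    """

    stages: list[tuple[float, float]] = field(default_factory=lambda: [
        (298.0, 5.0e3), (400.0, 5.0e3), (1000.0, 5.0e3), (900.0, 5.0e3),
        (800.0, 5.0e3), (700.0, 5.0e3), (600.0, 5.0e3), (500.0, 5.0e3),
        (400.0, 5.0e3), (298.0, 5.0e3)])   # (K, ps)
    timestep_fs: float = 1.0
    snapshot_interval_ps: float = 10.0

    def __post_init__(self):
        for temp, dur in self.stages:
            if temp <= 0 or dur <= 0:
                raise ValueError("temperatures and durations must be positive")

    def scaled(self, factor: float) -> "AnnealingSchedule":
        return AnnealingSchedule(
            [(t, d * factor) for t, d in self.stages],
            self.timestep_fs,
            self.snapshot_interval_ps * factor)


# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(masses, T, rng) -> np.ndarray:
    sigma = np.sqrt(KB * T * KCAL_TO_MD / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def minimize(structure: CGStructure, topology, ff, tol: float = 0.01,
             max_iter: int = 2000, model: EnergyModel | None = None):
    """Quasi-Newton (L-BFGS) local minimization to RMS gradient <= tol.

    Returns ``(relaxed structure, EnergyBreakdown, info)`` where ``info``
    carries convergence diagnostics.
    """
    model = model or EnergyModel(structure, ff, topology)
    x0 = structure.coords.ravel()
    e0 = model.energy(structure.coords).total
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at minimization start")

    def fun(flat):
        e, g = model.total(flat.reshape(-1, 3))
        return e.total, g.ravel()

    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iter, "ftol": 1e-12,
                                   "gtol": 1e-10})
    x = res.x.reshape(-1, 3)
    e, g = model.total(x)
    rms_g = float(np.sqrt(np.mean(g ** 2)))
    converged = rms_g <= tol
    if not converged and res.nit >= max_iter:
        warnings.warn(f"minimization hit max iterations (RMS grad {rms_g:.3g})")
    info = {"converged": converged, "rms_gradient": rms_g,
            "iterations": int(res.nit), "initial_energy": e0}
    return structure.with_coords(x), e, info


def md_run(state: MDState, topology, ff, T: float, dt_fs: float, n_steps: int,
           thermostat: str = "langevin", friction: float = 1.0,
           seed: int = 0, snapshot_stride: int = 0,
           model: EnergyModel | None = None,
           structure: CGStructure | None = None,
           extra_force=None) -> Trajectory:
    """Velocity-Verlet MD with an optional BAOAB Langevin thermostat.

    ``extra_force(x) -> (energy, gradient)`` adds a bias (umbrella
    restraints) to the physical potential.  With ``thermostat='none'``
    the run is NVE.  Identical seeds give bit-identical trajectories.
    """
    if dt_fs <= 0:
        raise ValueError("timestep must be positive")
    if model is None:
        if structure is None:
            raise ValueError("need an EnergyModel or a structure")
        model = EnergyModel(structure, ff, topology)
    rng = np.random.default_rng(seed)
    dt = dt_fs * 1e-3  # ps
    x = state.positions.copy()
    v = state.velocities.copy()
    m = state.masses
    inv_m = (KCAL_TO_MD / m)[:, None]

    def force(x):
        e, g = model.total(x)
        if extra_force is not None:
            eb, gb = extra_force(x)
            g = g + gb
        return e, -g

    traj = Trajectory()
    e, f = force(x)
    if thermostat == "langevin":
        c1 = math.exp(-friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * T * KCAL_TO_MD / m)[:, None]
    elif thermostat != "none":
        raise ValueError(f"unknown thermostat {thermostat!r}")

    t = state.time
    for step in range(1, n_steps + 1):
        v = v + 0.5 * dt * f * inv_m
        x = x + 0.5 * dt * v
        if thermostat == "langevin":
            v = c1 * v + c2 * rng.normal(size=v.shape)
        x = x + 0.5 * dt * v
        e, f = force(x)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite coordinates at step {step}")
        v = v + 0.5 * dt * f * inv_m
        t += dt
        if snapshot_stride and step % snapshot_stride == 0:
            ke = 0.5 * float(np.sum(m[:, None] * v ** 2)) / KCAL_TO_MD
            traj.append(t, x, e, ke)
    ke = 0.5 * float(np.sum(m[:, None] * v ** 2)) / KCAL_TO_MD
    if not traj.frames or traj.times[-1] != t:
        traj.append(t, x, e, ke)
    traj.final_state = MDState(x.copy(), v.copy(), m, t)
    return traj


def simulated_annealing(structure: CGStructure, topology, ff,
                        schedule: AnnealingSchedule | None = None,
                        seed: int = 0,
                        model: EnergyModel | None = None) -> Trajectory:
    """Sequential thermostatted runs through the annealing ladder."""
    schedule = schedule or AnnealingSchedule()
    model = model or EnergyModel(structure, ff, topology)
    rng = np.random.default_rng(seed)
    m = model.masses
    state = MDState(structure.coords.copy(),
                    maxwell_boltzmann_velocities(m, schedule.stages[0][0], rng),
                    m)
    out = Trajectory()
    dt = schedule.timestep_fs
    for si, (temp, dur_ps) in enumerate(schedule.stages):
        n_steps = max(1, int(round(dur_ps / (dt * 1e-3))))
        stride = max(1, int(round(schedule.snapshot_interval_ps / (dt * 1e-3))))
        seg = md_run(state, topology, ff, temp, dt, n_steps,
                     seed=int(rng.integers(2 ** 31)), snapshot_stride=stride,
                     model=model)
        for t, x, e, ke in zip(seg.times, seg.frames, seg.energies, seg.kinetic):
            out.append(t, x, e, ke)
        state = seg.final_state
    out.final_state = state
    return out


# ---------------------------------------------------------------------------

def rmsd(a, b) -> float:
    """Least-squares (Kabsch) superposed RMSD over all beads, Å."""
    xa = a.coords if isinstance(a, CGStructure) else np.asarray(a)
    xb = b.coords if isinstance(b, CGStructure) else np.asarray(b)
    if xa.shape != xb.shape:
        raise ValueError(f"bead count mismatch: {xa.shape} vs {xb.shape}")
    pa = xa - xa.mean(axis=0)
    pb = xb - xb.mean(axis=0)
    h = pa.T @ pb
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pb - pa @ rot.T
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def energy_landscape(snapshots, native: CGStructure, topology, ff,
                     tol: float = 0.05, max_iter: int = 500):
    """Minimize every snapshot and score it as (RMSD to native, energy).

    Returns ``(points, best_structure, best_energy)`` where points is an
    (n, 2) array of (RMSD Å, minimized energy kcal/mol) and
    ``best_structure`` is the minimum-energy structure — the structure
    prediction the annealing workflow reports.
    """
    if len(snapshots) == 0:
        raise ValueError("no snapshots given")
    model = EnergyModel(native, ff, topology)
    points = []
    best = None
    for x in snapshots:
        s = native.with_coords(np.asarray(x))
        relaxed, e, _ = minimize(s, topology, ff, tol=tol, max_iter=max_iter,
                                 model=model)
        r = rmsd(relaxed, native)
        points.append((r, e.total))
        if best is None or e.total < best[1]:
            best = (relaxed, e.total)
    return np.array(points), best[0], best[1]
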