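"""Umbrella-sampling pulling, WHAM, and standard-state folding free energy.

The folding coordinate is the end-to-end extension r between terminal
sugar beads.  Harmonic windows (k = 1 kcal/mol/Å², quadratic with no 1/2
factor like every harmonic term in this package) are spaced 1 Å apart
from 5.5 Å up to the contour length at 5.9 Å per nucleotide.  Window
samples are unbiased and stitched with the standard WHAM self-consistent
iteration; uncertainties come from a moving-block bootstrap (MD samples
are time-correlated).  The folded-state standard-state free energy is

    ΔG = -kT ln[ (1/V_ref) ∫_folded exp(-Δω(r)/kT) J(r) dr ]

with V_ref = 1660 Å³ (1 M) and Δω referenced to zero at the unfolded
state, located where the 4 Å-smoothed force dΔω/dr falls below
0.1 kcal/mol/Å just before the over-stretched rise.  The volume element
J(r) defaults to the spherical shell 4πr² (which makes V_ref
dimensionally consistent); J = 1 Å² is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import KB, T_REF
from .dynamics import MDState, maxwell_boltzmann_velocities, md_run
from .energy import EnergyModel
from .topology import CGStructure


@dataclass
class UmbrellaWindow:
    center: float                  # Å
    spring_k: float = 1.0          # kcal/mol/Å²
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.spring_k < 0:
            raise ValueError("spring constant must be non-negative")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite window samples")

    def bias(self, r):
        return self.spring_k * (np.asarray(r) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    r: np.ndarray                  # Å
    omega: np.ndarray              # Δω, kcal/mol (min anchored to 0)
    error: np.ndarray | None = None
    temperature: float = T_REF

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if np.any(self.error < 0):
                raise ValueError("negative uncertainty")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# free-energy profile, T={self.temperature} K\n")
            fh.write("# r(A)  dOmega(kcal/mol)  err(kcal/mol)\n")
            err = self.error if self.error is not None else np.zeros_like(self.r)
            for r, w, e in zip(self.r, self.omega, err):
                fh.write(f"{r:10.4f} {w:12.6f} {e:12.6f}\n")

    @classmethod
    def read(cls, path) -> "FreeEnergyProfile":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1],
                   data[:, 2] if data.shape[1] > 2 else None)


@dataclass
class PullConfig:
    kind: str = "hairpin"          # "hairpin" | "duplex"
    spacing: float = 1.0           # Å between window centers
    start: float = 5.5             # Å, first center
    max_center: float | None = None
    spring_k: float = 1.0          # kcal/mol/Å²
    contour_per_nt: float = 5.9    # Å per nucleotide

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.max_center is not None and self.max_center <= self.start:
            raise ValueError("max_center must exceed start")


def setup_windows(n_nt: int, config: PullConfig | None = None) -> list[UmbrellaWindow]:
    """Window centers start, start+spacing, ... up to the first grid point
    at or beyond the contour length n_nt × 5.9 Å (explicit ``max_center``
    overrides the formula)."""
    config = config or PullConfig()
    if n_nt < 2:
        raise ValueError("need at least 2 nucleotides")
    target = config.max_center
    if target is None:
        target = n_nt * config.contour_per_nt
    n_win = max(1, math.ceil((target - config.start) / config.spacing - 1e-9) + 1)
    centers = [config.start + i * config.spacing for i in range(n_win)]
    return [UmbrellaWindow(c, config.spring_k) for c in centers]


# ---------------------------------------------------------------------------
# reaction coordinate and biased MD

def _terminal_sugars(structure: CGStructure, kind: str):
    """Bead indices defining the pulling coordinate (and the duplex hold)."""
    chains = structure.chain_ids
    try:
        if kind == "hairpin":
            cid = chains[0]
            mask = structure.chain_mask(cid)
            r_lo = int(structure.resid[mask].min())
            r_hi = int(structure.resid[mask].max())
            return (structure.bead_index(cid, r_lo, "S"),
                    structure.bead_index(cid, r_hi, "S")), None
        if kind == "duplex":
            ca, cb = chains[0], chains[1]
            ma, mb = structure.chain_mask(ca), structure.chain_mask(cb)
            a_lo, a_hi = int(structure.resid[ma].min()), int(structure.resid[ma].max())
            b_lo, b_hi = int(structure.resid[mb].min()), int(structure.resid[mb].max())
            pulled = (structure.bead_index(ca, a_lo, "S"),
                      structure.bead_index(cb, b_hi, "S"))
            held = (structure.bead_index(ca, a_hi, "S"),
                    structure.bead_index(cb, b_lo, "S"))
            return pulled, held
    except KeyError as exc:
        raise ValueError(f"missing terminal sugar bead: {exc}") from None
    raise ValueError(f"unknown molecule kind {kind!r}")


def reaction_coordinate(structure: CGStructure, kind: str = "hairpin") -> float:
    """End-to-end extension: distance between terminal sugar beads, Å."""
    (i, j), _ = _terminal_sugars(structure, kind)
    return float(np.linalg.norm(structure.coords[j] - structure.coords[i]))


class _PullBias:
    """Umbrella bias on the extension plus optional duplex restraints.

    The duplex hold keeps the far-end terminal sugars together; the
    anti-hairpin restraint is a flat-bottom intra-strand end-to-end term
    engaging only when a strand contracts below ``anti_hairpin_floor``
    (preventing long-lived hairpin-like intra-strand states).
    """

    def __init__(self, structure, kind, center, spring_k,
                 hold_k=1.0, anti_hairpin_k=0.1, anti_hairpin_floor=None):
        (self.i, self.j), self.held = _terminal_sugars(structure, kind)
        self.center = center
        self.k = spring_k
        self.hold_k = hold_k
        self.hold_r0 = None
        self.anti = []
        if self.held is not None:
            self.hold_r0 = float(np.linalg.norm(
                structure.coords[self.held[1]] - structure.coords[self.held[0]]))
            if anti_hairpin_k > 0:
                for cid in structure.chain_ids:
                    mask = structure.chain_mask(cid)
                    lo = int(structure.resid[mask].min())
                    hi = int(structure.resid[mask].max())
                    a = structure.bead_index(cid, lo, "S")
                    b = structure.bead_index(cid, hi, "S")
                    n_res = hi - lo + 1
                    floor = anti_hairpin_floor
                    if floor is None:
                        floor = 0.5 * float(np.linalg.norm(
                            structure.coords[b] - structure.coords[a]))
                    self.anti.append((a, b, anti_hairpin_k, floor))

    def coordinate(self, x):
        return float(np.linalg.norm(x[self.j] - x[self.i]))

    def __call__(self, x):
        g = np.zeros_like(x)
        d = x[self.j] - x[self.i]
        r = float(np.linalg.norm(d))
        e = self.k * (r - self.center) ** 2
        f = 2.0 * self.k * (r - self.center) / r * d
        g[self.j] += f
        g[self.i] -= f
        if self.held is not None:
            a, b = self.held
            d2 = x[b] - x[a]
            r2 = float(np.linalg.norm(d2))
            e += self.hold_k * (r2 - self.hold_r0) ** 2
            f2 = 2.0 * self.hold_k * (r2 - self.hold_r0) / r2 * d2
            g[b] += f2
            g[a] -= f2
        for a, b, k, floor in self.anti:
            d3 = x[b] - x[a]
            r3 = float(np.linalg.norm(d3))
            if r3 < floor:
                e += k * (r3 - floor) ** 2
                f3 = 2.0 * k * (r3 - floor) / r3 * d3
                g[b] += f3
                g[a] -= f3
        return e, g


def run_pulling(structure: CGStructure, topology, ff,
                windows: list[UmbrellaWindow], kind: str = "hairpin",
                T: float = T_REF, dt_fs: float = 4.0,
                steps_per_window: int = 5000, equil_fraction: float = 0.2,
                sample_stride: int = 10, seed: int = 0,
                anti_hairpin_k: float = 0.1) -> list[UmbrellaWindow]:
    """Biased MD in each window; returns windows with sampled coordinates.

    Each window starts from the previous window's final frame (serial
    pulling), discards ``equil_fraction`` as equilibration and records
    the extension every ``sample_stride`` steps.
    """
    model = EnergyModel(structure, ff, topology)
    rng = np.random.default_rng(seed)
    state = MDState(structure.coords.copy(),
                    maxwell_boltzmann_velocities(model.masses, T, rng),
                    model.masses)
    out = []
    for w in windows:
        bias = _PullBias(structure, kind, w.center, w.spring_k,
                         anti_hairpin_k=anti_hairpin_k)
        traj = md_run(state, topology, ff, T, dt_fs, steps_per_window,
                      seed=int(rng.integers(2 ** 31)),
                      snapshot_stride=sample_stride, model=model,
                      extra_force=bias)
        n_eq = int(equil_fraction * len(traj.frames))
        samples = np.array([bias.coordinate(x) for x in traj.frames[n_eq:]])
        out.append(UmbrellaWindow(w.center, w.spring_k, samples))
        state = traj.final_state
    return out


# ---------------------------------------------------------------------------
# WHAM

def wham(windows: list[UmbrellaWindow], bin_width: float = 0.2,
         tol: float = 1e-6, T: float = T_REF, max_iter: int = 100000,
         check_overlap: bool = True) -> FreeEnergyProfile:
    """Standard WHAM self-consistent unbiasing of umbrella windows.

    Iterates the coupled equations for the unbiased distribution P(r)
    and the per-window shifts f_i until the largest shift change is
    below ``tol`` (kcal/mol); the profile is -kT ln P anchored at min 0.
    """
    windows = [w for w in windows if w.samples.size]
    if not windows:
        raise ValueError("no sampled windows")
    if check_overlap and len(windows) > 1:
        order = np.argsort([w.center for w in windows])
        for a, b in zip(order[:-1], order[1:]):
            if windows[a].samples.max() < windows[b].samples.min():
                raise ValueError(
                    "no sampling overlap between windows centered at "
                    f"{windows[a].center} and {windows[b].center} Å")
    kt = KB * T
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    nbins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(nbins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_iw = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_tot = n_iw.sum(axis=0).astype(float)
    n_i = n_iw.sum(axis=1).astype(float)
    bias = np.stack([w.bias(centers) for w in windows])     # (W, B)
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = np.sum(n_i[:, None] * np.exp(f[:, None] / kt) * boltz, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_tot / denom, 0.0)
        z = boltz @ (p * bin_width)
        f_new = -kt * np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        warnings.warn("WHAM did not converge to tolerance")
    denom = np.sum(n_i[:, None] * np.exp(f[:, None] / kt) * boltz, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, n_tot / denom, np.nan)
    with np.errstate(divide="ignore"):
        omega = -kt * np.log(p / np.nansum(p * bin_width))
    omega[~np.isfinite(omega)] = np.nan
    omega -= np.nanmin(omega)
    return FreeEnergyProfile(centers, omega, None, T)


def _autocorr_time(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time (samples), clipped to >= 1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0:
        return 1.0
    max_lag = max_lag or min(n // 4, 512)
    tau = 1.0
    for lag in range(1, max_lag):
        c = float(np.dot(x[:-lag], x[lag:]) / (n - lag)) / var
        if c < 0.05:
            break
        tau += 2.0 * c
    return max(tau, 1.0)


def bootstrap_error(windows: list[UmbrellaWindow], n_boot: int = 100,
                    seed: int = 0, bin_width: float = 0.2,
                    tol: float = 1e-6, T: float = T_REF):
    """Moving-block bootstrap over window time series, re-running WHAM.

    Returns ``(profile, flags)`` where the profile carries per-bin
    standard deviations interpolated onto the full-data grid.  With
    n_boot < 2 the estimate has zero variance and is flagged
    insufficient.
    """
    base = wham(windows, bin_width, tol, T)
    flags = {"sufficient": n_boot >= 2, "n_boot": n_boot}
    if n_boot < 2:
        base.error = np.zeros_like(base.omega)
        return base, flags
    rng = np.random.default_rng(seed)
    blocks = [max(1, int(round(_autocorr_time(w.samples)))) for w in windows]
    profiles = np.full((n_boot, len(base.r)), np.nan)
    for b in range(n_boot):
        resampled = []
        for w, bl in zip(windows, blocks):
            x = w.samples
            n = len(x)
            n_blocks = math.ceil(n / bl)
            starts = rng.integers(0, max(n - bl, 1), size=n_blocks)
            xs = np.concatenate([x[s:s + bl] for s in starts])[:n]
            resampled.append(UmbrellaWindow(w.center, w.spring_k, xs))
        try:
            p = wham(resampled, bin_width, tol, T, check_overlap=False)
        except ValueError:
            continue
        profiles[b] = np.interp(base.r, p.r, p.omega, left=np.nan, right=np.nan)
    err = np.nanstd(profiles, axis=0)
    base.error = np.where(np.isfinite(err), err, 0.0)
    return base, flags


# ---------------------------------------------------------------------------
# force curve, unfolded state, ΔG

def force_curve(profile: FreeEnergyProfile, smoothing: float = 4.0) -> np.ndarray:
    """dΔω/dr smoothed by a running average of width ``smoothing`` Å.

    Centered finite differences on the uniform grid; the averaging
    window shrinks symmetrically at the edges.
    """
    r, w = profile.r, profile.omega
    dx = np.diff(r)
    if not np.allclose(dx, dx[0], rtol=1e-6):
        raise ValueError("profile grid must be uniform")
    h = float(dx[0])
    half = int(round(0.5 * smoothing / h))
    if half < 1:
        raise ValueError("grid too coarse for the smoothing window")
    raw = np.gradient(w, r)
    sm = np.empty_like(raw)
    n = len(raw)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        sm[i] = raw[i - k:i + k + 1].mean()
    return sm


def find_unfolded_state(profile: FreeEnergyProfile, force: np.ndarray,
                        threshold: float = 0.1, require_rise: bool = True):
    """Locate the unfolded state: last sub-threshold force point before the
    terminal contiguous super-threshold (over-stretched) rise.

    Returns ``(r_unfolded, omega_unfolded)``; raises if the force never
    drops below threshold, or (unless ``require_rise`` is False) if no
    terminal rise exists.
    """
    force = np.asarray(force)
    sub = force < threshold
    if not np.any(sub):
        raise ValueError("no unfolded plateau: force everywhere above threshold")
    if sub[-1]:
        if require_rise:
            raise ValueError("no over-stretched rise at the end of the profile")
        idx = int(np.nonzero(sub)[0][-1])
    else:
        idx = int(np.nonzero(sub)[0][-1])   # last sub-threshold point
    return float(profile.r[idx]), float(profile.omega[idx])


def delta_g_fold(profile: FreeEnergyProfile, r_unfolded: float,
                 T: float = T_REF, v_ref: float = 1660.0,
                 jacobian: str = "spherical") -> float:
    """Standard-state folding free energy from the extension profile.

    Δω is referenced to zero at the unfolded state, the folded region is
    every grid point left of ``r_unfolded``, and

        ΔG = -kT ln[(1/V_ref) ∫ exp(-Δω/kT) J(r) dr]

    with J(r) = 4πr² (``jacobian='spherical'``) or 1 Å²
    (``jacobian='unit'``).
    """
    kt = KB * T
    r, w = profile.r, profile.omega
    shift = float(np.interp(r_unfolded, r, w))
    sel = r <= r_unfolded
    if not np.any(sel):
        raise ValueError("empty folded region")
    rr, ww = r[sel], w[sel] - shift
    if jacobian == "spherical":
        J = 4.0 * math.pi * rr ** 2
    elif jacobian == "unit":
        J = np.ones_like(rr)
    else:
        raise ValueError(f"unknown jacobian convention {jacobian!r}")
    integral = float(np.trapezoid(np.exp(-ww / kt) * J, rr))
    return -kt * math.log(integral / v_ref)


# ---------------------------------------------------------------------------
# comparison against reference tables

def correlation_report(predicted, reference):
    """Least-squares regression of predicted ΔG on reference ΔG.

    Inputs are label→value mappings (or pandas Series); labels must
    match exactly.  Returns R², slope, intercept and per-label residuals
    from the fitted line.
    """
    from scipy.stats import linregress

    pred = dict(predicted)
    ref = dict(reference)
    if set(pred) != set(ref):
        missing = set(pred) ^ set(ref)
        raise ValueError(f"mismatched labels: {sorted(missing)}")
    labels = sorted(pred)
    if len(labels) < 3:
        raise ValueError("need at least 3 points for a correlation report")
    x = np.array([ref[k] for k in labels])
    y = np.array([pred[k] for k in labels])
    fit = linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return {
        "r_squared": float(fit.rvalue ** 2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": len(labels),
        "residuals": dict(zip(labels, resid.tolist())),
    }


def load_reference_table(path=None):
    """Bundled table of published unfolding free energies (11 RNAs)."""
    import pandas as pd

    if path is None:
        path = Path(__file__).parent / "data" / "unfolding_dg.tsv"
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# window-file I/O (plain-text time series, one file per window)

def write_window_set(windows, directory, dt_ps: float = 1.0) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = ["# window  center(A)  spring_k(kcal/mol/A^2)  file"]
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        with open(d / fname, "w") as fh:
            fh.write("# time(ps)  r(A)\n")
            for t, r in enumerate(w.samples):
                fh.write(f"{t * dt_ps:12.3f} {r:10.4f}\n")
        meta.append(f"{i:3d} {w.center:10.3f} {w.spring_k:8.3f}  {fname}")
    (d / "windows.meta").write_text("\n".join(meta) + "\n")


def read_window_set(directory) -> list[UmbrellaWindow]:
    d = Path(directory)
    windows = []
    for line in (d / "windows.meta").read_text().splitlines():
        if line.startswith("#"):
            continue
        _, center, k, fname = line.split()
        data = np.loadtxt(d / fname)
        samples = data[:, 1] if data.ndim > 1 else np.empty(0)
        windows.append(UmbrellaWindow(float(center), float(k), samples))
    return windows
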