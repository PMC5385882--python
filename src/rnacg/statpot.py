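"""Statistical potentials from structure sets.

Pair distances between bead types are harvested into histograms,
normalized into radial distribution functions, and Boltzmann-inverted
into potentials of mean force, G(r) = -kT ln g(r), shifted so the
minimum is 0.  Two RDF normalizations are supported: the conventional
3-D spherical-shell form n(r)/(4πr²Δr) appropriate for isotropic
systems, and a 1-D form n(r)/Δr appropriate for quasi-linear molecules
such as short RNA helices.  For a linear molecule the 3-D PMF keeps
rising at long range (the shell volume grows but the molecule does not
fill it) while the 1-D PMF decays to zero — the diagnostic that
motivates the 1-D treatment.

Energy-term parameters are fitted to PMF curves by weighted least
squares (`fit_vdw_eff`, `fit_bonded`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import KB, T_REF
from .forcefield import vdw_eff
from .topology import CGStructure, build_topology


@dataclass
class DistanceHistogram:
    pair: tuple[str, str]
    edges: np.ndarray          # Å, len nbins+1
    counts: np.ndarray         # per-bin pair counts
    n_i: int                   # total beads of first type
    n_j: int                   # total beads of second type
    n_structures: int = 1

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n_pairs(self) -> float:
        """Distinct pair count used for normalization."""
        if self.pair[0] == self.pair[1]:
            return self.n_i * (self.n_i - 1) / 2.0
        return float(self.n_i * self.n_j)


@dataclass
class PMFCurve:
    r: np.ndarray              # Å
    g_r: np.ndarray            # kcal/mol (G(r); name keeps free energy/rdf apart)
    mode: str                  # "1D" | "3D"
    temperature: float = T_REF
    valid: np.ndarray = field(default=None)   # bins with nonzero counts

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.g_r = np.asarray(self.g_r, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.g_r)

    def write(self, path, header: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"# PMF curve ({self.mode} normalization, T={self.temperature} K)\n")
            if header:
                fh.write(f"# {header}\n")
            fh.write("# r(A)  G(kcal/mol)\n")
            for r, g, v in zip(self.r, self.g_r, self.valid):
                fh.write(f"{r:10.4f} {g:12.6f}\n" if v else f"{r:10.4f}      nan\n")


# ---------------------------------------------------------------------------

def collect_pair_distances(structures, pair, r_max: float = 20.0,
                           bin_width: float = 0.1) -> DistanceHistogram:
    """Histogram all non-excluded distances between beads of a type pair.

    Bonded 1-2 and 1-3 pairs are skipped (they carry bonded terms, not
    non-bonded statistics).
    """
    structures = list(structures)
    if not structures:
        raise ValueError("empty structure list")
    ta, tb = pair
    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    counts = np.zeros(nbins)
    n_i = n_j = 0
    for s in structures:
        if not isinstance(s, CGStructure):
            raise TypeError("expected CGStructure inputs")
        top = build_topology(s)
        types = np.asarray(s.bead_types)
        ia = np.nonzero(types == ta)[0]
        ib = np.nonzero(types == tb)[0]
        n_i += len(ia)
        n_j += len(ib)
        seen = set()
        for i in ia:
            for j in ib:
                if i == j:
                    continue
                key = frozenset((int(i), int(j)))
                if key in seen or key in top.exclusions:
                    continue
                seen.add(key)
                r = float(np.linalg.norm(s.coords[j] - s.coords[i]))
                if r < edges[-1]:
                    counts[int(r / bin_width)] += 1
    return DistanceHistogram((ta, tb), edges, counts, n_i, n_j, len(structures))


def histogram_from_points(points: np.ndarray, r_max: float = 20.0,
                          bin_width: float = 0.1) -> DistanceHistogram:
    """All-pairs histogram of a bare point set (RDF fixtures)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    r = d[iu]
    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    counts, _ = np.histogram(r, bins=edges)
    return DistanceHistogram(("X", "X"), edges, counts.astype(float), n, n)


def rdf(histogram: DistanceHistogram, mode: str, volume: float | None = None,
        length: float | None = None) -> np.ndarray:
    """Normalize a distance histogram into g(r) on the bin grid.

    3D mode divides by the ideal-gas shell expectation
    ``n_pairs * 4πr²Δr / V``; 1D mode divides by ``n_pairs * Δr / L``.
    When the reference volume/length is not given, g is self-normalized
    so its mean over the outer 20% of the r range is 1 (the operational
    g→1 asymptote).
    """
    if histogram.counts.sum() == 0:
        raise ValueError("empty histogram")
    r = histogram.centers
    dr = histogram.widths
    if np.any(dr <= 0):
        raise ValueError("zero-width bins")
    if mode == "3D":
        ref = histogram.n_pairs * 4.0 * math.pi * r ** 2 * dr
        g = histogram.counts / ref                       # density × V
        if volume is not None:
            g = g * volume
        else:
            g = _self_normalize(g, histogram.counts)
    elif mode == "1D":
        # the 1-D "shell" at distance r is the two points ±r: factor 2 dr
        ref = histogram.n_pairs * 2.0 * dr
        g = histogram.counts / ref                       # density × L
        if length is not None:
            g = g * length
        else:
            g = _self_normalize(g, histogram.counts)
    else:
        raise ValueError(f"unknown RDF mode {mode!r}")
    return g


def _self_normalize(g, counts):
    n = len(g)
    tail = slice(int(0.8 * n), n)
    w = counts[tail]
    if w.sum() == 0:
        raise ValueError("no counts in the outer 20% of the r range; "
                         "supply an explicit reference volume/length")
    scale = np.average(g[tail], weights=np.ones_like(w))
    return g / scale


def pmf_from_rdf(g: np.ndarray, r: np.ndarray, T: float = T_REF,
                 mode: str = "1D") -> PMFCurve:
    """Boltzmann inversion G(r) = -kT ln g(r), minimum shifted to zero."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("negative g(r)")
    valid = g > 0
    if not np.any(valid):
        raise ValueError("g(r) vanishes everywhere")
    G = np.full_like(g, np.nan)
    G[valid] = -KB * T * np.log(g[valid])
    G[valid] -= np.nanmin(G[valid])
    return PMFCurve(r, G, mode, T, valid)


# ---------------------------------------------------------------------------
# fitting

def fit_vdw_eff(pmf: PMFCurve, r_window: tuple[float, float]):
    """Fit (eps, sigma, gamma) of the effective vdW form to a PMF well.

    The PMF is referenced to min = 0 while the pair potential has its
    minimum at -eps, so a free additive offset is fitted alongside.
    Multi-start least squares; returns a dict with parameters, residual
    and a convergence flag (``ok=False`` with no parameters when the
    window has no interior well).
    """
    lo, hi = r_window
    sel = pmf.valid & (pmf.r >= lo) & (pmf.r <= hi)
    r = pmf.r[sel]
    G = pmf.g_r[sel]
    if len(r) < 8:
        return {"ok": False, "reason": "too few valid points in window"}
    imin = int(np.argmin(G))
    plateau = G[-max(3, len(G) // 5):].mean()
    if imin in (0, len(G) - 1) or G[imin] >= plateau - 1e-3:
        return {"ok": False, "reason": "no interior minimum in window"}

    sigma0 = r[imin]
    depth0 = max(plateau - G[imin], 1e-3)

    def resid(p):
        eps, sigma, gamma, c = p
        u, _ = vdw_eff(r, eps, sigma, gamma)
        return u + c - G

    best = None
    for gamma0 in (5.0, 10.0, 20.0):
        try:
            res = least_squares(resid, [depth0, sigma0, gamma0, depth0],
                                bounds=([1e-6, 0.5, 0.5, -50.0],
                                        [50.0, 20.0, 200.0, 50.0]))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return {"ok": False, "reason": "optimization failed"}
    eps, sigma, gamma, c = best.x
    return {"ok": True, "eps": float(eps), "sigma": float(sigma),
            "gamma": float(gamma), "offset": float(c),
            "residual": float(np.sqrt(2 * best.cost / len(r)))}


def fit_bonded(samples: np.ndarray, kind: str, T: float = T_REF,
               nbins: int = 72):
    """Boltzmann-invert a bonded-coordinate sample set and fit parameters.

    kind='bond'/'angle': weighted least-squares harmonic fit
    ``k(x-x0)^2 + c`` to -kT ln p(x); for a Gaussian distribution this
    recovers k = kT/(2 sd²) analytically.  kind='torsion': three-term
    Fourier fit returning (k_n, delta_n), via the linear reparameterization
    ``sum_n a_n cos(n phi) + b_n sin(n phi) + const``.
    A multimodal bond/angle distribution triggers a warning and the fit
    is restricted to the dominant mode.
    """
    import warnings as _w

    x = np.asarray(samples, dtype=float)
    if kind in ("bond", "angle"):
        counts, edges = np.histogram(x, bins=nbins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        sel = counts > 0
        # detect multimodality: number of separated count clusters
        occupied = counts > max(3, 0.02 * counts.max())
        runs = np.diff(np.concatenate([[0], occupied.astype(int), [0]]))
        if (runs == 1).sum() > 1:
            _w.warn(f"multimodal {kind} distribution; fitting dominant mode")
            # keep the run containing the global maximum
            starts = np.nonzero(runs == 1)[0]
            ends = np.nonzero(runs == -1)[0]
            imax = int(np.argmax(counts))
            for s0, e0 in zip(starts, ends):
                if s0 <= imax < e0:
                    sel = sel & (np.arange(nbins) >= s0) & (np.arange(nbins) < e0)
        G = -KB * T * np.log(counts[sel] / counts[sel].max())
        c = centers[sel]
        w = counts[sel].astype(float)
        # weighted quadratic fit
        A = np.stack([c ** 2, c, np.ones_like(c)], axis=1)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], G * sw, rcond=None)
        a2, a1, _ = coef
        if a2 <= 0:
            return {"ok": False, "reason": "non-convex inverted distribution"}
        k = float(a2)
        x0 = float(-a1 / (2 * a2))
        return {"ok": True, "k": k, "x0": x0}
    if kind == "torsion":
        counts, edges = np.histogram(x, bins=nbins, range=(-math.pi, math.pi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        sel = counts > 0
        G = -KB * T * np.log(counts[sel] / counts[sel].max())
        c = centers[sel]
        w = np.sqrt(counts[sel].astype(float))
        cols = [np.ones_like(c)]
        for n in (1, 2, 3):
            cols += [np.cos(n * c), np.sin(n * c)]
        A = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(A * w[:, None], G * w, rcond=None)
        out = {"ok": True, "k": [], "delta": []}
        for n in (1, 2, 3):
            a, b = coef[2 * n - 1], coef[2 * n]
            out["k"].append(float(math.hypot(a, b)))
            out["delta"].append(float(math.atan2(b, a)))
        return out
    raise ValueError(f"unknown bonded kind {kind!r}")
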