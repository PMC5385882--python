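"""Force-field parameter tables and the non-bonded pair functions.

The potential has six terms: harmonic bonds ``k(r-r0)^2`` and angles
``k(theta-theta0)^2`` (no 1/2 prefactor — the convention the parameter
files assume), a three-term Fourier torsion ``sum_n k_n[1+cos(n*phi -
delta_n)]``, an effective van-der-Waals pair potential with a tunable
short-range wall, a directional hydrogen-bond term between eligible
base-bead pairs, and Debye-Hückel screened electrostatics on the
phosphates.

The effective vdW term is a potential of mean force between bead pairs,
not a true dispersion interaction; it is parameterized per bead type by
a well depth ``eps`` (kcal/mol), a minimum-energy distance ``sigma``
(Å) and a dimensionless steepness ``gamma``.  The implemented form is
Morse-like,

    U(r) = eps * (exp(-2*g*(r-sigma)) - 2*exp(-g*(r-sigma))),  g = gamma/sigma

which satisfies U(sigma) = -eps, U'(sigma) = 0, U(inf) = 0, has a
short-range wall far softer than a Lennard-Jones r^-12 (the reason a
flexible third parameter is needed at all), and steepens as gamma
grows.  Combining rules for unlike types: geometric mean for eps and
gamma, arithmetic mean for sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class HBondParams:
    eps_max: float = 2.0       # kcal/mol, well depth at ideal geometry
    sigma_eq: float = 2.9      # Å, equilibrium H-bond distance
    cutoff: float = 6.0        # Å, base-edge cutoff
    switch_on: float = 4.5     # Å, start of the smooth truncation window
    # unordered type-pair → (class, scale); pair energy depth = eps_max*scale
    pairs: dict[frozenset, tuple[str, float]] = field(default_factory=dict)


@dataclass
class ForceField:
    """Parameter tables for all six energy terms.

    Bond/angle/torsion parameters are keyed by bead-type tuples
    (direction-canonicalized); lookups raise ``KeyError`` naming the
    offending key when a term has no parameters.
    """

    types: dict[str, "object"] = field(default_factory=dict)   # name → PseudoatomType
    bonds: dict = field(default_factory=dict)      # (tA,tB) sorted → (k, r0)
    angles: dict = field(default_factory=dict)     # canonical triple → (k, theta0 rad)
    torsions: dict = field(default_factory=dict)   # canonical quad → ((k1,k2,k3),(d1,d2,d3) rad)
    vdw: dict = field(default_factory=dict)        # type → (eps, sigma, gamma)
    hbond: HBondParams = field(default_factory=HBondParams)
    dielectric: float = 25.0
    debye_length: float = 10.0                     # Å
    vdw_cutoff: float = 12.0                       # Å
    ele_cutoff_factor: float = 4.0                 # cutoff = factor * debye_length

    def __post_init__(self):
        for name, (eps, sig, gam) in self.vdw.items():
            if eps < 0 or sig <= 0 or gam <= 0:
                raise ValueError(f"invalid vdW parameters for type {name}")
        if self.dielectric <= 0 or self.debye_length <= 0:
            raise ValueError("dielectric and Debye length must be positive")
        if self.hbond.cutoff <= self.hbond.sigma_eq:
            raise ValueError("H-bond cutoff must exceed the equilibrium distance")

    # -- lookups -----------------------------------------------------------
    def bond_params(self, ta: str, tb: str):
        key = tuple(sorted((ta, tb)))
        try:
            return self.bonds[key]
        except KeyError:
            raise KeyError(f"no bond parameters for type pair {key}") from None

    def angle_params(self, ta: str, tb: str, tc: str):
        key = min((ta, tb, tc), (tc, tb, ta))
        try:
            return self.angles[key]
        except KeyError:
            raise KeyError(f"no angle parameters for type triple {key}") from None

    def torsion_params(self, ta, tb, tc, td):
        key = min((ta, tb, tc, td), (td, tc, tb, ta))
        try:
            return self.torsions[key]
        except KeyError:
            raise KeyError(f"no torsion parameters for type quad {key}") from None

    def combine_vdw(self, ta: str, tb: str):
        """Pair (eps, sigma, gamma): geometric eps/gamma, arithmetic sigma."""
        ea, sa, ga = self.vdw[ta]
        eb, sb, gb = self.vdw[tb]
        return math.sqrt(ea * eb), 0.5 * (sa + sb), math.sqrt(ga * gb)

    def charge(self, t: str) -> float:
        return self.types[t].charge

    @property
    def ele_cutoff(self) -> float:
        return self.ele_cutoff_factor * self.debye_length

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def default(cls) -> "ForceField":
        return cls.from_file(_DATA_DIR / "default.ff")

    @classmethod
    def from_file(cls, path) -> "ForceField":
        from .topology import PseudoatomType

        ff = cls()
        section = None
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            tok = line.split()
            if section == "types":
                ff.types[tok[0]] = PseudoatomType(tok[0], tok[1], float(tok[2]), float(tok[3]))
            elif section == "bonds":
                ff.bonds[tuple(sorted(tok[:2]))] = (float(tok[2]), float(tok[3]))
            elif section == "angles":
                key = min(tuple(tok[:3]), tuple(tok[:3])[::-1])
                ff.angles[key] = (float(tok[3]), math.radians(float(tok[4])))
            elif section == "torsions":
                key = min(tuple(tok[:4]), tuple(tok[:4])[::-1])
                ks = tuple(float(tok[4 + 2 * n]) for n in range(3))
                ds = tuple(math.radians(float(tok[5 + 2 * n])) for n in range(3))
                ff.torsions[key] = (ks, ds)
            elif section == "vdw":
                ff.vdw[tok[0]] = (float(tok[1]), float(tok[2]), float(tok[3]))
            elif section == "hbond":
                if tok[0] == "pair":
                    ff.hbond.pairs[frozenset(tok[1:3])] = (
                        tok[3], float(tok[4]) if len(tok) > 4 else 1.0)
                else:
                    setattr(ff.hbond, tok[0], float(tok[1]))
            elif section == "electrostatics":
                if tok[0] == "dielectric":
                    ff.dielectric = float(tok[1])
                elif tok[0] == "debye_length":
                    ff.debye_length = float(tok[1])
                elif tok[0] == "cutoff_factor":
                    ff.ele_cutoff_factor = float(tok[1])
            elif section == "options":
                if tok[0] == "vdw_cutoff":
                    ff.vdw_cutoff = float(tok[1])
            else:
                raise ValueError(f"line outside a known section: {raw!r}")
        ff.__post_init__()
        return ff


# ---------------------------------------------------------------------------
# pair functions (scalar r; vectorized over numpy arrays)

def vdw_eff(r, eps, sigma, gamma):
    """Effective vdW pair energy (kcal/mol) and dU/dr."""
    a = gamma / sigma
    e1 = np.exp(-a * (r - sigma))
    u = eps * (e1 * e1 - 2.0 * e1)
    du = eps * a * (-2.0 * e1 * e1 + 2.0 * e1)
    return u, du


def vdw_eff_shifted(r, eps, sigma, gamma, cutoff):
    """Cutoff form: energy-shifted to zero at the cutoff, zero beyond."""
    u, du = vdw_eff(r, eps, sigma, gamma)
    uc, _ = vdw_eff(cutoff, eps, sigma, gamma)
    inside = r < cutoff
    return np.where(inside, u - uc, 0.0), np.where(inside, du, 0.0)


def debye_huckel(r, qq, dielectric, debye_length, coulomb):
    """Screened Coulomb energy C*q_i*q_j*exp(-r/xi)/(D*r) and dU/dr."""
    pref = coulomb * qq / dielectric
    e = np.exp(-np.asarray(r) / debye_length)
    u = pref * e / r
    du = -pref * e * (1.0 / (r * r) + 1.0 / (debye_length * r))
    return u, du


def debye_huckel_shifted(r, qq, dielectric, debye_length, coulomb, cutoff):
    u, du = debye_huckel(r, qq, dielectric, debye_length, coulomb)
    uc, _ = debye_huckel(cutoff, qq, dielectric, debye_length, coulomb)
    inside = np.asarray(r) < cutoff
    return np.where(inside, u - uc, 0.0), np.where(inside, du, 0.0)


def hbond_radial(r, sigma_eq):
    """10-12 radial profile R(r) with R(sigma_eq)=1, R'(sigma_eq)=0."""
    s = sigma_eq / np.asarray(r)
    s10 = s ** 10
    s12 = s ** 12
    val = 6.0 * s10 - 5.0 * s12
    dval = (-60.0 * s10 + 60.0 * s12) / r
    return val, dval


def hbond_switch(r, switch_on, cutoff):
    """Quintic switch: 1 below switch_on, 0 at/after cutoff, C2 smooth."""
    r = np.asarray(r, dtype=float)
    t = np.clip((r - switch_on) / (cutoff - switch_on), 0.0, 1.0)
    s = 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t * t)
    ds = -(30.0 * t ** 2 - 60.0 * t ** 3 + 30.0 * t ** 4) / (cutoff - switch_on)
    ds = np.where((r > switch_on) & (r < cutoff), ds, 0.0)
    return s, ds


def hbond_pair_energy(r, cos_i, cos_j, hb: HBondParams, scale: float = 1.0):
    """Pair energy -eps*R(r)*S(r)*f(cos_i)*f(cos_j), f(c)=max(c,0)^2.

    ``cos_i``/``cos_j`` are the cosines of the directional angles between
    each base's edge vector and the interatomic direction; at ideal
    alignment (both 1) and r = sigma_eq the energy is -eps_max*scale.
    """
    if r >= hb.cutoff:
        return 0.0
    rad, _ = hbond_radial(r, hb.sigma_eq)
    sw, _ = hbond_switch(r, hb.switch_on, hb.cutoff)
    fi = max(cos_i, 0.0) ** 2
    fj = max(cos_j, 0.0) ** 2
    return float(-hb.eps_max * scale * rad * sw * fi * fj)
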