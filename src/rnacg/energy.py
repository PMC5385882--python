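"""Six-term potential energy and its analytic gradient.

``EnergyModel`` binds a structure's topology to a force field once and
precomputes index/parameter arrays; every term then evaluates in a few
vectorized numpy operations.  All terms return ``(energy, gradient)``
with the gradient dE/dx of shape (N, 3); forces are the negative.

Conventions: harmonic terms use ``k*(x-x0)**2`` with no 1/2 prefactor;
torsion angles follow the IUPAC sign convention; non-bonded terms skip
1-2 and 1-3 pairs and use energy-shifted cutoffs, except the hydrogen
bond whose quintic switch zeroes both energy and gradient at 6 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB
from .forcefield import (ForceField, debye_huckel_shifted, hbond_radial,
                         hbond_switch, vdw_eff_shifted)
from .topology import CGStructure, Topology, build_topology

_SIN_FLOOR = 1e-8


@dataclass
class EnergyBreakdown:
    e_bond: float
    e_angle: float
    e_torsion: float
    e_vdw_eff: float
    e_hb: float
    e_ele: float
    total: float

    @classmethod
    def from_terms(cls, b, a, t, v, h, e):
        return cls(b, a, t, v, h, e, b + a + t + v + h + e)


class EnergyModel:
    """Precompiled evaluator for one (structure, force field) pair."""

    def __init__(self, structure: CGStructure, ff: ForceField,
                 topology: Topology | None = None):
        self.ff = ff
        self.structure = structure
        if topology is None:
            topology = build_topology(structure, set(ff.hbond.pairs))
        self.topology = topology
        types = structure.bead_types
        n = structure.n_beads
        self.n_beads = n
        self.masses = np.array([ff.types[t].mass for t in types])

        self.bond_idx = np.array(topology.bonds, dtype=int).reshape(-1, 2)
        bp = [ff.bond_params(types[i], types[j]) for i, j in topology.bonds]
        self.bond_k = np.array([p[0] for p in bp])
        self.bond_r0 = np.array([p[1] for p in bp])

        self.angle_idx = np.array(topology.angles, dtype=int).reshape(-1, 3)
        ap = [ff.angle_params(types[i], types[j], types[k])
              for i, j, k in topology.angles]
        self.angle_k = np.array([p[0] for p in ap])
        self.angle_t0 = np.array([p[1] for p in ap])

        self.tors_idx = np.array(topology.torsions, dtype=int).reshape(-1, 4)
        tp = [ff.torsion_params(types[i], types[j], types[k], types[l])
              for i, j, k, l in topology.torsions]
        self.tors_k = np.array([p[0] for p in tp]).reshape(-1, 3)
        self.tors_d = np.array([p[1] for p in tp]).reshape(-1, 3)

        # non-bonded pair lists (exclusions applied once)
        pi, pj = np.triu_indices(n, k=1)
        keep = np.array([frozenset((int(a), int(b))) not in topology.exclusions
                         for a, b in zip(pi, pj)], dtype=bool)
        self.nb_i, self.nb_j = pi[keep], pj[keep]
        comb = [ff.combine_vdw(types[i], types[j])
                for i, j in zip(self.nb_i, self.nb_j)]
        self.nb_eps = np.array([c[0] for c in comb])
        self.nb_sig = np.array([c[1] for c in comb])
        self.nb_gam = np.array([c[2] for c in comb])

        q = np.array([ff.charge(t) for t in types])
        qq = q[self.nb_i] * q[self.nb_j]
        sel = qq != 0.0
        self.el_i, self.el_j, self.el_qq = self.nb_i[sel], self.nb_j[sel], qq[sel]

        self.hb_idx = np.array(topology.hbond_pairs, dtype=int).reshape(-1, 2)
        self.hb_scale = np.array([
            ff.hbond.pairs[frozenset((types[i], types[j]))][1]
            for i, j in topology.hbond_pairs])
        self.base_mates = topology.base_mates

    # -- individual terms --------------------------------------------------
    def e_bond(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.bond_idx) == 0:
            return 0.0, g
        d = x[self.bond_idx[:, 1]] - x[self.bond_idx[:, 0]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise ValueError("zero-length bond")
        dr = r - self.bond_r0
        e = float(np.sum(self.bond_k * dr * dr))
        f = (2.0 * self.bond_k * dr / r)[:, None] * d
        np.add.at(g, self.bond_idx[:, 1], f)
        np.add.at(g, self.bond_idx[:, 0], -f)
        return e, g

    def e_angle(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.angle_idx) == 0:
            return 0.0, g
        ia, ib, ic = self.angle_idx.T
        u = x[ia] - x[ib]
        v = x[ic] - x[ib]
        lu = np.linalg.norm(u, axis=1)
        lv = np.linalg.norm(v, axis=1)
        uh, vh = u / lu[:, None], v / lv[:, None]
        c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        th = np.arccos(c)
        s = np.maximum(np.sqrt(1.0 - c * c), _SIN_FLOOR)
        dth = th - self.angle_t0
        e = float(np.sum(self.angle_k * dth * dth))
        pref = -2.0 * self.angle_k * dth / s
        ga = pref[:, None] * (vh - c[:, None] * uh) / lu[:, None]
        gc = pref[:, None] * (uh - c[:, None] * vh) / lv[:, None]
        np.add.at(g, ia, ga)
        np.add.at(g, ic, gc)
        np.add.at(g, ib, -(ga + gc))
        return e, g

    def e_torsion(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.tors_idx) == 0:
            return 0.0, g
        ii, jj, kk, ll = self.tors_idx.T
        b1 = x[jj] - x[ii]
        b2 = x[kk] - x[jj]
        b3 = x[ll] - x[kk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        l2 = np.linalg.norm(b2, axis=1)
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        sc1 = np.sum(b1 * b1, axis=1) * np.sum(b2 * b2, axis=1)
        sc2 = np.sum(b2 * b2, axis=1) * np.sum(b3 * b3, axis=1)
        degen = (n1sq < 1e-12 * sc1) | (n2sq < 1e-12 * sc2)
        if np.any(degen):
            warnings.warn("degenerate torsion geometry; contribution zeroed")
        phi = np.arctan2(np.sum(np.cross(n1, n2) * b2, axis=1) / np.maximum(l2, 1e-12),
                         np.sum(n1 * n2, axis=1))
        narg = phi[:, None] * np.array([1.0, 2.0, 3.0]) - self.tors_d
        term = self.tors_k * (1.0 + np.cos(narg))
        term[degen] = 0.0
        e = float(np.sum(term))
        dedphi = np.sum(-self.tors_k * np.array([1.0, 2.0, 3.0]) * np.sin(narg),
                        axis=1)
        dedphi[degen] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            dphi_di = -(l2 / np.maximum(n1sq, 1e-30))[:, None] * n1
            dphi_dl = (l2 / np.maximum(n2sq, 1e-30))[:, None] * n2
        dphi_di[degen] = 0.0
        dphi_dl[degen] = 0.0
        b1b2 = (np.sum(b1 * b2, axis=1) / np.maximum(l2 * l2, 1e-30))[:, None]
        b3b2 = (np.sum(b3 * b2, axis=1) / np.maximum(l2 * l2, 1e-30))[:, None]
        dphi_dj = -(1.0 + b1b2) * dphi_di + b3b2 * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
        w = dedphi[:, None]
        np.add.at(g, ii, w * dphi_di)
        np.add.at(g, jj, w * dphi_dj)
        np.add.at(g, kk, w * dphi_dk)
        np.add.at(g, ll, w * dphi_dl)
        return e, g

    def e_vdw_eff(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.nb_i) == 0:
            return 0.0, g
        d = x[self.nb_j] - x[self.nb_i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise ValueError("overlapping non-excluded beads (r = 0)")
        u, du = vdw_eff_shifted(r, self.nb_eps, self.nb_sig, self.nb_gam,
                                self.ff.vdw_cutoff)
        e = float(np.sum(u))
        f = (du / r)[:, None] * d
        np.add.at(g, self.nb_j, f)
        np.add.at(g, self.nb_i, -f)
        return e, g

    def e_debye_huckel(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.el_i) == 0:
            return 0.0, g
        d = x[self.el_j] - x[self.el_i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise ValueError("overlapping charged beads (r = 0)")
        u, du = debye_huckel_shifted(r, self.el_qq, self.ff.dielectric,
                                     self.ff.debye_length, COULOMB,
                                     self.ff.ele_cutoff)
        e = float(np.sum(u))
        f = (du / r)[:, None] * d
        np.add.at(g, self.el_j, f)
        np.add.at(g, self.el_i, -f)
        return e, g

    def e_hbond(self, x):
        g = np.zeros((self.n_beads, 3))
        if len(self.hb_idx) == 0:
            return 0.0, g
        hb = self.ff.hbond
        d = x[self.hb_idx[:, 1]] - x[self.hb_idx[:, 0]]
        r = np.linalg.norm(d, axis=1)
        active = np.nonzero(r < hb.cutoff)[0]
        e = 0.0
        for a in active:
            i, j = int(self.hb_idx[a, 0]), int(self.hb_idx[a, 1])
            e += self._hbond_pair(x, i, j, float(self.hb_scale[a]), g)
        return e, g

    def _hbond_pair(self, x, i, j, scale, g):
        hb = self.ff.hbond
        rij = x[j] - x[i]
        r = float(np.linalg.norm(rij))
        rhat = rij / r
        rad, drad = hbond_radial(r, hb.sigma_eq)
        sw, dsw = hbond_switch(r, hb.switch_on, hb.cutoff)
        amp = -hb.eps_max * scale
        A = amp * rad * sw
        dA = amp * (drad * sw + rad * dsw)

        mi = self.base_mates[i]
        mj = self.base_mates[j]
        ui = x[i] - (x[i] + x[mi[0]] + x[mi[1]]) / 3.0
        uj = x[j] - (x[j] + x[mj[0]] + x[mj[1]]) / 3.0
        li = float(np.linalg.norm(ui))
        lj = float(np.linalg.norm(uj))
        if li < 1e-10 or lj < 1e-10:
            warnings.warn("degenerate base geometry in H-bond; pair skipped")
            return 0.0
        uih, ujh = ui / li, uj / lj
        ci = float(uih @ rhat)
        cj = float(ujh @ -rhat)
        fi = max(ci, 0.0) ** 2
        fj = max(cj, 0.0) ** 2
        e = A * fi * fj
        if fi * fj == 0.0:
            # a directional factor at/beyond its node: f and f' both vanish,
            # so energy and gradient are exactly zero
            return 0.0

        # radial part
        grad_r = dA * fi * fj
        g[j] += grad_r * rhat
        g[i] -= grad_r * rhat

        # directional part for bead i (factor fi = max(ci,0)^2)
        dfi = 2.0 * max(ci, 0.0)
        if dfi != 0.0:
            w = A * fj * dfi
            dci_du = (rhat - ci * uih) / li          # d ci / d ui
            dci_dr = (uih - ci * rhat) / r           # d ci / d rij
            g[i] += w * ((2.0 / 3.0) * dci_du - dci_dr)
            g[mi[0]] += w * (-(1.0 / 3.0) * dci_du)
            g[mi[1]] += w * (-(1.0 / 3.0) * dci_du)
            g[j] += w * dci_dr

        # directional part for bead j (cj uses -rhat)
        dfj = 2.0 * max(cj, 0.0)
        if dfj != 0.0:
            w = A * fi * dfj
            dcj_du = (-rhat - cj * ujh) / lj
            dcj_dr = -(ujh + cj * rhat) / r          # d cj / d rij
            g[j] += w * ((2.0 / 3.0) * dcj_du + dcj_dr)
            g[mj[0]] += w * (-(1.0 / 3.0) * dcj_du)
            g[mj[1]] += w * (-(1.0 / 3.0) * dcj_du)
            g[i] += w * -dcj_dr
        return e

    # -- totals ------------------------------------------------------------
    def total(self, x):
        eb, gb = self.e_bond(x)
        ea, ga = self.e_angle(x)
        et, gt = self.e_torsion(x)
        ev, gv = self.e_vdw_eff(x)
        eh, gh = self.e_hbond(x)
        ee, ge = self.e_debye_huckel(x)
        return (EnergyBreakdown.from_terms(eb, ea, et, ev, eh, ee),
                gb + ga + gt + gv + gh + ge)

    def energy(self, x) -> EnergyBreakdown:
        return self.total(x)[0]

    def gradient(self, x) -> np.ndarray:
        return self.total(x)[1]


# ---------------------------------------------------------------------------
# functional wrappers matching the per-term interface

def _model(structure, topology, ff):
    return EnergyModel(structure, ff, topology)


def e_bond(structure, topology, ff):
    return _model(structure, topology, ff).e_bond(structure.coords)


def e_angle(structure, topology, ff):
    return _model(structure, topology, ff).e_angle(structure.coords)


def e_torsion(structure, topology, ff):
    return _model(structure, topology, ff).e_torsion(structure.coords)


def e_vdw_eff(structure, topology, ff):
    return _model(structure, topology, ff).e_vdw_eff(structure.coords)


def e_hbond(structure, topology, ff):
    return _model(structure, topology, ff).e_hbond(structure.coords)


def e_debye_huckel(structure, topology, ff):
    return _model(structure, topology, ff).e_debye_huckel(structure.coords)


def total_energy(structure, topology, ff):
    return _model(structure, topology, ff).total(structure.coords)
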