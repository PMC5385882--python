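"""Synthetic input generators: ideal A-form lattices, toy all-atom models,
linear point sets and exact 1-D Boltzmann samplers.

These generators define the geometries and statistical ensembles the test
suite runs on, so their construction values double as oracles: the helix
builder places Watson-Crick imino beads of paired residues exactly
``bp_separation`` apart with perfectly aligned edge vectors, and the
Boltzmann sampler draws exact inverse-CDF samples from a stated density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .topology import CGStructure, MappingTable, RNA_RESIDUES

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: order of base beads per residue in the mapping table: ring, imino, edge
_BASE_ROLES = ("B1", "B2", "B3")


@dataclass
class HelixSpec:
    """Geometry of the idealized A-form lattice."""

    sequence: str
    sequence_b: str | None = None        # second strand (duplex mode)
    stem: int | None = None              # hairpin stem length (residues)
    rise: float = 2.8                    # Å per base pair
    twist: float = 32.7                  # degrees per base pair
    radius: float = 9.2                  # Å, sugar-bead radius
    radius_p: float = 10.4               # Å, phosphate-bead radius
    backbone_phase: float = 35.0         # degrees, sugar angular offset
    bp_separation: float = 2.9           # Å between paired imino beads
    base_u_ring: float = 4.6             # Å, ring bead radial position
    base_u_edge: float = 3.4             # Å, edge bead radial position
    base_t: float = 1.2                  # Å, ring/edge bead tangential offset

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) degrees")

    def local_template(self) -> dict[str, np.ndarray]:
        """Per-residue bead positions in the local (u, t, z) frame."""
        d = math.radians(self.backbone_phase)
        om = math.radians(self.twist)
        return {
            "P": np.array([self.radius_p * math.cos(d - om / 2),
                           self.radius_p * math.sin(d - om / 2),
                           -self.rise / 2]),
            "S": np.array([self.radius * math.cos(d),
                           self.radius * math.sin(d), 0.0]),
            "B1": np.array([self.base_u_ring, self.base_t, 0.0]),   # ring
            "B2": np.array([self.bp_separation / 2, 0.0, 0.0]),     # WC imino
            "B3": np.array([self.base_u_edge, -self.base_t, 0.0]),  # WC edge
        }


def _bead_types(res: str, mapping: MappingTable) -> list[str]:
    return [t for t, _ in mapping.entries[res]]


def _place_strand(seq, bp_index, antisense, spec, chain_id, mapping,
                  include_5p=True):
    """Bead coordinates for one strand on the helical lattice.

    ``bp_index[j]`` is the base-pair rung of residue ``j``.  Antisense
    strands are generated by a proper rotation (pi about the local radial
    axis), so bonded geometry — including torsion signs — matches the
    sense strand exactly.
    """
    tmpl = spec.local_template()
    om = math.radians(spec.twist)
    coords, types, resid, chain = [], [], [], []
    for j, res in enumerate(seq):
        k = bp_index[j]
        phi = k * om + (math.pi if antisense else 0.0)
        eu = np.array([math.cos(phi), math.sin(phi), 0.0])
        et = np.array([-math.sin(phi), math.cos(phi), 0.0])
        if antisense:
            et = -et
        z0 = k * spec.rise
        for role, bead_type in zip(("P", "S", "B1", "B2", "B3"),
                                   _bead_types(res, mapping)):
            if role == "P" and j == 0 and not include_5p:
                continue
            u, t, zl = tmpl[role]
            zz = -zl if antisense else zl
            coords.append(u * eu + t * et + np.array([0.0, 0.0, z0 + zz]))
            types.append(bead_type)
            resid.append(j)
            chain.append(chain_id)
    return coords, types, resid, chain


def make_single_helix(sequence: str, chain_id: str = "A",
                      spec: HelixSpec | None = None,
                      mapping: MappingTable | None = None) -> CGStructure:
    """Single strand laid on the A-form lattice."""
    spec = spec or HelixSpec(sequence)
    mapping = mapping or MappingTable.default()
    n = len(sequence)
    c, t, r, ch = _place_strand(sequence, list(range(n)), False, spec,
                                chain_id, mapping)
    return CGStructure(np.array(c), t, np.array(r), np.array(ch, dtype=object),
                       {chain_id: sequence})


def make_duplex(sequence: str, sequence_b: str | None = None,
                spec: HelixSpec | None = None,
                mapping: MappingTable | None = None) -> CGStructure:
    """Antiparallel duplex; strand B defaults to the reverse complement.

    Paired imino beads sit exactly ``bp_separation`` apart with their edge
    vectors anti-aligned (ideal hydrogen-bonding geometry).
    """
    seq_a = sequence.upper()
    seq_b = (sequence_b or "".join(COMPLEMENT[c] for c in reversed(seq_a))).upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("duplex strands must have equal length")
    for a, b in zip(seq_a, reversed(seq_b)):
        if COMPLEMENT[a] != b:
            raise ValueError(f"strands not complementary at pair {a}-{b}")
    spec = spec or HelixSpec(seq_a, seq_b)
    mapping = mapping or MappingTable.default()
    n = len(seq_a)
    ca, ta, ra, cha = _place_strand(seq_a, list(range(n)), False, spec, "A", mapping)
    cb, tb, rb, chb = _place_strand(seq_b, [n - 1 - j for j in range(n)], True,
                                    spec, "B", mapping)
    return CGStructure(np.array(ca + cb), ta + tb, np.array(ra + rb),
                       np.array(cha + chb, dtype=object),
                       {"A": seq_a, "B": seq_b})


def make_hairpin(sequence: str, stem: int, chain_id: str = "A",
                 spec: HelixSpec | None = None,
                 mapping: MappingTable | None = None) -> CGStructure:
    """Hairpin: terminal ``stem`` residues paired, the rest on a loop arc."""
    seq = sequence.upper()
    n = len(seq)
    if not 0 < stem <= n // 2:
        raise ValueError("stem must satisfy 0 < stem <= len(sequence)/2")
    for j in range(stem):
        if COMPLEMENT[seq[j]] != seq[n - 1 - j]:
            raise ValueError(f"stem not complementary at pair {j}")
    spec = spec or HelixSpec(seq, stem=stem)
    mapping = mapping or MappingTable.default()
    tmpl = spec.local_template()

    c5, t5, r5, ch5 = _place_strand(seq[:stem], list(range(stem)), False, spec,
                                    chain_id, mapping)
    c3, t3, r3, _ = _place_strand(seq[n - stem:],
                                  [stem - 1 - j for j in range(stem)], True,
                                  spec, chain_id, mapping)
    r3 = [ri + (n - stem) for ri in r3]

    # loop: sugar beads on a circular arc bridging the two stem ends,
    # bases pointing outward; per-residue internal geometry reuses the
    # helix template so bonded terms match the stem parameters.
    loop_seq = seq[stem:n - stem]
    coords_l, types_l, resid_l = [], [], []
    if loop_seq:
        s_top_a = np.array(c5[len(c5) - 4])   # S bead of last 5' stem residue
        idx_b = [i for i, ri in enumerate(r3) if ri == n - stem]
        s_top_b = np.array(c3[idx_b[1]])      # S bead of first 3' stem residue
        mid = 0.5 * (s_top_a + s_top_b)
        half = 0.5 * np.linalg.norm(s_top_b - s_top_a)
        w = (s_top_b - s_top_a) / (2 * half)
        zhat = np.array([0.0, 0.0, 1.0])
        arc_r = max(half, 1.8 * spec.rise * (len(loop_seq) + 1) / math.pi)
        for m, res in enumerate(loop_seq):
            th = math.pi * (m + 1) / (len(loop_seq) + 1)
            s_pos = mid - math.cos(th) * half * w + math.sin(th) * arc_r * zhat
            a_out = (-math.cos(th) * w * half / arc_r + math.sin(th) * zhat)
            a_out = a_out / np.linalg.norm(a_out)
            b_tan = np.cross(zhat if abs(a_out[2]) < 0.9 else w, a_out)
            b_tan /= np.linalg.norm(b_tan)
            frame = np.stack([-a_out, b_tan, np.cross(-a_out, b_tan)], axis=1)
            for role, bead_type in zip(("P", "S", "B1", "B2", "B3"),
                                       _bead_types(res, mapping)):
                rel = tmpl[role] - tmpl["S"]
                coords_l.append(s_pos + frame @ rel)
                types_l.append(bead_type)
                resid_l.append(stem + m)

    coords = c5 + coords_l + c3
    types = t5 + types_l + t3
    resid = r5 + resid_l + r3
    chain = [chain_id] * len(coords)
    return CGStructure(np.array(coords), types, np.array(resid),
                       np.array(chain, dtype=object), {chain_id: seq})


def make_ideal_helix(spec: HelixSpec,
                     mapping: MappingTable | None = None) -> CGStructure:
    """Dispatch on the HelixSpec: duplex, hairpin or single strand."""
    if spec.sequence_b is not None:
        return make_duplex(spec.sequence, spec.sequence_b, spec, mapping)
    if spec.stem:
        return make_hairpin(spec.sequence, spec.stem, "A", spec, mapping)
    return make_single_helix(spec.sequence, "A", spec, mapping)


def make_extended_strand(sequence: str, chain_id: str = "A",
                         spacing: float = 5.9,
                         mapping: MappingTable | None = None) -> CGStructure:
    """Straight-line strand at the single-strand contour spacing."""
    mapping = mapping or MappingTable.default()
    offsets = {
        "P": np.array([-2.4, -1.8, 0.0]),
        "S": np.array([0.0, 0.0, 0.0]),
        "B1": np.array([0.8, 3.2, 0.0]),
        "B2": np.array([1.2, 5.6, 1.1]),
        "B3": np.array([2.4, 5.0, -1.1]),
    }
    coords, types, resid, chain = [], [], [], []
    for j, res in enumerate(sequence):
        base = np.array([j * spacing, 0.0, 0.0])
        for role, bead_type in zip(("P", "S", "B1", "B2", "B3"),
                                   _bead_types(res, mapping)):
            coords.append(base + offsets[role])
            types.append(bead_type)
            resid.append(j)
            chain.append(chain_id)
    return CGStructure(np.array(coords), types, np.array(resid),
                       np.array(chain, dtype=object), {chain_id: sequence})


# ---------------------------------------------------------------------------
# toy all-atom models for mapping tests

def make_anchor_model(cg: CGStructure, mapping: MappingTable | None = None):
    """Synthetic all-atom Bio.PDB model with anchor atoms at bead positions.

    The returned structure is a stand-in for an experimental model: each
    residue carries exactly the five anchor atoms (full float64 precision),
    so mapping it back is an exact coordinate copy.
    """
    from Bio.PDB.Structure import Structure
    from Bio.PDB.Model import Model
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Residue import Residue
    from Bio.PDB.Atom import Atom

    mapping = mapping or MappingTable.default()
    struct = Structure("synthetic")
    model = Model(0)
    struct.add(model)
    serial = 1
    for chain_id in cg.chain_ids:
        chain = Chain(chain_id)
        model.add(chain)
        seq = cg.sequences[chain_id]
        mask = cg.chain_mask(chain_id)
        for ri in sorted(set(cg.resid[mask])):
            res_name = seq[ri]
            residue = Residue((" ", int(ri) + 1, " "), res_name, "")
            chain.add(residue)
            anchors = dict(mapping.entries[res_name])
            anchor_of = {bt: an for bt, an in mapping.entries[res_name]}
            sel = np.nonzero(mask & (cg.resid == ri))[0]
            for idx in sel:
                bt = cg.bead_types[idx]
                name = anchor_of[bt]
                atom = Atom(name, np.array(cg.coords[idx], dtype=float), 0.0,
                            1.0, " ", name, serial, element=name[0])
                residue.add(atom)
                serial += 1
            del anchors
    return struct


# ---------------------------------------------------------------------------
# statistical fixtures

def make_linear_point_set(n_points: int, length: float, jitter: float = 0.0,
                          seed: int = 0) -> np.ndarray:
    """Points uniformly spaced on a line segment with Gaussian jitter."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length, n_points)
    pts = np.zeros((n_points, 3))
    pts[:, 0] = x
    if jitter > 0:
        pts += rng.normal(0.0, jitter, size=pts.shape)
    return pts


def sample_boltzmann_1d(potential, T: float, n: int, seed: int = 0,
                        bias: tuple[float, float] | None = None,
                        domain: tuple[float, float] = (0.0, 30.0),
                        grid: int = 8192) -> np.ndarray:
    """Exact inverse-CDF samples from density ∝ exp(-(U + bias)/kT).

    ``bias`` is an optional harmonic window ``(center, k)`` adding
    ``k*(r-center)**2`` (no 1/2 factor, matching the bonded convention).
    """
    from .constants import KB

    lo, hi = domain
    r = np.linspace(lo, hi, grid)
    u = np.asarray([potential(x) for x in r], dtype=float)
    if bias is not None:
        c, k = bias
        u = u + k * (r - c) ** 2
    u = u - u.min()
    w = np.exp(-u / (KB * T))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(r))])
    if not np.isfinite(cdf[-1]) or cdf[-1] <= 0:
        raise ValueError("density is not normalizable on the domain")
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    # strictly increasing CDF grid for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(rng.random(n), cdf[keep], r[keep])
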