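"""Five-bead-per-nucleotide coarse-grained representation of RNA.

Each nucleotide is reduced to five pseudoatoms: a phosphate bead (P,
anchored at the P atom), a sugar bead (S, anchored at C4') and three
base beads lying in the base plane.  Nine distinct bead types exist in
the default table; only the phosphate carries charge.  The base-bead
anchor atoms and type assignment are configuration data
(:class:`MappingTable`), not code, because the assignment is a modelling
convention: the shipped table uses a shared ring bead (RA on purine C8,
RY on pyrimidine C6), a shared Watson-Crick imino bead (NI on purine N1
/ pyrimidine N3) and a residue-specific edge bead (N6, O6, N4 or O4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_DATA_DIR = Path(__file__).parent / "data"

RNA_RESIDUES = ("A", "G", "C", "U")

#: PDB residue-name aliases accepted for the four ribonucleotides
RESNAME_ALIASES = {
    "A": "A", "ADE": "A", "RA": "A",
    "G": "G", "GUA": "G", "RG": "G",
    "C": "C", "CYT": "C", "RC": "C",
    "U": "U", "URA": "U", "URI": "U", "RU": "U",
}


@dataclass(frozen=True)
class PseudoatomType:
    """One of the nine coarse-grained bead types."""

    name: str
    group: str          # "phosphate" | "sugar" | "base"
    mass: float         # amu
    charge: float       # e

    def __post_init__(self):
        if self.group not in ("phosphate", "sugar", "base"):
            raise ValueError(f"unknown bead group {self.group!r}")
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")


@dataclass
class MappingTable:
    """Residue → five (bead type, anchor atom) pairs.

    Bead order per residue is P, S, B1, B2, B3 where B1 is the base bead
    bonded to the sugar (ring bead), and B1-B2-B3 form a closed triangle.
    """

    entries: dict[str, list[tuple[str, str]]]

    def __post_init__(self):
        for res, beads in self.entries.items():
            if len(beads) != 5:
                raise ValueError(f"residue {res} maps to {len(beads)} beads, expected 5")

    @classmethod
    def default(cls) -> "MappingTable":
        return cls.from_file(_DATA_DIR / "mapping.tsv")

    @classmethod
    def from_file(cls, path) -> "MappingTable":
        entries: dict[str, list[tuple[str, str]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, bead, anchor = line.split()
            entries.setdefault(res, []).append((bead, anchor))
        return cls(entries)


@dataclass
class CGStructure:
    """Bead coordinates plus per-bead typing/indexing for one CG model.

    ``resid`` is contiguous within each chain (0-based).  ``meta`` records
    bookkeeping such as dropped 5'-terminal phosphates.
    """

    coords: np.ndarray                     # (N, 3) Å
    bead_types: list[str]
    resid: np.ndarray                      # (N,) int
    chain: np.ndarray                      # (N,) str
    sequences: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.resid = np.asarray(self.resid, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)
        n = len(self.coords)
        if not (len(self.bead_types) == len(self.resid) == len(self.chain) == n):
            raise ValueError("inconsistent per-bead array lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return np.asarray([c == chain_id for c in self.chain])

    def bead_index(self, chain_id: str, resid: int, bead_type: str) -> int:
        hits = np.nonzero(
            self.chain_mask(chain_id)
            & (self.resid == resid)
            & np.asarray([t == bead_type for t in self.bead_types])
        )[0]
        if len(hits) != 1:
            raise KeyError(f"bead {chain_id}/{resid}/{bead_type}: {len(hits)} matches")
        return int(hits[0])

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        return replace(self, coords=np.array(coords, dtype=float))

    def copy(self) -> "CGStructure":
        return replace(
            self,
            coords=self.coords.copy(),
            bead_types=list(self.bead_types),
            resid=self.resid.copy(),
            chain=self.chain.copy(),
            sequences=dict(self.sequences),
            meta=dict(self.meta),
        )


@dataclass
class Topology:
    """Bonded-term and exclusion bookkeeping derived from the bead graph."""

    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    torsions: list[tuple[int, int, int, int]]
    exclusions: set[frozenset]
    hbond_pairs: list[tuple[int, int]]           # eligible base-bead pairs
    base_mates: dict[int, tuple[int, int]]       # base bead → its two triangle mates

    def __post_init__(self):
        for i, j in self.bonds:
            if i == j:
                raise ValueError("self-bond")
        for b in self.bonds:
            if frozenset(b) not in self.exclusions:
                raise ValueError("bond missing from exclusion set")


# ---------------------------------------------------------------------------
# construction

def build_topology(structure: CGStructure, hbond_types: set | None = None) -> Topology:
    """Enumerate bonds, angles, torsions, exclusions and H-bond candidates.

    Bonds per residue: P-S, S-B1, B1-B2, B2-B3, B3-B1; S(i)-P(i+1) links
    consecutive residues of a chain.  Angles and torsions are enumerated
    exhaustively from the bond graph; exclusions are all 1-2 and 1-3
    pairs.  A gap in residue numbering splits the chain with a warning.
    """
    bonds: list[tuple[int, int]] = []
    base_mates: dict[int, tuple[int, int]] = {}
    # group bead indices per (chain, resid)
    residues: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for idx in range(structure.n_beads):
        key = (structure.chain[idx], int(structure.resid[idx]))
        if key not in residues:
            residues[key] = {}
            order.append(key)
        residues[key][_role(structure, residues[key], idx)] = idx

    prev_key = None
    for key in order:
        beads = residues[key]
        s = beads.get("S")
        p = beads.get("P")
        b1, b2, b3 = beads.get("B1"), beads.get("B2"), beads.get("B3")
        if p is not None and s is not None:
            bonds.append((p, s))
        if s is not None and b1 is not None:
            bonds.append((s, b1))
        if b1 is not None and b2 is not None:
            bonds.append((b1, b2))
        if b2 is not None and b3 is not None:
            bonds.append((b2, b3))
        if b3 is not None and b1 is not None:
            bonds.append((b3, b1))
        for bead, mates in ((b1, (b2, b3)), (b2, (b1, b3)), (b3, (b1, b2))):
            if bead is not None and None not in mates:
                base_mates[bead] = mates
        if prev_key is not None and prev_key[0] == key[0]:
            if key[1] == prev_key[1] + 1:
                sp, pn = residues[prev_key].get("S"), beads.get("P")
                if sp is not None and pn is not None:
                    bonds.append((sp, pn))
            else:
                warnings.warn(
                    f"chain break in chain {key[0]} between residues "
                    f"{prev_key[1]} and {key[1]}; topology split"
                )
        prev_key = key

    adj: dict[int, set] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    angles = []
    for j in sorted(adj):
        nb = sorted(adj[j])
        for ai in range(len(nb)):
            for ci in range(ai + 1, len(nb)):
                angles.append((nb[ai], j, nb[ci]))

    torsions = []
    for j, k in bonds:
        for orient in ((j, k), (k, j)):
            a, b = orient
            for i in adj[a] - {b}:
                for l in adj[b] - {a}:
                    if i == l:
                        continue  # 3-ring closure, not a proper torsion
                    quad = (i, a, b, l)
                    if quad[::-1] < quad:
                        quad = quad[::-1]
                    if quad not in torsions:
                        torsions.append(quad)
    torsions = sorted(set(torsions))

    exclusions = {frozenset(b) for b in bonds}
    exclusions |= {frozenset((a, c)) for a, _, c in angles}

    hbond_pairs = []
    if hbond_types:
        eligible = [
            i for i in range(structure.n_beads)
            if structure.bead_types[i] in {t for pair in hbond_types for t in pair}
        ]
        for ii, i in enumerate(eligible):
            for j in eligible[ii + 1:]:
                if (structure.chain[i], structure.resid[i]) == (structure.chain[j], structure.resid[j]):
                    continue
                key = frozenset((structure.bead_types[i], structure.bead_types[j]))
                if key in hbond_types and i in base_mates and j in base_mates:
                    hbond_pairs.append((i, j))

    return Topology(bonds, angles, torsions, exclusions, hbond_pairs, base_mates)


def _role(structure: CGStructure, assigned: dict, idx: int) -> str:
    t = structure.bead_types[idx]
    if t == "P":
        return "P"
    if t == "S":
        return "S"
    for role in ("B1", "B2", "B3"):
        if role not in assigned:
            return role
    raise ValueError(f"residue has more than 5 beads (extra bead type {t})")


# ---------------------------------------------------------------------------
# all-atom → CG mapping

def map_all_atom_to_cg(pdb_structure, mapping: MappingTable | None = None,
                       strict: bool = True, model_index: int = 0) -> CGStructure:
    """Map an all-atom Bio.PDB entity (or PDB path) onto the 5-bead model.

    Each bead is placed exactly at its anchor atom's coordinates.  A
    residue missing an anchor atom raises in strict mode; otherwise the
    residue (and the rest of its chain) is truncated with a warning.
    Missing 5'-terminal phosphates are simply omitted and recorded in
    ``meta['missing_5p']``.
    """
    from .pdbio import load_all_atom

    mapping = mapping or MappingTable.default()
    model = load_all_atom(pdb_structure, model_index)

    coords, types, resid, chain_col = [], [], [], []
    sequences: dict[str, str] = {}
    missing_5p: list[str] = []

    for chain in model:
        seq = []
        res_counter = 0
        residues = [r for r in chain if r.id[0] == " "]
        for ri, res in enumerate(residues):
            raw = res.get_resname().strip()
            if raw not in RESNAME_ALIASES:
                raise ValueError(f"unknown residue name {raw!r} at {chain.id}/{res.id[1]}")
            resname = RESNAME_ALIASES[raw]
            beads = mapping.entries[resname]
            placed = []
            for bead_type, anchor in beads:
                atom = _find_atom(res, anchor)
                if atom is None:
                    if bead_type == "P" and ri == 0:
                        missing_5p.append(chain.id)
                        continue
                    msg = (f"residue {chain.id}/{res.id[1]} ({resname}) missing "
                           f"anchor atom {anchor!r}")
                    if strict:
                        raise ValueError(msg)
                    warnings.warn(msg + "; chain truncated")
                    placed = None
                    break
                placed.append((bead_type, np.asarray(atom.get_coord(), dtype=float)))
            if placed is None:
                break
            for bead_type, xyz in placed:
                coords.append(xyz)
                types.append(bead_type)
                resid.append(res_counter)
                chain_col.append(chain.id)
            seq.append(resname)
            res_counter += 1
        if seq:
            sequences[chain.id] = "".join(seq)

    if not coords:
        raise ValueError("no RNA residues mapped")
    return CGStructure(np.array(coords), types, np.array(resid),
                       np.array(chain_col, dtype=object), sequences,
                       meta={"missing_5p": missing_5p})


def _find_atom(res, name):
    best = None
    for atom in res:
        if atom.get_name().strip() == name or atom.get_name().strip() == name.replace("'", "*"):
            if atom.is_disordered():
                atom = atom.disordered_get()  # highest occupancy altloc
            if best is None or atom.get_occupancy() is None or \
                    (best.get_occupancy() or 1.0) < (atom.get_occupancy() or 1.0):
                best = atom
    return best


def build_from_sequence(sequence: str, geometry: str = "a_form",
                        stem: int | None = None, chain_id: str = "A") -> CGStructure:
    """Build a clash-free starting structure for a bare RNA sequence.

    ``extended`` lays residues along a straight line at the single-strand
    contour spacing; ``a_form`` places the strand on an idealized A-form
    helical lattice.  With ``stem`` set, the first/last ``stem`` residues
    are folded back as a paired hairpin stem (delegated to the fixture
    helix generator).
    """
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    for pos, ch in enumerate(sequence):
        if ch not in RNA_RESIDUES:
            raise ValueError(f"invalid RNA character {ch!r} at position {pos}")
    from . import fixtures

    if geometry == "extended":
        return fixtures.make_extended_strand(sequence, chain_id=chain_id)
    if geometry == "a_form":
        if stem:
            return fixtures.make_hairpin(sequence, stem=stem, chain_id=chain_id)
        return fixtures.make_single_helix(sequence, chain_id=chain_id)
    raise ValueError(f"unknown geometry {geometry!r}")
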