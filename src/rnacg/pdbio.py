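"""PDB reading/writing.

All-atom files are read with Biopython; coarse-grained structures are
written/read as plain ATOM records with the bead type in the atom-name
field, one residue per nucleotide, coordinates at the standard three
decimals (so a CG→PDB→CG round trip is bit-exact on what was written).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .topology import CGStructure


def load_all_atom(source, model_index: int = 0):
    """Return a Bio.PDB Model from a path or an existing Bio.PDB entity."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Structure import Structure
    from Bio.PDB.Model import Model

    if isinstance(source, Model):
        return source
    if isinstance(source, Structure):
        return list(source)[model_index]
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("rna", str(source))
    return list(structure)[model_index]


def write_cg_pdb(structure: CGStructure, path, frames=None) -> None:
    """Write a CG structure (or a multi-model trajectory) as PDB text.

    ``frames`` is an optional iterable of coordinate arrays; each becomes
    one MODEL block sharing the structure's bead metadata.
    """
    lines: list[str] = []
    frame_list = [structure.coords] if frames is None else list(frames)
    multi = len(frame_list) > 1
    for mi, coords in enumerate(frame_list, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for idx in range(structure.n_beads):
            x, y, z = coords[idx]
            resname = _resname(structure, idx)
            lines.append(
                f"ATOM  {serial:5d} {structure.bead_types[idx]:<4s} "
                f"{resname:>3s} {str(structure.chain[idx])[:1]}"
                f"{int(structure.resid[idx]) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _resname(structure: CGStructure, idx: int) -> str:
    seq = structure.sequences.get(str(structure.chain[idx]))
    if seq is None:
        return "N"
    return seq[int(structure.resid[idx])]


def read_cg_pdb(path):
    """Read CG PDB text back into one CGStructure (or a list for multi-model)."""
    models: list[CGStructure] = []
    coords, types, resid, chain = [], [], [], []
    sequences: dict[str, dict[int, str]] = {}

    def flush():
        nonlocal coords, types, resid, chain, sequences
        if not coords:
            return
        seqs = {c: "".join(d[k] for k in sorted(d)) for c, d in sequences.items()}
        models.append(CGStructure(np.array(coords), types, np.array(resid),
                                  np.array(chain, dtype=object), seqs))
        coords, types, resid, chain, sequences = [], [], [], [], {}

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            flush()
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            ch = line[21]
            rs = int(line[22:26])
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed PDB record at line {lineno}: {exc}") from None
        coords.append(xyz)
        types.append(name)
        resid.append(rs - 1)
        chain.append(ch)
        sequences.setdefault(ch, {})[rs - 1] = resname if len(resname) == 1 else "N"
    flush()
    if not models:
        raise ValueError(f"no ATOM records found in {path}")
    return models[0] if len(models) == 1 else models
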