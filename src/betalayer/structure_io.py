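"""Reading and writing structures; biological-assembly expansion.

Detection operates on biological assemblies — the oligomeric form of a
deposited structure — because β-layer hydrogen bonds cross chains that
may only be present as symmetry copies.  Files are parsed with gemmi
(PDB and mmCIF); only the first model's polymer chains are kept, with
waters, ligands and hydrogens discarded and alternate locations resolved
to a single conformer (altloc 'A' or blank, highest occupancy on a tie).
Assembly definitions (REMARK 350 / pdbx_struct_assembly) are carried on
the model so they can be applied later.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gemmi
import numpy as np

from .chain import BACKBONE_ATOMS, BackboneChain, StructureModel

logger = logging.getLogger(__name__)

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Single conformer: altloc blank, else 'A', else highest occupancy."""
    for want in ("", "A"):
        hits = [a for a in atoms if a.altloc.strip() == want]
        if hits:
            return max(hits, key=lambda a: a.occ)
    return max(atoms, key=lambda a: a.occ)


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        return info.one_letter_code.upper()
    return "X"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a backbone structure model.

    Returns all polymer chains of the first model; heteroatoms, waters
    and hydrogens are excluded, alternate locations resolved to one
    conformer.  Residues missing any of N/CA/C/O are kept but flagged
    incomplete (NaN coordinates); chains with no complete residue are
    dropped with a warning.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models in file")
    model = st[0]
    chains: list[BackboneChain] = []
    for gchain in model:
        polymer = gchain.get_polymer()
        residues = list(polymer) if len(polymer) else [
            r for r in gchain if gemmi.find_tabulated_residue(r.name) is not None
            and gemmi.find_tabulated_residue(r.name).is_amino_acid()
        ]
        if not residues:
            continue
        seq_ids, icodes, aas = [], [], []
        coords = {name: [] for name in BACKBONE_ATOMS}
        for res in residues:
            seq_ids.append(res.seqid.num)
            icodes.append(res.seqid.icode.strip())
            aas.append(_one_letter(res.name))
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.name in BACKBONE_ATOMS:
                    by_name.setdefault(atom.name, []).append(atom)
            for name in BACKBONE_ATOMS:
                if name in by_name:
                    a = _pick_altloc(by_name[name])
                    coords[name].append([a.pos.x, a.pos.y, a.pos.z])
                else:
                    coords[name].append([np.nan] * 3)
        chain = BackboneChain(
            gchain.name, seq_ids, icodes, aas,
            {k: np.asarray(v) for k, v in coords.items()},
        )
        if not chain.complete_mask.any():
            warnings.warn(
                f"{path.name}: chain {gchain.name} has no complete backbone "
                "residue; dropped"
            )
            continue
        chains.append(chain)
    if not chains:
        raise ValueError(f"{path.name}: no polymer chains with backbone atoms")
    assemblies = {}
    for asm in st.assemblies:
        gens = []
        for gen in asm.generators:
            ops = []
            for op in gen.operators:
                t = op.transform
                R = np.array(t.mat.tolist())
                v = np.array([t.vec.x, t.vec.y, t.vec.z])
                ops.append((R, v))
            gens.append((list(gen.chains), ops))
        assemblies[asm.name] = gens
    return StructureModel(path.stem, chains, assembly_id=None, assemblies=assemblies)


def select_assembly(model: StructureModel, assembly: str = "1") -> StructureModel:
    """Expand a named biological assembly, or return the deposited chains.

    ``assembly="asu"`` returns the asymmetric-unit chains unchanged.  A
    named assembly applies the file's symmetry operators, renaming copies
    uniquely (A1, A2, ...).  Expanding an already-expanded model is an
    error.
    """
    if assembly == "asu":
        return StructureModel(
            model.identifier, list(model.chains), assembly_id="asu",
            assemblies=model.assemblies,
        )
    if model.assembly_id is not None and model.assembly_id != "asu":
        raise ValueError(
            f"model already expanded to assembly {model.assembly_id!r}"
        )
    if assembly not in model.assemblies:
        raise ValueError(
            f"unknown assembly {assembly!r}; available: "
            f"{sorted(model.assemblies) or ['asu']}"
        )
    new_chains: list[BackboneChain] = []
    for chain_ids, ops in model.assemblies[assembly]:
        for cid in chain_ids:
            try:
                base = model.chain(cid)
            except KeyError:
                continue
            for k, (R, v) in enumerate(ops, start=1):
                new_chains.append(base.transformed(R, v, chain_id=f"{cid}{k}"))
    if not new_chains:
        raise ValueError(
            f"assembly {assembly!r} references no chains present in the model"
        )
    return StructureModel(
        model.identifier, new_chains, assembly_id=assembly,
        assemblies=model.assemblies,
    )


def default_assembly(model: StructureModel) -> str:
    """Assembly "1" when defined, else the asymmetric unit (logged)."""
    if "1" in model.assemblies:
        return "1"
    logger.info(
        "%s defines no assembly '1'; using the asymmetric unit", model.identifier
    )
    return "asu"


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    """Convert a backbone model to a gemmi Structure (for writing)."""
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for i in range(len(chain)):
            res = gemmi.Residue()
            res.name = _THREE_LETTER.get(chain.aas[i], "ALA")
            res.seqid = gemmi.SeqId(chain.seq_ids[i], chain.icodes[i] or " ")
            for name in BACKBONE_ATOMS:
                xyz = chain.coords[name][i]
                if not np.isfinite(xyz).all():
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            gchain.add_residue(res)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    for name, gens in model.assemblies.items():
        asm = gemmi.Assembly(name)
        for chain_ids, ops in gens:
            gen = gemmi.Assembly.Gen()
            gen.chains = list(chain_ids)
            for R, v in ops:
                op = gemmi.Assembly.Operator()
                op.transform = gemmi.Transform(
                    gemmi.Mat33([list(row) for row in np.asarray(R)]),
                    gemmi.Vec3(*np.asarray(v)),
                )
                gen.operators.append(op)
            asm.generators.append(gen)
        st.assemblies.append(asm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as PDB (assembly definitions become REMARK 350)."""
    to_gemmi(model).write_pdb(str(path))


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
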