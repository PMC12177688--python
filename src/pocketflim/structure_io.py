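"""Reading, writing and selecting atoms of protein-ligand complexes.

Backed by gemmi for PDB/mmCIF parsing; exposes a small uniform atomic data
model (`Atom`, `Structure`) that the rest of the package consumes. All
coordinates are in Angstrom.

Conventions:
  * alternate locations are collapsed to the highest-occupancy conformer
    (ties broken by altloc letter order), so every downstream geometry is
    single-conformer and deterministic;
  * hydrogens are retained in the data model but excluded by default from
    distance and hull computations (callers filter on ``Atom.is_heavy``),
    because predicted models vary in whether hydrogens are present.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import gemmi
import numpy as np

from .errors import EmptyStructureError, SelectionError, StructureFormatError

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom of one model: element, name, position and residue identity."""

    element: str
    name: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_id: ResidueId
    is_hetero: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("Atom.element must be nonempty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.strip().upper() not in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclasses.dataclass
class Structure:
    """A multi-model atomic coordinate set with an optional flagged ligand.

    ``atoms[m]`` is the atom list of model index ``m`` (indices as stored in
    the source file, usually 1-based). ``ligand_selector`` names the dye:
    either a residue name string or a ``(chain, resnum)`` /
    ``(chain, resnum, icode)`` tuple.
    """

    entry_id: str
    models: list[int]
    atoms: dict[int, list[Atom]]
    ligand_selector: str | tuple | None = None

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model_atoms(self, model: int) -> list[Atom]:
        if model not in self.atoms:
            raise KeyError(f"no model {model}; available: {self.models}")
        return self.atoms[model]

    def coords_array(self, model: int, heavy_only: bool = True) -> np.ndarray:
        sel = [a for a in self.model_atoms(model) if a.is_heavy or not heavy_only]
        return np.array([a.coords for a in sel], dtype=float).reshape(-1, 3)

    def hetero_residue_names(self, model: int | None = None) -> list[str]:
        model = self.models[0] if model is None else model
        names: list[str] = []
        for a in self.model_atoms(model):
            if a.is_hetero and a.residue_name not in names:
                names.append(a.residue_name)
        return names


def _altloc_key(atom: gemmi.Atom) -> tuple[float, int]:
    # higher occupancy wins; ties go to the earlier altloc letter ('' first)
    return (atom.occ, -ord(atom.altloc) if atom.altloc else 0)


def _collapse_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None or _altloc_key(atom) > _altloc_key(prev):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(
    path: str | Path,
    fmt: str = "auto",
    ligand_selector: str | tuple | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into the uniform data model.

    Parameters
    ----------
    path:
        Input file. With ``fmt="auto"`` the format is inferred from the
        extension (gemmi's detection), ``.pdb`` / ``.cif`` / ``.mmcif``.
    fmt:
        One of ``{"pdb", "mmcif", "auto"}``.
    ligand_selector:
        Optional selector stored on the returned structure.

    Every MODEL block yields one entry in ``Structure.models``; all
    ATOM/HETATM records are represented (altlocs collapsed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if fmt not in fmt_map:
        raise ValueError(f"fmt must be one of {sorted(fmt_map)}, got {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    st.setup_entities()

    models: list[int] = []
    atoms: dict[int, list[Atom]] = {}
    for model in st:
        idx = int(model.num) if str(model.num).isdigit() else len(models) + 1
        model_atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                is_het = residue.het_flag == "H"
                rid: ResidueId = (
                    chain.name,
                    residue.seqid.num,
                    residue.seqid.icode.strip(),
                )
                for atom in _collapse_altlocs(residue):
                    model_atoms.append(
                        Atom(
                            element=atom.element.name,
                            name=atom.name,
                            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                            residue_name=residue.name,
                            residue_id=rid,
                            is_hetero=is_het,
                            occupancy=atom.occ,
                        )
                    )
        models.append(idx)
        atoms[idx] = model_atoms

    if not models or all(len(v) == 0 for v in atoms.values()):
        raise EmptyStructureError(f"{path}: no atoms found")
    return Structure(
        entry_id=st.name or path.stem,
        models=models,
        atoms=atoms,
        ligand_selector=ligand_selector,
    )


def _matches(atom: Atom, selector: str | tuple) -> bool:
    if isinstance(selector, str):
        return atom.residue_name == selector
    if len(selector) == 2:
        chain, num = selector
        return atom.residue_id[0] == chain and atom.residue_id[1] == int(num)
    chain, num, icode = selector
    return atom.residue_id == (chain, int(num), icode)


def select_ligand(
    structure: Structure, selector: str | tuple | None = None
) -> dict[int, list[Atom]]:
    """All atoms of the residue(s) matched by ``selector``, per model.

    ``selector`` is a residue name (e.g. ``"LIG"``) or a
    ``(chain, resnum[, icode])`` tuple; defaults to
    ``structure.ligand_selector``. Raises :class:`SelectionError` listing
    the available hetero residue names when nothing matches.
    """
    selector = selector if selector is not None else structure.ligand_selector
    if selector is None:
        raise SelectionError("no ligand selector given and none stored on structure")
    out: dict[int, list[Atom]] = {}
    for m in structure.models:
        hits = [a for a in structure.model_atoms(m) if _matches(a, selector)]
        if not hits:
            raise SelectionError(
                f"selector {selector!r} matched nothing in model {m}; "
                f"hetero residues present: {structure.hetero_residue_names(m)}"
            )
        out[m] = hits
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a standard multi-MODEL PDB file."""
    path = Path(path)
    lines: list[str] = []
    multi = structure.n_models > 1
    for m in structure.models:
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 0
        for a in structure.model_atoms(m):
            serial += 1
            record = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 or len(a.element) > 1 else f" {a.name}"
            chain, resnum, icode = a.residue_id
            x, y, z = a.coords
            lines.append(
                f"{record}{serial % 100000:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
                f"{chain[:1]:1s}{resnum:4d}{icode[:1]:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Write the structure as mmCIF (via gemmi)."""
    _to_gemmi(structure).make_mmcif_document().write_file(str(path))


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    # gemmi containers copy on add_*, so build each level completely
    # (atoms -> residue -> chain -> model) before inserting it
    st = gemmi.Structure()
    st.name = structure.entry_id
    for m in structure.models:
        grouped: dict[str, dict[tuple, list[Atom]]] = {}
        for a in structure.model_atoms(m):
            chain_id, resnum, icode = a.residue_id
            grouped.setdefault(chain_id, {}).setdefault(
                (resnum, icode, a.residue_name, a.is_hetero), []
            ).append(a)
        model = gemmi.Model(m)
        for chain_id, residues in grouped.items():
            chain = gemmi.Chain(chain_id)
            for (resnum, icode, resname, is_het), atoms in residues.items():
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, icode if icode else " ")
                res.het_flag = "H" if is_het else "A"
                for a in atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.coords)
                    atom.occ = a.occupancy
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st
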