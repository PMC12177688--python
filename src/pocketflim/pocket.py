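"""Ligand-defined binding pocket extraction and its five scalar descriptors.

The pocket is the set of protein residues having at least one heavy atom
within a cutoff distance (default 5 A) of any ligand heavy atom — distances
between atom centers, not surfaces. The descriptors are:

  * convex-hull volume (A^3) and surface area (A^2) of the pocket
    heavy-atom centers,
  * mean Kyte-Doolittle hydropathy of the pocket residues,
  * solvent-accessible surface area (Shrake-Rupley, probe 1.4 A) of the
    pocket atoms computed in the context of the whole model,
  * magnitude of the pocket dipole moment (e*A) about the geometric
    center of the pocket heavy atoms.

The dipole depends on a charge scheme ("formal" integer side-chain charges
or a bundled "partial_table"); because the pocket may carry net charge the
origin is always the pocket geometric center and is recorded alongside the
value.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from . import chem_data
from .errors import DegenerateGeometryError, EmptyPocketError
from .structure_io import Atom, ResidueId, Structure, select_ligand


@dataclasses.dataclass
class Pocket:
    """The residue shell around the ligand for one model."""

    residues: list[tuple[ResidueId, str]]  # (residue id, residue name)
    atoms: list[Atom]  # all heavy atoms of those residues
    cutoff: float
    model_index: int

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclasses.dataclass
class DipoleMoment:
    """Pocket dipole with full provenance of origin and charge scheme."""

    magnitude: float  # e*A
    vector: np.ndarray  # e*A, 3-vector
    origin: np.ndarray  # A, geometric center used as reference point
    charge_scheme: str
    net_charge: float  # e
    n_charged_atoms: int

    @property
    def magnitude_debye(self) -> float:
        return self.magnitude * chem_data.EA_TO_DEBYE

    def __float__(self) -> float:
        return float(self.magnitude)


@dataclasses.dataclass
class PocketProperties:
    """The five descriptors of one pocket (one protein, one model)."""

    volume: float  # A^3
    surface_area: float  # A^2
    hydropathy: float  # dimensionless, in [-4.5, 4.5]
    sasa: float  # A^2
    dipole_magnitude: float  # e*A
    n_residues: int
    model_index: int
    charge_scheme: str
    dipole_origin: tuple[float, float, float]


def extract_pocket(
    structure: Structure,
    model: int,
    ligand_atoms: list[Atom],
    cutoff: float = 5.0,
    include_hydrogens: bool = False,
) -> Pocket:
    """Protein residues with >=1 (heavy) atom within ``cutoff`` of the ligand.

    Ligand atoms never belong to the pocket. An empty pocket is returned
    with a warning rather than raising; descriptor operations on it raise.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not ligand_atoms:
        raise ValueError("ligand_atoms is empty")

    ligand_ids = {a.residue_id for a in ligand_atoms}
    lig_xyz = np.array(
        [a.coords for a in ligand_atoms if a.is_heavy or include_hydrogens]
    ).reshape(-1, 3)
    tree = cKDTree(lig_xyz)

    hits: dict[ResidueId, str] = {}
    for a in structure.model_atoms(model):
        if a.residue_id in ligand_ids:
            continue
        if not (a.is_heavy or include_hydrogens):
            continue
        if tree.query_ball_point(a.xyz, cutoff, return_sorted=False):
            hits.setdefault(a.residue_id, a.residue_name)

    residues = sorted(hits.items())
    atoms = [
        a
        for a in structure.model_atoms(model)
        if a.residue_id in hits and a.is_heavy
    ]
    if not residues:
        warnings.warn(
            f"empty pocket: no residue within {cutoff} A of the ligand "
            f"(model {model})",
            stacklevel=2,
        )
    return Pocket(residues=residues, atoms=atoms, cutoff=cutoff, model_index=model)


def pocket_hydropathy(pocket: Pocket) -> float:
    """Unweighted mean Kyte-Doolittle index over standard pocket residues."""
    scores = []
    for _, name in pocket.residues:
        if name in chem_data.KYTE_DOOLITTLE:
            scores.append(chem_data.KYTE_DOOLITTLE[name])
        else:
            warnings.warn(f"nonstandard residue {name} skipped for hydropathy", stacklevel=2)
    if not scores:
        raise EmptyPocketError("no standard residues in pocket; hydropathy undefined")
    return float(np.mean(scores))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    directions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point counting.

    ``coords``/``radii`` describe *all* context atoms; areas are returned
    for the ``subset`` indices only (default: all). ``directions`` allows
    substituting the quadrature point set (unit vectors); by default the
    deterministic Fibonacci spiral is used, so results are bit-reproducible.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if subset is None:
        subset = np.arange(len(coords))
    pts = fibonacci_sphere(n_points) if directions is None else np.asarray(directions)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(subset))
    for out_i, i in enumerate(np.asarray(subset)):
        r_i = expanded[i]
        surface = coords[i] + r_i * pts
        neighbors = tree.query_ball_point(coords[i], r_i + max_r)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(len(surface), dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", surface - coords[j], surface - coords[j])
            accessible &= d2 > expanded[j] ** 2
        areas[out_i] = accessible.mean() * 4.0 * np.pi * r_i**2
    return areas


def pocket_sasa(
    structure: Structure,
    pocket: Pocket,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley SASA (A^2) summed over pocket heavy atoms.

    The occlusion context is every heavy atom of the model — protein and
    ligand alike — so neighboring atoms outside the pocket can bury pocket
    atoms, as they do physically.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    if not pocket.atoms:
        raise EmptyPocketError("cannot compute SASA of an empty pocket")
    context = [a for a in structure.model_atoms(pocket.model_index) if a.is_heavy]
    coords = np.array([a.coords for a in context])
    radii = np.array([chem_data.vdw_radius(a.element) for a in context])
    index_of = { (a.residue_id, a.name): i for i, a in enumerate(context) }
    subset = np.array([index_of[(a.residue_id, a.name)] for a in pocket.atoms])
    areas = shrake_rupley_sasa(coords, radii, subset=subset, probe=probe, n_points=n_points)
    return float(areas.sum())


def pocket_hull_metrics(pocket: Pocket) -> tuple[float, float]:
    """Convex-hull (volume A^3, surface area A^2) of pocket heavy-atom centers."""
    xyz = pocket.coords()
    if len(xyz) < 4:
        raise DegenerateGeometryError(
            f"need >=4 heavy atoms for a hull, have {len(xyz)}"
        )
    centered = xyz - xyz.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise DegenerateGeometryError("pocket atoms are coplanar; hull is degenerate")
    try:
        hull = ConvexHull(xyz)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometryError(str(exc)) from exc
    return float(hull.volume), float(hull.area)


def pocket_dipole(pocket: Pocket, charge_scheme: str = "formal") -> DipoleMoment:
    """Dipole moment |sum_i q_i (r_i - r_mean)| of the pocket heavy atoms.

    ``r_mean`` is the geometric center of the pocket heavy atoms; it is
    returned in the result because a pocket with net charge has an
    origin-dependent dipole. Atoms the scheme does not resolve count as
    neutral (warning if the whole pocket resolves to nothing).
    """
    if not pocket.atoms:
        raise EmptyPocketError("cannot compute dipole of an empty pocket")
    try:
        lookup = chem_data.CHARGE_SCHEMES[charge_scheme]
    except KeyError:
        raise ValueError(
            f"unknown charge scheme {charge_scheme!r}; "
            f"choose from {sorted(chem_data.CHARGE_SCHEMES)}"
        ) from None
    xyz = pocket.coords()
    origin = xyz.mean(axis=0)
    charges = np.array(
        [lookup(a.residue_name, a.name) or 0.0 for a in pocket.atoms], dtype=float
    )
    n_charged = int(np.count_nonzero(charges))
    if n_charged == 0:
        warnings.warn(
            f"charge scheme {charge_scheme!r} resolved no charged atom in the "
            "pocket; dipole is 0",
            stacklevel=2,
        )
    vector = charges @ (xyz - origin)
    return DipoleMoment(
        magnitude=float(np.linalg.norm(vector)),
        vector=vector,
        origin=origin,
        charge_scheme=charge_scheme,
        net_charge=float(charges.sum()),
        n_charged_atoms=n_charged,
    )


def compute_all_properties(
    structure: Structure,
    ligand_selector: str | tuple | None = None,
    cutoff: float = 5.0,
    charge_scheme: str = "formal",
    probe: float = 1.4,
    n_points: int = 960,
) -> list[PocketProperties]:
    """All five descriptors for every model of the structure.

    The residue shell is re-extracted per model, so pockets may differ in
    membership between models of the same entry. Errors raised by a
    descriptor are re-raised tagged with the model index.
    """
    if not structure.models:
        raise ValueError("structure has no models")
    ligand_per_model = select_ligand(structure, ligand_selector)
    out: list[PocketProperties] = []
    for m in structure.models:
        try:
            pocket = extract_pocket(structure, m, ligand_per_model[m], cutoff=cutoff)
            volume, area = pocket_hull_metrics(pocket)
            dip = pocket_dipole(pocket, charge_scheme=charge_scheme)
            out.append(
                PocketProperties(
                    volume=volume,
                    surface_area=area,
                    hydropathy=pocket_hydropathy(pocket),
                    sasa=pocket_sasa(structure, pocket, probe=probe, n_points=n_points),
                    dipole_magnitude=dip.magnitude,
                    n_residues=pocket.n_residues,
                    model_index=m,
                    charge_scheme=charge_scheme,
                    dipole_origin=tuple(dip.origin),
                )
            )
        except Exception as exc:
            raise type(exc)(f"model {m}: {exc}") from exc
    return out


DESCRIPTOR_COLUMNS = ["volume_A3", "area_A2", "hydropathy", "sasa_A2", "dipole_eA"]


def properties_table(
    per_protein: dict[str, list[PocketProperties]]
) -> pd.DataFrame:
    """Tidy per-(protein, model) descriptor table, one row per pocket."""
    rows = []
    for protein_id, props in per_protein.items():
        for p in props:
            rows.append(
                {
                    "protein_id": protein_id,
                    "model": p.model_index,
                    "n_residues": p.n_residues,
                    "volume_A3": p.volume,
                    "area_A2": p.surface_area,
                    "hydropathy": p.hydropathy,
                    "sasa_A2": p.sasa,
                    "dipole_eA": p.dipole_magnitude,
                    "dipole_D": p.dipole_magnitude * chem_data.EA_TO_DEBYE,
                    "charge_scheme": p.charge_scheme,
                    "origin_xyz": "{:.3f};{:.3f};{:.3f}".format(*p.dipole_origin),
                }
            )
    return pd.DataFrame(rows)
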