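"""Synthetic inputs with known ground truth for every pipeline arm.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_decay` — TCSPC photon-count histograms drawn from a
  period-wrapped multi-exponential mixture (wrapped, not truncated,
  because at short repetition periods the tail of one excitation cycle
  spills into the next), with optional Gaussian IRF blur.
* :func:`simulate_flim_image` — multi-region time-resolved image stacks
  mimicking a three-organelle cell: an elliptical nucleus, a perinuclear
  ring (Golgi-like) and scattered dots (mitochondria/vesicle-like), each
  tied to a lifetime component. Default component lifetimes are the
  measured values for the dye bound to two HaloTag mutants in cells
  (5.9 and 5.5 ns) and for the unbound dye in cells (1.4 ns).
* :func:`simulate_structure_set` — pseudo-protein binding pockets around
  a fixed ligand, built from real amino-acid heavy-atom templates so
  hydropathy and charge lookups work unmodified. Each protein carries an
  exactly realized net-neutral target dipole (one Arg/Asp pair at a
  solved angular separation), and lifetimes follow a noisy decreasing
  function of the dipole magnitude: tau = a + b*|mu| + eps with b < 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lifetime_stats import LifetimeTable
from .phasor import DecayHistogram
from .pocket import fibonacci_sphere
from .structure_io import Atom, Structure, write_pdb


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# decays


def simulate_decay(
    components: float | list[tuple[float, float]],
    n_photons: int,
    n_bins: int = 256,
    period: float = 25.0,
    irf_sigma: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> DecayHistogram:
    """Photon-count decay histogram from a wrapped exponential mixture.

    ``components`` is a single lifetime (ns) or a list of
    ``(tau_ns, fraction)`` pairs whose fractions sum to 1. Arrival times
    are exponential draws wrapped modulo the repetition ``period``; an
    optional Gaussian IRF of width ``irf_sigma`` is added (also mod
    period). The histogram always sums to exactly ``n_photons``.
    """
    if isinstance(components, (int, float)):
        components = [(float(components), 1.0)]
    taus = np.array([c[0] for c in components], dtype=float)
    fracs = np.array([c[1] for c in components], dtype=float)
    if (taus <= 0).any():
        raise ValueError(f"lifetimes must be > 0 ns, got {taus}")
    if (fracs < 0).any() or not np.isclose(fracs.sum(), 1.0, atol=1e-9):
        raise ValueError(f"fractions must be >= 0 and sum to 1, got {fracs}")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    rng = _as_rng(seed)
    # zero-fraction components are dropped so that a degenerate mixture
    # consumes the RNG exactly like the equivalent single-component call
    keep = fracs > 0
    taus, fracs = taus[keep], fracs[keep]
    if len(taus) == 1:
        counts_per_comp = np.array([n_photons])
    else:
        counts_per_comp = rng.multinomial(n_photons, fracs)
    times = np.concatenate(
        [rng.exponential(tau, size=n) for tau, n in zip(taus, counts_per_comp)]
    )
    if irf_sigma:
        times = times + rng.normal(0.0, irf_sigma, size=times.shape)
    times = np.mod(times, period)
    edges = np.linspace(0.0, period, n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    return DecayHistogram(bin_edges=edges, counts=counts, period=period)


def wrapped_exponential_pdf(t: np.ndarray, tau: float, period: float) -> np.ndarray:
    """Density of the period-wrapped exponential on [0, period)."""
    t = np.asarray(t, dtype=float)
    return np.exp(-t / tau) / (tau * (1.0 - np.exp(-period / tau)))


# ---------------------------------------------------------------------------
# FLIM scenes


@dataclasses.dataclass
class RegionSpec:
    """One labeled region of a synthetic scene.

    ``kind`` is one of ``ellipse`` (params cy, cx, ay, ax), ``ring``
    (params cy, cx, r_inner, r_outer) or ``dots`` (params n_dots, radius);
    ``component`` indexes into ``SceneSpec.components``;
    ``mean_photons`` is the Poisson mean photon count per pixel.
    """

    kind: str
    params: dict
    component: int
    mean_photons: float


@dataclasses.dataclass
class SceneSpec:
    """Geometry + photophysics of a synthetic FLIM acquisition."""

    shape: tuple[int, int] = (128, 128)
    regions: list[RegionSpec] = dataclasses.field(default_factory=list)
    components: list[tuple[str, float]] = dataclasses.field(default_factory=list)
    period: float = 25.0
    n_bins: int = 256
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name, tau in self.components:
            if tau <= 0:
                raise ValueError(f"component {name} lifetime must be > 0, got {tau}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        raw = yaml.safe_load(Path(path).read_text())
        raw["regions"] = [RegionSpec(**r) for r in raw.get("regions", [])]
        raw["components"] = [tuple(c) for c in raw.get("components", [])]
        raw["shape"] = tuple(raw.get("shape", (128, 128)))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["components"] = [list(c) for c in self.components]
        Path(path).write_text(yaml.safe_dump(d))


def default_scene(seed: int | None = 0, mean_photons: float = 10_000.0) -> SceneSpec:
    """Three-organelle scene: Golgi-like ring (5.9 ns), nucleus (5.5 ns),
    mitochondria/vesicle-like dots (1.4 ns)."""
    return SceneSpec(
        shape=(128, 128),
        components=[("HT-CMHYA", 5.9), ("HT-MHYAD", 5.5), ("unbound", 1.4)],
        regions=[
            RegionSpec("ring", {"cy": 64, "cx": 64, "r_inner": 26, "r_outer": 33},
                       component=0, mean_photons=mean_photons),
            RegionSpec("ellipse", {"cy": 64, "cx": 64, "ay": 22, "ax": 16},
                       component=1, mean_photons=mean_photons),
            RegionSpec("dots", {"n_dots": 40, "radius": 2.5},
                       component=2, mean_photons=mean_photons),
        ],
        seed=seed,
    )


def region_mask(region: RegionSpec, shape: tuple[int, int],
                rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    p = region.params
    if region.kind == "ellipse":
        return ((yy - p["cy"]) / p["ay"]) ** 2 + ((xx - p["cx"]) / p["ax"]) ** 2 <= 1.0
    if region.kind == "ring":
        r = np.hypot(yy - p["cy"], xx - p["cx"])
        return (r >= p["r_inner"]) & (r <= p["r_outer"])
    if region.kind == "dots":
        mask = np.zeros(shape, dtype=bool)
        centers_y = rng.uniform(0, shape[0], size=p["n_dots"])
        centers_x = rng.uniform(0, shape[1], size=p["n_dots"])
        for cy, cx in zip(centers_y, centers_x):
            mask |= np.hypot(yy - cy, xx - cx) <= p["radius"]
        return mask
    raise ValueError(f"unknown region kind {region.kind!r}")


def simulate_flim_image(spec: SceneSpec) -> tuple[np.ndarray, dict]:
    """Simulate a (T_bins, Y, X) photon-count stack plus ground truth.

    Overlapping regions mix by photon budget: each region adds its mean
    photons/pixel to its component's rate map, and per-pixel fractions are
    the rate shares. Ground truth returned: ``component_index`` map
    (argmax rate, -1 where no photons expected), per-component
    ``fraction_maps``, and the expected-photon map.
    """
    if not spec.regions or not spec.components:
        raise ValueError("scene needs at least one region and one component")
    ny, nx = spec.shape
    n_comp = len(spec.components)
    rng = _as_rng(spec.seed)
    rates = np.zeros((n_comp, ny, nx))
    for region in spec.regions:
        if not 0 <= region.component < n_comp:
            raise ValueError(f"region component {region.component} out of range")
        rates[region.component][region_mask(region, spec.shape, rng)] += region.mean_photons
    total_rate = rates.sum(axis=0)
    if total_rate.sum() <= 0:
        raise ValueError("scene produces zero expected photons")

    stack = np.zeros((spec.n_bins, ny, nx), dtype=np.int64)
    bin_width = spec.period / spec.n_bins
    n_pix = ny * nx
    for c, (_, tau) in enumerate(spec.components):
        counts = rng.poisson(rates[c]).ravel()
        total = int(counts.sum())
        if total == 0:
            continue
        pix = np.repeat(np.arange(n_pix), counts)
        t = np.mod(rng.exponential(tau, size=total), spec.period)
        b = np.minimum((t / bin_width).astype(np.int64), spec.n_bins - 1)
        flat = np.bincount(pix * spec.n_bins + b, minlength=n_pix * spec.n_bins)
        stack += flat.reshape(n_pix, spec.n_bins).T.reshape(spec.n_bins, ny, nx)

    with np.errstate(invalid="ignore", divide="ignore"):
        fraction_maps = np.where(total_rate > 0, rates / total_rate, 0.0)
    component_index = np.where(total_rate > 0, rates.argmax(axis=0), -1)
    truth = {
        "component_index": component_index,
        "fraction_maps": fraction_maps,
        "expected_photons": total_rate,
        "components": list(spec.components),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# structure sets


# Heavy-atom residue templates in a local frame: CA at the origin, side
# chain extending toward +x (the inward, ligand-facing axis after
# placement). Geometries are idealized but bond lengths are realistic, so
# distance-based pocket extraction, SASA and hull metrics behave like
# they do on real coordinates.
_BACKBONE = [
    ("N", "N", (-0.57, 1.36, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (-0.55, -1.01, -0.88)),
    ("O", "O", (-1.54, -0.96, -1.61)),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00))],
    "SER": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)), ("OG", "O", (2.22, 1.14, 0.10))],
    "THR": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)),
                         ("OG1", "O", (2.15, 1.20, 0.10)), ("CG2", "C", (2.15, -1.25, 0.10))],
    "VAL": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)),
                         ("CG1", "C", (2.05, 1.30, 0.00)), ("CG2", "C", (2.05, -1.30, 0.00))],
    "ILE": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)), ("CG1", "C", (2.05, 1.35, 0.20)),
                         ("CG2", "C", (2.10, -1.25, 0.30)), ("CD1", "C", (3.57, 1.40, 0.20))],
    "LEU": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)), ("CG", "C", (2.53, 0.60, -0.40)),
                         ("CD1", "C", (3.98, 0.45, -0.10)), ("CD2", "C", (2.28, 2.05, -0.60))],
    "ASP": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)), ("CG", "C", (2.54, 1.13, 0.00)),
                         ("OD1", "O", (2.20, 2.30, 0.10)), ("OD2", "O", (3.77, 0.90, -0.10))],
    "ARG": _BACKBONE + [("CB", "C", (1.53, 0.00, 0.00)), ("CG", "C", (2.56, 1.10, 0.12)),
                         ("CD", "C", (4.00, 1.05, 0.10)), ("NE", "N", (4.65, -0.20, 0.05)),
                         ("CZ", "C", (6.00, -0.30, 0.00)), ("NH1", "N", (6.60, 0.80, 0.00)),
                         ("NH2", "N", (6.70, -1.40, 0.00))],
}

# charge-carrying atom of each charged template (formal scheme)
_CHARGE_ATOM = {"ARG": "CZ", "ASP": "CG"}
_NEUTRAL_CYCLE = ["ILE", "LEU", "VAL", "SER", "THR", "ALA"]

# flat two-ring dye-like ligand: 6-membered carbon ring + exocyclic N and O
LIGAND_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (1.40, 0.00, 0.00)),
    ("C2", "C", (0.70, 1.21, 0.00)),
    ("C3", "C", (-0.70, 1.21, 0.00)),
    ("C4", "C", (-1.40, 0.00, 0.00)),
    ("C5", "C", (-0.70, -1.21, 0.00)),
    ("C6", "C", (0.70, -1.21, 0.00)),
    ("N1", "N", (2.80, 0.00, 0.10)),
    ("O1", "O", (-2.75, 0.00, -0.10)),
]


@dataclasses.dataclass
class StructureSetSpec:
    """Conditions of a synthetic pocket/lifetime study.

    Lifetimes follow tau = lifetime_a + lifetime_b * |mu| + eps with
    lifetime_b < 0 (more polar pocket, shorter lifetime) and
    eps ~ N(0, noise_sd). Defaults give 12 proteins x 10 models with
    dipoles spanning 0.5-7.5 e*A and lifetimes in roughly the 2.5-6.3 ns
    window the dye exhibits across environments.
    """

    n_proteins: int = 12
    n_models: int = 10
    n_pocket_residues: int = 12
    dipole_range: tuple[float, float] = (0.5, 7.5)
    lifetime_a: float = 6.5  # ns at zero dipole
    lifetime_b: float = -0.5  # ns per e*A, must be < 0
    noise_sd: float = 0.15  # ns
    jitter: float = 0.15  # A per-model coordinate noise
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 3:
            raise ValueError("need n_proteins >= 3")
        if self.lifetime_b >= 0:
            raise ValueError("lifetime_b must be negative (anticorrelation)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StructureSetSpec":
        raw = yaml.safe_load(Path(path).read_text())
        if "dipole_range" in raw:
            raw["dipole_range"] = tuple(raw["dipole_range"])
        return cls(**raw)


@dataclasses.dataclass
class StructureSet:
    structures: dict[str, Structure]
    lifetimes: LifetimeTable
    truth: pd.DataFrame  # protein_id, dipole_target_eA, tau_ns
    ligand_name: str = "LIG"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for pid, st in self.structures.items():
            p = out_dir / f"{pid}.pdb"
            write_pdb(st, p)
            paths[pid] = p
        self.lifetimes.to_frame().to_csv(out_dir / "lifetimes.csv", index=False)
        self.truth.to_csv(out_dir / "truth.csv", index=False)
        return paths


def _rotation_to(axis_from: np.ndarray, axis_to: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector axis_from to axis_to."""
    a = axis_from / np.linalg.norm(axis_from)
    b = axis_to / np.linalg.norm(axis_to)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


_TIP_RADIUS = 4.0  # A: radius at which side-chain tips / charge atoms sit


def _place_residue(
    name: str,
    direction: np.ndarray,
    resnum: int,
    anchor_atom: str | None = None,
) -> list[Atom]:
    """Place a template with its side chain pointing inward along -direction.

    If ``anchor_atom`` is given, that atom lands exactly at
    ``_TIP_RADIUS * direction``; otherwise the template's farthest
    side-chain atom is used as the anchor. This makes charge-atom
    positions, and hence the constructed dipole, exact.
    """
    template = RESIDUE_TEMPLATES[name]
    R = _rotation_to(np.array([1.0, 0.0, 0.0]), -direction)
    anchor = anchor_atom or max(template, key=lambda t: t[2][0])[0]
    tip_local = next(np.asarray(t[2]) for t in template if t[0] == anchor)
    offset = _TIP_RADIUS * direction - R @ tip_local
    atoms = []
    for atom_name, element, local in template:
        pos = R @ np.asarray(local) + offset
        atoms.append(
            Atom(
                element=element,
                name=atom_name,
                coords=tuple(pos),
                residue_name=name,
                residue_id=("A", resnum, ""),
            )
        )
    return atoms


def _charged_placements(target_dipole: float) -> list[tuple[str, np.ndarray]]:
    """Residue placements realizing an exact net-neutral dipole magnitude.

    One Arg(+1 at CZ) / Asp(-1 at CG) pair at angular separation theta on
    the tip sphere gives |mu| = 2 * R_tip * sin(theta/2), independent of
    origin. A (near-)zero target uses a centrosymmetric four-residue
    arrangement instead.
    """
    max_mu = 2.0 * _TIP_RADIUS
    if target_dipole > max_mu + 1e-12 or target_dipole < 0:
        raise ValueError(
            f"target dipole {target_dipole:.3f} e*A infeasible; "
            f"must be within [0, {max_mu:.1f}] for this residue budget"
        )
    if target_dipole < 1e-9:
        return [
            ("ARG", np.array([0.0, 0.0, 1.0])),
            ("ARG", np.array([0.0, 0.0, -1.0])),
            ("ASP", np.array([0.0, 1.0, 0.0])),
            ("ASP", np.array([0.0, -1.0, 0.0])),
        ]
    half = np.arcsin(min(target_dipole / max_mu, 1.0))
    u_plus = np.array([np.sin(half), 0.0, np.cos(half)])
    u_minus = np.array([-np.sin(half), 0.0, np.cos(half)])
    return [("ARG", u_plus), ("ASP", u_minus)]


def build_pocket_structure(
    target_dipole: float,
    n_residues: int = 12,
    n_models: int = 1,
    jitter: float = 0.0,
    entry_id: str = "SYN",
    neutral_offset: int = 0,
    rng: np.random.Generator | None = None,
) -> Structure:
    """One pseudo-protein: ligand at the origin, residue shell around it.

    Charged residues realize ``target_dipole`` exactly (at jitter 0);
    the remaining residues cycle through neutral amino-acid templates.
    All models share topology; per-model Gaussian coordinate noise of sd
    ``jitter`` emulates predictor variability.
    """
    rng = _as_rng(rng)
    charged = _charged_placements(target_dipole)
    n_neutral = n_residues - len(charged)
    if n_neutral < 0:
        raise ValueError(f"n_residues={n_residues} too small for the charge arrangement")

    placements: list[tuple[str, np.ndarray]] = list(charged)
    # neutral shell directions: spiral points, skewed away from the poles
    # used by the charged pair by a fixed roll about y
    dirs = fibonacci_sphere(max(n_neutral, 1))
    roll = _rotation_to(np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]) / np.sqrt(3))
    for i in range(n_neutral):
        name = _NEUTRAL_CYCLE[(i + neutral_offset) % len(_NEUTRAL_CYCLE)]
        placements.append((name, roll @ dirs[i]))

    base_atoms: list[Atom] = [
        Atom(element=el, name=an, coords=tuple(np.asarray(xyz)),
             residue_name="LIG", residue_id=("L", 900, ""), is_hetero=True)
        for an, el, xyz in LIGAND_TEMPLATE
    ]
    for resnum, (name, direction) in enumerate(placements, start=1):
        base_atoms.extend(
            _place_residue(name, direction, resnum, anchor_atom=_CHARGE_ATOM.get(name))
        )

    base_xyz = np.array([a.coords for a in base_atoms])
    models = list(range(1, n_models + 1))
    atoms: dict[int, list[Atom]] = {}
    for m in models:
        noise = rng.normal(0.0, jitter, size=base_xyz.shape) if jitter > 0 else 0.0
        xyz = base_xyz + noise
        atoms[m] = [
            dataclasses.replace(a, coords=tuple(xyz[i])) for i, a in enumerate(base_atoms)
        ]
    return Structure(entry_id=entry_id, models=models, atoms=atoms, ligand_selector="LIG")


def simulate_structure_set(
    spec: StructureSetSpec, out_dir: str | Path | None = None
) -> StructureSet:
    """Full synthetic study: structures + lifetime table + dipole truth.

    Target dipoles are evenly spread over ``spec.dipole_range`` (a
    deterministic grid, so the covered range does not fluctuate with the
    seed); lifetimes are drawn from the noisy linear law. Optionally
    writes PDB files plus lifetimes.csv / truth.csv to ``out_dir``.
    """
    rng = _as_rng(spec.seed)
    lo, hi = spec.dipole_range
    targets = np.linspace(lo, hi, spec.n_proteins)
    entries: dict[str, float] = {}
    structures: dict[str, Structure] = {}
    rows = []
    for i, mu in enumerate(targets):
        pid = f"SYN{i + 1:02d}"
        structures[pid] = build_pocket_structure(
            float(mu),
            n_residues=spec.n_pocket_residues,
            n_models=spec.n_models,
            jitter=spec.jitter,
            entry_id=pid,
            neutral_offset=i,
            rng=rng,
        )
        tau = spec.lifetime_a + spec.lifetime_b * mu + rng.normal(0.0, spec.noise_sd)
        if tau <= 0:
            raise ValueError(
                f"lifetime law produced tau={tau:.3f} ns <= 0 for |mu|={mu:.2f}; "
                "adjust lifetime_a/lifetime_b/noise_sd"
            )
        entries[pid] = float(tau)
        rows.append({"protein_id": pid, "dipole_target_eA": float(mu), "tau_ns": float(tau)})

    out = StructureSet(
        structures=structures,
        lifetimes=LifetimeTable(entries=entries, source="synthetic"),
        truth=pd.DataFrame(rows),
    )
    if out_dir is not None:
        out.write(out_dir)
    return out
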