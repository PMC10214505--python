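"""Structure parsing, contacts, interface residues, SASA/BSA and superposition.

Works on plain PDB files (single- or multi-model) read through gemmi;
each atom is tagged with the side of the ternary system it belongs to
(receptor ``R``, ligand protein ``L``, stabilizer ``S``) via a
chain-to-side map supplied by the caller.  Distances are in Å.

Atom radii follow the pocket-contact convention used throughout the
package (H 1.2, C 1.7, N 1.55, O 1.52, F 1.47, B 1.92, P 1.8, S 1.8 Å).
Chlorine defaults to 1.75 Å; a physically implausible legacy value of
0.2 Å is available behind ``literal_chlorine`` for strict
reproduction of older contact counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ATOM_RADII",
    "AtomRecord",
    "ProbeRecord",
    "ResidueId",
    "SurfaceReport",
    "SuperpositionResult",
    "assign_radius",
    "read_structure",
    "read_structure_models",
    "in_contact",
    "interface_residues",
    "sasa",
    "buried_surface",
    "superpose",
    "irmsd_series",
]

#: van der Waals radii (Å) used for atom–probe contacts and SASA.
ATOM_RADII = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52,
    "F": 1.47, "B": 1.92, "P": 1.8, "S": 1.8, "CL": 1.75,
}

#: Legacy chlorine radius retained for strict contact-count reproduction.
LITERAL_CL_RADIUS = 0.2

ResidueId = tuple  # (chain, resnum, icode)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its side tag (R/L/S/other) and contact radius."""

    serial: int
    name: str
    element: str
    chain: str
    resnum: int
    icode: str
    resname: str
    coords: tuple[float, float, float]
    side_tag: str
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"atom radius must be positive, got {self.radius!r}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.resnum, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class ProbeRecord:
    """A pocket probe sphere (polar or apolar) from a cavity-detection tool."""

    center: tuple[float, float, float]
    radius: float
    polarity: str  # "polar" | "apolar"
    pocket_id: int

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"probe radius must be positive, got {self.radius!r}")
        if self.polarity not in ("polar", "apolar"):
            raise ValueError(f"polarity must be 'polar' or 'apolar', got {self.polarity!r}")


@dataclass(frozen=True)
class SurfaceReport:
    """SASA of components/pairs and the derived buried surface areas, Å²."""

    sasa_r: float
    sasa_l: float
    sasa_s: float
    sasa_rs: float
    sasa_ls: float
    sasa_rls: float
    bsa_rs: float
    bsa_ls: float
    ratio: float | None  # BSA_LS / BSA_RS; None when BSA_RS ~ 0


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid superposition (proper rotation) and post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def assign_radius(
    element: str,
    default: float = 1.7,
    strict: bool = False,
    literal_chlorine: bool = False,
) -> float:
    """Contact radius (Å) for an element symbol.

    Unknown elements fall back to ``default`` with a warning, or raise
    when ``strict``.
    """
    el = element.strip().upper()
    if el == "CL" and literal_chlorine:
        return LITERAL_CL_RADIUS
    try:
        return ATOM_RADII[el]
    except KeyError:
        if strict:
            raise KeyError(f"no radius tabulated for element {element!r}")
        warnings.warn(
            f"no radius tabulated for element {element!r}; using default {default} Å",
            stacklevel=2,
        )
        return default


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom-name convention (' CA ' -> C)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("cannot infer element from empty atom name")
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "NA", "CA") and len(name) >= 2 and not name[:1].isspace():
        # left-justified two-letter element in columns 13-14
        return two
    return stripped[0].upper()


def read_structure(
    path,
    side_map: dict[str, str],
    default_radius: float = 1.7,
    literal_chlorine: bool = False,
    model_index: int = 0,
) -> list[AtomRecord]:
    """Read one model of a PDB file into side-tagged atom records.

    ``side_map`` maps chain names to side tags (``R``, ``L``, ``S`` or
    ``other``); a chain missing from the map is an error so silent
    mis-tagging cannot occur.  Elements come from the PDB element column
    when present, else from the atom-name convention.
    """
    models = read_structure_models(path, side_map, default_radius, literal_chlorine)
    return models[model_index]


def read_structure_models(
    path,
    side_map: dict[str, str],
    default_radius: float = 1.7,
    literal_chlorine: bool = False,
) -> list[list[AtomRecord]]:
    """Read every model of a (multi-model) PDB file; see :func:`read_structure`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc

    models: list[list[AtomRecord]] = []
    for model in structure:
        atoms: list[AtomRecord] = []
        for chain in model:
            if chain.name not in side_map:
                raise KeyError(
                    f"{path}: chain {chain.name!r} absent from side map "
                    f"(known: {sorted(side_map)})"
                )
            tag = side_map[chain.name]
            for residue in chain:
                for atom in residue:
                    el = (atom.element.name or "").strip().upper()
                    if not el or el == "X":
                        el = _element_from_name(atom.name)
                    atoms.append(AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=el,
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        resname=residue.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        side_tag=tag,
                        radius=assign_radius(el, default=default_radius,
                                             literal_chlorine=literal_chlorine),
                    ))
        models.append(atoms)
    if not models or not any(models):
        raise ValueError(f"{path}: no atoms found")
    return models


def coords_of(atoms) -> np.ndarray:
    """Coordinate array (n, 3) of a sequence of atom records."""
    return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


def in_contact(atom: AtomRecord, probe: ProbeRecord) -> bool:
    """True when the atom–probe distance is strictly below the radius sum."""
    d = math.dist(atom.coords, probe.center)
    return d < atom.radius + probe.radius


def interface_residues(
    r_atoms, l_atoms, cutoff: float = 5.0
) -> tuple[set, set]:
    """Residues of each side with any atom within ``cutoff`` Å of the partner.

    The standard interface definition: a residue is interfacial when any
    of its atoms lies within the cutoff (default 5 Å) of any partner
    atom.  Evaluated with a KD-tree but identical to the all-pairs
    double loop.  Returns ``(receptor_side, ligand_side)`` residue-id
    sets.
    """
    if not r_atoms or not l_atoms:
        raise ValueError("interface_residues requires non-empty atom sets on both sides")
    r_xyz, l_xyz = coords_of(r_atoms), coords_of(l_atoms)
    tree = cKDTree(l_xyz)
    pairs = tree.query_ball_point(r_xyz, r=cutoff)
    r_set: set = set()
    l_set: set = set()
    for i, hits in enumerate(pairs):
        if hits:
            r_set.add(r_atoms[i].residue_id)
            for j in hits:
                l_set.add(l_atoms[j].residue_id)
    return r_set, l_set


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    atoms,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area via a Shrake–Rupley point count.

    Each atom's solvent-extended sphere (radius + probe radius) is
    sampled with a deterministic Fibonacci lattice of ``n_points``
    points; a point is accessible when outside every neighbor's extended
    sphere.  Hydrogens are excluded by default (conventional SASA); the
    contact-radius table still covers them when included.  Returns
    ``(total, per_atom)`` in Å²; per-atom areas sum to the total.
    """
    if n_points < 16:
        raise ValueError(f"n_points must be at least 16, got {n_points}")
    work = [a for a in atoms if include_hydrogens or not a.is_hydrogen]
    if not work:
        raise ValueError("no atoms to compute SASA for")
    xyz = coords_of(work)
    radii = np.array([a.radius for a in work]) + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    per_atom = np.zeros(len(work))
    for i in range(len(work)):
        pts = xyz[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 >= radii[j] ** 2
        per_atom[i] = accessible.sum() / n_points * 4.0 * math.pi * radii[i] ** 2
    # map back onto the original atom order (zeros for excluded hydrogens)
    out = np.zeros(len(atoms))
    k = 0
    for idx, a in enumerate(atoms):
        if include_hydrogens or not a.is_hydrogen:
            out[idx] = per_atom[k]
            k += 1
    return float(per_atom.sum()), out


def buried_surface(
    r_atoms, l_atoms, s_atoms,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SurfaceReport:
    """Buried surface area between the stabilizer and each protein partner.

    BSA_RS = (SASA(R) + SASA(S) − SASA(R∪S)) / 2 with component SASAs
    computed in isolation; BSA_LS analogously.  The ratio BSA_LS/BSA_RS
    is a quick geometric gauge of dual binding: near 1 when the
    stabilizer contacts both partners evenly, near 0 when it sits on the
    receptor only (undefined when it does not touch the receptor at all).
    """
    if not s_atoms:
        raise ValueError("buried_surface requires a non-empty stabilizer atom set")
    kw = dict(probe_radius=probe_radius, n_points=n_points)
    sasa_r = sasa(r_atoms, **kw)[0]
    sasa_l = sasa(l_atoms, **kw)[0]
    sasa_s = sasa(s_atoms, **kw)[0]
    sasa_rs = sasa(list(r_atoms) + list(s_atoms), **kw)[0]
    sasa_ls = sasa(list(l_atoms) + list(s_atoms), **kw)[0]
    sasa_rls = sasa(list(r_atoms) + list(l_atoms) + list(s_atoms), **kw)[0]
    bsa_rs = max(0.0, (sasa_r + sasa_s - sasa_rs) / 2.0)
    bsa_ls = max(0.0, (sasa_l + sasa_s - sasa_ls) / 2.0)
    tiny = 1e-9 * (sasa_s + 1.0)
    ratio = (bsa_ls / bsa_rs) if bsa_rs > tiny else None
    return SurfaceReport(
        sasa_r=sasa_r, sasa_l=sasa_l, sasa_s=sasa_s,
        sasa_rs=sasa_rs, sasa_ls=sasa_ls, sasa_rls=sasa_rls,
        bsa_rs=bsa_rs, bsa_ls=bsa_ls, ratio=ratio,
    )


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1), translation and post-fit
    RMSD.  Requires at least 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - mc, ref - rc
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) coordinate set; rotation is ill-defined")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    trans = rc - rot @ mc
    fitted = (rot @ mob.T).T + trans
    rmsd = float(np.sqrt(((fitted - ref) ** 2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def irmsd_series(
    frames,
    reference,
    interface: set,
    selection: str = "heavy",
    window_frames: int | None = None,
) -> np.ndarray:
    """Interface RMSD per frame against a reference structure.

    The interface residue set is determined once on the reference (by
    the caller, via :func:`interface_residues`); per frame, the selected
    interface atoms (``heavy`` or ``backbone``) are superposed onto the
    reference selection and the post-fit RMSD reported.  An optional
    boxcar ``window_frames`` smooths the series (sliding-window mean;
    choose the window from the trajectory frame spacing, e.g. 2 ns
    worth of frames).
    """
    if selection not in ("heavy", "backbone"):
        raise ValueError(f"selection must be 'heavy' or 'backbone', got {selection!r}")
    backbone_names = {"N", "CA", "C", "O"}

    def select(atoms):
        out = []
        for a in atoms:
            if a.residue_id not in interface or a.is_hydrogen:
                continue
            if selection == "backbone" and a.name.strip() not in backbone_names:
                continue
            out.append(a)
        return out

    ref_sel = select(reference)
    if not ref_sel:
        raise ValueError("no interface atoms selected on the reference")
    ref_xyz = coords_of(ref_sel)
    ref_keys = [(a.residue_id, a.name) for a in ref_sel]

    series = np.empty(len(frames))
    for fi, frame in enumerate(frames):
        sel = select(frame)
        keys = [(a.residue_id, a.name) for a in sel]
        if keys != ref_keys:
            raise ValueError(
                f"frame {fi}: interface atom selection mismatch with reference "
                f"({len(sel)} vs {len(ref_sel)} atoms)"
            )
        series[fi] = superpose(coords_of(sel), ref_xyz).rmsd
    if window_frames is not None and window_frames > 1:
        kernel = np.ones(window_frames) / window_frames
        series = np.convolve(series, kernel, mode="valid")
    return series
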