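"""Interface-pocket classification, ligand coverage and volume summaries.

Pockets are consumed as sets of polar/apolar probe spheres plus
externally supplied druggability scores (pocket score, drug score) in
the style emitted by cavity-detection tools; nothing here re-detects
cavities or re-scores them.

Probe file dialect (PQR-style, whitespace-delimited)::

    ATOM  serial  name  resname  chain  pocket_id  x  y  z  charge  radius

with ``resname`` ``POL`` (polar) or ``APL`` (apolar) and probes grouped
by ``pocket_id``.  Scores ride in a sidecar TSV with columns
``pocket_id, pocket_score, drug_score``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import AtomRecord, ProbeRecord, coords_of

__all__ = [
    "Pocket",
    "CoverageReport",
    "VolumeSummary",
    "read_probe_file",
    "read_pockets",
    "read_volume_series",
    "contact_counts",
    "interface_pocket_stats",
    "ligand_coverage",
    "rank_pockets",
    "volume_summary",
]


@dataclass(frozen=True)
class Pocket:
    """A probe-sphere pocket with external druggability scores."""

    pocket_id: int
    probes: tuple[ProbeRecord, ...]
    pocket_score: float | None = None
    drug_score: float | None = None

    def __post_init__(self) -> None:
        if any(p.pocket_id != self.pocket_id for p in self.probes):
            raise ValueError(f"pocket {self.pocket_id}: probe with foreign pocket_id")


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of ligand (stabilizer) atoms touching a pocket's probes."""

    pocket_id: int
    n_ligand_total: int
    n_ligand_in_contact: int
    fraction: float
    no_probes: bool = False


@dataclass(frozen=True)
class VolumeSummary:
    """Distribution summary of a per-frame pocket-volume series, Å³."""

    pocket_id: int
    n_frames: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    ligand_volume: float | None
    accommodation_fraction: float | None  # fraction of frames with volume >= ligand volume


def read_probe_file(path) -> list[ProbeRecord]:
    """Parse a PQR-style probe file (see module docstring for the dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"probe file not found: {path}")
    probes: list[ProbeRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "REMARK", "TER", "END")):
            continue
        parts = line.split()
        if parts[0] not in ("ATOM", "HETATM"):
            continue
        if len(parts) < 11:
            raise ValueError(f"{path}:{lineno}: malformed probe record ({len(parts)} fields)")
        resname = parts[3].upper()
        if resname not in ("POL", "APL"):
            raise ValueError(f"{path}:{lineno}: unknown polarity tag {resname!r}")
        probes.append(ProbeRecord(
            center=(float(parts[6]), float(parts[7]), float(parts[8])),
            radius=float(parts[10]),
            polarity="polar" if resname == "POL" else "apolar",
            pocket_id=int(parts[5]),
        ))
    if not probes:
        raise ValueError(f"{path}: no probe records found")
    return probes


def read_pockets(probe_path, scores_path=None) -> list[Pocket]:
    """Group probes by pocket id and attach sidecar scores when given."""
    probes = read_probe_file(probe_path)
    scores: dict[int, tuple[float, float]] = {}
    if scores_path is not None:
        df = pd.read_csv(scores_path, sep=None, engine="python", comment="#")
        for col in ("pocket_id", "pocket_score", "drug_score"):
            if col not in df.columns:
                raise ValueError(f"{scores_path}: missing column {col!r}")
        scores = {
            int(r.pocket_id): (float(r.pocket_score), float(r.drug_score))
            for r in df.itertuples()
        }
    pockets: list[Pocket] = []
    for pid in sorted({p.pocket_id for p in probes}):
        ps, ds = scores.get(pid, (None, None))
        pockets.append(Pocket(
            pocket_id=pid,
            probes=tuple(p for p in probes if p.pocket_id == pid),
            pocket_score=ps,
            drug_score=ds,
        ))
    return pockets


def read_volume_series(path) -> pd.DataFrame:
    """Read a per-frame pocket volume series TSV (columns frame, volume)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("frame", "volume"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["volume"] < 0).any():
        raise ValueError(f"{path}: negative pocket volume")
    return df


def _atoms_in_contact(atoms, probes) -> np.ndarray:
    """Boolean mask over ``atoms``: touches at least one probe sphere.

    Contact rule: distance strictly below the atom/probe radius sum
    (shared with geometry.in_contact); KD-tree accelerated but identical
    to the all-pairs evaluation.
    """
    if not atoms or not probes:
        return np.zeros(len(atoms), dtype=bool)
    xyz = coords_of(atoms)
    a_rad = np.array([a.radius for a in atoms])
    centers = np.array([p.center for p in probes])
    p_rad = np.array([p.radius for p in probes])
    tree = cKDTree(centers)
    mask = np.zeros(len(atoms), dtype=bool)
    max_p = p_rad.max()
    for i in range(len(atoms)):
        for j in tree.query_ball_point(xyz[i], a_rad[i] + max_p):
            if np.linalg.norm(xyz[i] - centers[j]) < a_rad[i] + p_rad[j]:
                mask[i] = True
                break
    return mask


def contact_counts(pocket: Pocket, r_atoms, l_atoms) -> tuple[int, int]:
    """Distinct receptor and ligand-protein atoms in contact with the pocket."""
    return (
        int(_atoms_in_contact(list(r_atoms), pocket.probes).sum()),
        int(_atoms_in_contact(list(l_atoms), pocket.probes).sum()),
    )


def interface_pocket_stats(
    pockets, r_atoms, l_atoms, min_atoms=(5, 10, 20)
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Interface-pocket criterion: distinct atoms from both sides in probe contact.

    A pocket passes threshold ``m`` when at least ``m`` distinct receptor
    atoms *and* ``m`` distinct ligand-protein atoms touch its probes
    (counting atoms, not contact pairs).  Returns a per-pocket table of
    side counts and pass flags, plus per-threshold totals.  An empty
    pocket list yields zero counts.
    """
    rows = []
    totals = {int(m): 0 for m in min_atoms}
    for pocket in pockets:
        n_r, n_l = contact_counts(pocket, r_atoms, l_atoms)
        row = {"pocket_id": pocket.pocket_id, "n_contact_r": n_r, "n_contact_l": n_l}
        for m in min_atoms:
            passed = n_r >= m and n_l >= m
            row[f"pass_{int(m)}"] = passed
            if passed:
                totals[int(m)] += 1
        rows.append(row)
    columns = ["pocket_id", "n_contact_r", "n_contact_l"] + [f"pass_{int(m)}" for m in min_atoms]
    return pd.DataFrame(rows, columns=columns), totals


def ligand_coverage(ligand_atoms, pocket: Pocket) -> CoverageReport:
    """Fraction of stabilizer atoms in contact with the pocket's probes.

    Each ligand atom counts once no matter how many probes it touches;
    the denominator is every supplied stabilizer atom (hydrogens
    included when present).  A well-placed pocket explains the known
    binding site when the fraction approaches 1.  An empty probe set
    reports fraction 0 with ``no_probes`` flagged.
    """
    ligand_atoms = list(ligand_atoms)
    if not ligand_atoms:
        raise ValueError("ligand_coverage requires a non-empty ligand atom set")
    if not pocket.probes:
        return CoverageReport(pocket.pocket_id, len(ligand_atoms), 0, 0.0, no_probes=True)
    n_hit = int(_atoms_in_contact(ligand_atoms, pocket.probes).sum())
    return CoverageReport(
        pocket_id=pocket.pocket_id,
        n_ligand_total=len(ligand_atoms),
        n_ligand_in_contact=n_hit,
        fraction=n_hit / len(ligand_atoms),
    )


def rank_pockets(
    pockets, by: str = "drug_score", true_pocket: int | None = None
) -> tuple[pd.DataFrame, int | None]:
    """Rank pockets by an externally supplied druggability score.

    Descending by ``pocket_score`` or ``drug_score`` with deterministic
    ties broken by pocket id.  When a designated ``true_pocket`` (the
    known stabilizer-binding pocket) is given, its rank is returned for
    coverage-versus-rank benchmarking.
    """
    if by not in ("pocket_score", "drug_score"):
        raise ValueError(f"rank key must be 'pocket_score' or 'drug_score', got {by!r}")
    rows = []
    for p in pockets:
        score = getattr(p, by)
        if score is None:
            raise ValueError(f"pocket {p.pocket_id} lacks {by}")
        rows.append({"pocket_id": p.pocket_id, by: score})
    df = pd.DataFrame(rows).sort_values(
        [by, "pocket_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    true_rank = None
    if true_pocket is not None:
        hit = df.index[df["pocket_id"] == true_pocket]
        if len(hit) == 0:
            raise ValueError(f"true pocket {true_pocket} not among ranked pockets")
        true_rank = int(df.loc[hit[0], "rank"])
    return df, true_rank


def volume_summary(
    volumes, pocket_id: int = 0, ligand_volume: float | None = None
) -> VolumeSummary:
    """Summarize a per-frame pocket-volume series (Å³).

    Beyond the usual moments, reports the accommodation fraction: the
    fraction of frames whose pocket volume is at least the stabilizer's
    molecular volume, i.e. how often a breathing pocket opens wide
    enough to accept the compound.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume series")
    if (v < 0).any():
        raise ValueError("negative pocket volume in series")
    frac = None
    if ligand_volume is not None:
        frac = float((v >= ligand_volume).mean())
    return VolumeSummary(
        pocket_id=pocket_id,
        n_frames=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        minimum=float(v.min()),
        maximum=float(v.max()),
        ligand_volume=ligand_volume,
        accommodation_fraction=frac,
    )
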