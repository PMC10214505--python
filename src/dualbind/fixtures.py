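"""Synthetic fixtures with planted, self-verified ground truth.

Generates every input the toolkit consumes — toy protein–protein
complexes in PDB format, pocket-probe files with score sidecars,
per-frame interaction-energy tables, and compound rosters — together
with a manifest of the planted truths (interface residues, coverage
fractions, replica means, filter pass counts, shortlist membership).

The geometry is deliberately schematic: atoms sit on lattices with
spacings chosen so that every planted contact/interface relation is
unambiguous (margins far larger than any radius sum involved).  Each
generator re-checks its planted truths by brute force before writing
and embeds them in the manifest, so downstream tests compare against
verified, realized values.  All randomness flows from an explicit seed;
fixtures are byte-stable under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energetics import EnergyFrameTable, aggregate, dual_binding_selector
from .geometry import AtomRecord, ProbeRecord, assign_radius

__all__ = [
    "make_toy_complex",
    "make_pocket_fixture",
    "make_energy_tables",
    "make_compound_roster",
    "make_candidate_energies",
    "write_manifest",
    "read_manifest",
]

_ELEMENTS = ("C", "N", "O", "S")
_GRID_SPACING = 8.0  # Å between lattice sites; >> any radius sum used
_LATERAL_OFFSET = 4.0  # Å offset of non-facing residues


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _pdb_atom_line(serial, name, resname, chain, resnum, x, y, z, element, het=False):
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial:5d} {name:<4s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_toy_complex(
    n_atoms_per_chain: int = 12,
    gap: float = 4.0,
    seed: int = 0,
    n_stabilizer_atoms: int = 4,
) -> tuple[str, dict]:
    """Two facing atom lattices (chains R, L) with an optional stabilizer group.

    Chain R occupies the plane x = 0 and chain L the plane x = ``gap``;
    the first half of each chain's residues face a partner residue
    directly across the gap (and are therefore interfacial at the usual
    5 Å cutoff when ``gap`` < 5), while the rest are laterally offset so
    their nearest partner distance is sqrt(gap² + offset²).  Stabilizer
    atoms (HETATM, chain S) sit mid-gap below the lattice.  Returns the
    PDB text and a manifest with the planted (and brute-force verified)
    interface residue lists.
    """
    if gap <= 0:
        raise ValueError(f"gap must be positive, got {gap!r}")
    if n_atoms_per_chain < 2:
        raise ValueError("need at least 2 atoms per chain")
    rng = np.random.default_rng(seed)

    n_facing = n_atoms_per_chain // 2
    lines = ["REMARK synthetic toy complex (schematic lattice; not physical geometry)"]
    serial = 0
    # non-facing residues retreat from the interface plane along x so that
    # only the first n_facing residues of each chain can be interfacial
    back = _GRID_SPACING + 2.0
    positions: dict[str, list[tuple[int, float, float, float, str]]] = {"R": [], "L": []}
    for chain, x_face, x_back in (("R", 0.0, -back), ("L", gap, gap + back)):
        for i in range(n_atoms_per_chain):
            row, col = divmod(i, 4)
            y = col * _GRID_SPACING
            z = row * _GRID_SPACING
            el = _ELEMENTS[int(rng.integers(len(_ELEMENTS)))]
            x = x_face if i < n_facing else x_back
            positions[chain].append((i + 1, x, y, z, el))

    for chain in ("R", "L"):
        for resnum, x, y, z, el in positions[chain]:
            serial += 1
            lines.append(_pdb_atom_line(serial, f"{el}1", "ALA", chain, resnum, x, y, z, el))

    stab = []
    for k in range(n_stabilizer_atoms):
        serial += 1
        x, y, z = gap / 2.0, -2.0 * _GRID_SPACING - k * 4.0, 0.0
        stab.append((k + 1, x, y, z, "C"))
        lines.append(_pdb_atom_line(serial, "C1", "STB", "S", k + 1, x, y, z, "C", het=True))
    lines.append("END")

    # brute-force interface check (all-pairs double loop, cutoff 5 Å)
    cutoff = 5.0
    r_iface, l_iface = set(), set()
    for rn_r, xr, yr, zr, _ in positions["R"]:
        for rn_l, xl, yl, zl, _ in positions["L"]:
            if math.dist((xr, yr, zr), (xl, yl, zl)) <= cutoff:
                r_iface.add(rn_r)
                l_iface.add(rn_l)
    expected = set(range(1, n_facing + 1)) if gap <= cutoff else set()
    if not (r_iface == l_iface == expected):
        raise RuntimeError("toy-complex plant failed self-verification")

    manifest = {
        "kind": "toy_complex",
        "seed": int(seed),
        "gap": float(gap),
        "n_atoms_per_chain": int(n_atoms_per_chain),
        "n_stabilizer_atoms": int(n_stabilizer_atoms),
        "side_map": {"R": "R", "L": "L", "S": "S"},
        "interface_residues_r": sorted(r_iface),
        "interface_residues_l": sorted(l_iface),
        "stabilizer_positions": [[float(x), float(y), float(z)] for _, x, y, z, _ in stab],
    }
    return "\n".join(lines) + "\n", manifest


def make_pocket_fixture(
    atoms: list[AtomRecord],
    planted_coverage_atoms: int,
    planted_side_counts: tuple[int, int],
    seed: int = 0,
    probe_radius: float = 0.4,
    n_decoy_pockets: int = 2,
) -> tuple[list[str], pd.DataFrame, dict]:
    """Probe set planted to hit exact side counts and ligand coverage.

    Pocket 1 gets one probe centred on each of ``planted_side_counts``
    receptor/ligand-protein atoms and on ``planted_coverage_atoms`` of
    the stabilizer atoms (probe radius small enough that each probe
    touches only its own atom on the sparse fixture lattice); decoy
    pockets sit far from everything.  The sidecar scores rank pocket 1
    first.  Contacts are re-verified by brute force before the files are
    emitted; an infeasible plant raises.

    Returns (probe file lines, scores sidecar frame, manifest).
    """
    rng = np.random.default_rng(seed)
    by_side = {s: [a for a in atoms if a.side_tag == s] for s in ("R", "L", "S")}
    n_r, n_l = planted_side_counts
    if n_r > len(by_side["R"]) or n_l > len(by_side["L"]):
        raise ValueError("planted side counts exceed available atoms")
    if planted_coverage_atoms > len(by_side["S"]):
        raise ValueError("planted coverage exceeds available stabilizer atoms "
                         "(fraction would exceed 1)")

    chosen = (
        [a for a in by_side["R"][:n_r]]
        + [a for a in by_side["L"][:n_l]]
        + [a for a in by_side["S"][:planted_coverage_atoms]]
    )
    probes = [ProbeRecord(center=a.coords, radius=probe_radius,
                          polarity="polar" if i % 2 == 0 else "apolar", pocket_id=1)
              for i, a in enumerate(chosen)]

    # brute-force verification of the plant against every atom
    def touched(probe_list):
        hits = {"R": set(), "L": set(), "S": set()}
        for a in atoms:
            if a.side_tag not in hits:
                continue
            for p in probe_list:
                if math.dist(a.coords, p.center) < a.radius + p.radius:
                    hits[a.side_tag].add(a.serial)
                    break
        return hits["R"], hits["L"], hits["S"]

    hit_r, hit_l, hit_s = touched(probes)
    if (len(hit_r), len(hit_l), len(hit_s)) != (n_r, n_l, planted_coverage_atoms):
        raise RuntimeError(
            "pocket plant failed self-verification: "
            f"got ({len(hit_r)}, {len(hit_l)}, {len(hit_s)})"
        )

    far = 200.0 + 50.0 * rng.random()
    for d in range(n_decoy_pockets):
        for k in range(3):
            probes.append(ProbeRecord(
                center=(-far - 30.0 * d, 10.0 * k, 0.0),
                radius=probe_radius, polarity="apolar", pocket_id=2 + d,
            ))

    lines = ["# synthetic pocket probes (PQR dialect: ATOM serial name resname chain "
             "pocket_id x y z charge radius)"]
    for i, p in enumerate(probes, start=1):
        resname = "POL" if p.polarity == "polar" else "APL"
        x, y, z = p.center
        lines.append(
            f"ATOM {i:5d} PRB {resname} P {p.pocket_id:4d} "
            f"{x:10.3f} {y:10.3f} {z:10.3f} {0.0:8.3f} {p.radius:8.3f}"
        )

    pocket_ids = sorted({p.pocket_id for p in probes})
    scores = pd.DataFrame({
        "pocket_id": pocket_ids,
        "pocket_score": [0.9 if pid == 1 else 0.3 - 0.05 * pid for pid in pocket_ids],
        "drug_score": [0.85 if pid == 1 else 0.25 - 0.05 * pid for pid in pocket_ids],
    })

    n_s = len(by_side["S"])
    manifest = {
        "kind": "pocket_fixture",
        "seed": int(seed),
        "true_pocket": 1,
        "planted_side_counts": [int(n_r), int(n_l)],
        "planted_coverage_fraction": planted_coverage_atoms / n_s if n_s else 0.0,
        "n_stabilizer_atoms": int(n_s),
        "pocket_ids": [int(p) for p in pocket_ids],
    }
    return lines, scores, manifest


def make_energy_tables(
    plan: dict[str, dict[str, tuple[float, float]]],
    n_replicas: int = 5,
    n_frames: int = 75,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-frame energy tables drawn around planted means with planted spread.

    ``plan`` maps complex id -> {term: (mean, sd)} in kcal/mol; frame
    energies are Gaussian around per-complex means (the noise model is a
    fixture convention, not a physical claim).  The manifest records the
    realized per-replica sample means per term, so replica aggregation
    can be checked against realized rather than nominal values.
    The default replica structure mirrors end-point practice: five
    independent replicas, 75 analysis frames each.
    """
    rng = np.random.default_rng(seed)
    rows = []
    realized: dict[str, dict[str, list[float]]] = {}
    for cid, terms in plan.items():
        realized[cid] = {}
        for term, (mean, sd) in terms.items():
            if sd < 0:
                raise ValueError(f"{cid}/{term}: sd must be non-negative, got {sd!r}")
            per_replica = []
            for rep in range(1, n_replicas + 1):
                vals = mean + sd * rng.standard_normal(n_frames)
                per_replica.append(float(vals.mean()))
                for fr, v in enumerate(vals):
                    rows.append((cid, f"rep{rep}", fr, term, float(v)))
            realized[cid][term] = per_replica
    table = pd.DataFrame(rows, columns=["complex_id", "replica_id", "frame", "term", "value"])
    manifest = {
        "kind": "energy_tables",
        "seed": int(seed),
        "n_replicas": int(n_replicas),
        "n_frames": int(n_frames),
        "plan": {cid: {t: [float(m), float(s)] for t, (m, s) in terms.items()}
                 for cid, terms in plan.items()},
        "realized_replica_means": realized,
    }
    return table, manifest


def make_candidate_energies(
    n_candidates: int = 50,
    n_dual_binding: int = 34,
    seed: int = 0,
    n_replicas: int = 5,
    n_frames: int = 75,
    frame_sd: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Candidate energy tables planted to pass/fail the dual-binding window.

    Passers sit well inside the selector window (weaker side < −15
    kcal/mol and balance < 10 kcal/mol, with margins an order of
    magnitude above the frame noise); failers violate the weaker-side
    bound, the balance bound, or both, in rotation.  The realized
    selection is re-derived by brute-force predicate evaluation on the
    aggregated tables before returning; a plant that does not reproduce
    its own shortlist raises.
    """
    if n_dual_binding > n_candidates:
        raise ValueError("cannot plant more passers than candidates")
    rng = np.random.default_rng(seed)
    plan: dict[str, dict[str, tuple[float, float]]] = {}
    shortlist = []
    for i in range(n_candidates):
        cid = f"cand{i + 1:03d}"
        if i < n_dual_binding:
            rs = -25.0 - 3.0 * rng.random()
            ls = rs + (4.0 * rng.random() - 2.0)  # balance well below 10
            shortlist.append(cid)
        else:
            mode = (i - n_dual_binding) % 3
            if mode == 0:      # weaker side too weak
                rs, ls = -30.0, -8.0 + 2.0 * rng.random()
            elif mode == 1:    # unbalanced
                rs, ls = -40.0, -22.0 + 2.0 * rng.random()
            else:              # both violated
                rs, ls = -12.0, -3.0
        plan[cid] = {
            "ddg_rs": (rs, frame_sd),
            "ddg_ls": (ls, frame_sd),
            "ddg_rls": (rs + ls - 10.0, frame_sd),
        }
    table, manifest = make_energy_tables(plan, n_replicas, n_frames, seed=seed + 1)

    # brute-force verification of the realized shortlist
    aggregated = []
    for cid, group in table.groupby("complex_id", sort=False):
        wide = group.pivot_table(index=["replica_id", "frame"], columns="term",
                                 values="value").reset_index()
        wide.columns.name = None
        aggregated.append(aggregate(EnergyFrameTable(complex_id=str(cid), frames=wide)))
    realized_pass = [e.complex_id for e in aggregated
                     if e.weaker_side < -15.0 and e.balance_mean < 10.0]
    if sorted(realized_pass) != sorted(shortlist):
        raise RuntimeError("candidate-energy plant failed self-verification")

    manifest.update({
        "kind": "candidate_energies",
        "n_candidates": int(n_candidates),
        "planted_shortlist": shortlist,
        "n_dual_binding": int(n_dual_binding),
    })
    return table, manifest


def make_compound_roster(
    n: int = 1000,
    n_filter_pass: int = 372,
    n_below_cutoff: int | None = None,
    docking_cutoff: float = -6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Compound descriptor roster planted around the screening windows.

    ``n_filter_pass`` compounds sit strictly inside the property-filter
    windows (molecular weight 375–425 Da, LogP 2–4.5, complexity ≤ 700);
    the rest violate exactly one criterion in rotation, so the audit
    counts are fully determined.  Docking scores are planted so that
    exactly ``n_below_cutoff`` of the passing compounds score at or
    below the cutoff (default −6 kcal/mol).  Verified by brute force
    before returning.
    """
    if n_filter_pass > n:
        raise ValueError("cannot plant more passers than compounds")
    if n_below_cutoff is None:
        n_below_cutoff = int(round(0.75 * n_filter_pass))
    if n_below_cutoff > n_filter_pass:
        raise ValueError("cannot plant more cutoff passers than filter passers")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cid = f"ZS{i + 1:06d}"
        if i < n_filter_pass:
            mw = 380.0 + 40.0 * rng.random()
            logp = 2.2 + 2.0 * rng.random()
            cx = 150.0 + 500.0 * rng.random()
        else:
            mode = (i - n_filter_pass) % 3
            mw, logp, cx = 400.0, 3.0, 400.0
            if mode == 0:
                mw = 450.0 + 100.0 * rng.random()
            elif mode == 1:
                logp = 5.0 + rng.random()
            else:
                cx = 750.0 + 400.0 * rng.random()
        if i < n_below_cutoff:
            score = docking_cutoff - 0.5 - 5.0 * rng.random()
        else:
            score = docking_cutoff + 0.5 + 3.0 * rng.random()
        rows.append((cid, round(mw, 2), round(logp, 2), round(cx, 1), round(score, 2)))
    df = pd.DataFrame(rows, columns=["compound_id", "molecular_weight", "logp",
                                     "complexity", "docking_score"])

    in_window = ((df.molecular_weight >= 375) & (df.molecular_weight <= 425)
                 & (df.logp >= 2) & (df.logp <= 4.5) & (df.complexity <= 700))
    if int(in_window.sum()) != n_filter_pass:
        raise RuntimeError("compound-roster plant failed filter self-verification")
    kept = df[in_window]
    if int((kept.docking_score <= docking_cutoff).sum()) != n_below_cutoff:
        raise RuntimeError("compound-roster plant failed score self-verification")

    manifest = {
        "kind": "compound_roster",
        "seed": int(seed),
        "n": int(n),
        "n_filter_pass": int(n_filter_pass),
        "n_below_cutoff": int(n_below_cutoff),
        "docking_cutoff": float(docking_cutoff),
        "score_cut_fraction": n_below_cutoff / n_filter_pass,
    }
    return df, manifest
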