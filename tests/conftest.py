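"""Shared fixtures: synthetic complexes, probes and energy tables, plus an
independent brute-force mass-action oracle used to validate the exact solver."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dualbind import fixtures as fx
from dualbind import geometry as geo


# ------------------------------------------------------------------ oracle
def oracle_species(k_rs, k_ls, phi, r0, l0, s_free, n_iter=400):
    """Species at fixed free stabilizer by damped fixed-point iteration.

    Deliberately avoids the production solver's closed-form reduction:
    receptor and ligand conservation are iterated as
    R <- r0 / (1 + Sf/K_RS + phi*L*Sf/(K_RS*K_LS)) and the symmetric
    ligand update until self-consistent.  Works on scalars or arrays.
    """
    if np.isscalar(s_free) or getattr(s_free, "ndim", 0) == 0:
        sf = float(s_free)
        r, l = r0, l0
        w = phi * sf / (k_rs * k_ls)
        for _ in range(n_iter):
            r_new = r0 / (1.0 + sf / k_rs + w * l)
            l = 0.5 * l + 0.5 * (l0 / (1.0 + sf / k_ls + w * r_new))
            r = 0.5 * r + 0.5 * r_new
        return r, l, r * sf / k_rs, l * sf / k_ls, w * r * l
    s_free = np.asarray(s_free, dtype=float)
    r = np.full_like(s_free, r0, dtype=float)
    l = np.full_like(s_free, l0, dtype=float)
    w = phi * s_free / (k_rs * k_ls)
    for _ in range(n_iter):
        r_new = r0 / (1.0 + s_free / k_rs + w * l)
        l_new = l0 / (1.0 + s_free / k_ls + w * r_new)
        r = 0.5 * r + 0.5 * r_new
        l = 0.5 * l + 0.5 * l_new
    rls = w * r * l
    return r, l, r * s_free / k_rs, l * s_free / k_ls, rls


def _oracle_total_s(k_rs, k_ls, phi, r0, l0, sf):
    r, l, rs, ls, rls = oracle_species(k_rs, k_ls, phi, r0, l0, sf)
    return sf + rs + ls + rls


def oracle_solve(k_rs, k_ls, phi, r0, l0, s0, n_grid=3000):
    """Brute-force equilibrium: dense log-grid scan in s_free + bisection polish.

    Returns (r_free, l_free, s_free, rs, ls, rls).
    """
    if s0 == 0.0:
        return r0, l0, 0.0, 0.0, 0.0, 0.0

    grid = np.concatenate([[0.0], np.logspace(math.log10(s0) - 14, math.log10(s0), n_grid)])
    excess = _oracle_total_s(k_rs, k_ls, phi, r0, l0, grid) - s0
    idx = int(np.argmax(excess >= 0))
    lo, hi = float(grid[max(idx - 1, 0)]), float(grid[idx])
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        if _oracle_total_s(k_rs, k_ls, phi, r0, l0, mid) - s0 >= 0:
            hi = mid
        else:
            lo = mid
    sf = 0.5 * (lo + hi)
    r, l, rs, ls, rls = oracle_species(k_rs, k_ls, phi, r0, l0, sf)
    return float(r), float(l), sf, float(rs), float(ls), float(rls)


@pytest.fixture(scope="session")
def random_parameter_sets():
    """100 random (K_RS, K_LS, phi, r0, l0, s0) draws spanning the modelled ranges."""
    rng = np.random.default_rng(20230414)
    draws = []
    for _ in range(100):
        k_rs = 10.0 ** rng.uniform(-9, -1)
        k_ls = 10.0 ** rng.uniform(-9, -1)
        phi = float(rng.choice([0.1, 1.0, 10.0]))
        r0 = 10.0 ** rng.uniform(-8, -3)
        l0 = 10.0 ** rng.uniform(-8, -3)
        s0 = 10.0 ** rng.uniform(-8, -2)
        draws.append((k_rs, k_ls, phi, r0, l0, s0))
    return draws


# ------------------------------------------------------------------ fixtures
@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    """Toy complex PDB on disk plus its manifest and parsed atoms."""
    out = tmp_path_factory.mktemp("complex")
    pdb, manifest = fx.make_toy_complex(n_atoms_per_chain=12, gap=4.0, seed=7)
    path = out / "complex.pdb"
    path.write_text(pdb)
    atoms = geo.read_structure(path, manifest["side_map"])
    return {"path": path, "manifest": manifest, "atoms": atoms}


@pytest.fixture(scope="session")
def pocket_bundle(toy_complex, tmp_path_factory):
    """Probe file + scores sidecar planted on the toy complex."""
    out = tmp_path_factory.mktemp("pockets")
    lines, scores, manifest = fx.make_pocket_fixture(
        toy_complex["atoms"], planted_coverage_atoms=3,
        planted_side_counts=(5, 4), seed=11,
    )
    probe_path = out / "probes.pqr"
    probe_path.write_text("\n".join(lines) + "\n")
    scores_path = out / "scores.tsv"
    scores.to_csv(scores_path, sep="\t", index=False)
    return {"probe_path": probe_path, "scores_path": scores_path, "manifest": manifest}


@pytest.fixture(scope="session")
def candidate_energy_table(tmp_path_factory):
    """50-candidate long-format energy table with 34 planted dual binders."""
    out = tmp_path_factory.mktemp("energies")
    table, manifest = fx.make_candidate_energies(
        n_candidates=50, n_dual_binding=34, seed=5, n_frames=25
    )
    path = out / "energies.tsv"
    table.to_csv(path, sep="\t", index=False)
    return {"path": path, "table": table, "manifest": manifest}
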