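"""Replica-aware aggregation and dual-binding scoring of interaction-energy tables.

Consumes per-frame interaction free energies from MM/GBSA-style
end-point post-processing (typically 5 replicas x 75 frames per
complex) and turns them into the quantities the dual-binding theory
needs:

* ``ddg_rs`` / ``ddg_ls`` — compound interaction free energy with the
  receptor and ligand protein, kcal/mol;
* ``ddg_rls`` — total interaction with the protein pair (an independent
  end-point estimate, not the sum of the per-partner terms);
* ``ddg_rl`` — the direct receptor–ligand interaction (with or without
  the stabilizer bound);
* ``weaker_side`` = max(ddG_RS, ddG_LS), the side that limits
  dual-binding stabilization;
* ``balance`` = |ddG_RS − ddG_LS| per frame, how evenly the compound
  engages the two partners.

Replica convention: per-replica means first, then mean and sample
standard deviation across replica means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ENERGY_TERMS",
    "EnergyFrameTable",
    "StabilizerEnergetics",
    "MechanismCall",
    "ShieldingReport",
    "load_energy_frames",
    "load_residue_decomposition",
    "aggregate",
    "classify_mechanism",
    "dual_binding_selector",
    "rank_compounds",
    "rl_interaction_change",
    "shielding_overlap",
]

ENERGY_TERMS = ("ddg_rs", "ddg_ls", "ddg_rls", "ddg_rl")

#: kcal/mol; the weaker-side interaction needed to reach a micromolar
#: effective protein-pair K_D at 1 uM totals (see dualbind.equilibrium).
DUAL_BINDING_THRESHOLD = -5.0

RANK_CRITERIA = {
    "total": "ddg_rls_mean",
    "receptor": "ddg_rs_mean",
    "ligand": "ddg_ls_mean",
    "weaker_side": "weaker_side",
    "balance": "balance_mean",
}


@dataclass(frozen=True)
class EnergyFrameTable:
    """Validated per-frame energy table for one complex (wide layout).

    ``frames`` has columns ``replica_id``, ``frame`` plus at least one
    of the energy terms; frame indices are unique within a replica and
    all energies are finite.
    """

    complex_id: str
    frames: pd.DataFrame

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in ENERGY_TERMS if t in self.frames.columns)

    @property
    def replica_ids(self) -> tuple[str, ...]:
        return tuple(self.frames["replica_id"].unique())


@dataclass(frozen=True)
class StabilizerEnergetics:
    """Replica-aggregated energetics of one complex/candidate, kcal/mol."""

    complex_id: str
    n_replicas: int
    ddg_rs_mean: float = math.nan
    ddg_rs_sd: float = math.nan
    ddg_ls_mean: float = math.nan
    ddg_ls_sd: float = math.nan
    ddg_rls_mean: float = math.nan
    ddg_rls_sd: float = math.nan
    ddg_rl_mean: float = math.nan
    ddg_rl_sd: float = math.nan
    balance_mean: float = math.nan
    balance_sd: float = math.nan
    single_replica: bool = False
    annotations: dict = field(default_factory=dict)

    @property
    def weaker_side(self) -> float:
        """max(ddG_RS, ddG_LS): the side limiting dual-binding stabilization."""
        return max(self.ddg_rs_mean, self.ddg_ls_mean)

    @property
    def mean_gap(self) -> float:
        """|mean(ddG_RS) − mean(ddG_LS)|; always <= balance_mean."""
        return abs(self.ddg_rs_mean - self.ddg_ls_mean)


@dataclass(frozen=True)
class MechanismCall:
    """Mechanism classification of one stabilizer."""

    complex_id: str
    call: str  # "dual-binding" | "allosteric-candidate"
    weaker_side: float
    threshold_used: float


@dataclass(frozen=True)
class ShieldingReport:
    """Overlap between stabilizer-contact residues and RL contact classes."""

    n_favorable: int
    n_unfavorable: int
    favorable_overlap: float | None
    unfavorable_overlap: float | None
    favorable_residues: tuple
    unfavorable_residues: tuple
    favorable_shared: tuple
    unfavorable_shared: tuple


def _validate_frames(complex_id: str, df: pd.DataFrame, source: str) -> pd.DataFrame:
    present = [t for t in ENERGY_TERMS if t in df.columns]
    if not present:
        raise ValueError(
            f"{source}: no energy column found for complex {complex_id!r}; "
            f"expected at least one of {ENERGY_TERMS}"
        )
    for col in present:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals) & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{source}: non-finite or non-numeric energy in column {col!r} "
                f"for complex {complex_id!r}, rows {list(bad[:5])}"
            )
        df[col] = vals
    dup = df.duplicated(subset=["replica_id", "frame"])
    if dup.any():
        raise ValueError(
            f"{source}: duplicate frame index within a replica for "
            f"complex {complex_id!r}, rows {list(df.index[dup][:5])}"
        )
    return df


def load_energy_frames(path, layout: str = "long") -> dict[str, EnergyFrameTable]:
    """Read a delimited energy table and return one table per complex.

    Long layout columns: ``complex_id, replica_id, frame, term, value``
    with ``term`` drawn from ``ENERGY_TERMS``.  Wide layout columns:
    ``complex_id, replica_id, frame`` plus one column per energy term.
    Separator is inferred (TSV or CSV).  Schema violations name the
    offending column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"energy table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"{path}: energy table is empty")

    if layout == "long":
        required = ["complex_id", "replica_id", "frame", "term", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        unknown = set(df["term"]) - set(ENERGY_TERMS)
        if unknown:
            raise ValueError(f"{path}: unknown energy term(s) {sorted(unknown)}")
        wide = df.pivot_table(
            index=["complex_id", "replica_id", "frame"],
            columns="term", values="value", aggfunc="first",
        ).reset_index()
        wide.columns.name = None
    elif layout == "wide":
        required = ["complex_id", "replica_id", "frame"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        wide = df
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'long' or 'wide'")

    out: dict[str, EnergyFrameTable] = {}
    for cid, group in wide.groupby("complex_id", sort=False):
        g = group.drop(columns=["complex_id"]).reset_index(drop=True)
        g["replica_id"] = g["replica_id"].astype(str)
        out[str(cid)] = EnergyFrameTable(
            complex_id=str(cid), frames=_validate_frames(str(cid), g, str(path))
        )
    return out


def load_residue_decomposition(path) -> pd.DataFrame:
    """Read a residue-wise energy decomposition table.

    Columns: ``chain, resnum, resname, partner, energy`` with partner in
    {RL, RS, LS} and energy in kcal/mol.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = ["chain", "resnum", "resname", "partner", "energy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    dup = df.duplicated(subset=["chain", "resnum", "partner"])
    if dup.any():
        raise ValueError(f"{path}: duplicate residue id within a partner table")
    return df


def aggregate(table: EnergyFrameTable) -> StabilizerEnergetics:
    """Aggregate a per-frame table to replica-level means and spreads.

    Per-replica means are computed first; the reported mean is the mean
    of replica means and the reported sd the sample (ddof=1) standard
    deviation across replica means.  The balance term |ddG_RS − ddG_LS|
    is computed per frame, then aggregated identically.  With a single
    replica, sds are reported as 0 and ``single_replica`` is flagged.
    """
    df = table.frames.copy()
    if "ddg_rs" in df.columns and "ddg_ls" in df.columns:
        df["balance"] = (df["ddg_rs"] - df["ddg_ls"]).abs()
    terms = [t for t in (*ENERGY_TERMS, "balance") if t in df.columns]
    replica_means = df.groupby("replica_id")[terms].mean()
    n_rep = len(replica_means)
    single = n_rep == 1

    fields: dict[str, float] = {}
    for t in terms:
        m = replica_means[t].dropna()
        fields[f"{t}_mean"] = float(m.mean()) if len(m) else math.nan
        fields[f"{t}_sd"] = 0.0 if len(m) <= 1 else float(m.std(ddof=1))
    return StabilizerEnergetics(
        complex_id=table.complex_id, n_replicas=n_rep, single_replica=single,
        **fields,
    )


def classify_mechanism(
    e: StabilizerEnergetics | None = None,
    threshold: float = DUAL_BINDING_THRESHOLD,
    strict: bool = False,
    *,
    ddg_rs: float | None = None,
    ddg_ls: float | None = None,
    complex_id: str = "",
) -> MechanismCall:
    """Classify a stabilizer as dual-binding or allosteric-candidate.

    A compound is called dual-binding when its weaker-side interaction
    max(ddG_RS, ddG_LS) is at or below ``threshold`` (default −5
    kcal/mol, the minimum per-partner binding free energy that yields a
    micromolar effective protein-pair K_D at 1 uM totals).  Compounds
    above the threshold cannot stabilize through dual binding at these
    concentrations; they are flagged as allosteric candidates — they may
    still act by pre-organizing one partner's binding interface, which
    requires long stabilizer-free simulations to confirm.
    """
    if e is None:
        if ddg_rs is None or ddg_ls is None:
            raise ValueError("provide either aggregated energetics or both ddg_rs/ddg_ls")
        weaker = max(ddg_rs, ddg_ls)
        cid = complex_id
    else:
        weaker = e.weaker_side
        cid = e.complex_id
    if not math.isfinite(weaker):
        raise ValueError(f"weaker-side energy must be finite, got {weaker!r}")
    is_dual = weaker < threshold if strict else weaker <= threshold
    return MechanismCall(
        complex_id=cid,
        call="dual-binding" if is_dual else "allosteric-candidate",
        weaker_side=weaker,
        threshold_used=threshold,
    )


def dual_binding_selector(
    entries,
    max_weaker: float = -15.0,
    max_balance: float = 10.0,
    strict: bool = True,
) -> list[StabilizerEnergetics]:
    """Select candidates satisfying the dual-binding design window.

    Keeps entries whose weaker-side interaction max(ddG_RS, ddG_LS) is
    lower than ``max_weaker`` (default −15 kcal/mol) and whose balance
    |ddG_RS − ddG_LS| is smaller than ``max_balance`` (default 10
    kcal/mol); comparisons are strict by default, matching the
    "lower than"/"smaller than" reading of the window.  Input order is
    preserved.
    """
    def keep(e: StabilizerEnergetics) -> bool:
        if strict:
            return e.weaker_side < max_weaker and e.balance_mean < max_balance
        return e.weaker_side <= max_weaker and e.balance_mean <= max_balance

    return [e for e in entries if keep(e)]


def rank_compounds(entries, criterion: str = "total") -> pd.DataFrame:
    """Rank candidates by one of the dual-binding criteria.

    ``criterion`` is one of ``total`` (ddG_(RL)S), ``receptor``
    (ddG_RS), ``ligand`` (ddG_LS), ``weaker_side`` or ``balance``; more
    negative is better, so the sort is ascending.  Ties break
    deterministically by compound id.  The returned frame carries the
    scores of every criterion side by side for comparison tables, the
    requested criterion's rank (1 = best), and pass-through annotations.
    """
    if criterion not in RANK_CRITERIA:
        raise ValueError(
            f"unknown criterion {criterion!r}; choose from {sorted(RANK_CRITERIA)}"
        )
    entries = list(entries)
    if not entries:
        raise ValueError("no entries to rank")
    rows = []
    for e in entries:
        rows.append({
            "compound_id": e.complex_id,
            "total": e.ddg_rls_mean,
            "receptor": e.ddg_rs_mean,
            "ligand": e.ddg_ls_mean,
            "weaker_side": e.weaker_side,
            "balance": e.balance_mean,
            **{f"annot_{k}": v for k, v in e.annotations.items()},
        })
    df = pd.DataFrame(rows)
    col = criterion
    if df[col].isna().any():
        bad = df.loc[df[col].isna(), "compound_id"].tolist()
        raise ValueError(f"criterion {criterion!r} missing for compound(s) {bad}")
    df = df.sort_values([col, "compound_id"], kind="mergesort").reset_index(drop=True)
    df.insert(1, "rank", np.arange(1, len(df) + 1))
    df.insert(2, "criterion", criterion)
    return df


def rl_interaction_change(
    bound: EnergyFrameTable, free: EnergyFrameTable
) -> tuple[float, float]:
    """Change in direct receptor–ligand interaction on stabilizer binding.

    Returns ``(mean, sd)`` of ddG_RL(stabilizer-bound) −
    ddG_RL(stabilizer-free), with the sd propagated in quadrature from
    the across-replica sds of the two forms.  Negative values mean the
    stabilizer-bound interface interacts more favorably.
    """
    for name, t in (("bound", bound), ("free", free)):
        if "ddg_rl" not in t.frames.columns:
            raise ValueError(f"{name} table for {t.complex_id!r} lacks a ddg_rl column")
    a, b = aggregate(bound), aggregate(free)
    return a.ddg_rl_mean - b.ddg_rl_mean, math.hypot(a.ddg_rl_sd, b.ddg_rl_sd)


def shielding_overlap(rl_decomposition: pd.DataFrame, stabilizer_contacts) -> ShieldingReport:
    """Overlap of stabilizer-contact residues with un/favorable RL contacts.

    ``rl_decomposition`` is a residue decomposition table restricted (or
    restrictable) to the RL partner; residues with negative energies are
    favorable RL contacts, positive energies unfavorable.  The report
    gives |class ∩ stabilizer contacts| / |class| per class; an empty
    class yields ``None`` (undefined) rather than a division error.
    A high unfavorable overlap indicates the stabilizer shields
    unfavorable protein-protein contacts, an indirect stabilization
    route on top of dual binding.
    """
    df = rl_decomposition
    if "partner" in df.columns:
        df = df[df["partner"] == "RL"]
    if df.empty:
        raise ValueError("decomposition table has no RL partner rows")
    contacts = {tuple(c) if not isinstance(c, tuple) else c for c in stabilizer_contacts}
    ids = list(zip(df["chain"], df["resnum"]))
    energy = df["energy"].to_numpy()
    favorable = tuple(sorted({i for i, e in zip(ids, energy) if e < 0}))
    unfavorable = tuple(sorted({i for i, e in zip(ids, energy) if e > 0}))
    fav_shared = tuple(sorted(set(favorable) & contacts))
    unf_shared = tuple(sorted(set(unfavorable) & contacts))
    return ShieldingReport(
        n_favorable=len(favorable),
        n_unfavorable=len(unfavorable),
        favorable_overlap=len(fav_shared) / len(favorable) if favorable else None,
        unfavorable_overlap=len(unf_shared) / len(unfavorable) if unfavorable else None,
        favorable_residues=favorable,
        unfavorable_residues=unfavorable,
        favorable_shared=fav_shared,
        unfavorable_shared=unf_shared,
    )
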