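"""In-silico stabilizer-discovery pipeline.

Orchestrates the discovery funnel as a configurable sequence of pure
stages:

1. structure/pocket intake — parse the complex, classify and rank
   interface pockets;
2. compound property pre-filter — molecular weight 375–425 Da, LogP
   2–4.5, BertzCT-type complexity ≤ 700 (the window typical of known
   interface stabilizers);
3. optional random sub-sampling of the filtered roster;
4. docking — adapter-only: an external command template is shelled out
   per compound (a score table can stand in for it), scores recorded
   with provenance and resumable on interrupt;
5. docking-score cut (default: keep scores ≤ −6 kcal/mol);
6. dual-binding evaluation of the shortlist from per-candidate
   interaction-energy tables (weaker side < −15 kcal/mol, balance
   < 10 kcal/mol).

Every stage is a pure function of (inputs, config, seed); stage seeds
are derived deterministically from the top-level seed by stage-name
hash, and a rerun with identical config and seed reproduces every
artifact.
"""

from __future__ import annotations

import json
import shlex
import subprocess
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import (
    aggregate,
    dual_binding_selector,
    load_energy_frames,
    rank_compounds,
)
from .geometry import read_structure
from .pockets import interface_pocket_stats, rank_pockets, read_pockets

__all__ = [
    "CompoundRecord",
    "FilterAudit",
    "AdapterConfig",
    "PipelineConfig",
    "load_compounds",
    "property_filter",
    "sample_compounds",
    "docking_stage",
    "score_cut",
    "evaluate_candidates",
    "run_pipeline",
    "stage_seed",
]

DESCRIPTOR_COLUMNS = ("molecular_weight", "logp", "complexity")


@dataclass
class CompoundRecord:
    """One screening compound with its pre-filter descriptors."""

    compound_id: str
    molecular_weight: float | None = None
    logp: float | None = None
    complexity: float | None = None
    docking_score: float | None = None
    annotations: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FilterAudit:
    """Book-keeping of the property filter; counts sum to the input size."""

    n_input: int
    removed_by_weight: int
    removed_by_logp: int
    removed_by_complexity: int
    needs_descriptors: int
    n_kept: int

    def __post_init__(self) -> None:
        total = (self.removed_by_weight + self.removed_by_logp
                 + self.removed_by_complexity + self.needs_descriptors + self.n_kept)
        if total != self.n_input:
            raise ValueError("filter audit counts do not sum to the input size")


@dataclass(frozen=True)
class AdapterConfig:
    """External docking adapter: a command template plus score parsing.

    ``command_template`` is formatted with ``{compound_id}`` (and any
    annotation keys) and must print the docking score, either as a bare
    number or as a ``SCORE <value>`` line, on stdout.  When
    ``score_table`` is set instead, scores are read from that TSV
    (columns ``compound_id, docking_score``) and no process is spawned.
    """

    command_template: str | None = None
    score_table: str | None = None

    def __post_init__(self) -> None:
        if (self.command_template is None) == (self.score_table is None):
            raise ValueError("configure exactly one of command_template or score_table")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def load_compounds(path) -> list[CompoundRecord]:
    """Read a compound roster CSV/TSV into records; extra columns become annotations."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'compound_id'")
    known = {"compound_id", *DESCRIPTOR_COLUMNS, "docking_score"}
    out = []
    for row in df.to_dict("records"):
        def num(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        out.append(CompoundRecord(
            compound_id=str(row["compound_id"]),
            molecular_weight=num("molecular_weight"),
            logp=num("logp"),
            complexity=num("complexity"),
            docking_score=num("docking_score"),
            annotations={k: v for k, v in row.items() if k not in known},
        ))
    return out


def property_filter(
    compounds,
    mw_window: tuple[float, float] = (375.0, 425.0),
    logp_window: tuple[float, float] = (2.0, 4.5),
    max_complexity: float = 700.0,
) -> tuple[list[CompoundRecord], FilterAudit]:
    """Drug-likeness pre-filter for interface stabilizers.

    Keeps compounds with molecular weight inside ``mw_window`` (Da),
    LogP inside ``logp_window`` and complexity at most
    ``max_complexity`` (compounds above it are hard to parameterize for
    simulation).  Criteria are applied in the declared order weight →
    LogP → complexity, which affects only the audit attribution, not
    the kept set.  Compounds missing any descriptor are routed to a
    needs-descriptors bin rather than silently dropped.
    """
    kept: list[CompoundRecord] = []
    n_mw = n_logp = n_cx = n_missing = 0
    for c in compounds:
        if c.molecular_weight is None or c.logp is None or c.complexity is None:
            n_missing += 1
        elif not (mw_window[0] <= c.molecular_weight <= mw_window[1]):
            n_mw += 1
        elif not (logp_window[0] <= c.logp <= logp_window[1]):
            n_logp += 1
        elif c.complexity > max_complexity:
            n_cx += 1
        else:
            kept.append(c)
    audit = FilterAudit(
        n_input=len(list(compounds)) if not hasattr(compounds, "__len__") else len(compounds),
        removed_by_weight=n_mw,
        removed_by_logp=n_logp,
        removed_by_complexity=n_cx,
        needs_descriptors=n_missing,
        n_kept=len(kept),
    )
    return kept, audit


def sample_compounds(compounds, n: int, seed: int) -> list[CompoundRecord]:
    """Uniform sub-sample without replacement, reproducible under ``seed``."""
    compounds = list(compounds)
    if n > len(compounds):
        raise ValueError(f"cannot sample {n} from a roster of {len(compounds)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(compounds), size=n, replace=False)
    return [compounds[i] for i in sorted(idx)]


def docking_stage(
    compounds,
    adapter: AdapterConfig,
    ledger_path=None,
) -> tuple[list[CompoundRecord], list[dict]]:
    """Attach docking scores to compounds through the configured adapter.

    Every compound ends with either a score or an explicit failure
    record; adapter failures are isolated per compound.  When
    ``ledger_path`` is given, scored compounds are appended to a TSV
    provenance ledger and compounds already present are not re-scored,
    so an interrupted stage resumes where it stopped.
    """
    already: dict[str, float] = {}
    ledger_rows: list[str] = []
    if ledger_path is not None:
        ledger_path = Path(ledger_path)
        if ledger_path.exists():
            prior = pd.read_csv(ledger_path, sep="\t")
            already = dict(zip(prior.compound_id.astype(str), prior.docking_score))

    table_scores: dict[str, float] = {}
    if adapter.score_table is not None:
        df = pd.read_csv(adapter.score_table, sep=None, engine="python", comment="#")
        for col in ("compound_id", "docking_score"):
            if col not in df.columns:
                raise ValueError(f"{adapter.score_table}: missing column {col!r}")
        table_scores = dict(zip(df.compound_id.astype(str), df.docking_score.astype(float)))

    failures: list[dict] = []
    out: list[CompoundRecord] = []
    for c in compounds:
        if c.compound_id in already:
            c.docking_score = float(already[c.compound_id])
            out.append(c)
            continue
        if adapter.score_table is not None:
            if c.compound_id in table_scores:
                c.docking_score = table_scores[c.compound_id]
                out.append(c)
                ledger_rows.append(f"{c.compound_id}\t{c.docking_score}")
            else:
                failures.append({"compound_id": c.compound_id,
                                 "error": "no score in table"})
            continue
        cmd = adapter.command_template.format(compound_id=c.compound_id, **c.annotations)
        try:
            proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True,
                                  timeout=300)
        except (OSError, subprocess.TimeoutExpired) as exc:
            failures.append({"compound_id": c.compound_id, "error": str(exc)})
            continue
        if proc.returncode != 0:
            failures.append({"compound_id": c.compound_id,
                             "error": f"adapter exit {proc.returncode}",
                             "stderr": proc.stderr[-500:]})
            continue
        score = _parse_score(proc.stdout)
        if score is None:
            failures.append({"compound_id": c.compound_id,
                             "error": "unparsable adapter output",
                             "stdout": proc.stdout[-500:]})
            continue
        c.docking_score = score
        out.append(c)
        ledger_rows.append(f"{c.compound_id}\t{score}")

    if ledger_path is not None and ledger_rows:
        new = not ledger_path.exists()
        with open(ledger_path, "a") as fh:
            if new:
                fh.write("compound_id\tdocking_score\n")
            fh.write("\n".join(ledger_rows) + "\n")
    return out, failures


def _parse_score(stdout: str) -> float | None:
    for line in reversed(stdout.strip().splitlines()):
        parts = line.split()
        if not parts:
            continue
        token = parts[1] if parts[0].upper() == "SCORE" and len(parts) > 1 else parts[0]
        try:
            return float(token)
        except ValueError:
            continue
    return None


def score_cut(
    compounds, cutoff: float = -6.0
) -> tuple[list[CompoundRecord], float, int]:
    """Keep compounds docking at or better than (≤) the cutoff, kcal/mol.

    Returns (kept, fraction of scored compounds passing, number
    unscored); unscored compounds are excluded and counted separately.
    """
    scored = [c for c in compounds if c.docking_score is not None]
    n_unscored = len(list(compounds)) - len(scored)
    kept = [c for c in scored if c.docking_score <= cutoff]
    fraction = len(kept) / len(scored) if scored else 0.0
    return kept, fraction, n_unscored


def evaluate_candidates(
    compounds,
    energy_table_path,
    max_weaker: float = -15.0,
    max_balance: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Dual-binding evaluation of docked candidates from energy tables.

    Aggregates each candidate's per-frame interaction energies, emits a
    scatter-style table (weaker side vs balance, one row per candidate)
    and the shortlist passing the dual-binding window, ranked by the
    weaker-side interaction.
    """
    tables = load_energy_frames(energy_table_path, layout="long")
    ids = [c.compound_id for c in compounds] if compounds else list(tables)
    missing = [i for i in ids if i not in tables]
    if missing:
        raise ValueError(f"no energy table for candidate(s) {missing[:5]}")
    aggregated = [aggregate(tables[i]) for i in ids]
    selected = dual_binding_selector(aggregated, max_weaker, max_balance)
    sel_ids = {e.complex_id for e in selected}
    report = pd.DataFrame({
        "compound_id": [e.complex_id for e in aggregated],
        "ddg_rs": [e.ddg_rs_mean for e in aggregated],
        "ddg_ls": [e.ddg_ls_mean for e in aggregated],
        "weaker_side": [e.weaker_side for e in aggregated],
        "balance": [e.balance_mean for e in aggregated],
        "selected": [e.complex_id in sel_ids for e in aggregated],
    })
    shortlist = rank_compounds(selected, "weaker_side")["compound_id"].tolist() if selected else []
    return report, shortlist


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    run_dir: str
    seed: int = 0
    # intake
    structure_path: str | None = None
    side_map: dict = field(default_factory=lambda: {"R": "R", "L": "L", "S": "S"})
    probe_path: str | None = None
    pocket_scores_path: str | None = None
    min_atoms_per_side: int = 5
    # compounds
    compound_roster_path: str | None = None
    mw_window: tuple[float, float] = (375.0, 425.0)
    logp_window: tuple[float, float] = (2.0, 4.5)
    max_complexity: float = 700.0
    sample_n: int | None = None
    # docking
    docking_command: str | None = None
    docking_score_table: str | None = None
    docking_cutoff: float = -6.0
    # dual-binding evaluation
    energy_table_path: str | None = None
    max_weaker: float = -15.0
    max_balance: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for key in ("structure_path", "probe_path", "pocket_scores_path",
                    "compound_roster_path", "docking_score_table", "energy_table_path"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} does not exist: {p}")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured discovery stages in order and write a run directory.

    Outputs: per-stage TSV artifacts, a plain-text log, and
    ``manifest.json`` recording inputs, parameters, package version and
    stage summaries.  A rerun with identical config and seed reproduces
    the artifacts byte-for-byte (no timestamps are embedded).
    """
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # stage 1: structure / pocket intake
    if config.structure_path and config.probe_path:
        atoms = read_structure(config.structure_path, config.side_map)
        r_atoms = [a for a in atoms if a.side_tag == "R"]
        l_atoms = [a for a in atoms if a.side_tag == "L"]
        pockets = read_pockets(config.probe_path, config.pocket_scores_path)
        stats, totals = interface_pocket_stats(
            pockets, r_atoms, l_atoms,
            min_atoms=(config.min_atoms_per_side, 10, 20),
        )
        stats.to_csv(run_dir / "pocket_stats.tsv", sep="\t", index=False)
        if config.pocket_scores_path:
            ranking, _ = rank_pockets(pockets, by="drug_score")
            ranking.to_csv(run_dir / "pocket_ranking.tsv", sep="\t", index=False)
        summary["stages"]["pockets"] = {
            "n_pockets": len(pockets),
            "interface_pass_counts": {str(k): v for k, v in totals.items()},
        }
        log.append(f"pockets: {len(pockets)} pockets, pass counts {totals}")

    compounds: list[CompoundRecord] = []
    if config.compound_roster_path:
        compounds = load_compounds(config.compound_roster_path)
        kept, audit = property_filter(
            compounds, config.mw_window, config.logp_window, config.max_complexity
        )
        summary["stages"]["property_filter"] = asdict(audit)
        log.append(f"property_filter: kept {audit.n_kept}/{audit.n_input}")
        compounds = kept

        if config.sample_n is not None:
            compounds = sample_compounds(
                compounds, config.sample_n, stage_seed(config.seed, "sample")
            )
            summary["stages"]["sample"] = {"n": len(compounds)}
            log.append(f"sample: {len(compounds)} compounds")

        if config.docking_command or config.docking_score_table:
            adapter = AdapterConfig(
                command_template=config.docking_command,
                score_table=config.docking_score_table,
            )
            compounds, failures = docking_stage(
                compounds, adapter, ledger_path=run_dir / "docking_ledger.tsv"
            )
            summary["stages"]["docking"] = {
                "n_scored": len(compounds), "n_failed": len(failures),
            }
            if failures:
                (run_dir / "docking_failures.json").write_text(json.dumps(failures, indent=1))
            log.append(f"docking: scored {len(compounds)}, failed {len(failures)}")

            kept, fraction, n_unscored = score_cut(compounds, config.docking_cutoff)
            summary["stages"]["score_cut"] = {
                "cutoff": config.docking_cutoff,
                "n_kept": len(kept),
                "fraction_passing": fraction,
                "n_unscored": n_unscored,
            }
            log.append(f"score_cut: kept {len(kept)} (fraction {fraction:.4f})")
            compounds = kept

        pd.DataFrame(
            [{"compound_id": c.compound_id, "molecular_weight": c.molecular_weight,
              "logp": c.logp, "complexity": c.complexity,
              "docking_score": c.docking_score} for c in compounds]
        ).to_csv(run_dir / "compounds_after_funnel.tsv", sep="\t", index=False)

    if config.energy_table_path:
        report, shortlist = evaluate_candidates(
            compounds if compounds else [],
            config.energy_table_path,
            config.max_weaker,
            config.max_balance,
        )
        report.to_csv(run_dir / "dual_binding_report.tsv", sep="\t", index=False)
        (run_dir / "shortlist.txt").write_text("\n".join(shortlist) + "\n")
        summary["stages"]["evaluate"] = {
            "n_candidates": int(len(report)),
            "n_selected": int(report["selected"].sum()),
            "shortlist": shortlist,
        }
        log.append(f"evaluate: {int(report['selected'].sum())}/{len(report)} selected")

    (run_dir / "pipeline.log").write_text("\n".join(log) + "\n")
    (run_dir / "manifest.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
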