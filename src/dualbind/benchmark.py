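"""Curated benchmark of 18 known PPI-stabilizer complexes.

Literature MM/GBSA interaction free energies (means +/- standard
deviation across five independent simulation replicas, kcal/mol) for 18
stabilizers bound at 15 protein-protein interfaces, together with the
buried-surface-area ratio BSA_LS/BSA_RS of each crystal structure.
Sets: "A" — stabilizer-induced PPIs with two stabilizers of measured,
differing potency per protein pair; "B" — other stabilizer-induced
PPIs; "C" — stabilizer-enhanced PPIs (the protein pair also associates
without the compound).

These values are inputs to the classification machinery (they are not
recomputed here); ``potent`` marks the experimentally more potent
compound within each set-A pair.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["known_stabilizers"]

_ROWS = [
    # label, pdb_id, set, potent, bsa_ratio,
    #   ddg_rs, sd, ddg_ls, sd, balance, sd, ddg_rls, sd
    ("A1-a", "3m50", "A", True, 0.98, -6.27, 1.61, -8.43, 3.97, 4.54, 3.36, -17.16, 3.52),
    ("A1-b", "3m51", "A", False, 0.24, -17.45, 1.70, 0.11, 0.57, 17.56, 2.22, -24.46, 2.50),
    ("A2-a", "5j89", "A", True, 0.81, -23.68, 2.06, -23.79, 0.66, 1.78, 1.07, -54.89, 2.59),
    ("A2-b", "5j8o", "A", False, 0.79, -35.16, 0.97, -21.08, 0.52, 14.08, 0.79, -62.58, 1.53),
    ("A3-a", "5ad3", "A", True, 1.18, -29.64, 0.87, -27.95, 2.01, 2.30, 1.20, -61.94, 2.93),
    ("A3-b", "5ad2", "A", False, 1.08, -25.93, 2.02, -28.70, 2.65, 3.77, 2.97, -58.47, 3.24),
    ("B1", "6ygj", "B", None, 0.63, -43.03, 11.45, -12.93, 3.94, 30.11, 15.11, -87.96, 4.40),
    ("B2", "2o98", "B", None, 0.30, -50.51, 0.78, -4.35, 0.34, 46.16, 0.72, -64.26, 2.36),
    ("B3", "5fqd", "B", None, 0.42, -35.90, 1.43, -7.33, 0.24, 28.57, 1.47, -48.65, 1.53),
    ("B4", "4mdk", "B", None, 0.00, -37.84, 3.22, -2.66, 1.67, 35.18, 3.51, -45.46, 3.68),
    ("B5", "1kkq", "B", None, 0.00, -62.43, 3.84, -2.17, 0.75, 60.26, 4.31, -66.32, 3.73),
    ("B6", "3u15", "B", None, 1.04, -41.06, 0.54, -41.25, 0.60, 0.78, 0.59, -93.54, 0.72),
    ("B7", "3vbg", "B", None, 1.11, -40.61, 1.99, -41.84, 0.95, 2.19, 1.79, -93.43, 2.25),
    ("C1", "3tct", "C", None, 1.08, -29.84, 1.67, -26.53, 3.12, 3.31, 2.70, -61.82, 2.93),
    ("C2", "3ko0", "C", None, 1.34, -47.25, 3.22, -47.39, 6.29, 8.81, 3.35, -104.13, 3.42),
    ("C3", "3bbr", "C", None, 1.02, -21.14, 1.79, -20.29, 1.41, 1.77, 1.57, -53.64, 2.43),
    ("C4", "6mg5", "C", None, 0.96, -17.93, 0.86, -18.61, 0.61, 1.25, 0.26, -44.36, 1.06),
    ("C5", "4j9z", "C", None, 1.17, -8.79, 1.12, -30.69, 1.20, 21.90, 2.16, -42.76, 0.65),
]


def known_stabilizers() -> pd.DataFrame:
    """Return the 18-complex benchmark as a DataFrame indexed by label.

    Columns: ``pdb_id``, ``set``, ``potent``, ``bsa_ratio``,
    ``ddg_rs_mean``/``ddg_rs_sd``, ``ddg_ls_mean``/``ddg_ls_sd``,
    ``balance_mean``/``balance_sd`` (per-frame |ddG_RS - ddG_LS|,
    replica-aggregated), ``ddg_rls_mean``/``ddg_rls_sd`` (total
    protein-pair/stabilizer interaction, an independent column, not the
    sum of the per-partner terms).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "label", "pdb_id", "set", "potent", "bsa_ratio",
            "ddg_rs_mean", "ddg_rs_sd", "ddg_ls_mean", "ddg_ls_sd",
            "balance_mean", "balance_sd", "ddg_rls_mean", "ddg_rls_sd",
        ],
    )
    return df.set_index("label")
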