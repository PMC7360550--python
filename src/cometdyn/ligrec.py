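"""Ligand-receptor interaction scores from cell-type expression profiles.

For every ordered (sender, receiver) cell-type pair the score is
mean(ligand | sender) * mean(receptor | receiver), normalized to the
maximum observed product so the strongest pair scores exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def interaction_scores(
    expression: pd.DataFrame,
    cell_types: pd.Series | np.ndarray,
    ligand: str,
    receptor: str,
) -> pd.DataFrame:
    """Score every ordered cell-type pair for one ligand-receptor axis.

    ``expression`` is cells x genes (raw or library-normalized counts);
    ``cell_types`` labels each row.  Returns one row per (sender,
    receiver) pair with the raw product and the max-normalized score in
    [0, 1].  If the ligand or receptor is silent everywhere all scores are
    0 and ``df.attrs["all_zero"]`` is set (no division happens).
    """
    for gene in (ligand, receptor):
        if gene not in expression.columns:
            raise KeyError(f"gene '{gene}' not in expression matrix")
    labels = pd.Series(np.asarray(cell_types), index=expression.index,
                       name="cell_type")
    if labels.isna().any():
        raise ValueError("every cell needs a cell-type label")

    lig_mean = expression.groupby(labels)[ligand].mean()
    rec_mean = expression.groupby(labels)[receptor].mean()
    rows = []
    for sender in lig_mean.index:
        for receiver in rec_mean.index:
            rows.append(
                {
                    "sender": sender,
                    "receiver": receiver,
                    "ligand": ligand,
                    "receptor": receptor,
                    "sender_ligand_mean": float(lig_mean[sender]),
                    "receiver_receptor_mean": float(rec_mean[receiver]),
                    "raw_product": float(lig_mean[sender] * rec_mean[receiver]),
                }
            )
    out = pd.DataFrame(rows)
    max_raw = out["raw_product"].max()
    all_zero = max_raw == 0
    out["score"] = 0.0 if all_zero else out["raw_product"] / max_raw
    out.attrs["all_zero"] = bool(all_zero)
    return out
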