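"""Virtual-screening rank lists for drug repositioning.

A trained affinity model scores every candidate molecule of a SMILES
library against one target protein; candidates are ranked by predicted pKd
descending (higher pKd = lower Kd = stronger predicted binding). Post-hoc
filters then flag, without dropping scores, (a) molecules below a
molecular-weight threshold (default 200 Da -- sub-drug-sized fragments
score unreliably) and (b) an explicit exclusion list that encodes manual
curation such as removing topical drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .featurization import encode_protein, featurize_drugs

__all__ = [
    "RankedCandidates",
    "rank_candidates",
    "molecular_weight",
    "apply_filters",
]

COLUMNS = [
    "rank",
    "drug_id",
    "smiles",
    "predicted_pkd",
    "molecular_weight",
    "excluded",
    "exclusion_reason",
]


@dataclass
class RankedCandidates:
    """Ordered screening output; ``table`` columns follow :data:`COLUMNS`."""

    table: pd.DataFrame
    target_id: str = ""

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ranked table missing columns: {sorted(missing)}")

    def retained(self) -> pd.DataFrame:
        """Rows that survived all filters, consecutively ranked."""
        return self.table[~self.table["excluded"]].reset_index(drop=True)

    def top(self, n: int) -> pd.DataFrame:
        return self.retained().head(n)

    def __len__(self) -> int:
        return len(self.table)


def molecular_weight(smiles: str) -> float:
    """Average molecular weight (Da) of the molecule, hydrogens implicit."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))


def rank_candidates(
    model,
    candidates: Sequence[tuple[str, str]],
    target_seq: str,
    target_id: str = "",
    batch: int = 256,
) -> RankedCandidates:
    """Score ``(id, smiles)`` candidates against one protein and rank them.

    Unparseable SMILES are skipped with a warning. Ties in predicted pKd
    keep input order (stable sort), so the ranking is deterministic.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    max_len = getattr(getattr(model, "config", None), "prot_max_len", 1000)
    enc = encode_protein(target_seq, max_len=max_len).matrix[None]

    kept_ids, kept_smiles, kept_mw = [], [], []
    from rdkit import Chem

    for cid, smi in candidates:
        if Chem.MolFromSmiles(smi) is None:
            warnings.warn(f"skipping unparseable SMILES for {cid!r}: {smi!r}")
            continue
        kept_ids.append(cid)
        kept_smiles.append(smi)
        kept_mw.append(molecular_weight(smi))
    if not kept_ids:
        raise ValueError("no candidate SMILES could be parsed")

    fps = featurize_drugs(kept_smiles)
    scores = np.empty(len(kept_ids), dtype=float)
    for s in range(0, len(kept_ids), batch):
        sl = slice(s, s + batch)
        block = fps[sl]
        scores[sl] = model.predict(
            block, np.repeat(enc, len(block), axis=0)
        )

    order = np.argsort(-scores, kind="stable")
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "drug_id": [kept_ids[i] for i in order],
            "smiles": [kept_smiles[i] for i in order],
            "predicted_pkd": scores[order],
            "molecular_weight": [kept_mw[i] for i in order],
            "excluded": False,
            "exclusion_reason": "none",
        }
    )
    return RankedCandidates(table=table, target_id=target_id)


def apply_filters(
    ranked: RankedCandidates,
    mw_threshold: float = 200.0,
    exclusion_ids: Iterable[str] = (),
) -> RankedCandidates:
    """Flag sub-threshold molecular weights and listed ids, then re-rank.

    Scores are never altered; excluded rows stay in the table with their
    reason, and surviving rows get consecutive ranks 1..k in score order.
    """
    excl = set(exclusion_ids)
    table = ranked.table.copy()
    mw_flag = table["molecular_weight"] < mw_threshold
    list_flag = table["drug_id"].isin(excl)
    table["excluded"] = mw_flag | list_flag
    table["exclusion_reason"] = np.select(
        [mw_flag, list_flag], ["mw_below_threshold", "exclusion_list"], "none"
    )
    table = table.sort_values(
        "predicted_pkd", ascending=False, kind="stable"
    ).reset_index(drop=True)
    ranks = np.full(len(table), pd.NA, dtype=object)
    ranks[np.flatnonzero(~table["excluded"].to_numpy())] = np.arange(
        1, int((~table["excluded"]).sum()) + 1
    )
    table["rank"] = ranks
    return RankedCandidates(table=table, target_id=ranked.target_id)
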