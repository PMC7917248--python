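"""Extended-dataset I/O: the four-file drug-target affinity layout.

An extended dataset bundles a dense drugs x proteins dissociation-constant
(Kd, nanomolar) matrix with the drug SMILES table, the protein FASTA file,
and a same-shaped matrix of *negative-sample* SMILES: for each cell (i, j)
the SMILES of some drug that binds protein j weakly (Kd above the
positive/negative boundary, 50 nM by default). Affinities are regressed in
log space, pKd = -log10(Kd * 1e-9 + 1e-10), so Kd = 0 maps to pKd = 10 and
Kd = 10000 nM to pKd ~ 5.

File dialect: tab-separated values. The SMILES table has columns
``drug_id<TAB>smiles`` with a header row; matrices carry drug ids as the row
index and protein ids as the column header; proteins are a standard
multi-record FASTA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AffinityMatrix",
    "ExtendedDataset",
    "AffinityRecord",
    "DEFAULT_BOUNDARY_NM",
    "DAVIS_KD_RANGE_NM",
    "kd_to_pkd",
    "pkd_to_kd",
    "label_pair",
    "build_negative_matrix",
    "read_extended_dataset",
    "write_extended_dataset",
    "split_records",
]

#: Kd boundary (nM) between positive (<= boundary) and negative samples.
DEFAULT_BOUNDARY_NM = 50.0

#: Davis-style Kd values live in this range (nM); out-of-range warns only.
DAVIS_KD_RANGE_NM = (0.0, 10000.0)


def kd_to_pkd(kd):
    """Log-space affinity pKd = -log10(Kd * 1e-9 + 1e-10), Kd in nanomolar.

    Evaluated as the algebraically identical ``10 - log10(10*Kd + 1)`` so
    that Kd = 0 yields exactly 10.0. Strictly decreasing in Kd; accepts
    scalars or arrays.
    """
    arr = np.asarray(kd, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("Kd must be finite")
    if np.any(arr < 0):
        raise ValueError("Kd must be non-negative (nanomolar)")
    out = 10.0 - np.log10(10.0 * arr + 1.0)
    return float(out) if np.isscalar(kd) or arr.ndim == 0 else out


def pkd_to_kd(pkd):
    """Inverse of :func:`kd_to_pkd`: Kd(nM) = (10**(-pKd) - 1e-10) / 1e-9."""
    arr = np.asarray(pkd, dtype=float)
    out = (np.power(10.0, -arr) - 1e-10) / 1e-9
    return float(out) if np.isscalar(pkd) or arr.ndim == 0 else out


def label_pair(kd: float, boundary: float = DEFAULT_BOUNDARY_NM) -> bool:
    """True (positive sample) iff ``kd <= boundary``, both in nanomolar."""
    if kd < 0:
        raise ValueError("Kd must be non-negative")
    return kd <= boundary


@dataclass
class AffinityMatrix:
    """Dense drugs x proteins Kd matrix with aligned identifier lists."""

    drug_ids: list[str]
    drug_smiles: list[str]
    protein_ids: list[str]
    protein_seqs: list[str]
    kd: np.ndarray  # (n_drugs, n_proteins), nanomolar

    def __post_init__(self) -> None:
        self.kd = np.asarray(self.kd, dtype=float)
        self.validate()

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_drugs, self.n_proteins)

    def validate(self) -> None:
        if len(self.drug_smiles) != self.n_drugs:
            raise ValueError(
                f"{len(self.drug_smiles)} SMILES for {self.n_drugs} drug ids"
            )
        if len(self.protein_seqs) != self.n_proteins:
            raise ValueError(
                f"{len(self.protein_seqs)} sequences for "
                f"{self.n_proteins} protein ids"
            )
        if self.kd.ndim != 2 or self.kd.shape != self.shape:
            raise ValueError(
                f"Kd matrix shape {self.kd.shape} does not match "
                f"({self.n_drugs} drugs, {self.n_proteins} proteins)"
            )
        if not np.all(np.isfinite(self.kd)):
            raise ValueError("Kd matrix must be dense and finite")
        if np.any(self.kd < 0):
            raise ValueError("Kd values must be non-negative")
        lo, hi = DAVIS_KD_RANGE_NM
        if np.any(self.kd > hi):
            warnings.warn(
                f"Kd values above {hi} nM found; Davis-style data lies in "
                f"[{lo}, {hi}]",
                stacklevel=2,
            )


@dataclass
class AffinityRecord:
    """One drug-protein measurement with its sampled negative drug."""

    drug_index: int
    protein_index: int
    kd: float
    pkd: float
    label: bool  # True = positive (Kd <= boundary)
    negative_smiles: str


@dataclass
class ExtendedDataset:
    """AffinityMatrix plus negative-sample SMILES matrix and labels."""

    base: AffinityMatrix
    negative_smiles: np.ndarray  # (n_drugs, n_proteins), dtype=object
    boundary: float = DEFAULT_BOUNDARY_NM
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.negative_smiles = np.asarray(self.negative_smiles, dtype=object)
        if self.negative_smiles.shape != self.base.shape:
            raise ValueError(
                f"negative-sample matrix shape {self.negative_smiles.shape} "
                f"does not match affinity matrix {self.base.shape}"
            )
        self.labels = self.base.kd <= self.boundary
        _validate_smiles(
            sorted(set(self.negative_smiles.ravel().tolist())),
            what="negative-sample matrix",
        )

    @property
    def n_records(self) -> int:
        return self.base.kd.size

    def records(self) -> list[AffinityRecord]:
        """Flatten the matrices into one record per (drug, protein) cell."""
        pkd = kd_to_pkd(self.base.kd)
        out = []
        for i in range(self.base.n_drugs):
            for j in range(self.base.n_proteins):
                out.append(
                    AffinityRecord(
                        drug_index=i,
                        protein_index=j,
                        kd=float(self.base.kd[i, j]),
                        pkd=float(pkd[i, j]),
                        label=bool(self.labels[i, j]),
                        negative_smiles=str(self.negative_smiles[i, j]),
                    )
                )
        return out

    def __iter__(self) -> Iterator[AffinityRecord]:
        return iter(self.records())


def _validate_smiles(smiles: Sequence[str], what: str) -> None:
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        for k, s in enumerate(smiles):
            if not s or Chem.MolFromSmiles(str(s)) is None:
                raise ValueError(f"unparseable SMILES in {what}, entry {k}: {s!r}")
    finally:
        RDLogger.EnableLog("rdApp.error")


def build_negative_matrix(
    base: AffinityMatrix,
    boundary: float = DEFAULT_BOUNDARY_NM,
    seed: int = 0,
) -> np.ndarray:
    """Sample a negative-drug SMILES for every (drug, protein) cell.

    For cell (i, j) the negative is drawn uniformly (seeded) from the drugs
    whose Kd against protein j exceeds ``boundary``. A protein column with
    no such drug falls back, with a warning, to sampling from the pooled
    negatives of all other proteins; if no negative exists anywhere the
    dataset cannot be extended and an error is raised.
    """
    rng = np.random.default_rng(seed)
    is_neg = base.kd > boundary  # (drugs, proteins)
    if not is_neg.any():
        raise ValueError(
            f"no drug exceeds the boundary {boundary} nM for any protein; "
            "cannot build a negative-sample matrix"
        )
    smiles = np.asarray(base.drug_smiles, dtype=object)
    # pooled fallback: (drug, protein) pairs that are negative anywhere
    pool_drugs = np.flatnonzero(is_neg.any(axis=1))
    out = np.empty(base.shape, dtype=object)
    fallback_cols = []
    for j in range(base.n_proteins):
        admissible = np.flatnonzero(is_neg[:, j])
        if admissible.size == 0:
            fallback_cols.append(base.protein_ids[j])
            admissible = pool_drugs
        picks = rng.choice(admissible, size=base.n_drugs, replace=True)
        out[:, j] = smiles[picks]
    if fallback_cols:
        warnings.warn(
            f"{len(fallback_cols)} protein column(s) had no negative drug; "
            f"sampled negatives from other proteins instead: "
            f"{fallback_cols[:5]}{'...' if len(fallback_cols) > 5 else ''}",
            stacklevel=2,
        )
    return out


def _read_smiles_table(path: Path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: expected two tab-separated columns (id, smiles)"
        )
    ids = df.iloc[:, 0].tolist()
    smiles = df.iloc[:, 1].tolist()
    for row, s in enumerate(smiles):
        if not isinstance(s, str) or not s:
            raise ValueError(f"{path}: missing SMILES at row {row} ({ids[row]})")
    _validate_smiles(smiles, what=str(path))
    return ids, smiles


def read_extended_dataset(
    smiles_path: str | Path,
    fasta_path: str | Path,
    affinity_path: str | Path,
    negatives_path: str | Path | None = None,
    boundary: float = DEFAULT_BOUNDARY_NM,
    seed: int = 0,
) -> ExtendedDataset:
    """Load (or complete) the four-file extended-dataset layout.

    When ``negatives_path`` is omitted the negative-sample matrix is built
    with :func:`build_negative_matrix` using ``seed``.
    """
    drug_ids, drug_smiles = _read_smiles_table(Path(smiles_path))
    fasta = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not fasta:
        raise ValueError(f"{fasta_path}: no FASTA records")
    protein_ids = [r.id for r in fasta]
    protein_seqs = [str(r.seq).upper() for r in fasta]

    kd_df = pd.read_csv(affinity_path, sep="\t", index_col=0)
    if list(kd_df.index.astype(str)) != [str(d) for d in drug_ids]:
        raise ValueError(
            f"{affinity_path}: row labels do not match the drug-id list"
        )
    if list(kd_df.columns.astype(str)) != [str(p) for p in protein_ids]:
        raise ValueError(
            f"{affinity_path}: column header does not match the FASTA ids"
        )
    base = AffinityMatrix(
        drug_ids=[str(d) for d in drug_ids],
        drug_smiles=drug_smiles,
        protein_ids=[str(p) for p in protein_ids],
        protein_seqs=protein_seqs,
        kd=kd_df.to_numpy(dtype=float),
    )

    if negatives_path is None:
        negatives = build_negative_matrix(base, boundary=boundary, seed=seed)
    else:
        neg_df = pd.read_csv(negatives_path, sep="\t", index_col=0, dtype=str)
        negatives = neg_df.to_numpy(dtype=object)
        if negatives.shape != base.shape:
            raise ValueError(
                f"{negatives_path}: negative matrix shape {negatives.shape} "
                f"does not match affinity matrix {base.shape}"
            )
    return ExtendedDataset(base=base, negative_smiles=negatives, boundary=boundary)


def write_extended_dataset(
    dataset: ExtendedDataset,
    outdir: str | Path,
    seed: int | None = None,
    warnings_log: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the four-file layout plus a JSON sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = dataset.base
    paths = {
        "smiles": outdir / "drugs.tsv",
        "fasta": outdir / "proteins.fasta",
        "affinity": outdir / "affinity.tsv",
        "negatives": outdir / "negatives.tsv",
        "sidecar": outdir / "dataset.json",
    }
    pd.DataFrame({"drug_id": base.drug_ids, "smiles": base.drug_smiles}).to_csv(
        paths["smiles"], sep="\t", index=False
    )
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in zip(base.protein_ids, base.protein_seqs)
    ]
    SeqIO.write(records, str(paths["fasta"]), "fasta")
    pd.DataFrame(
        base.kd, index=base.drug_ids, columns=base.protein_ids
    ).to_csv(paths["affinity"], sep="\t", float_format="%.6g")
    pd.DataFrame(
        dataset.negative_smiles, index=base.drug_ids, columns=base.protein_ids
    ).to_csv(paths["negatives"], sep="\t")
    paths["sidecar"].write_text(
        json.dumps(
            {
                "boundary_nM": dataset.boundary,
                "seed": seed,
                "n_drugs": base.n_drugs,
                "n_proteins": base.n_proteins,
                "warnings": list(warnings_log),
            },
            indent=2,
        )
    )
    return paths


def split_records(
    records: Sequence[AffinityRecord],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list[AffinityRecord], list[AffinityRecord], list[AffinityRecord]]:
    """Seeded shuffle, then 7:1:2-style split into (train, val, test).

    Validation and test sizes are ``floor(n * ratio)``; the remainder goes
    to the training split. Deterministic for a fixed seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [records[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
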