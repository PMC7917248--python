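"""Drug and protein featurization.

Drugs: extended-connectivity (Morgan/circular) fingerprints of radius 2
folded to 1024 bits, computed with RDKit after canonicalization so that
different spellings of the same molecule yield identical bits.

Proteins: amino-acid sequences one-hot encoded against a frozen 26-symbol
vocabulary -- a "?" start-of-sequence symbol prepended to every sequence,
plus 25 residue letters (the 20 standard amino acids and the extended codes
B, J, U, X, Z). Sequences are embedded in a fixed 1000 x 26 binary matrix:
row 0 is always "?", rows beyond the sequence are all-zero padding, and
sequences longer than 999 residues are truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROTEIN_VOCAB",
    "PROTEIN_MAX_LEN",
    "FP_BITS",
    "FP_RADIUS",
    "DrugFingerprint",
    "ProteinEncoding",
    "ecfp_fingerprint",
    "encode_protein",
    "featurize_drugs",
    "featurize_proteins",
]

#: Frozen 26-symbol protein vocabulary: "?" then A-Z without O (pyrrolysine
#: is not used in kinase panels; O is the one letter absent from the set).
PROTEIN_VOCAB = "?" + "".join(c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if c != "O")
_VOCAB_INDEX = {c: i for i, c in enumerate(PROTEIN_VOCAB)}

PROTEIN_MAX_LEN = 1000
FP_BITS = 1024
FP_RADIUS = 2


@dataclass(frozen=True)
class DrugFingerprint:
    """Folded circular fingerprint of one molecule."""

    bits: np.ndarray  # uint8 vector, length n_bits, entries in {0, 1}
    radius: int
    source_smiles: str  # canonical SMILES of the parsed molecule

    def __len__(self) -> int:
        return self.bits.shape[0]


@dataclass(frozen=True)
class ProteinEncoding:
    """Fixed-size one-hot matrix for one protein sequence.

    ``true_length`` counts the rows actually used, including the prepended
    "?" symbol in row 0; every later row is all-zero padding.
    """

    matrix: np.ndarray  # uint8, (max_len, 26)
    true_length: int


def ecfp_fingerprint(
    smiles: str, radius: int = FP_RADIUS, n_bits: int = FP_BITS
) -> DrugFingerprint:
    """Radius-``radius`` circular fingerprint hashed to ``n_bits`` bits."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return DrugFingerprint(
        bits=bits, radius=radius, source_smiles=Chem.MolToSmiles(mol)
    )


def encode_protein(
    sequence: str, max_len: int = PROTEIN_MAX_LEN
) -> ProteinEncoding:
    """One-hot encode ``"?" + sequence`` into a ``max_len x 26`` matrix.

    Sequences longer than ``max_len - 1`` residues keep the "?" prefix and
    the first ``max_len - 1`` residues; shorter ones are zero-padded.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = "?" + sequence.upper()[: max_len - 1]
    matrix = np.zeros((max_len, len(PROTEIN_VOCAB)), dtype=np.uint8)
    for pos, ch in enumerate(seq):
        idx = _VOCAB_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"character {ch!r} at position {pos} is outside the "
                f"protein vocabulary {PROTEIN_VOCAB!r}"
            )
        matrix[pos, idx] = 1
    return ProteinEncoding(matrix=matrix, true_length=len(seq))


def featurize_drugs(
    smiles_list, radius: int = FP_RADIUS, n_bits: int = FP_BITS
) -> np.ndarray:
    """Stack fingerprints for a list of SMILES into an (n, n_bits) array."""
    return np.stack(
        [ecfp_fingerprint(s, radius, n_bits).bits for s in smiles_list]
    )


def featurize_proteins(sequences, max_len: int = PROTEIN_MAX_LEN) -> np.ndarray:
    """Stack encodings for a list of sequences into (n, max_len, 26)."""
    return np.stack([encode_protein(s, max_len).matrix for s in sequences])
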