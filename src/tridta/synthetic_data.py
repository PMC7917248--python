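"""Synthetic extended-dataset generator with planted, recoverable structure.

Emulates a Davis-style panel: a dense drugs x proteins Kd matrix in
[~1, 10000] nM, valid SMILES for the drugs, and random amino-acid
sequences for the proteins. Affinities follow a planted bilinear model in
a low-dimensional latent space,

    pKd*(d, p) = 5 + signal_scale * <u_d, v_p>,   u_d, v_p ~ N(0, I_k),

clipped to (0, 10], with Gaussian observation noise (sd = ``noise_sd`` pKd
units) added before converting back to Kd. Because each drug and protein
has a distinct featurization, a model that learns the interaction can
recover the planted ordering on held-out pairs -- which is what the
learning-sanity tests measure.

Drugs are assembled by seeded concatenation of chemically closed SMILES
fragments, so every emitted string parses; distinctness is enforced on
canonical SMILES. Protein sequences draw uniformly from the 20 standard
residues with lengths in [200, 1200].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import (
    AffinityMatrix,
    ExtendedDataset,
    build_negative_matrix,
    pkd_to_kd,
)

__all__ = ["SyntheticSpec", "generate_library", "generate_affinities", "generate_dataset"]

# Fragments chosen so that any concatenation is a valid SMILES chain:
# no unclosed rings or branches, ring-closure digits are reused only after
# closing. Terminal fragments may end in a triple bond or acid group.
_CHAIN_FRAGMENTS = [
    "C", "CC", "CO", "CN", "CS", "C(C)", "C(F)", "C(Cl)", "C(Br)",
    "C(C)(C)", "C(=O)", "C(=O)N", "CCO", "CCN", "c1ccccc1", "c1ccncc1",
    "c1ccsc1", "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "c1ccc(F)cc1",
    "c1ccc(Cl)cc1", "C(=O)NC", "COC", "CNC",
]
_TERMINAL_FRAGMENTS = ["C", "O", "N", "Cl", "F", "C#N", "C(=O)O", "CO", "C(N)=O"]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_LENGTH_RANGE = (200, 1200)


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of one synthetic dataset."""

    n_drugs: int
    n_proteins: int
    latent_dim: int = 4
    signal_scale: float = 1.0
    noise_sd: float = 0.2  # pKd units
    kd_clip: tuple[float, float] = (1.0, 10000.0)  # nanomolar
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("need at least one drug and one protein")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.kd_clip[0] < self.kd_clip[1]:
            raise ValueError("kd_clip must satisfy low < high")


def generate_library(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """Seeded (SMILES list, protein sequence list) for the spec's shape."""
    if spec.n_drugs > 20000:
        raise ValueError(
            f"{spec.n_drugs} distinct molecules exceeds the fragment-assembly "
            "space; the generator supports at most 20000 drugs"
        )
    rng = np.random.default_rng(spec.seed)
    smiles: list[str] = []
    seen: set[str] = set()

    from rdkit import Chem

    stall_limit = 5000  # consecutive duplicates/failures before giving up
    stalled = 0
    while len(smiles) < spec.n_drugs:
        if stalled > stall_limit:
            raise ValueError(
                f"could not assemble {spec.n_drugs} distinct molecules from "
                f"the fragment vocabulary ({len(smiles)} found)"
            )
        n_frag = int(rng.integers(2, 6))
        parts = [str(rng.choice(_CHAIN_FRAGMENTS)) for _ in range(n_frag)]
        if rng.random() < 0.5:
            parts.append(str(rng.choice(_TERMINAL_FRAGMENTS)))
        cand = "".join(parts)
        mol = Chem.MolFromSmiles(cand)
        if mol is None:  # defensive: the fragment grammar should preclude this
            stalled += 1
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            stalled += 1
            continue
        seen.add(canon)
        smiles.append(cand)
        stalled = 0

    lengths = rng.integers(_LENGTH_RANGE[0], _LENGTH_RANGE[1] + 1, spec.n_proteins)
    residues = np.array(list(_RESIDUES))
    proteins = [
        "".join(rng.choice(residues, size=int(L))) for L in lengths
    ]
    return smiles, proteins


def generate_affinities(
    library: tuple[list[str], list[str]],
    spec: SyntheticSpec,
    return_truth: bool = False,
):
    """Planted-bilinear Kd matrix for a library from :func:`generate_library`.

    With ``return_truth=True`` also returns a dict holding the noiseless
    planted pKd matrix and the latent factors, for recovery tests.
    """
    smiles, proteins = library
    if len(smiles) != spec.n_drugs or len(proteins) != spec.n_proteins:
        raise ValueError("library shape does not match the spec")
    # affinity stream is independent of the library stream
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    u = rng.standard_normal((spec.n_drugs, spec.latent_dim))
    v = rng.standard_normal((spec.n_proteins, spec.latent_dim))
    pkd_true = np.clip(5.0 + spec.signal_scale * (u @ v.T), 1e-6, 10.0)
    pkd_obs = pkd_true + rng.normal(0.0, spec.noise_sd, pkd_true.shape)
    kd = np.clip(pkd_to_kd(pkd_obs), spec.kd_clip[0], spec.kd_clip[1])
    base = AffinityMatrix(
        drug_ids=[f"D{i:04d}" for i in range(spec.n_drugs)],
        drug_smiles=list(smiles),
        protein_ids=[f"P{j:04d}" for j in range(spec.n_proteins)],
        protein_seqs=list(proteins),
        kd=kd,
    )
    if return_truth:
        return base, {"pkd_true": pkd_true, "drug_latents": u, "protein_latents": v}
    return base


def generate_dataset(
    spec: SyntheticSpec,
    boundary: float = 50.0,
    return_truth: bool = False,
):
    """One-call synthetic ExtendedDataset (library + affinities + negatives).

    Reports the positive-label fraction in the truth dict so the caller
    can see how ``signal_scale`` shifted the class balance.
    """
    library = generate_library(spec)
    base, truth = generate_affinities(library, spec, return_truth=True)
    negatives = build_negative_matrix(base, boundary=boundary, seed=spec.seed)
    dataset = ExtendedDataset(base=base, negative_smiles=negatives, boundary=boundary)
    truth["positive_fraction"] = float(dataset.labels.mean())
    if return_truth:
        return dataset, truth
    return dataset
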