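"""Condition embeddings: chemical fingerprints, gene/DNA providers, splits.

Drugs are represented by Morgan (circular substructure) fingerprints; the
1024-bit hashed variant is the non-trainable embedding fed to the condition
encoder. Pairwise compound similarity is reported as the Tanimoto
coefficient |A∩B| / |A∪B|. Hashing folds distinct substructures onto the
same bit and perturbs similarity values slightly, so similarity reporting
defaults to the unhashed count-based fingerprint (radius 2), which is
bit-collision free.

Genetic modalities concatenate a target-gene co-expression embedding with a
DNA-sequence embedding of the CRISPR guide or ORF 5'-flank. Both providers
are pluggable interfaces; the built-in stand-ins (a seeded random gene
lookup and a random-projected k-mer spectrum) keep the pipeline testable
offline and are synthetic, not trained models.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .utils import stream_rng

RDLogger.DisableLog("rdApp.*")

# structures of compound pairs discussed in the drug-screen analyses
REFERENCE_SMILES = {
    "paclitaxel": (
        "CC1=C2C(C(=O)C3(C(CC4C(C3C(C(C2(C)C)(CC1OC(=O)C(C(C5=CC=CC=C5)NC(=O)"
        "C6=CC=CC=C6)O)O)OC(=O)C7=CC=CC=C7)(CO4)OC(=O)C)O)C)OC(=O)C"
    ),
    "docetaxel": (
        "CC1=C2C(C(=O)C3(C(CC4C(C3C(C(C2(C)C)(CC1OC(=O)C(C(C5=CC=CC=C5)NC(=O)"
        "OC(C)(C)C)O)O)OC(=O)C6=CC=CC=C6)(CO4)OC(=O)C)O)C)O"
    ),
    "methotrexate": (
        "CN(CC1=CN=C2C(=N1)C(=NC(=N2)N)N)C3=CC=C(C=C3)C(=O)NC(CCC(=O)O)C(=O)O"
    ),
    "chlorambucil": "C1=CC(=CC=C1CCCC(=O)O)N(CCCl)CCCl",
    "simvastatin": "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12",
    "mevinolin": "CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12",
    "calpeptin": "CCCCC(C=O)NC(=O)C(CC(C)C)NC(=O)OCC1=CC=CC=C1",
    "mg132": "CC(C)CC(C=O)NC(=O)C(CC(C)C)NC(=O)C(CC(C)C)NC(=O)OCC1=CC=CC=C1",
}


@dataclass(frozen=True)
class FingerprintBits:
    bits: np.ndarray      # uint8 0/1 vector, length n_bits
    smiles: str

    def __len__(self):
        return len(self.bits)

    def popcount(self):
        return int(self.bits.sum())


def _mol(smiles):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse to a molecule: {smiles!r}")
    return mol


def morgan_fingerprint(smiles, n_bits=1024, radius=2):
    """Hashed Morgan/ECFP bit vector (deterministic in smiles, radius, n_bits)."""
    mol = _mol(smiles)
    fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return FingerprintBits(bits=arr, smiles=smiles)


def morgan_counts(smiles, radius=2):
    """Unhashed count-based Morgan fingerprint as {substructure id: count}."""
    mol = _mol(smiles)
    return dict(AllChem.GetMorganFingerprint(mol, radius).GetNonzeroElements())


def tanimoto(a, b):
    """Tanimoto coefficient |A∩B| / |A∪B| for equal-length bit vectors.

    Both all-zero is defined as 1.0 (identical empty substructure sets).
    """
    av = a.bits if isinstance(a, FingerprintBits) else np.asarray(a)
    bv = b.bits if isinstance(b, FingerprintBits) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"fingerprint lengths differ: {av.shape} vs {bv.shape}")
    av = av.astype(bool)
    bv = bv.astype(bool)
    union = np.logical_or(av, bv).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(av, bv).sum() / union)


def tanimoto_counts(ca, cb):
    """Count-vector Tanimoto: sum(min) / sum(max) over substructure ids."""
    ids = set(ca) | set(cb)
    if not ids:
        return 1.0
    num = sum(min(ca.get(i, 0), cb.get(i, 0)) for i in ids)
    den = sum(max(ca.get(i, 0), cb.get(i, 0)) for i in ids)
    return float(num / den)


def compound_similarity(smiles_a, smiles_b, radius=2):
    """Tanimoto similarity between two compounds (count fingerprints)."""
    return tanimoto_counts(morgan_counts(smiles_a, radius), morgan_counts(smiles_b, radius))


# ---------------------------------------------------------------------------
# pluggable providers for gene / DNA embeddings
# ---------------------------------------------------------------------------

class GeneEmbeddingProvider:
    """Interface: map a gene symbol to a fixed-dimension vector."""

    dimension: int

    def embed(self, gene: str) -> np.ndarray:
        raise NotImplementedError


class DnaEmbeddingProvider:
    """Interface: map a nucleotide sequence to a fixed-dimension vector."""

    dimension: int

    def embed(self, sequence: str) -> np.ndarray:
        raise NotImplementedError


class RandomGeneEmbedding(GeneEmbeddingProvider):
    """Synthetic stand-in: a seeded random vector per gene symbol.

    Deterministic in (seed, gene); carries no biology. Production use should
    plug in a published co-expression embedding table instead.
    """

    def __init__(self, dimension=200, seed=0):
        self.dimension = dimension
        self.seed = seed

    def embed(self, gene):
        rng = stream_rng(self.seed, "gene", gene.upper())
        return rng.standard_normal(self.dimension) / np.sqrt(self.dimension)


class KmerDnaEmbedding(DnaEmbeddingProvider):
    """Synthetic stand-in: random projection of the k-mer spectrum.

    Sequences with similar k-mer content map to nearby vectors, which is all
    the model requires of a DNA featurizer; it is not a trained language
    model.
    """

    def __init__(self, dimension=32, k=4, seed=0):
        self.dimension = dimension
        self.k = k
        rng = stream_rng(seed, "kmer_projection", f"k{k}", f"d{dimension}")
        self._proj = rng.standard_normal((4**k, dimension)) / np.sqrt(4**k)
        self._index = {b: i for i, b in enumerate("ACGT")}

    def embed(self, sequence):
        seq = sequence.upper()
        counts = Counter(
            seq[i : i + self.k]
            for i in range(len(seq) - self.k + 1)
            if set(seq[i : i + self.k]) <= set("ACGT")
        )
        spectrum = np.zeros(4**self.k)
        for kmer, n in counts.items():
            idx = 0
            for base in kmer:
                idx = idx * 4 + self._index[base]
            spectrum[idx] = n
        total = spectrum.sum()
        if total > 0:
            spectrum /= total
        return spectrum @ self._proj


# ---------------------------------------------------------------------------
# multi-modal condition embeddings
# ---------------------------------------------------------------------------

@dataclass
class ModalEmbeddingSpec:
    """Ordered component list defining one modality's embedding layout."""

    modality: str
    components: list  # [(name, provider_callable, dimension), ...]

    @property
    def total_dimension(self):
        return sum(d for _, _, d in self.components)


def build_condition_embedding(spec: ModalEmbeddingSpec, inputs: dict):
    """Concatenate component embeddings in spec order.

    drug = [Morgan fingerprint; gene vector]; crispr = [gene vector; guide
    sequence embedding]; orf = [gene vector; 5'-flank embedding] -- the
    layout is whatever the component list of ``spec`` says; this function
    only enforces order, presence and dimensions.
    """
    if not spec.components:
        raise ValueError("embedding spec has no components")
    parts = []
    for name, provider, dim in spec.components:
        if name not in inputs:
            raise KeyError(f"missing input for component {name!r}")
        vec = np.asarray(provider(inputs[name]), dtype=np.float64).ravel()
        if vec.size != dim:
            raise ValueError(
                f"component {name!r} produced length {vec.size}, declared {dim}"
            )
        parts.append(vec)
    return np.concatenate(parts)


def drug_embedding_spec(gene_provider=None, n_bits=1024, radius=2):
    """Drug layout: hashed fingerprint, optionally + target-gene embedding."""
    components = [
        ("smiles", lambda s: morgan_fingerprint(s, n_bits, radius).bits.astype(float), n_bits)
    ]
    if gene_provider is not None:
        components.append(("target_gene", gene_provider.embed, gene_provider.dimension))
    return ModalEmbeddingSpec(modality="drug", components=components)


def crispr_embedding_spec(gene_provider, dna_provider):
    return ModalEmbeddingSpec(
        modality="crispr",
        components=[
            ("target_gene", gene_provider.embed, gene_provider.dimension),
            ("guide_sequence", dna_provider.embed, dna_provider.dimension),
        ],
    )


def orf_embedding_spec(gene_provider, dna_provider):
    return ModalEmbeddingSpec(
        modality="orf",
        components=[
            ("target_gene", gene_provider.embed, gene_provider.dimension),
            ("flank_sequence", dna_provider.embed, dna_provider.dimension),
        ],
    )


# ---------------------------------------------------------------------------
# scaffold-based compound splitting
# ---------------------------------------------------------------------------

def scaffold_split(smiles_list, test_fraction, rng=None):
    """Bemis-Murcko scaffold split: whole scaffold groups stay on one side.

    The test side is filled greedily from the smallest scaffold groups until
    it holds at least ``test_fraction`` of the molecules; ties in group size
    are broken by a seeded shuffle when ``rng`` is given, else by group
    order of appearance.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = {}
    for i, smi in enumerate(smiles_list):
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=_mol(smi))
        groups.setdefault(scaffold, []).append(i)
    order = list(groups.values())
    if rng is not None:
        rng.shuffle(order)
    order.sort(key=len)
    target = test_fraction * len(smiles_list)
    test_ids, count = [], 0
    for group in order:
        if count >= target:
            break
        test_ids.extend(group)
        count += len(group)
    test = sorted(test_ids)
    train = sorted(set(range(len(smiles_list))) - set(test))
    return train, test
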