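"""Ligand graph featurization and substructure embeddings.

Ligand atoms get a one-hot-style feature vector (element / degree /
attached hydrogens / implicit valence blocks plus an aromatic flag),
following the GraphDTA convention of heavy-atom nodes with bonds as
edges.  Pocket residue features come from a 30-dimensional substructure
embedding: every molecule is read as a "sentence" of Morgan circular
substructure identifiers (radius 0 then radius 1 per atom, in atom
order), a skip-gram model with negative sampling is trained on a corpus
of such sentences, and each of the 20 standard amino acids is embedded
as the sum of its sentence-token vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import AllChem

from .chemio import LigandMolecule, parse_ligand


# ---------------------------------------------------------------------------
# atom features


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Concatenated one-hot blocks; out-of-vocabulary values land in the
    last ("other") position of their block, never raise."""

    elements: tuple[str, ...] = (
        "C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "B", "other",
    )
    max_degree: int = 10
    max_num_h: int = 10
    max_implicit_valence: int = 10

    @property
    def n_features(self) -> int:
        return (
            len(self.elements)
            + (self.max_degree + 1)
            + (self.max_num_h + 1)
            + (self.max_implicit_valence + 1)
            + 1
        )

    def block_slices(self) -> dict[str, slice]:
        e = len(self.elements)
        d = self.max_degree + 1
        h = self.max_num_h + 1
        v = self.max_implicit_valence + 1
        return {
            "element": slice(0, e),
            "degree": slice(e, e + d),
            "num_h": slice(e + d, e + d + h),
            "implicit_valence": slice(e + d + h, e + d + h + v),
            "aromatic": slice(e + d + h + v, e + d + h + v + 1),
        }


DEFAULT_SCHEMA = AtomFeatureSchema()


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0  # overflow -> last position
    return v


def atom_features(atom: dict, schema: AtomFeatureSchema = DEFAULT_SCHEMA) -> np.ndarray:
    elem = np.zeros(len(schema.elements))
    try:
        elem[schema.elements.index(atom["element"])] = 1.0
    except ValueError:
        elem[-1] = 1.0  # "other" bucket
    return np.concatenate(
        [
            elem,
            _one_hot(atom["degree"], schema.max_degree + 1),
            _one_hot(atom["num_h"], schema.max_num_h + 1),
            _one_hot(atom["implicit_valence"], schema.max_implicit_valence + 1),
            [1.0 if atom["aromatic"] else 0.0],
        ]
    )


@dataclass
class LigandGraph:
    """Atom-level graph: N x F feature matrix and a symmetric directed edge
    list (each bond present in both directions, no self-loops)."""

    node_features: np.ndarray
    edges: list[tuple[int, int]]
    n_atoms: int
    degenerate: bool = False  # single-atom molecule, no edges

    def edge_array(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)


def ligand_to_graph(
    mol: LigandMolecule, schema: AtomFeatureSchema = DEFAULT_SCHEMA
) -> LigandGraph:
    if mol.n_atoms < 1:
        raise ValueError("molecule has no atoms")
    x = np.array([atom_features(a, schema) for a in mol.atoms])
    edges: list[tuple[int, int]] = []
    for i, j, _order, _arom in mol.bonds:
        edges.append((i, j))
        edges.append((j, i))
    return LigandGraph(
        node_features=x, edges=edges, n_atoms=mol.n_atoms,
        degenerate=mol.n_atoms == 1,
    )


# ---------------------------------------------------------------------------
# substructure sentences


def molecule_sentence(mol: LigandMolecule) -> list[int]:
    """Morgan substructure identifiers at radius 0 then radius 1 for each
    atom, in atom order (length = 2 x heavy-atom count).

    An isolated atom has no radius-1 environment; its radius-0 identifier
    is repeated so sentence length stays 2 per atom.
    """
    m = mol.rdkit_mol
    info: dict[int, tuple] = {}
    AllChem.GetMorganFingerprint(m, 1, bitInfo=info)
    per_atom: dict[tuple[int, int], int] = {}
    for ident, hits in info.items():
        for atom_idx, radius in hits:
            per_atom[(atom_idx, radius)] = ident
    sentence: list[int] = []
    for idx in range(m.GetNumAtoms()):
        r0 = per_atom[(idx, 0)]
        sentence.append(r0)
        sentence.append(per_atom.get((idx, 1), r0))
    return sentence


# ---------------------------------------------------------------------------
# skip-gram embedding (word2vec SGNS, single-threaded, seeded)


@dataclass
class EmbeddingModel:
    """Token -> vector map trained by skip-gram with negative sampling.

    Out-of-vocabulary tokens map to the zero vector.
    """

    vectors: dict[int, np.ndarray]
    dim: int
    seed: int
    corpus_fingerprint: int = 0

    def __getitem__(self, token: int) -> np.ndarray:
        vec = self.vectors.get(token)
        if vec is None:
            return np.zeros(self.dim)
        return vec

    def embed_sentence(self, sentence: list[int], combine: str = "sum") -> np.ndarray:
        vecs = np.array([self[t] for t in sentence])
        return vecs.mean(axis=0) if combine == "mean" else vecs.sum(axis=0)


def train_embedding(
    corpus: list[list[int]],
    dim: int = 30,
    seed: int = 0,
    window: int = 10,
    min_count: int = 1,
    epochs: int = 100,
    negative: int = 5,
    lr: float = 0.025,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling vectors on token sentences.

    Deterministic for fixed (corpus, seed): single worker, one fixed RNG
    stream drives initialization, window subsampling and negative draws.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    counts: dict[int, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))
    # unigram^(3/4) negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())
    sents = [np.array([index[t] for t in s if t in index]) for s in corpus]
    sents = [s for s in sents if len(s) > 1]
    for epoch in range(epochs):
        alpha = lr * max(1.0 - epoch / epochs, 1e-2)
        for s in sents:
            reduced = rng.integers(1, window + 1, size=len(s))
            for pos, center in enumerate(s):
                w = reduced[pos]
                lo, hi = max(0, pos - w), min(len(s), pos + w + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    ctx = s[ctx_pos]
                    targets = np.empty(negative + 1, dtype=np.int64)
                    targets[0] = ctx
                    targets[1:] = np.searchsorted(noise_cdf, rng.random(negative))
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    v = W_in[center]
                    u = W_out[targets]
                    scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -30.0, 30.0)))
                    g = (labels - scores) * alpha
                    W_in[center] = v + g @ u
                    W_out[targets] += np.outer(g, v)
    fp = 0
    for sent in corpus:
        fp = (fp * 1000003 + hash(tuple(sent))) & 0x7FFFFFFF
    return EmbeddingModel(
        vectors={t: W_in[i].copy() for t, i in index.items()},
        dim=dim,
        seed=seed,
        corpus_fingerprint=fp,
    )


# ---------------------------------------------------------------------------
# amino-acid embedding table

AMINO_ACID_SMILES: dict[str, str] = {
    "ALA": "CC(N)C(=O)O",
    "ARG": "NC(CCCNC(=N)N)C(=O)O",
    "ASN": "NC(=O)CC(N)C(=O)O",
    "ASP": "NC(CC(=O)O)C(=O)O",
    "CYS": "NC(CS)C(=O)O",
    "GLN": "NC(=O)CCC(N)C(=O)O",
    "GLU": "NC(CCC(=O)O)C(=O)O",
    "GLY": "NCC(=O)O",
    "HIS": "NC(Cc1c[nH]cn1)C(=O)O",
    "ILE": "CCC(C)C(N)C(=O)O",
    "LEU": "CC(C)CC(N)C(=O)O",
    "LYS": "NCCCCC(N)C(=O)O",
    "MET": "CSCCC(N)C(=O)O",
    "PHE": "NC(Cc1ccccc1)C(=O)O",
    "PRO": "OC(=O)C1CCCN1",
    "SER": "NC(CO)C(=O)O",
    "THR": "CC(O)C(N)C(=O)O",
    "TRP": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "TYR": "NC(Cc1ccc(O)cc1)C(=O)O",
    "VAL": "CC(C)C(N)C(=O)O",
}


@dataclass
class AminoAcidEmbeddingTable:
    """Residue 3-letter code -> 30-vector; the pocket node feature source."""

    table: dict[str, np.ndarray]
    dim: int
    corpus_fingerprint: int
    seed: int

    def __getitem__(self, res_name: str) -> np.ndarray:
        try:
            return self.table[res_name.upper()]
        except KeyError:
            raise KeyError(f"residue {res_name!r} not in embedding table") from None

    def __contains__(self, res_name: str) -> bool:
        return res_name.upper() in self.table


def amino_acid_sentences() -> dict[str, list[int]]:
    return {
        code: molecule_sentence(parse_ligand(smi))
        for code, smi in AMINO_ACID_SMILES.items()
    }


def embed_amino_acids(
    model: EmbeddingModel, combine: str = "sum", standardize: bool = True
) -> AminoAcidEmbeddingTable:
    """Embed the 20 standard amino acids as the sum (default; mean by flag)
    of their sentence-token vectors.

    With ``standardize`` (default) each embedding column is z-scored
    across the 20 residues, so pocket node features enter the network on
    a unit scale regardless of corpus size (summed substructure vectors
    otherwise grow with sentence length); constant columns become 0.
    """
    table = {
        code: model.embed_sentence(sent, combine=combine)
        for code, sent in amino_acid_sentences().items()
    }
    if standardize:
        codes = sorted(table)
        mat = np.array([table[c] for c in codes])
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
        table = {c: mat[i] for i, c in enumerate(codes)}
    return AminoAcidEmbeddingTable(
        table=table,
        dim=model.dim,
        corpus_fingerprint=model.corpus_fingerprint,
        seed=model.seed,
    )


def default_embedding_table(
    ligand_smiles: list[str], dim: int = 30, seed: int = 0, epochs: int = 20,
) -> AminoAcidEmbeddingTable:
    """Convenience: train on the dataset's own ligands plus the 20 amino
    acids (the default corpus when none is supplied) and embed residues."""
    corpus = [molecule_sentence(parse_ligand(s)) for s in ligand_smiles]
    corpus += list(amino_acid_sentences().values())
    model = train_embedding(corpus, dim=dim, seed=seed, epochs=epochs)
    return embed_amino_acids(model)


def embedding_table_to_tsv(table: AminoAcidEmbeddingTable) -> str:
    lines = []
    for code in sorted(table.table):
        vec = "\t".join(f"{v:.8g}" for v in table.table[code])
        lines.append(f"{code}\t{vec}")
    return "\n".join(lines) + "\n"
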