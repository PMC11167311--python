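"""Deterministic synthetic study generator with a planted binding signal.

Emulates the pipeline's real inputs at desk scale: toy receptor
structures in PDB format with a placed hetero ligand, an enumerable
SMILES library, and an affinity table whose values carry a recoverable
pocket-composition x ligand-feature interaction.

The planted model: for protein p and ligand l,

    pKa(p, l) = base + beta * z_hyd(p) * z_aro(l) + Normal(0, sigma)

where z_hyd is the z-scored hydrophobic-residue fraction of the pocket
and z_aro the z-scored aromatic-atom fraction of the ligand, and
value_nM = 10^(9 - pKa).  Both factors are visible to the downstream
model through its stated features (residue embeddings; aromatic atom
flags), so learnability tests exercise the wiring, not hidden
chemistry.  With beta = 0 labels are independent of every feature.

Every latent quantity is recorded in manifests so that downstream
results can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chemio, curate, featurize, pocket as pocket_mod

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "PRO"}
)
BASE_PKA = 6.5

_RESIDUE_NAMES = sorted(featurize.AMINO_ACID_SMILES)


@dataclass(frozen=True)
class SynthConfig:
    n_proteins: int = 20
    residues_per_pocket: int = 12
    n_ligands: int = 100
    beta: float = 2.0
    sigma: float = 1.0
    pos_max_nM: float = 4.0
    neg_min_nM: float = 4000.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proteins, self.residues_per_pocket, self.n_ligands) < 1:
            raise ValueError("counts must be positive")
        if self.sigma < 0 or self.beta < 0:
            raise ValueError("sigma and beta must be >= 0")


# ---------------------------------------------------------------------------
# toy structures


def make_toy_structure(n_residues: int, seed: int) -> tuple[str, dict]:
    """A helical toy receptor plus one placed multi-atom hetero ligand.

    Backbone N/CA/C/O plus a CB sidechain per residue (GLY exempt) on a
    helix; the ligand (5 atoms, residue name LIG) sits near the helix
    axis so a subset of residues falls within 0.6 nm.  The manifest
    records residue names and each residue's minimum ligand distance in
    nm (computed by brute-force scan over all atom pairs), which is the
    ground-truth oracle for pocket extraction.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    names = [ _RESIDUE_NAMES[i] for i in rng.integers(0, 20, size=n_residues) ]
    # helix in angstroms: radius 6 A, rise 1.5 A/residue, 100 deg turn
    lines = []
    serial = 1
    for i in range(n_residues):
        ang = math.radians(100.0 * i)
        ca = np.array([6.0 * math.cos(ang), 6.0 * math.sin(ang), 1.5 * i])
        offsets = {
            "N": np.array([-1.2, 0.3, -0.6]),
            "CA": np.zeros(3),
            "C": np.array([1.2, 0.4, 0.5]),
            "O": np.array([1.6, 1.4, 1.0]),
        }
        coords = {}
        for name, off in offsets.items():
            coords[name] = ca + off
        if names[i] != "GLY":
            inward = -ca[:2] / np.linalg.norm(ca[:2])
            coords["CB"] = ca + np.array([1.5 * inward[0], 1.5 * inward[1], 0.3])
        for name, xyz in coords.items():
            lines.append(_pdb_line("ATOM", serial, name, names[i], "A", i + 1, xyz))
            serial += 1
    # ligand on the helix axis near the structure's vertical midpoint
    mid_z = 1.5 * (n_residues - 1) / 2.0
    lig_center = np.array([2.0, 0.0, mid_z])
    lig_offsets = np.array(
        [[0, 0, 0], [1.4, 0, 0], [-1.4, 0, 0], [0, 1.4, 0], [0, 0, 1.4]]
    )
    lig_coords = lig_center + lig_offsets
    lig_names = ["C1", "C2", "C3", "O1", "N1"]
    for name, xyz in zip(lig_names, lig_coords):
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "A", n_residues + 1, xyz))
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    # manifest distances from the text as written (3-decimal columns), via
    # a brute-force scan over the re-parsed atoms
    parsed = chemio.read_structure(pdb_text)
    lig_parsed = parsed.hetero_coords("LIG")
    min_dist_nm: dict[int, float] = {}
    for a in parsed.protein_atoms():
        d = float(
            np.linalg.norm(np.array(a.coord) - lig_parsed, axis=1).min()
        )
        key = int(a.res_seq)
        min_dist_nm[key] = min(min_dist_nm.get(key, np.inf), d)
    pocket_06 = sorted(i for i, d in min_dist_nm.items() if d <= 0.6)
    if not pocket_06:
        raise RuntimeError("ligand placement produced an empty 0.6 nm pocket")
    manifest = {
        "n_residues": n_residues,
        "seed": seed,
        "residue_names": names,
        "min_ligand_distance_nm": min_dist_nm,
        "pocket_residues_0.6nm": pocket_06,
        "pocket_residues_0.8nm": sorted(
            i for i, d in min_dist_nm.items() if d <= 0.8
        ),
        "hydrophobic_fraction_pocket": float(
            np.mean([names[i - 1] in HYDROPHOBIC_RESIDUES for i in pocket_06])
        ),
    }
    return pdb_text, manifest


def _pdb_line(record, serial, atom_name, res_name, chain, res_seq, xyz) -> str:
    element = atom_name[0]
    return (
        f"{record:<6}{serial:>5} {atom_name:<4} {res_name:>3} {chain}"
        f"{res_seq:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


# ---------------------------------------------------------------------------
# ligand library

_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCCC1", "C1CCOC1", "CCCC", "CCCCCC", "CC(C)C",
]
_SUBSTITUENTS = ["", "C", "CC", "O", "N", "CO", "C(=O)O", "CN", "OC", "C#N"]


def make_ligand_library(n: int, seed: int) -> list[str]:
    """n distinct, parseable SMILES from a closed grammar of scaffolds and
    substituents (aromatic and aliphatic, O/N decorated)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = [
        sub + scaffold if sub else scaffold
        for scaffold in _SCAFFOLDS
        for sub in _SUBSTITUENTS
    ]
    # extend with chain-elongated variants to cover large n
    k = 1
    while len(candidates) < 4 * n:
        candidates.extend("C" * k + s for s in _SCAFFOLDS)
        candidates.extend("C" * k + "O" + s for s in _SCAFFOLDS[:5])
        candidates.extend("C" * k + "N" + s for s in _SCAFFOLDS[5:])
        k += 1
    seen = set()
    valid = []
    for smi in candidates:
        if smi in seen:
            continue
        seen.add(smi)
        try:
            chemio.parse_ligand(smi)
        except chemio.ParseError:
            continue
        valid.append(smi)
    if len(valid) < n:
        raise RuntimeError("grammar exhausted before reaching n ligands")
    idx = rng.permutation(len(valid))[:n]
    return [valid[i] for i in sorted(idx)]


def aromatic_fraction(smiles: str) -> float:
    mol = chemio.parse_ligand(smiles)
    return sum(a["aromatic"] for a in mol.atoms) / mol.n_atoms


# ---------------------------------------------------------------------------
# planted affinities


def planted_affinity(
    z_hydrophobic: float, z_aromatic: float, beta: float, sigma: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(value_nM, latent pKa) for one pair under the planted model."""
    pka = BASE_PKA + beta * z_hydrophobic * z_aromatic + (
        rng.normal(0.0, sigma) if sigma > 0 else 0.0
    )
    return 10.0 ** (9.0 - pka), pka


@dataclass
class SynthDataset:
    config: SynthConfig
    pdb_texts: dict[str, str]
    structure_manifests: dict[str, dict]
    ligand_smiles: dict[str, str]
    affinity_table: str
    manifest: dict = field(default_factory=dict)


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full input bundle: structures, ligand library, affinity table.

    Deterministic: identical config gives byte-identical outputs.  The
    bundle manifest records per-pair latent pKa, the z-scored factors
    and every structure manifest, for oracle checks downstream.
    """
    root = np.random.SeedSequence(cfg.seed)
    struct_seeds, lib_seed, affinity_seed, measure_seed = root.spawn(4)
    pdb_texts, manifests, hyd = {}, {}, []
    for i, ss in enumerate(struct_seeds.spawn(cfg.n_proteins)):
        pid = f"SYNP{i:03d}"
        text, man = make_toy_structure(
            cfg.residues_per_pocket, seed=int(ss.generate_state(1)[0] % 2**31)
        )
        pdb_texts[pid] = text
        manifests[pid] = man
        hyd.append(man["hydrophobic_fraction_pocket"])
    smiles = make_ligand_library(
        cfg.n_ligands, seed=int(lib_seed.generate_state(1)[0] % 2**31)
    )
    ligands = {f"SYNL{j:03d}": s for j, s in enumerate(smiles)}
    aro = [aromatic_fraction(s) for s in smiles]

    def zscore(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    z_h, z_a = zscore(hyd), zscore(aro)
    rng = np.random.default_rng(affinity_seed.generate_state(1)[0] % 2**31)
    mrng = np.random.default_rng(measure_seed.generate_state(1)[0] % 2**31)
    measures = [m.value for m in chemio.Measure]
    rows = ["\t".join(chemio.AFFINITY_COLUMNS)]
    pair_latents = {}
    for i, pid in enumerate(pdb_texts):
        for j, (lid, smi) in enumerate(ligands.items()):
            value, pka = planted_affinity(z_h[i], z_a[j], cfg.beta, cfg.sigma, rng)
            measure = measures[mrng.integers(0, len(measures))]
            rows.append(f"{pid}\t{lid}\t{smi}\t{measure}\t{value:.6g}")
            pair_latents[f"{pid}|{lid}"] = {"pka": pka, "value_nM": value}
    return SynthDataset(
        config=cfg,
        pdb_texts=pdb_texts,
        structure_manifests=manifests,
        ligand_smiles=ligands,
        affinity_table="\n".join(rows) + "\n",
        manifest={
            "z_hydrophobic": {p: float(z) for p, z in zip(pdb_texts, z_h)},
            "z_aromatic": {l: float(z) for l, z in zip(ligands, z_a)},
            "pairs": pair_latents,
            "base_pka": BASE_PKA,
        },
    )


# ---------------------------------------------------------------------------
# end-to-end assembly (structures + table -> labeled pairs)


def build_labeled_pairs(
    ds: SynthDataset,
    mode: str = "bc",
    table: featurize.AminoAcidEmbeddingTable | None = None,
    pocket_cutoff_nm: float = pocket_mod.POCKET_CUTOFF_BC_NM,
    embedding_seed: int = 0,
) -> tuple[list[curate.LabeledPair], dict]:
    """Run the real pipeline over a synthetic bundle.

    Extracts each protein's pocket from its PDB text, builds contact
    graphs with embedding features (training the default embedding on
    the bundle's own ligands when no table is given), parses and labels
    the affinity table, and assembles LabeledPair objects.
    """
    if table is None:
        table = featurize.default_embedding_table(
            list(ds.ligand_smiles.values()), seed=embedding_seed
        )
    pocket_graphs = {}
    for pid, text in ds.pdb_texts.items():
        structure = chemio.read_structure(text)
        residues = pocket_mod.extract_pocket(
            structure, structure.hetero_coords("LIG"), cutoff_nm=pocket_cutoff_nm
        )
        pocket_graphs[pid] = pocket_mod.build_pocket_graph(
            residues, table, pocket_cutoff_nm=pocket_cutoff_nm
        )
    ligand_graphs = {
        lid: featurize.ligand_to_graph(chemio.parse_ligand(smi))
        for lid, smi in ds.ligand_smiles.items()
    }
    records, n_rejected = chemio.read_affinity_table(ds.affinity_table)
    cfg = curate.CurationConfig(
        pos_max_nM=ds.config.pos_max_nM, neg_min_nM=ds.config.neg_min_nM
    )
    labeled, counts = curate.label_records(records, mode=mode, cfg=cfg)
    pairs = [
        curate.LabeledPair(
            protein_id=rec.protein_id,
            ligand_id=rec.ligand_id,
            pocket=pocket_graphs[rec.protein_id],
            ligand=ligand_graphs[rec.ligand_id],
            label=label,
            label_kind="binary" if mode == "bc" else "pka",
        )
        for rec, label in labeled
    ]
    info = {"label_counts": counts, "n_rejected": n_rejected,
            "n_records": len(records)}
    return pairs, info
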