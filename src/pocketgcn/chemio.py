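"""Readers and writers for the formats the pipeline touches.

Covers a restricted PDB dialect (ATOM/HETATM/TER/END, first model only),
SMILES/SDF ligand input via RDKit, delimited affinity tables, and a
compressed archive format for labeled graph datasets.

All internal coordinates are stored in nanometres because every distance
cutoff in the pipeline (0.5 / 0.6 / 0.8 nm) is defined in nm.  Conversion
from the PDB's angstrom columns is done by shifting the decimal point in
the column *text* before float conversion, which makes the A->nm->A round
trip exact for every value representable in PDB coordinate columns
(binary float division by 10 is not exact for ~12% of such values).
"""

from __future__ import annotations

import io as _io
import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Malformed input text; message names the offending line when known."""


class SchemaError(ValueError):
    """A delimited table is missing required columns."""


class IntegrityError(ValueError):
    """A graph archive failed its checksum or structural validation."""


# ---------------------------------------------------------------------------
# units


def angstrom_text_to_nm(text: str) -> float:
    """Convert a PDB coordinate field (angstroms) to nm by decimal shift.

    ``"  12.345"`` -> ``float("1.2345")``.  Exact for all fixed-column PDB
    values, unlike dividing the parsed float by 10.
    """
    t = text.strip()
    if not t:
        raise ValueError("empty coordinate field")
    sign = ""
    if t[0] in "+-":
        sign, t = t[0].replace("+", ""), t[1:]
    if not t or any(c not in "0123456789." for c in t) or t.count(".") > 1:
        raise ValueError(f"malformed coordinate field {text!r}")
    whole, _, frac = t.partition(".")
    whole = whole or "0"
    if len(whole) >= 1:
        shifted = f"{whole[:-1] or '0'}.{whole[-1]}{frac}"
    return float(sign + shifted)


def nm_to_angstrom(x_nm: float) -> float:
    return x_nm * 10.0


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class Atom:
    """One accepted ATOM/HETATM record (coordinates in nm)."""

    kind: str              # "protein" | "hetero"
    chain: str
    res_seq: str           # residue number + insertion code, e.g. "42" or "42A"
    res_name: str
    atom_name: str
    element: str
    altloc: str
    coord: tuple[float, float, float]


@dataclass
class StructureModel:
    atoms: list[Atom]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.kind == "protein"]

    def hetero_atoms(self, res_name: str | None = None) -> list[Atom]:
        out = [a for a in self.atoms if a.kind == "hetero"]
        if res_name is not None:
            out = [a for a in out if a.res_name == res_name]
        return out

    def hetero_coords(self, res_name: str | None = None) -> np.ndarray:
        return np.array([a.coord for a in self.hetero_atoms(res_name)], dtype=float)


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def is_standard_residue(name: str) -> bool:
    return name.upper() in _STANDARD_RESIDUES


def read_structure(pdb_text: str) -> StructureModel:
    """Parse ATOM/HETATM records from fixed-column PDB text.

    Policies: first model only (records after the first ENDMDL are dropped),
    first-listed altloc kept per (chain, residue, atom name), ANISOU and all
    other record types ignored.  Coordinates are converted A -> nm exactly.
    """
    atoms: list[Atom] = []
    seen_alt: dict[tuple[str, str, str], str] = {}
    in_first_model = True
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            in_first_model = False
        if not in_first_model or rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: truncated {rec} record")
        try:
            coord = (
                angstrom_text_to_nm(line[30:38]),
                angstrom_text_to_nm(line[38:46]),
                angstrom_text_to_nm(line[46:54]),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if not all(np.isfinite(coord)):
            raise ParseError(f"line {lineno}: non-finite coordinate")
        altloc = line[16].strip()
        chain = line[21].strip()
        res_seq = (line[22:27]).strip()  # includes insertion code column
        atom_name = line[12:16].strip()
        key = (chain, res_seq, atom_name)
        if altloc:
            if key in seen_alt and seen_alt[key] != altloc:
                continue  # later-listed altloc dropped
            seen_alt[key] = altloc
        atoms.append(
            Atom(
                kind="protein" if rec == "ATOM" else "hetero",
                chain=chain,
                res_seq=res_seq,
                res_name=line[17:20].strip(),
                atom_name=atom_name,
                element=line[76:78].strip() if len(line) >= 78 else "",
                altloc=altloc,
                coord=coord,
            )
        )
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# affinity tables


class Measure(str, Enum):
    IC50 = "IC50"
    KI = "Ki"
    KD = "Kd"


@dataclass(frozen=True)
class AffinityRecord:
    """One measured receptor-ligand pair; value in nM (positive)."""

    protein_id: str
    ligand_id: str
    smiles: str
    measure: Measure
    value_nM: float

    def __post_init__(self):
        if not (self.value_nM > 0):
            raise ValueError(f"value_nM must be > 0, got {self.value_nM}")


AFFINITY_COLUMNS = ("protein_id", "ligand_id", "smiles", "measure", "value_nM")


def read_affinity_table(
    table_text: str, sep: str = "\t"
) -> tuple[list[AffinityRecord], int]:
    """Parse a delimited affinity export; returns (records, n_rejected).

    Rows with non-numeric or non-positive values, or an unknown measurement
    type, are rejected and counted rather than raised.
    """
    df = pd.read_csv(_io.StringIO(table_text), sep=sep, dtype=str)
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"affinity table missing columns: {missing}")
    records: list[AffinityRecord] = []
    rejected = 0
    valid_measures = {m.value: m for m in Measure}
    for row in df.itertuples(index=False):
        try:
            value = float(row.value_nM)
        except (TypeError, ValueError):
            rejected += 1
            continue
        if not np.isfinite(value) or value <= 0 or row.measure not in valid_measures:
            rejected += 1
            continue
        records.append(
            AffinityRecord(
                protein_id=str(row.protein_id),
                ligand_id=str(row.ligand_id),
                smiles=str(row.smiles),
                measure=valid_measures[str(row.measure)],
                value_nM=value,
            )
        )
    if not records:
        raise ParseError("affinity table contains zero valid rows")
    return records, rejected


# ---------------------------------------------------------------------------
# ligand molecules


@dataclass
class LigandMolecule:
    """Heavy-atom molecular graph parsed from SMILES (largest fragment)."""

    atoms: list[dict]          # element, charge, aromatic, degree, num_h
    bonds: list[tuple[int, int, float, bool]]  # (i, j, order, aromatic)
    source_smiles: str
    rdkit_mol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def parse_ligand(smiles: str) -> LigandMolecule:
    """Parse SMILES into a heavy-atom molecule, keeping the largest covalent
    fragment (salt stripping; ties broken by first fragment)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        Chem.SanitizeMol(mol)
    atoms = [
        {
            "element": a.GetSymbol(),
            "charge": a.GetFormalCharge(),
            "aromatic": a.GetIsAromatic(),
            "degree": a.GetDegree(),
            "num_h": a.GetTotalNumHs(),
            "implicit_valence": a.GetImplicitValence(),
        }
        for a in mol.GetAtoms()
    ]
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            b.GetBondTypeAsDouble(),
            b.GetIsAromatic(),
        )
        for b in mol.GetBonds()
    ]
    return LigandMolecule(atoms=atoms, bonds=bonds, source_smiles=smiles, rdkit_mol=mol)


def read_smiles_file(text: str) -> list[str]:
    """One SMILES per line; blank lines and '#' comments skipped.  A second
    whitespace-separated token, when present, is ignored (title column)."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def read_sdf(text: str) -> list[LigandMolecule]:
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text)
    mols = []
    for m in supplier:
        if m is None:
            raise ParseError("unparseable SDF block")
        mols.append(parse_ligand(Chem.MolToSmiles(m)))
    return mols


# ---------------------------------------------------------------------------
# graph archives

_ARCHIVE_VERSION = 1


def _pair_payload(pair) -> dict:
    """Flatten one LabeledPair (duck-typed, see curate.LabeledPair) to arrays."""
    return {
        "px": np.asarray(pair.pocket.node_features, dtype=np.float64),
        "pe": np.asarray(pair.pocket.edges, dtype=np.int64).reshape(-1, 2),
        "lx": np.asarray(pair.ligand.node_features, dtype=np.float64),
        "le": np.asarray(pair.ligand.edges, dtype=np.int64).reshape(-1, 2),
    }


def write_graph_archive(pairs: Sequence, path) -> None:
    """Serialize labeled pocket/ligand graph pairs to a compressed .npz.

    Round-trip identity with :func:`read_graph_archive` holds field-for-field
    including bitwise-equal feature arrays; an adler32 checksum over the
    array bytes guards against corruption.
    """
    if not pairs:
        raise ValueError("cannot write an empty graph archive")
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": _ARCHIVE_VERSION,
        "n_pairs": len(pairs),
        "label_kind": pairs[0].label_kind,
        "protein_ids": [p.protein_id for p in pairs],
        "ligand_ids": [p.ligand_id for p in pairs],
    }
    labels = np.array([p.label for p in pairs], dtype=np.float64)
    arrays["labels"] = labels
    checksum = zlib.adler32(labels.tobytes())
    for i, pair in enumerate(pairs):
        for suffix, arr in _pair_payload(pair).items():
            arrays[f"g{i}_{suffix}"] = arr
            checksum = zlib.adler32(arr.tobytes(), checksum)
    meta["checksum"] = checksum
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ).copy()
    np.savez_compressed(path, **arrays)


def read_graph_archive(path) -> list:
    from . import curate, featurize, pocket as pocket_mod  # local: avoid cycle

    try:
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode("utf-8"))
    except Exception as exc:  # zip/CRC/JSON failures all mean corruption
        raise IntegrityError(f"unreadable graph archive: {exc}") from None
    labels = data["labels"]
    checksum = zlib.adler32(labels.tobytes())
    pairs = []
    for i in range(meta["n_pairs"]):
        arrs = {s: data[f"g{i}_{s}"] for s in ("px", "pe", "lx", "le")}
        for s in ("px", "pe", "lx", "le"):
            checksum = zlib.adler32(arrs[s].tobytes(), checksum)
        pairs.append(
            curate.LabeledPair(
                protein_id=meta["protein_ids"][i],
                ligand_id=meta["ligand_ids"][i],
                pocket=pocket_mod.PocketGraph.from_arrays(arrs["px"], arrs["pe"]),
                ligand=featurize.LigandGraph(
                    node_features=arrs["lx"],
                    edges=[tuple(e) for e in arrs["le"]],
                    n_atoms=arrs["lx"].shape[0],
                ),
                label=float(labels[i]),
                label_kind=meta["label_kind"],
            )
        )
    if checksum != meta["checksum"]:
        raise IntegrityError("graph archive checksum mismatch")
    return pairs
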