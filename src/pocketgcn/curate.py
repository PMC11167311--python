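"""Affinity curation: labels, duplicate reconciliation, dataset splits.

Binary labels follow the strong/weak-binder rule: affinity (IC50, Ki or
Kd) below 4 nM is a positive, above 4000 nM a negative, and the
ambiguous mid-range is excluded.  Regression labels are
pKa = -log10(affinity in molar), so 1 nM -> 9.0.  Splits can be
pair-disjoint (held-out pairs, proteins may recur) or protein-disjoint
(whole receptors held out, the realistic novel-target scenario).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .chemio import AffinityRecord, Measure


@dataclass(frozen=True)
class CurationConfig:
    pos_max_nM: float = 4.0
    neg_min_nM: float = 4000.0
    duplicate_policy: Literal["median", "best", "first"] = "median"
    boundary_policy: Literal["strict", "inclusive"] = "strict"

    def __post_init__(self):
        if not (0 < self.pos_max_nM < self.neg_min_nM):
            raise ValueError("need 0 < pos_max_nM < neg_min_nM")


def assign_binary_label(
    record: AffinityRecord, cfg: CurationConfig = CurationConfig()
) -> Literal["positive", "negative", "excluded"]:
    """Strict policy: values exactly at a threshold are excluded; the
    inclusive policy (used by the 5/3000 nM variant) keeps them."""
    v = record.value_nM
    if cfg.boundary_policy == "inclusive":
        if v <= cfg.pos_max_nM:
            return "positive"
        if v >= cfg.neg_min_nM:
            return "negative"
        return "excluded"
    if v < cfg.pos_max_nM:
        return "positive"
    if v > cfg.neg_min_nM:
        return "negative"
    return "excluded"


def pka_from_affinity(value_nM: float) -> float:
    """pKa = -log10(K) with K in molar; value is supplied in nM."""
    if not (value_nM > 0) or not math.isfinite(value_nM):
        raise ValueError(f"affinity must be a positive finite nM value, got {value_nM}")
    return 9.0 - math.log10(value_nM)


_MEASURE_PREFERENCE = (Measure.KI, Measure.KD, Measure.IC50)


def reconcile_duplicates(
    records: list[AffinityRecord],
    policy: Literal["median", "best", "first"] = "median",
    measure_preference: tuple[Measure, ...] = _MEASURE_PREFERENCE,
) -> tuple[list[AffinityRecord], dict[tuple[str, str], int]]:
    """Collapse repeated (protein, ligand) measurements to one record.

    When a pair was measured with several assay types, only the most
    preferred type present (Ki over Kd over IC50) is reconciled.  The
    median policy takes the median value; for an even count, the
    geometric mean of the two central values.  Returns the reconciled
    records (input order of first occurrence) and an audit log of
    collapsed group sizes.
    """
    groups: dict[tuple[str, str], list[AffinityRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.protein_id, rec.ligand_id)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec)
    out: list[AffinityRecord] = []
    audit: dict[tuple[str, str], int] = {}
    for key in order:
        group = groups[key]
        smiles = {r.smiles for r in group}
        if len(smiles) > 1:
            raise ValueError(f"conflicting SMILES for pair {key}: {sorted(smiles)}")
        if len(group) == 1:
            out.append(group[0])
            continue
        audit[key] = len(group)
        best_measure = next(m for m in measure_preference if any(r.measure == m for r in group))
        sub = [r for r in group if r.measure == best_measure]
        if policy == "first":
            rep, value = sub[0], sub[0].value_nM
        elif policy == "best":
            rep = min(sub, key=lambda r: r.value_nM)
            value = rep.value_nM
        else:  # median
            vals = sorted(r.value_nM for r in sub)
            k = len(vals)
            if k % 2 == 1:
                value = vals[k // 2]
            else:
                value = math.sqrt(vals[k // 2 - 1] * vals[k // 2])
            rep = sub[0]
        out.append(
            AffinityRecord(
                protein_id=rep.protein_id,
                ligand_id=rep.ligand_id,
                smiles=rep.smiles,
                measure=best_measure,
                value_nM=value,
            )
        )
    return out, audit


@dataclass
class LabeledPair:
    """The training unit: one pocket graph, one ligand graph, one label."""

    protein_id: str
    ligand_id: str
    pocket: "object"        # pocket.PocketGraph
    ligand: "object"        # featurize.LigandGraph
    label: float
    label_kind: Literal["binary", "pka"] = "binary"

    def __post_init__(self):
        if self.label_kind == "binary" and self.label not in (0.0, 1.0):
            raise ValueError("binary label must be 0 or 1")
        if not math.isfinite(self.label):
            raise ValueError("label must be finite")


@dataclass
class DatasetSplit:
    train_ids: list[int]
    test_ids: list[int]
    level: Literal["pair", "protein"]
    seed: int
    class_balance: dict = field(default_factory=dict)


def split_dataset(
    pairs: list[LabeledPair],
    level: Literal["pair", "protein"] = "protein",
    fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Partition pairs into train/test.

    ``protein`` level assigns whole proteins to one side so no receptor
    seen in training appears at test time; ``pair`` level holds out pairs
    but proteins may recur.  Deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    target = fraction * n
    if level == "protein":
        proteins = sorted({p.protein_id for p in pairs})
        if len(proteins) < 2:
            raise ValueError("protein-disjoint split needs >= 2 distinct proteins")
        by_protein: dict[str, list[int]] = {}
        for i, p in enumerate(pairs):
            by_protein.setdefault(p.protein_id, []).append(i)
        shuffled = list(rng.permutation(proteins))
        test_ids: list[int] = []
        for prot in shuffled:
            if len(test_ids) >= target and test_ids:
                break
            test_ids.extend(by_protein[prot])
        if len(test_ids) == n:  # never empty the training side
            test_ids = [i for i in test_ids if pairs[i].protein_id != shuffled[0]]
        test_set = set(test_ids)
        train_ids = [i for i in range(n) if i not in test_set]
    else:
        perm = rng.permutation(n)
        k = max(1, min(n - 1, round(target)))
        test_ids = sorted(int(i) for i in perm[:k])
        train_ids = sorted(int(i) for i in perm[k:])
    if not train_ids or not test_ids:
        raise ValueError("split produced an empty partition; adjust fraction")

    def balance(ids):
        if not ids or pairs[ids[0]].label_kind != "binary":
            return {}
        pos = sum(1 for i in ids if pairs[i].label == 1.0)
        return {"pos": pos, "neg": len(ids) - pos}

    return DatasetSplit(
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        level=level,
        seed=seed,
        class_balance={"train": balance(sorted(train_ids)), "test": balance(sorted(test_ids))},
    )


def label_records(
    records: list[AffinityRecord],
    mode: Literal["bc", "rg"] = "bc",
    cfg: CurationConfig = CurationConfig(),
) -> tuple[list[tuple[AffinityRecord, float]], dict[str, int]]:
    """Map records to (record, label) pairs plus label-count bookkeeping.

    In ``bc`` mode mid-range records are excluded; counts always satisfy
    positives + negatives + excluded = input size.  In ``rg`` mode every
    record gets a pKa label.
    """
    counts = {"positive": 0, "negative": 0, "excluded": 0}
    labeled: list[tuple[AffinityRecord, float]] = []
    for rec in records:
        if mode == "rg":
            labeled.append((rec, pka_from_affinity(rec.value_nM)))
            continue
        cls = assign_binary_label(rec, cfg)
        counts[cls] += 1
        if cls == "positive":
            labeled.append((rec, 1.0))
        elif cls == "negative":
            labeled.append((rec, 0.0))
    return labeled, counts
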