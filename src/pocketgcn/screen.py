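"""Virtual-screening: multi-score candidate tables and threshold filters.

A screening campaign scores a compound library against one receptor
pocket with the classification (BC) and regression (RG) models, joins
externally computed docking scores (kcal/mol), and applies a
conjunction filter.  The two published filter styles are Strategy A
(BC score >= t_bc AND RG score >= t_rg AND docking <= t_dock) and
Strategy B (RG + docking only).  All threshold comparisons are
inclusive; survivors are ranked by RG score descending (affinity
surrogate), docking ascending, then compound id.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import pandas as pd

from . import chemio, gcnmodel


@dataclass
class CandidateScore:
    compound_id: str
    bc_score: float | None = None
    rg_score: float | None = None
    docking_score: float | None = None
    smiles: str | None = None

    def __post_init__(self):
        if self.bc_score is None and self.rg_score is None and self.docking_score is None:
            raise ValueError("candidate must carry at least one score")
        if self.bc_score is not None and not (0.0 <= self.bc_score <= 1.0):
            raise ValueError(f"bc_score outside [0,1]: {self.bc_score}")


@dataclass(frozen=True)
class ScreenStrategy:
    """Conjunction filter; a criterion set to None is inactive."""

    name: str
    bc_min: float | None = None
    rg_min: float | None = None
    dock_max: float | None = None
    missing: str = "strict"   # strict: absent score fails its criterion

    def __post_init__(self):
        if self.bc_min is None and self.rg_min is None and self.dock_max is None:
            raise ValueError("strategy must set at least one criterion")


# the two published campaign configurations
STRATEGY_A_GPR35 = ScreenStrategy("A/GPR35", bc_min=0.999, rg_min=9.0, dock_max=-6.7)
STRATEGY_A_GLP1R = ScreenStrategy("A/GLP-1R", bc_min=0.999, rg_min=9.5, dock_max=-8.7)
STRATEGY_B = ScreenStrategy("B", rg_min=10.0, dock_max=-6.35)


@dataclass
class ScreenReport:
    survivors: list[CandidateScore]
    stage_counts: dict[str, int]
    strategy: ScreenStrategy


def _passes(value: float | None, ok, missing: str) -> bool:
    if value is None:
        return missing == "lenient"
    return ok(value)


def apply_strategy(
    scores: list[CandidateScore], strategy: ScreenStrategy
) -> ScreenReport:
    """Filter candidates; stage counts record survivors after each
    criterion in BC -> RG -> docking order (bookkeeping only: the
    survivor set is the conjunction and order-independent)."""
    if not scores:
        raise ValueError("no candidates to screen")
    stage_counts = {"input": len(scores)}
    pool = list(scores)
    if strategy.bc_min is not None:
        pool = [c for c in pool
                if _passes(c.bc_score, lambda v: v >= strategy.bc_min, strategy.missing)]
        stage_counts["bc"] = len(pool)
    if strategy.rg_min is not None:
        pool = [c for c in pool
                if _passes(c.rg_score, lambda v: v >= strategy.rg_min, strategy.missing)]
        stage_counts["rg"] = len(pool)
    if strategy.dock_max is not None:
        pool = [c for c in pool
                if _passes(c.docking_score, lambda v: v <= strategy.dock_max, strategy.missing)]
        stage_counts["dock"] = len(pool)
    pool.sort(
        key=lambda c: (
            -(c.rg_score if c.rg_score is not None else -math.inf),
            c.docking_score if c.docking_score is not None else math.inf,
            c.compound_id,
        )
    )
    return ScreenReport(survivors=pool, stage_counts=stage_counts, strategy=strategy)


def score_library(
    bc_model: gcnmodel.GCNModel | None,
    rg_model: gcnmodel.GCNModel | None,
    pocket_graph,
    smiles_list: list[str],
    compound_ids: list[str] | None = None,
) -> tuple[list[CandidateScore], list[str]]:
    """Score every parseable compound against one pocket.

    Returns (records, skipped_ids); unparseable SMILES are skipped and
    reported, and an all-unparseable library is an error.
    """
    from . import featurize

    if compound_ids is None:
        compound_ids = [f"CMPD{i:05d}" for i in range(len(smiles_list))]
    graphs, kept_ids, kept_smiles, skipped = [], [], [], []
    for cid, smi in zip(compound_ids, smiles_list):
        try:
            graphs.append(featurize.ligand_to_graph(chemio.parse_ligand(smi)))
        except chemio.ParseError:
            skipped.append(cid)
            continue
        kept_ids.append(cid)
        kept_smiles.append(smi)
    if not graphs:
        raise chemio.ParseError("no compound in the library could be parsed")
    ligand_batch = gcnmodel.pack_graphs(graphs)
    pocket_batch = gcnmodel.pack_graphs([pocket_graph] * len(graphs))
    bc = bc_model.forward(pocket_batch, ligand_batch) if bc_model else None
    rg = rg_model.forward(pocket_batch, ligand_batch) if rg_model else None
    records = [
        CandidateScore(
            compound_id=cid,
            bc_score=float(bc[i]) if bc is not None else None,
            rg_score=float(rg[i]) if rg is not None else None,
            smiles=smi,
        )
        for i, (cid, smi) in enumerate(zip(kept_ids, kept_smiles))
    ]
    return records, skipped


def join_docking(
    scores: list[CandidateScore], docking_table_text: str, sep: str = "\t"
) -> tuple[list[CandidateScore], int]:
    """Left-join docking scores (kcal/mol) keyed by compound id.

    Unmatched compounds keep an absent docking score; returns the joined
    list and the unmatched count.  Duplicate ids in the docking table
    are an error.
    """
    df = pd.read_csv(_io.StringIO(docking_table_text), sep=sep)
    cols = list(df.columns[:2])
    if df[cols[0]].duplicated().any():
        dups = df[cols[0]][df[cols[0]].duplicated()].tolist()
        raise ValueError(f"duplicate compound ids in docking table: {dups}")
    lookup = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))
    joined, unmatched = [], 0
    for c in scores:
        dock = lookup.get(c.compound_id)
        if dock is None:
            unmatched += 1
        joined.append(
            CandidateScore(
                compound_id=c.compound_id,
                bc_score=c.bc_score,
                rg_score=c.rg_score,
                docking_score=dock,
                smiles=c.smiles,
            )
        )
    return joined, unmatched


def report_to_tsv(report: ScreenReport) -> str:
    lines = ["compound_id\tsmiles\tbc_score\trg_score\tdocking_score"]
    for c in report.survivors:
        fmt = lambda v, p: "" if v is None else f"{v:.{p}f}"
        lines.append(
            f"{c.compound_id}\t{c.smiles or ''}\t{fmt(c.bc_score, 4)}"
            f"\t{fmt(c.rg_score, 3)}\t{fmt(c.docking_score, 2)}"
        )
    return "\n".join(lines) + "\n"


def candidates_from_table(table_text: str, sep: str = "\t") -> list[CandidateScore]:
    """Read a candidate table with columns (id, bc, rg, dock) by name:
    ``compound_id``/``id``, ``bc_score``, ``rg_score``, ``docking_score``."""
    df = pd.read_csv(_io.StringIO(table_text), sep=sep)
    id_col = "compound_id" if "compound_id" in df.columns else "id"
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            CandidateScore(
                compound_id=str(d[id_col]),
                bc_score=float(d["bc_score"]) if "bc_score" in d else None,
                rg_score=float(d["rg_score"]) if "rg_score" in d else None,
                docking_score=float(d["docking_score"]) if "docking_score" in d else None,
                smiles=str(d["smiles"]) if "smiles" in d else None,
            )
        )
    return out
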