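"""Bundled reference tables for worked examples and consistency checks.

Two kinds of tables ship with the package:

* published per-receptor benchmark summaries for the classification and
  regression models on a 16-receptor external test panel (UniProt
  accessions, per-target metrics and class counts, plus the printed
  ALL / Average row), used to exercise the report aggregator; and
* the two published screening campaign candidate lists (GPR35 and
  GLP-1R, ChemDiv compound ids with BC / RG / docking scores), used as
  worked examples for the Strategy A filters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screen import CandidateScore, candidates_from_table


def _read(name: str) -> str:
    return (resources.files("pocketgcn") / "data" / name).read_text()


def _report(name: str, summary_name: str) -> tuple[list[dict], dict]:
    import io

    df = pd.read_csv(io.StringIO(_read(name)), sep="\t")
    rows = df.to_dict("records")
    per_target = [r for r in rows if r["name"] != summary_name]
    summary = next(r for r in rows if r["name"] == summary_name)
    return per_target, summary


def bc_benchmark_report() -> tuple[list[dict], dict]:
    """(per-target rows, printed ALL row) of the classification panel."""
    return _report("bc_extra_test_report.tsv", "ALL")


def rg_benchmark_report() -> tuple[list[dict], dict]:
    """(per-target rows, printed Average row) of the regression panel."""
    return _report("rg_extra_test_report.tsv", "Average")


def gpr35_candidates() -> list[CandidateScore]:
    """Published GPR35 Strategy A candidate list (8 compounds)."""
    return candidates_from_table(_read("gpr35_strategy_a_candidates.tsv"))


def glp1r_candidates() -> list[CandidateScore]:
    """Published GLP-1R Strategy A candidate list (12 compounds)."""
    return candidates_from_table(_read("glp1r_strategy_a_candidates.tsv"))
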