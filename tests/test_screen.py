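"""Screening filters, docking joins, and library scoring."""

import numpy as np
import pytest

from pocketgcn import gcnmodel, reference, screen, synthdata
from pocketgcn.screen import CandidateScore, ScreenStrategy


def random_candidates(n, seed, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        dock = float(rng.uniform(-10, -3))
        out.append(
            CandidateScore(
                compound_id=f"C{i:04d}",
                bc_score=float(rng.random()),
                rg_score=float(rng.uniform(4, 11)),
                docking_score=None if rng.random() < missing_rate else dock,
            )
        )
    return out


class TestApplyStrategy:
    def test_published_gpr35_row_survives(self):
        rec = CandidateScore("S948-0241", bc_score=1.00, rg_score=9.39,
                             docking_score=-7.61)
        report = screen.apply_strategy([rec], screen.STRATEGY_A_GPR35)
        assert [c.compound_id for c in report.survivors] == ["S948-0241"]

    def test_bc_below_threshold_fails(self):
        rec = CandidateScore("X", bc_score=0.998, rg_score=9.5, docking_score=-7.0)
        report = screen.apply_strategy([rec], screen.STRATEGY_A_GPR35)
        assert report.survivors == [] and report.stage_counts["bc"] == 0

    def test_inclusive_boundaries(self):
        rec = CandidateScore("B", bc_score=0.999, rg_score=9.0, docking_score=-6.7)
        report = screen.apply_strategy([rec], screen.STRATEGY_A_GPR35)
        assert len(report.survivors) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_predicate_oracle(self, seed):
        cands = random_candidates(100, seed, missing_rate=0.1)
        strat = ScreenStrategy("t", bc_min=0.5, rg_min=8.0, dock_max=-6.0)
        report = screen.apply_strategy(cands, strat)
        expected = {
            c.compound_id
            for c in cands
            if c.bc_score is not None and c.bc_score >= 0.5
            and c.rg_score is not None and c.rg_score >= 8.0
            and c.docking_score is not None and c.docking_score <= -6.0
        }
        assert {c.compound_id for c in report.survivors} == expected

    def test_threshold_tightening_monotone(self):
        cands = random_candidates(200, 3)
        base = screen.apply_strategy(cands, ScreenStrategy("b", bc_min=0.3, rg_min=7.0, dock_max=-5.0))
        for tighter in (
            ScreenStrategy("t1", bc_min=0.6, rg_min=7.0, dock_max=-5.0),
            ScreenStrategy("t2", bc_min=0.3, rg_min=9.0, dock_max=-5.0),
            ScreenStrategy("t3", bc_min=0.3, rg_min=7.0, dock_max=-7.0),
        ):
            sub = screen.apply_strategy(cands, tighter)
            assert {c.compound_id for c in sub.survivors} <= {
                c.compound_id for c in base.survivors
            }

    def test_idempotent(self):
        cands = random_candidates(150, 9)
        strat = ScreenStrategy("s", rg_min=8.5, dock_max=-6.0)
        first = screen.apply_strategy(cands, strat)
        second = screen.apply_strategy(first.survivors, strat) if first.survivors else None
        if second is not None:
            assert [c.compound_id for c in second.survivors] == [
                c.compound_id for c in first.survivors
            ]

    def test_survivors_ranked_by_rg_descending(self):
        cands = random_candidates(50, 5)
        report = screen.apply_strategy(cands, ScreenStrategy("r", rg_min=0.0))
        rgs = [c.rg_score for c in report.survivors]
        assert rgs == sorted(rgs, reverse=True)

    def test_lenient_mode_skips_missing(self):
        rec = CandidateScore("M", bc_score=1.0, rg_score=9.5, docking_score=None)
        strict = screen.apply_strategy([rec], screen.STRATEGY_A_GPR35)
        lenient = screen.apply_strategy(
            [rec], ScreenStrategy("l", bc_min=0.999, rg_min=9.0, dock_max=-6.7,
                                  missing="lenient")
        )
        assert strict.survivors == [] and len(lenient.survivors) == 1


class TestPublishedCandidateLists:
    def test_gpr35_table_fully_retained(self):
        cands = reference.gpr35_candidates()
        report = screen.apply_strategy(cands, screen.STRATEGY_A_GPR35)
        assert len(cands) == 8 and len(report.survivors) == 8

    def test_glp1r_table_fully_retained_including_boundary(self):
        cands = reference.glp1r_candidates()
        report = screen.apply_strategy(cands, screen.STRATEGY_A_GLP1R)
        assert len(cands) == 12 and len(report.survivors) == 12


class TestJoinDocking:
    def test_left_join_with_unmatched(self):
        cands = [CandidateScore("A", bc_score=0.9), CandidateScore("B", bc_score=0.8)]
        joined, unmatched = screen.join_docking(cands, "id\tdock\nA\t-7.5\n")
        assert joined[0].docking_score == -7.5
        assert joined[1].docking_score is None and unmatched == 1

    def test_empty_docking_table_all_absent(self):
        cands = [CandidateScore("A", bc_score=0.9)]
        joined, unmatched = screen.join_docking(cands, "id\tdock\n")
        assert joined[0].docking_score is None and unmatched == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            screen.join_docking([CandidateScore("A", bc_score=0.5)],
                                "id\tdock\nA\t-7\nA\t-8\n")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hash_join_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cands = random_candidates(60, seed)
        covered = [c.compound_id for c in cands if rng.random() < 0.7]
        table = "id\tdock\n" + "".join(f"{cid}\t{-6 - i * 0.01:.2f}\n"
                                       for i, cid in enumerate(covered))
        joined, unmatched = screen.join_docking(cands, table)
        lookup = {cid: -6 - i * 0.01 for i, cid in enumerate(covered)}
        for c in joined:
            expected = lookup.get(c.compound_id)
            if expected is None:
                assert c.docking_score is None
            else:
                assert c.docking_score == pytest.approx(expected)
        assert unmatched == len(cands) - len(covered)


class TestScoreLibrary:
    @pytest.fixture(scope="class")
    def models_and_pocket(self, small_bc_pairs):
        pairs, _ = small_bc_pairs
        dims = (30, pairs[0].ligand.node_features.shape[1])
        bc = gcnmodel.build_model(
            gcnmodel.ModelConfig(pocket_widths=(8,), ligand_widths=(8,),
                                 fc_widths=(8,), head="bc"), *dims, seed=0)
        rg = gcnmodel.build_model(
            gcnmodel.ModelConfig(pocket_widths=(8,), ligand_widths=(8,),
                                 fc_widths=(8,), head="rg"), *dims, seed=1)
        return bc, rg, pairs[0].pocket

    def test_toy_library_scored(self, models_and_pocket):
        bc, rg, pg = models_and_pocket
        records, skipped = screen.score_library(bc, rg, pg, ["CCO", "c1ccccc1", "CCN"])
        assert len(records) == 3 and skipped == []
        assert all(0 <= r.bc_score <= 1 for r in records)
        assert all(np.isfinite(r.rg_score) for r in records)

    def test_deterministic(self, models_and_pocket):
        bc, rg, pg = models_and_pocket
        lib = synthdata.make_ligand_library(30, seed=8)
        r1, _ = screen.score_library(bc, rg, pg, lib)
        r2, _ = screen.score_library(bc, rg, pg, lib)
        assert all(a.bc_score == b.bc_score and a.rg_score == b.rg_score
                   for a, b in zip(r1, r2))

    def test_matches_per_pair_inference_oracle(self, models_and_pocket):
        from pocketgcn import chemio, featurize

        bc, rg, pg = models_and_pocket
        lib = synthdata.make_ligand_library(40, seed=13)
        records, _ = screen.score_library(bc, rg, pg, lib)
        for rec, smi in zip(records, lib):
            lg = featurize.ligand_to_graph(chemio.parse_ligand(smi))
            assert rec.bc_score == pytest.approx(
                gcnmodel.forward_pair(bc, pg, lg), abs=1e-9)
            assert rec.rg_score == pytest.approx(
                gcnmodel.forward_pair(rg, pg, lg), abs=1e-9)

    def test_unparseable_compounds_skipped(self, models_and_pocket):
        bc, rg, pg = models_and_pocket
        records, skipped = screen.score_library(
            bc, rg, pg, ["CCO", "not_a_smiles(("], ["ok", "bad"])
        assert [r.compound_id for r in records] == ["ok"] and skipped == ["bad"]

    def test_all_unparseable_rejected(self, models_and_pocket):
        bc, rg, pg = models_and_pocket
        from pocketgcn import chemio

        with pytest.raises(chemio.ParseError):
            screen.score_library(bc, rg, pg, ["((", ")]"])
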