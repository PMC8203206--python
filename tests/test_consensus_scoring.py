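import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dockjury import (
    DockjuryError,
    PoolError,
    aggregate_modfolddock,
    average_chain_pair_scores,
    build_pool,
    dockq,
    ia_score,
    jury_score,
    make_reference_dimer,
    modfoldia_global,
    modfoldia_local,
    pairwise_scores,
    perturb_model,
    qs_score,
    read_external_scores,
    score_pool,
    si_score,
    write_caspqa,
    write_residue_tsv,
    write_scores_tsv,
)
from conftest import two_point_model


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------

class TestFormulas:
    @pytest.mark.parametrize(
        "dmin,expected",
        [(0.0, 1.0), (20.0, 0.5), (5.0, 1.0 / (1.0 + 0.0625))],
    )
    def test_si_sigmoid(self, dmin, expected):
        assert si_score(dmin) == pytest.approx(expected, abs=1e-12)

    def test_si_rejects_negative(self):
        with pytest.raises(ValueError):
            si_score(-0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_si_bounded_and_decreasing(self, d):
        s = si_score(d)
        assert 0.0 < s <= 1.0
        assert si_score(d + 1.0) < s

    @pytest.mark.parametrize(
        "si,mean_si,expected",
        [(1.0, 1.0, 1.0), (1.0, 0.5, 0.5),
         (0.5, 1.0 / 1.0625, 1.0 - abs(0.5 - 1.0 / 1.0625))],
    )
    def test_ia_absolute_difference(self, si, mean_si, expected):
        assert ia_score(si, mean_si) == pytest.approx(expected, abs=1e-10)

    def test_ia_grid_matches_independent_arithmetic(self):
        """IA = 1 - |Si - MeanSi| on a grid, against direct arithmetic."""
        grid = np.linspace(0.02, 1.0, 50)
        for si in grid:
            for mean_si in (0.25, 0.75):
                assert ia_score(si, mean_si) == pytest.approx(
                    1.0 - abs(si - mean_si), abs=1e-12
                )

    def test_ia_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ia_score(0.0, 0.5)
        with pytest.raises(ValueError):
            ia_score(0.5, 1.2)


# ---------------------------------------------------------------------------
# ModFOLDIA local/global
# ---------------------------------------------------------------------------

def hand_example_pool():
    """Two one-contact dimers: the residue pair touches (Dmin 0) in model 1
    and is 20 A apart in model 2."""
    return build_pool([two_point_model("m1", 0.0), two_point_model("m2", 20.0)])


class TestModfoldia:
    def test_identical_pool_all_ia_one(self, identical_pool):
        for mid in identical_pool.model_ids:
            local = modfoldia_local(identical_pool, mid)
            assert local, "interface must be non-empty"
            assert all(r.ia == pytest.approx(1.0) for r in local)
            assert modfoldia_global(identical_pool, mid) == pytest.approx(1.0)

    def test_hand_example_dmin_zero_vs_twenty(self):
        """Si=1 (contact), MeanSi=0.5 (20 A away elsewhere) -> IA=0.5; the
        empty interface of model 2 halves the mean interface size, so the
        global score is (0.5+0.5)/max(2, 1) = 0.5."""
        pool = hand_example_pool()
        local = modfoldia_local(pool, "m1")
        assert len(local) == 2  # both partner residues are interface
        for r in local:
            assert r.si == pytest.approx(1.0)
            assert r.mean_si == pytest.approx(0.5)
            assert r.ia == pytest.approx(0.5)
        assert modfoldia_global(pool, "m1") == pytest.approx(0.5)

    def test_empty_interface_scores_zero(self):
        pool = hand_example_pool()
        assert modfoldia_local(pool, "m2") == []
        assert modfoldia_global(pool, "m2") == 0.0

    def test_missing_residue_flagged_and_contributes_zero(self, caplog):
        a = two_point_model("a", 3.0)
        b = two_point_model("b", 3.0, chain_b_seq=2)
        pool = build_pool([a, b])
        with caplog.at_level("WARNING", logger="dockjury"):
            local = modfoldia_local(pool, "a")
        by_key = {r.key: r for r in local}
        assert by_key[("B", 1, "")].missing  # B:1 exists only in model a
        assert by_key[("B", 1, "")].ia is None
        assert not by_key[("A", 1, "")].missing  # A:1 exists in both
        assert any("missing" in r.message for r in caplog.records)
        # numerator counts only defined IA; n_interface still counts both
        # (both models have 2 interface residues, so the normaliser is 2)
        expected = by_key[("A", 1, "")].ia / 2
        assert modfoldia_global(pool, "a") == pytest.approx(expected)

    def test_pool_of_one_rejected(self):
        pool = hand_example_pool()
        pool.models = pool.models[:1]
        with pytest.raises(PoolError, match=">= 2"):
            modfoldia_local(pool, "m1")


# ---------------------------------------------------------------------------
# Jury scores
# ---------------------------------------------------------------------------

class TestJury:
    def test_identical_pool_scores_one(self, identical_pool):
        for mid in identical_pool.model_ids:
            assert jury_score(identical_pool, mid, "qs") == pytest.approx(1.0)
            assert jury_score(identical_pool, mid, "dockq") == pytest.approx(1.0)

    def test_matches_bruteforce_pairwise_table(self):
        """Jury means equal a direct loop over dockq()/qs_score() calls."""
        ref = make_reference_dimer(20, seed=4)
        models = [
            perturb_model(ref, rotation=r, translation=t, jitter_sd=0.1,
                          seed=i, model_id=f"m{i}")
            for i, (r, t) in enumerate([(1, 0.3), (2, 0.6), (25, 8.0), (40, 12.0)])
        ]
        pool = build_pool(models)
        table = pairwise_scores(pool)
        for m in models:
            others = [o for o in models if o.model_id != m.model_id]
            exp_dockq = np.mean([dockq(m, o).dockq for o in others])
            exp_qs = np.mean([qs_score(m, o) for o in others])
            assert jury_score(pool, m.model_id, "dockq", table=table) == \
                pytest.approx(exp_dockq, abs=1e-12)
            assert jury_score(pool, m.model_id, "qs", table=table) == \
                pytest.approx(exp_qs, abs=1e-12)

    def test_outlier_scores_below_consensus(self):
        ref = make_reference_dimer(20, seed=9)
        near1 = perturb_model(ref, rotation=2, translation=0.5, seed=1,
                              model_id="near1")
        near2 = perturb_model(ref, rotation=3, translation=0.8, seed=2,
                              model_id="near2")
        far = perturb_model(ref, rotation=50, translation=15, seed=3,
                            model_id="far")
        pool = build_pool([near1, near2, far])
        table = pairwise_scores(pool)
        for metric in ("qs", "dockq"):
            far_score = jury_score(pool, "far", metric, table=table)
            for mid in ("near1", "near2"):
                assert far_score < jury_score(pool, mid, metric, table=table)

    def test_bad_metric_name(self, identical_pool):
        with pytest.raises(ValueError):
            jury_score(identical_pool, "m1", "rmsd")


# ---------------------------------------------------------------------------
# External scores and aggregation
# ---------------------------------------------------------------------------

class TestExternalScores:
    def test_chain_pair_average(self):
        assert average_chain_pair_scores({("A", "B"): 0.7}) == pytest.approx(0.7)
        assert average_chain_pair_scores(
            {("A", "B"): 0.6, ("A", "C"): 0.8, ("B", "C"): 1.0}
        ) == pytest.approx(0.8)

    def test_chain_pair_validation(self):
        with pytest.raises(ValueError):
            average_chain_pair_scores({})
        with pytest.raises(ValueError):
            average_chain_pair_scores({("A", "B"): 1.2})

    def test_read_tsv_with_chain_pairs(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text(
            "method\tmodel_id\tchain_a\tchain_b\tscore\n"
            "proqdock\tm1\tA\tB\t0.6\n"
            "proqdock\tm1\tA\tC\t0.8\n"
            "voromqa\tm1\t\t\t0.9\n"
        )
        scores = read_external_scores(path)
        assert scores["proqdock"]["m1"] == pytest.approx(0.7)
        assert scores["voromqa"]["m1"] == pytest.approx(0.9)

    def test_unknown_model_rejected(self, tmp_path, identical_pool):
        path = tmp_path / "ext.tsv"
        path.write_text("method\tmodel_id\tscore\nproqdock\tnope\t0.5\n")
        with pytest.raises(DockjuryError, match="unknown model"):
            read_external_scores(path, pool=identical_pool)

    def test_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("method\tmodel_id\tscore\nproqdock\tm1\t1.5\n")
        with pytest.raises(DockjuryError, match="outside"):
            read_external_scores(path)


class TestAggregate:
    def test_five_component_mean(self):
        comp = {"m": {"qs_jury": 0.2, "dockq_jury": 0.4, "modfoldia_global": 0.6,
                      "proqdock": 0.8, "voromqa": 1.0}}
        scores = aggregate_modfolddock(comp)
        assert scores.models["m"].modfolddock_global == pytest.approx(0.6)
        assert scores.models["m"].external == {"proqdock": 0.8, "voromqa": 1.0}

    def test_three_component_fallback(self, caplog):
        comp = {"m": {"qs_jury": 0.3, "dockq_jury": 0.5, "modfoldia_global": 0.7}}
        with caplog.at_level("INFO", logger="dockjury"):
            scores = aggregate_modfolddock(comp)
        assert scores.models["m"].modfolddock_global == pytest.approx(0.5)
        assert any("3-component" in r.message for r in caplog.records)

    def test_missing_internal_component(self):
        with pytest.raises(DockjuryError, match="missing internal"):
            aggregate_modfolddock({"m": {"qs_jury": 0.5, "dockq_jury": 0.5}})

    def test_ranking_descending_with_id_tiebreak(self):
        comp = {
            mid: {"qs_jury": v, "dockq_jury": v, "modfoldia_global": v}
            for mid, v in [("b", 0.5), ("a", 0.5), ("c", 0.9)]
        }
        scores = aggregate_modfolddock(comp)
        assert scores.ranking == ["c", "a", "b"]


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------

class TestScorePool:
    def test_identical_pool_everything_one(self, identical_pool):
        scores = score_pool(identical_pool)
        for m in scores.models.values():
            assert m.qs_jury == pytest.approx(1.0)
            assert m.dockq_jury == pytest.approx(1.0)
            assert m.modfoldia_global == pytest.approx(1.0)
            assert m.modfolddock_global == pytest.approx(1.0)
            assert all(r.ia == pytest.approx(1.0) for r in m.residues)

    def test_permutation_invariance(self):
        ref = make_reference_dimer(15, seed=11)
        models = [
            perturb_model(ref, rotation=r, translation=t, seed=i,
                          model_id=f"m{i}")
            for i, (r, t) in enumerate([(1, 0.2), (4, 0.9), (30, 10.0), (55, 16.0)])
        ]
        s1 = score_pool(build_pool(models))
        s2 = score_pool(build_pool(models[::-1]))
        assert s1.ranking == s2.ranking
        for mid in s1.models:
            assert s1.models[mid].modfolddock_global == pytest.approx(
                s2.models[mid].modfolddock_global, abs=1e-12
            )
            assert s1.models[mid].qs_jury == pytest.approx(
                s2.models[mid].qs_jury, abs=1e-12
            )

    def test_external_scores_enter_aggregate(self, identical_pool, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text(
            "method\tmodel_id\tscore\n"
            + "".join(f"proqdock\t{m}\t0.4\n" for m in identical_pool.model_ids)
        )
        ext = read_external_scores(path, pool=identical_pool)
        scores = score_pool(identical_pool, external=ext)
        for m in scores.models.values():
            # mean of {1, 1, 1, 0.4}
            assert m.modfolddock_global == pytest.approx((3 + 0.4) / 4)

    def test_all_scores_bounded(self):
        ref = make_reference_dimer(15, seed=21)
        models = [
            perturb_model(ref, rotation=r, translation=t, jitter_sd=0.3, seed=i,
                          model_id=f"m{i}")
            for i, (r, t) in enumerate([(0, 0), (5, 1), (20, 6), (60, 18)])
        ]
        scores = score_pool(build_pool(models))
        for m in scores.models.values():
            for v in (m.qs_jury, m.dockq_jury, m.modfoldia_global,
                      m.modfolddock_global):
                assert 0.0 <= v <= 1.0
            for r in m.residues:
                if r.ia is not None:
                    assert 0.0 <= r.ia <= 1.0


class TestOutputs:
    def test_tsv_and_caspqa_files(self, identical_pool, tmp_path):
        scores = score_pool(identical_pool)
        write_scores_tsv(scores, tmp_path / "scores.tsv")
        write_residue_tsv(scores, tmp_path / "res.tsv")
        write_caspqa(scores, identical_pool, tmp_path / "qa.txt")

        header = (tmp_path / "scores.tsv").read_text().splitlines()[0].split("\t")
        assert header[:3] == ["rank", "model_id", "qs_jury"]
        assert "modfolddock_global" in header

        qa = (tmp_path / "qa.txt").read_text().splitlines()
        assert qa[0] == "PFRMAT QA"
        assert qa[-1] == "END"
        model_lines = [l for l in qa if l.startswith("m")]
        assert len(model_lines) == 3
        fields = model_lines[0].split()
        assert float(fields[1]) == pytest.approx(1.0)
        # per-residue IA follows in model residue order; non-interface are 'X'
        assert len(fields) == 2 + identical_pool.models[0].n_residues()
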