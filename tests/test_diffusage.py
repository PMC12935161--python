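import numpy as np
import pytest
from scipy import special

import isokit as ik
from isokit import diffusage as du
from isokit.errors import IsokitError


def make_design(n_ctrl, n_case, prefix="s"):
    groups = {f"{prefix}{j}": ("control" if j < n_ctrl else "case")
              for j in range(n_ctrl + n_case)}
    return ik.SampleDesign(groups, control="control", case="case")


def make_table(counts, gene_id="g1"):
    counts = np.asarray(counts, dtype=float)
    return du.UsageTable(gene_id, [f"t{j}" for j in range(counts.shape[1])],
                         [f"s{i}" for i in range(counts.shape[0])], counts)


def dm_null_table(rng, k, n_per_group, depth, precision, p=None):
    p = rng.dirichlet(np.full(k, 2.0)) if p is None else np.asarray(p)
    y = np.stack([rng.multinomial(depth, rng.dirichlet(precision * p))
                  for _ in range(2 * n_per_group)])
    return make_table(y)


class TestBuildUsageTables:
    def test_proportions(self):
        models = ik.toy_models(1, 2)
        counts = ik.CountMatrix(["G0001.T1", "G0001.T2"], ["a", "b", "c", "d"],
                                np.array([[30, 30, 30, 30], [70, 70, 70, 70]]))
        tables, excluded = ik.build_usage_tables(counts, models)
        assert excluded == []
        np.testing.assert_allclose(tables[0].proportions()[0], [0.3, 0.7])

    def test_single_transcript_gene_excluded(self):
        models = ik.toy_models(1, 1)
        counts = ik.CountMatrix(["G0001.T1"], ["a", "b"], np.array([[50, 50]]))
        tables, excluded = ik.build_usage_tables(counts, models)
        assert tables == []
        assert excluded == [("G0001", "fewer_than_2_expressed_transcripts")]

    def test_unknown_transcript_rejected(self):
        models = ik.toy_models(1, 2)
        counts = ik.CountMatrix(["mystery"], ["a", "b"], np.array([[5, 5]]))
        with pytest.raises(IsokitError, match="mystery"):
            ik.build_usage_tables(counts, models)

    def test_exclusion_matches_brute_force_filter(self):
        rng = np.random.default_rng(12)
        models = ik.toy_models(40, 2)
        tids = [t.transcript_id for m in models for t in m.transcripts]
        counts = rng.poisson(rng.choice([1, 2, 30], size=len(tids))[:, None],
                             size=(len(tids), 6))
        cm = ik.CountMatrix(tids, [f"s{j}" for j in range(6)], counts)
        tables, excluded = ik.build_usage_tables(cm, models, min_gene_count=10)
        expected_excluded = set()
        for g in range(40):
            block = counts[2 * g:2 * g + 2]
            expressed = (block.sum(axis=1) > 0).sum()
            totals = block.sum(axis=0)
            if expressed < 2:
                expected_excluded.add(f"G{g + 1:04d}")
            elif (totals < 10).sum() > 3:
                expected_excluded.add(f"G{g + 1:04d}")
        assert {g for g, _ in excluded} == expected_excluded
        assert {t.gene_id for t in tables} == {f"G{g + 1:04d}" for g in range(40)} - expected_excluded


class TestFitDm:
    def test_symmetric_single_sample(self):
        fit = ik.fit_dm(np.array([[5, 5]]))
        np.testing.assert_allclose(fit.proportions, [0.5, 0.5], atol=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        p_true = np.array([0.7, 0.2, 0.1])
        y = np.stack([rng.multinomial(200, rng.dirichlet(50 * p_true))
                      for _ in range(40)])
        fit = ik.fit_dm(y)
        np.testing.assert_allclose(fit.proportions, p_true, atol=0.05)

    def test_loglik_matches_gamma_sum_oracle(self):
        y = np.array([[3, 1, 0], [2, 2, 2]], dtype=float)
        p = np.array([0.5, 0.3, 0.2])
        s = 7.0
        expected = 0.0
        for row in y:
            n = row.sum()
            a = s * p
            expected += (special.gammaln(n + 1) - special.gammaln(row + 1).sum()
                         + special.gammaln(s) - special.gammaln(n + s)
                         + (special.gammaln(row + a) - special.gammaln(a)).sum())
        assert ik.dm_loglik(y, p, s) == pytest.approx(expected, abs=1e-10)

    def test_k_below_two_rejected(self):
        with pytest.raises(IsokitError):
            ik.fit_dm(np.array([[5.0], [3.0]]))

    def test_multinomial_limit_at_high_precision(self):
        rng = np.random.default_rng(8)
        p = np.array([0.5, 0.3, 0.2])
        y = np.stack([rng.multinomial(100, p) for _ in range(10)]).astype(float)
        ll_dm = ik.dm_loglik(y, p, 1e6)
        n = y.sum(axis=1)
        ll_mn = float(np.sum(special.gammaln(n + 1)
                             - special.gammaln(y + 1).sum(axis=1)
                             + (y * np.log(p)).sum(axis=1)))
        assert abs(ll_dm - ll_mn) / len(y) < 1e-3


class TestGeneLrt:
    def test_identical_groups_null_identity(self):
        block = np.array([[30, 50, 20]] * 4 + [[28, 52, 20]] * 4
                         + [[30, 50, 20]] * 4 + [[28, 52, 20]] * 4)
        # both groups see exactly the same 8 samples
        table = make_table(block)
        p = ik.gene_lrt(table, make_design(8, 8))
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        table = dm_null_table(rng, 3, 6, 250, 50)
        design = make_design(6, 6)
        swapped = ik.SampleDesign(design.groups, control="case", case="control")
        assert ik.gene_lrt(table, design) == pytest.approx(
            ik.gene_lrt(table, swapped), abs=1e-8)

    def test_insufficient_samples_raises(self):
        table = make_table(np.array([[10, 5], [8, 7], [9, 9]]))
        design = ik.SampleDesign({"s0": "control", "s1": "control", "s2": "case",
                                  "s3": "case"}, control="control", case="case")
        table.sample_ids[:] = ["s0", "s1", "s2"]
        with pytest.raises(IsokitError):
            ik.gene_lrt(make_table(table.counts[:3]), design)


class TestTranscriptTest:
    def test_k2_complementary_symmetry(self):
        rng = np.random.default_rng(5)
        table = dm_null_table(rng, 2, 5, 300, 50)
        design = make_design(5, 5)
        p0 = ik.transcript_test(table, design, "t0")
        p1 = ik.transcript_test(table, design, "t1")
        assert p0 == pytest.approx(p1, abs=1e-8)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(6)
        design = make_design(5, 5)
        ps = []
        for _ in range(300):
            table = dm_null_table(rng, 3, 5, 300, 50)
            ps.append(ik.transcript_test(table, design, "t0"))
        from scipy import stats
        assert stats.kstest(ps, "uniform").statistic < 0.1

    def test_power_at_large_shift(self):
        rng = np.random.default_rng(7)
        design = make_design(20, 20)
        hits = 0
        for _ in range(25):
            p0, p1 = np.array([0.5, 0.3, 0.2]), np.array([0.2, 0.3, 0.5])
            y = np.stack([rng.multinomial(300, rng.dirichlet(50 * (p0 if i < 20 else p1)))
                          for i in range(40)])
            hits += ik.transcript_test(make_table(y), design, "t0") < 0.05
        assert hits / 25 > 0.8


class TestStagewise:
    def test_gatekeeping_no_screened_genes(self):
        gene_ps = {"g1": 0.9, "g2": 0.8}
        tx_ps = {"g1": {"t1": 0.001}, "g2": {"t2": 0.002}}
        _, screened, _, confirmed = ik.stagewise_correct(gene_ps, tx_ps)
        assert screened == set()
        assert not any(any(v.values()) for v in confirmed.values())

    def test_single_strong_gene_confirmed(self):
        gene_q, screened, tx_adj, confirmed = ik.stagewise_correct(
            {"g1": 0.001}, {"g1": {"t1": 0.001}})
        assert screened == {"g1"}
        assert confirmed["g1"]["t1"]
        assert tx_adj["g1"]["t1"] <= 0.05

    def test_orphan_transcript_rejected(self):
        with pytest.raises(IsokitError):
            ik.stagewise_correct({"g1": 0.01}, {"g2": {"t": 0.01}})

    def test_confirmed_implies_screened_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            genes = {f"g{i}": float(rng.uniform()) for i in range(30)}
            tx = {g: {f"{g}t{j}": float(rng.uniform()) for j in range(3)}
                  for g in genes}
            gene_q, screened, _, confirmed = ik.stagewise_correct(genes, tx)
            for g, conf in confirmed.items():
                if any(conf.values()):
                    assert g in screened


class TestDeltaUsage:
    def test_hand_arithmetic(self):
        counts = np.array([[30, 70]] * 4 + [[60, 40]] * 4)
        table = make_table(counts)
        delta = ik.delta_usage(table, make_design(4, 4))
        assert delta["t0"] == pytest.approx(0.30)
        assert delta["t1"] == pytest.approx(-0.30)

    def test_identical_groups_zero(self):
        counts = np.array([[25, 75]] * 8)
        delta = ik.delta_usage(make_table(counts), make_design(4, 4))
        assert all(v == pytest.approx(0.0) for v in delta.values())

    def test_sums_to_zero_over_gene(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            counts = rng.integers(1, 100, size=(8, k))
            delta = ik.delta_usage(make_table(counts), make_design(4, 4))
            assert sum(delta.values()) == pytest.approx(0.0, abs=1e-9)


class TestRunDiu:
    def test_end_to_end_on_planted_mixture(self):
        cfg = ik.SimulationConfig(seed=55, n_genes=40, n_samples_per_group=10,
                                  depth=30_000, frac_de=0.0, frac_diu=0.2)
        models = ik.toy_models(40, 3)
        counts, design, truth = ik.simulate_counts(models, cfg)
        results, excluded = ik.run_diu(counts, models, design)
        assert results, "expected testable genes"
        # per-gene per-group usage vectors lie on the simplex
        by_gene = {}
        for r in results:
            by_gene.setdefault(r.gene_id, []).append(r)
        for rows in by_gene.values():
            assert sum(r.usage_control for r in rows) == pytest.approx(1.0, abs=1e-9)
            assert sum(r.usage_case for r in rows) == pytest.approx(1.0, abs=1e-9)
            assert sum(r.delta_usage for r in rows) == pytest.approx(0.0, abs=1e-9)
        # confirmed implies screened
        for r in results:
            if r.confirmed:
                assert r.gene_q <= 0.05
        # most planted genes are found
        true_diu = set(truth["diu"].gene_id)
        conf_genes = {r.gene_id for r in results if r.confirmed}
        assert len(conf_genes & true_diu) >= len(true_diu) * 0.5

    def test_table_round_trip(self, tmp_path):
        results = [ik.DIUResult("g1", "t1", 0.5, 0.2, -0.3, 1e-5, 1e-4,
                                1e-5, 1e-4, True)]
        ik.write_diu_table(results, tmp_path / "diu.tsv")
        back = ik.load_diu_table(tmp_path / "diu.tsv")
        assert back[0].gene_id == "g1"
        assert back[0].delta_usage == pytest.approx(-0.3)
        assert bool(back[0].confirmed) is True
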