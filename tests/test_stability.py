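import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from refgene.ingest import CtMatrix
from refgene.stability import (
    DilutionSeries,
    RelativeQuantityMatrix,
    amplification_efficiency,
    comprehensive_rank,
    ct_to_quantity,
    deltact_stability,
    genorm_m,
    genorm_rank,
    normfinder_stability,
    stability_report,
)

from conftest import random_ct_matrix


def ct_matrix(rows, efficiencies=None, groups=None, sample_prefix="S"):
    rows = np.asarray(rows, dtype=float)
    return CtMatrix(
        gene_ids=[f"G{i:02d}" for i in range(rows.shape[0])],
        sample_ids=[f"{sample_prefix}{j:02d}" for j in range(rows.shape[1])],
        ct_values=rows,
        efficiencies=efficiencies,
        groups=groups,
    )


# ---------------------------------------------------------------- oracles

def brute_genorm_m(log_q):
    """log_q: dict gene -> list of log2 quantities."""
    genes = list(log_q)
    m = {}
    for j in genes:
        variations = []
        for k in genes:
            if k == j:
                continue
            ratios = [a - b for a, b in zip(log_q[j], log_q[k])]
            variations.append(statistics.stdev(ratios))
        m[j] = sum(variations) / len(variations)
    return m


def brute_genorm_exclusion(log_q):
    remaining = dict(log_q)
    order = []
    while len(remaining) > 2:
        m = brute_genorm_m(remaining)
        worst_value = max(m.values())
        worst = max(g for g, v in m.items() if v == worst_value)
        del remaining[worst]
        order.append(worst)
    return order, sorted(remaining)


def brute_deltact(ct_rows):
    genes = list(ct_rows)
    out = {}
    for i in genes:
        sds = []
        for j in genes:
            if j == i:
                continue
            deltas = [a - b for a, b in zip(ct_rows[i], ct_rows[j])]
            sds.append(statistics.stdev(deltas))
        out[i] = sum(sds) / len(sds)
    return out


def brute_normfinder_ungrouped(y_rows):
    genes = list(y_rows)
    n_samples = len(next(iter(y_rows.values())))
    col_means = [
        sum(y_rows[g][s] for g in genes) / len(genes) for s in range(n_samples)
    ]
    out = {}
    for g in genes:
        centered = [y_rows[g][s] - col_means[s] for s in range(n_samples)]
        out[g] = statistics.stdev(centered)
    return out


def brute_normfinder_grouped(y_rows, sample_groups):
    genes = list(y_rows)
    n_samples = len(sample_groups)
    groups = list(dict.fromkeys(sample_groups))
    members = {g: [s for s, lbl in enumerate(sample_groups) if lbl == g] for g in groups}
    col_means = [sum(y_rows[g][s] for g in genes) / len(genes) for s in range(n_samples)]

    gm = {
        (i, g): sum(y_rows[i][s] for s in members[g]) / len(members[g])
        for i in genes
        for g in groups
    }
    row_mean = {i: sum(gm[(i, g)] for g in groups) / len(groups) for i in genes}
    col_mean = {g: sum(gm[(i, g)] for i in genes) / len(genes) for g in groups}
    grand = sum(gm.values()) / len(gm)

    out = {}
    for i in genes:
        total = 0.0
        for g in groups:
            d = gm[(i, g)] - row_mean[i] - col_mean[g] + grand
            centered = [y_rows[i][s] - col_means[s] for s in members[g]]
            var_within = statistics.variance(centered)
            total += abs(d) + math.sqrt(var_within / len(members[g]))
        out[i] = total / len(groups)
    return out


# ----------------------------------------------------------- ct_to_quantity

class TestCtToQuantity:
    def test_powers_of_two(self):
        ct = ct_matrix([[20.0, 21.0, 23.0]])
        q = ct_to_quantity(ct)
        assert q.quantities[0].tolist() == pytest.approx([1.0, 0.5, 0.125])

    def test_constant_row_all_ones(self):
        q = ct_to_quantity(ct_matrix([[25.0] * 4]))
        assert np.allclose(q.quantities, 1.0)

    def test_custom_efficiency(self):
        ct = ct_matrix([[20.0, 21.0]], efficiencies={"G00": 1.05})
        q = ct_to_quantity(ct)
        assert q.quantities[0, 1] == pytest.approx(1 / 2.05)

    def test_minimum_ct_sample_maps_to_one(self, rng):
        ct = random_ct_matrix(rng, n_genes=6, n_samples=9)
        q = ct_to_quantity(ct)
        assert np.allclose(q.quantities.max(axis=1), 1.0)
        assert np.all(q.quantities > 0)


class TestDilutionSeries:
    def test_perfect_doubling_gives_e_of_one(self):
        series = DilutionSeries.two_fold(100.0, 8)
        # slope exactly -1: Ct rises one cycle per halving
        ct = 15.0 - np.log2(series.inputs_ng / 100.0)
        fit = amplification_efficiency(DilutionSeries(series.inputs_ng, ct))
        assert fit.efficiency == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_for_other_slope(self):
        series = DilutionSeries.two_fold(100.0, 8)
        ct = 15.0 - 0.93 * np.log2(series.inputs_ng)
        fit = amplification_efficiency(DilutionSeries(series.inputs_ng, ct))
        assert fit.efficiency == pytest.approx(2 ** (1 / 0.93) - 1, abs=1e-9)

    def test_eight_point_lowest_input(self):
        series = DilutionSeries.two_fold(100.0, 8)
        assert series.lowest_input_ng == pytest.approx(100.0 / 2**7)
        assert round(series.lowest_input_ng, 2) == 0.78

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match=">=3"):
            DilutionSeries(np.array([100.0, 50.0]))

    def test_spacing_enforced(self):
        with pytest.raises(ValueError, match="factor of 2"):
            DilutionSeries(np.array([100.0, 50.0, 20.0]))

    def test_missing_ct_is_error(self):
        with pytest.raises(ValueError, match="no Ct"):
            amplification_efficiency(DilutionSeries.two_fold(100.0, 4))


# ----------------------------------------------------------------- geNorm

class TestGenormM:
    def test_proportional_pair_has_zero_m(self):
        # constant Ct offset -> constant quantity ratio
        ct = ct_matrix([[20.0, 22.0, 24.0], [21.0, 23.0, 25.0]])
        m = genorm_m(ct_to_quantity(ct))
        assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_pair_variation(self):
        # log2 ratios between the genes are (0, 1, 0, 1): sd = 0.5774
        ct = ct_matrix([[20.0, 20.0, 20.0, 20.0], [20.0, 19.0, 20.0, 19.0]])
        m = genorm_m(ct_to_quantity(ct))
        expected = statistics.stdev([0, 1, 0, 1])
        assert m.to_numpy() == pytest.approx([expected, expected])
        assert expected == pytest.approx(0.57735, abs=1e-5)

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            ct = random_ct_matrix(rng, n_genes=5, n_samples=8)
            q = ct_to_quantity(ct)
            m = genorm_m(q)
            log_q = {g: list(np.log2(q.quantities[i])) for i, g in enumerate(q.gene_ids)}
            expected = brute_genorm_m(log_q)
            for gene in q.gene_ids:
                assert m[gene] == pytest.approx(expected[gene], abs=1e-9)

    def test_invariant_under_sample_permutation(self, rng):
        ct = random_ct_matrix(rng, n_genes=4, n_samples=7)
        q = ct_to_quantity(ct)
        perm = rng.permutation(7)
        q2 = RelativeQuantityMatrix(
            gene_ids=q.gene_ids,
            sample_ids=[q.sample_ids[i] for i in perm],
            quantities=q.quantities[:, perm],
        )
        assert np.allclose(genorm_m(q).to_numpy(), genorm_m(q2).to_numpy())

    def test_requires_two_genes(self):
        with pytest.raises(ValueError, match=">=2 genes"):
            genorm_m(ct_to_quantity(ct_matrix([[20.0, 21.0]])))


class TestGenormRank:
    def test_noisy_gene_removed_first(self):
        ct = ct_matrix(
            [
                [20.0, 22.0, 24.0, 21.0],
                [21.0, 23.0, 25.0, 22.0],  # proportional to G00
                [25.0, 18.0, 30.0, 22.0],  # noisy
            ]
        )
        ranking = genorm_rank(ct_to_quantity(ct))
        assert ranking.exclusion_order == ["G02"]
        assert ranking.ranks["G00"] == 1.5 and ranking.ranks["G01"] == 1.5
        assert ranking.ranks["G02"] == 3.0

    def test_all_proportional_v_series_zero(self):
        base = np.array([20.0, 22.0, 24.0, 21.0, 23.0])
        ct = ct_matrix([base, base + 1.0, base + 2.0, base - 0.5])
        ranking = genorm_rank(ct_to_quantity(ct))
        assert all(abs(v) < 1e-12 for v in ranking.pairwise_variation.values())
        assert set(ranking.pairwise_variation) == {"V2/3", "V3/4"}

    def test_oracle_equivalence_of_exclusion_order(self, rng):
        for _ in range(10):
            ct = random_ct_matrix(rng, n_genes=6, n_samples=10)
            q = ct_to_quantity(ct)
            ranking = genorm_rank(q)
            log_q = {g: list(np.log2(q.quantities[i])) for i, g in enumerate(q.gene_ids)}
            order, final_pair = brute_genorm_exclusion(log_q)
            assert ranking.exclusion_order == order
            assert sorted(ranking.inclusion_order[:2]) == final_pair

    def test_v_series_length(self, rng):
        ct = random_ct_matrix(rng, n_genes=7, n_samples=6)
        ranking = genorm_rank(ct_to_quantity(ct))
        assert len(ranking.pairwise_variation) == 7 - 2

    def test_requires_three_genes(self):
        ct = ct_matrix([[20.0, 21.0], [22.0, 23.0]])
        with pytest.raises(ValueError, match=">=3"):
            genorm_rank(ct_to_quantity(ct))


# -------------------------------------------------------------- NormFinder

class TestNormfinder:
    def test_identical_patterns_zero_stability_ungrouped(self):
        base = np.array([20.0, 22.0, 21.0, 23.0])
        ct = ct_matrix([base, base + 1, base + 2])
        stability = normfinder_stability(ct)
        assert np.allclose(stability.to_numpy(), 0.0, atol=1e-12)

    def test_identical_patterns_zero_stability_grouped(self):
        base = np.array([20.0, 22.0, 20.0, 22.0])
        groups = {"S00": "A", "S01": "A", "S02": "B", "S03": "B"}
        ct = ct_matrix([base, base + 1, base + 2], groups=groups)
        stability = normfinder_stability(ct)
        assert np.allclose(stability.to_numpy(), 0.0, atol=1e-12)

    def test_interaction_gene_scores_highest(self):
        # zero within-group noise; G00 is +1 cycle in group A, -1 in group B
        k = 5
        base = np.full((k, 6), 22.0) + np.arange(k)[:, None]
        base[0, :3] += 1.0
        base[0, 3:] -= 1.0
        groups = {f"S{j:02d}": ("A" if j < 3 else "B") for j in range(6)}
        ct = ct_matrix(base, groups=groups)
        stability = normfinder_stability(ct)
        # |d| per group = (k-1)/k for the offset gene, 1/k for the rest
        assert stability["G00"] == pytest.approx((k - 1) / k, abs=1e-12)
        assert np.allclose(stability.drop("G00").to_numpy(), 1 / k, atol=1e-12)
        assert stability.idxmax() == "G00"

    def test_oracle_equivalence_ungrouped(self, rng):
        for _ in range(10):
            ct = random_ct_matrix(rng, n_genes=5, n_samples=7)
            stability = normfinder_stability(ct)
            y_rows = {
                g: list(-ct.ct_values[i]) for i, g in enumerate(ct.gene_ids)
            }
            expected = brute_normfinder_ungrouped(y_rows)
            for gene in ct.gene_ids:
                assert stability[gene] == pytest.approx(expected[gene], abs=1e-9)

    def test_oracle_equivalence_grouped(self, rng):
        sample_groups = ["A", "A", "A", "B", "B", "C", "C", "C"]
        for _ in range(10):
            groups = {f"S{j:02d}": g for j, g in enumerate(sample_groups)}
            ct = random_ct_matrix(rng, n_genes=5, n_samples=8, groups=groups)
            stability = normfinder_stability(ct)
            y_rows = {g: list(-ct.ct_values[i]) for i, g in enumerate(ct.gene_ids)}
            expected = brute_normfinder_grouped(y_rows, sample_groups)
            for gene in ct.gene_ids:
                assert stability[gene] == pytest.approx(expected[gene], abs=1e-9)

    def test_singleton_group_instructs_ungrouped(self):
        groups = {"S00": "A", "S01": "A", "S02": "B"}
        ct = ct_matrix(np.full((3, 3), 20.0), groups=groups)
        with pytest.raises(ValueError, match="use_groups=False"):
            normfinder_stability(ct)

    def test_requires_three_genes(self):
        with pytest.raises(ValueError, match=">=3 genes"):
            normfinder_stability(ct_matrix([[20.0, 21.0], [22.0, 23.0]]))


# ---------------------------------------------------------------- delta-Ct

class TestDeltact:
    def test_constant_offset_zero_stability(self):
        base = np.array([20.0, 22.0, 24.0])
        stability = deltact_stability(ct_matrix([base, base + 3]))
        assert np.allclose(stability.to_numpy(), 0.0, atol=1e-12)

    def test_identity_with_genorm_m_at_unit_efficiency(self, rng):
        # log2 quantity ratio = -(Ct_i - Ct_j) when E = 1 for all genes
        for _ in range(10):
            ct = random_ct_matrix(rng, n_genes=4, n_samples=6)
            dct = deltact_stability(ct)
            m = genorm_m(ct_to_quantity(ct))
            assert np.allclose(dct.to_numpy(), m.to_numpy(), atol=1e-9)

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            ct = random_ct_matrix(rng, n_genes=4, n_samples=6)
            stability = deltact_stability(ct)
            rows = {g: list(ct.ct_values[i]) for i, g in enumerate(ct.gene_ids)}
            expected = brute_deltact(rows)
            for gene in ct.gene_ids:
                assert stability[gene] == pytest.approx(expected[gene], abs=1e-9)

    def test_requires_two_genes(self):
        with pytest.raises(ValueError, match=">=2 genes"):
            deltact_stability(ct_matrix([[20.0, 21.0]]))


# --------------------------------------------------- comprehensive ranking

class TestComprehensiveRank:
    def scores(self, genorm, normfinder, deltact, genes=None):
        genes = genes or [f"G{i:02d}" for i in range(len(genorm))]
        return pd.DataFrame(
            {"genorm": genorm, "normfinder": normfinder, "deltact": deltact},
            index=pd.Index(genes, name="gene"),
        )

    def test_unanimous_best(self):
        out = comprehensive_rank(self.scores([0.1, 0.5], [0.2, 0.9], [0.1, 0.4]))
        assert out.loc["G00", "comprehensive_score"] == pytest.approx(1.0)
        assert out.loc["G00", "comprehensive_rank"] == 1.0

    def test_geometric_mean_of_ranks(self):
        # G00 gets ranks (1, 2, 4) -> (1 * 2 * 4)^(1/3) = 2
        out = comprehensive_rank(
            self.scores(
                genorm=[0.1, 0.2, 0.3, 0.4],
                normfinder=[0.2, 0.1, 0.3, 0.4],
                deltact=[0.4, 0.1, 0.2, 0.3],
            )
        )
        ranks = out.loc["G00", ["genorm_rank", "normfinder_rank", "deltact_rank"]]
        assert ranks.tolist() == [1.0, 2.0, 4.0]
        assert out.loc["G00", "comprehensive_score"] == pytest.approx(2.0)

    def test_ties_get_average_ranks(self):
        out = comprehensive_rank(self.scores([0.1, 0.1, 0.3], [1, 2, 3], [1, 2, 3]))
        assert out.loc["G00", "genorm_rank"] == 1.5
        assert out.loc["G01", "genorm_rank"] == 1.5

    def test_missing_score_names_gene_and_method(self):
        scores = self.scores([0.1, np.nan], [0.2, 0.3], [0.1, 0.2])
        with pytest.raises(ValueError, match="genorm.*G01"):
            comprehensive_rank(scores)

    def test_invariant_under_monotone_transform(self, rng):
        raw = self.scores(
            rng.uniform(0, 1, 6), rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        )
        out1 = comprehensive_rank(raw)
        transformed = raw.copy()
        transformed["genorm"] = np.exp(5 * transformed["genorm"])
        transformed["deltact"] = transformed["deltact"] ** 3
        out2 = comprehensive_rank(transformed)
        for col in ("genorm_rank", "normfinder_rank", "deltact_rank",
                    "comprehensive_score", "comprehensive_rank"):
            assert np.allclose(out1[col].to_numpy(), out2[col].to_numpy())


class TestWorstGeneAgreement:
    def test_high_noise_gene_scores_worst_in_all_methods(self):
        successes = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            signal = rng.uniform(18, 26, size=8)
            rows = [signal + rng.normal(0, 0.2, 8) for _ in range(5)]
            rows.append(signal + rng.normal(0, 2.0, 8))  # 10x noise
            ct = ct_matrix(np.clip(rows, 1.0, 45.0))
            noisy = ct.gene_ids[-1]
            ok = (
                genorm_m(ct_to_quantity(ct)).idxmax() == noisy
                and normfinder_stability(ct).idxmax() == noisy
                and deltact_stability(ct).idxmax() == noisy
            )
            successes += ok
        assert successes >= n_seeds - 1


class TestStabilityReport:
    def test_full_report_structure(self, rng):
        ct = random_ct_matrix(rng, n_genes=6, n_samples=8)
        report = stability_report(ct)
        table = report.ordered()
        assert list(table.columns) == [
            "genorm_M", "genorm_rank", "normfinder_stability", "normfinder_rank",
            "deltact_stability", "deltact_rank", "comprehensive_score",
            "comprehensive_rank",
        ]
        assert table["comprehensive_rank"].tolist() == list(range(1, 7))
        assert (table["comprehensive_score"] >= 1.0).all()
        assert len(report.genorm.pairwise_variation) == 4
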