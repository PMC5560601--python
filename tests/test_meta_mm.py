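import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcsig.meta_mm import (Study, consistent_dysregulated, gep70_score,
                           per_study_top_de, risk_screen, shared_universe,
                           signature_imbalance)
from pcsig.signatures import SignatureSet
from pcsig.synth import ImbalanceSpec, generate_gammopathy_studies


def _signatures(n_genes=800, size=100):
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    return genes, {
        "PC-up": SignatureSet("PC-up", "up", frozenset(genes[:size])),
        "PC-down": SignatureSet("PC-down", "down",
                                frozenset(genes[size:2 * size])),
    }


@pytest.fixture(scope="module")
def gammopathy():
    genes, sigs = _signatures()
    imbalance = [
        ImbalanceSpec("PC-up", "up", 0.6, {"MGUS": 0.5, "MM": 1.5}),
        ImbalanceSpec("PC-down", "down", 0.4, {"MGUS": 0.5, "MM": 1.5}),
    ]
    studies, truth = generate_gammopathy_studies(
        3, {"healthy": 8, "MGUS": 8, "MM": 8}, sigs, imbalance,
        n_genes=800, n_background_dysregulated=100, platform_shift=0.3,
        seed=13)
    return {"studies": studies, "truth": truth, "signatures": sigs}


class TestTopDE:
    def test_top_list_capped_and_sorted(self, gammopathy):
        top = per_study_top_de(gammopathy["studies"][0], "MM", k=50)
        assert len(top) == 50
        assert top["p"].is_monotonic_increasing
        assert (top["adj_p"] < 0.1).all()

    def test_planted_genes_dominate_top_list(self, gammopathy):
        truth = gammopathy["truth"]
        planted = set(truth.study_dysregulation["PC-up:up"]["genes"])
        top = per_study_top_de(gammopathy["studies"][0], "MM", k=1000)
        # every planted up gene reaches the significant list in MM
        assert len(planted & set(top.index)) / len(planted) > 0.9

    def test_duplicated_studies_identical_lists(self, gammopathy):
        s = gammopathy["studies"][0]
        a = per_study_top_de(s, "MM", k=100)
        b = per_study_top_de(s, "MM", k=100)
        assert a.equals(b)

    def test_missing_stage_rejected(self, gammopathy):
        with pytest.raises(KeyError):
            per_study_top_de(gammopathy["studies"][0], "SMM")


class TestConsistent:
    @staticmethod
    def _top(genes_dirs):
        return pd.DataFrame(
            {"log2FC": 1.0, "p": 1e-4, "adj_p": 1e-3,
             "direction": [d for _, d in genes_dirs]},
            index=[g for g, _ in genes_dirs])

    def test_min_one_is_union(self):
        a = self._top([("g1", "up")])
        b = self._top([("g2", "down")])
        out = consistent_dysregulated([a, b], min_studies=1)
        assert set(out.index) == {"g1", "g2"}

    def test_direction_conflict_excluded(self):
        a = self._top([("g1", "up")])
        b = self._top([("g1", "down")])
        out = consistent_dysregulated([a, b], min_studies=1)
        assert "g1" not in out.index

    def test_monotone_in_min_studies(self, gammopathy):
        tops = [per_study_top_de(s, "MM", k=300)
                for s in gammopathy["studies"]]
        sets = [set(consistent_dysregulated(tops, min_studies=m).index)
                for m in (1, 2, 3)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_recovers_planted_shared_genes(self, gammopathy):
        truth = gammopathy["truth"]
        planted = set(truth.study_dysregulation["PC-up:up"]["genes"])
        tops = [per_study_top_de(s, "MM", k=500)
                for s in gammopathy["studies"]]
        out = consistent_dysregulated(tops, min_studies=2)
        assert len(planted & set(out.index)) / len(planted) >= 0.95


class TestImbalance:
    def test_no_overlap_all_zero(self):
        _, sigs = _signatures()
        consistent = pd.DataFrame({"direction": ["up"], "n_studies": [2]},
                                  index=["ALIEN"])
        report = signature_imbalance({"MM": consistent}, sigs)
        assert (report["count"] == 0).all()

    def test_percentages_recompute_from_counts(self, gammopathy):
        tops = {s: [per_study_top_de(st, s, k=300)
                    for st in gammopathy["studies"]]
                for s in ("MGUS", "MM")}
        consistent = {s: consistent_dysregulated(t) for s, t in tops.items()}
        report = signature_imbalance(consistent, gammopathy["signatures"],
                                     tops)
        for _, row in report.iterrows():
            size = len(gammopathy["signatures"][row["signature"]])
            assert row["pct_of_signature"] == pytest.approx(
                100.0 * row["count"] / size)
            assert row["n_studies"] == 3

    def test_exacerbation_pattern_mm_exceeds_mgus(self, gammopathy):
        """Planted stage-graded dysregulation shows up as a larger
        dysregulated share of the signature in MM than in MGUS."""
        tops = {s: [per_study_top_de(st, s, k=300)
                    for st in gammopathy["studies"]]
                for s in ("MGUS", "MM")}
        consistent = {s: consistent_dysregulated(t) for s, t in tops.items()}
        report = signature_imbalance(consistent, gammopathy["signatures"])
        pick = report.set_index(["stage", "signature", "dysregulation"])
        assert pick.loc[("MM", "PC-up", "up"), "pct_of_signature"] > \
            pick.loc[("MGUS", "PC-up", "up"), "pct_of_signature"]
        assert pick.loc[("MM", "PC-up", "up"), "pct_of_signature"] > \
            pick.loc[("MM", "PC-up", "down"), "pct_of_signature"]


class TestGep70:
    def test_constant_matrix_mean_all(self):
        m = pd.DataFrame(3.0, index=[f"p{i}" for i in range(70)],
                         columns=["s1", "s2"])
        score = gep70_score(m, list(m.index))
        assert (score == 3.0).all()

    def test_constant_matrix_up_minus_down_zero(self):
        m = pd.DataFrame(3.0, index=[f"p{i}" for i in range(70)],
                         columns=["s1"])
        score = gep70_score(m, list(m.index[:51]), list(m.index[51:]),
                            mode="up_minus_down")
        assert score.iloc[0] == 0.0

    def test_matches_arithmetic_oracle(self, rng):
        m = pd.DataFrame(rng.normal(8, 1, (70, 5)),
                         index=[f"p{i}" for i in range(70)],
                         columns=[f"s{i}" for i in range(5)])
        up, down = list(m.index[:51]), list(m.index[51:])
        assert np.allclose(gep70_score(m, up + down),
                           m.to_numpy().mean(axis=0))
        assert np.allclose(
            gep70_score(m, up, down, mode="up_minus_down"),
            m.loc[up].to_numpy().mean(axis=0)
            - m.loc[down].to_numpy().mean(axis=0))

    def test_missing_probe_is_an_error(self):
        m = pd.DataFrame(1.0, index=["p1"], columns=["s1"])
        with pytest.raises(KeyError, match="p2"):
            gep70_score(m, ["p1", "p2"])


def _risk_dataset(rng, n_samples, gene_rows):
    m = pd.DataFrame(gene_rows,
                     columns=[f"s{i}" for i in range(n_samples)])
    score = pd.Series(rng.normal(size=n_samples), index=m.columns,
                      name="score")
    return m, score


class TestRiskScreen:
    def test_gene_equal_to_score_is_high_risk(self, rng):
        datasets = []
        for n in (20, 30):
            score = pd.Series(rng.normal(size=n),
                              index=[f"s{i}" for i in range(n)])
            m = pd.DataFrame([score.to_numpy()], index=["g1"],
                             columns=score.index)
            datasets.append((m, score))
        out = risk_screen(datasets, {"g1"})
        assert bool(out.loc["g1", "consistent"])
        assert out.loc["g1", "risk_class"] == "high"
        assert out.loc["g1", "r_0"] == pytest.approx(1.0)

    def test_anticorrelated_gene_is_low_risk(self, rng):
        datasets = []
        for n in (40, 40):
            score = pd.Series(rng.normal(size=n),
                              index=[f"s{i}" for i in range(n)])
            m = pd.DataFrame([-score.to_numpy()], index=["g1"],
                             columns=score.index)
            datasets.append((m, score))
        out = risk_screen(datasets, {"g1"})
        assert out.loc["g1", "risk_class"] == "low"

    def test_zero_variance_gene_not_consistent(self, rng):
        score = pd.Series(rng.normal(size=20),
                          index=[f"s{i}" for i in range(20)])
        m = pd.DataFrame([np.ones(20), score.to_numpy()],
                         index=["flat", "hit"], columns=score.index)
        out = risk_screen([(m, score), (m, score)], {"flat", "hit"})
        assert not out.loc["flat", "consistent"]
        assert out.loc["hit", "consistent"]

    def test_p_matches_exact_t_transform(self, rng):
        n = 30
        score = pd.Series(rng.normal(size=n),
                          index=[f"s{i}" for i in range(n)])
        gene = 0.5 * score.to_numpy() + rng.normal(size=n)
        m = pd.DataFrame([gene], index=["g1"], columns=score.index)
        out = risk_screen([(m, score), (m, score)], {"g1"})
        r = out.loc["g1", "r_0"]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert out.loc["g1", "p_0"] == pytest.approx(
            2 * stats.t.sf(abs(t), n - 2))

    def test_classes_disjoint_and_exhaustive(self, rng):
        genes = [f"g{i}" for i in range(50)]
        datasets = []
        for n in (40, 50):
            score = pd.Series(rng.normal(size=n),
                              index=[f"s{i}" for i in range(n)])
            rows = [0.8 * score.to_numpy() + rng.normal(size=n)
                    for _ in genes]
            datasets.append((pd.DataFrame(rows, index=genes,
                                          columns=score.index), score))
        out = risk_screen(datasets, set(genes))
        consistent = out[out["consistent"]]
        assert set(consistent["risk_class"]) <= {"low", "high"}
        assert (out.loc[~out["consistent"], "risk_class"] == "").all()

    def test_fewer_than_two_datasets_rejected(self, rng):
        score = pd.Series(rng.normal(size=20),
                          index=[f"s{i}" for i in range(20)])
        m = pd.DataFrame([score.to_numpy()], index=["g1"],
                         columns=score.index)
        with pytest.raises(ValueError):
            risk_screen([(m, score)], {"g1"})


class TestSharedUniverse:
    def test_intersection_across_studies(self, rng):
        def study(sid, genes):
            m = pd.DataFrame(rng.normal(size=(len(genes), 4)), index=genes,
                             columns=[f"{sid}_s{i}" for i in range(4)])
            d = pd.DataFrame({"sample_id": m.columns, "group": "healthy",
                              "study": sid, "stage": "healthy"}
                             ).set_index("sample_id", drop=False)
            return Study(sid, m, d)
        a = study("a", ["g1", "g2", "g3"])
        b = study("b", ["g2", "g3", "g4"])
        assert list(shared_universe([a, b])) == ["g2", "g3"]
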