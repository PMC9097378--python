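"""Normalisation, DE calling, pattern clustering and TE-gene concordance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from telocus import (
    call_de,
    cluster_patterns,
    de_test,
    log2fc,
    pair_and_concordance,
    run_timecourse_de,
    size_factors,
)
from telocus.config import AnalysisConfig
from telocus.differential_expression import (
    lfc_matrix,
    name_pattern,
    normalize_counts,
    read_external_de,
)
from telocus.locus_characterization import CompartmentAssignment
from telocus.synthetic_data import (
    DE_ARCHETYPES,
    CountPlan,
    concordance_count_plan,
    simulate_counts,
)


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_library(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        f = size_factors(counts)
        assert f["A"] == pytest.approx(1 / np.sqrt(2))
        assert f["B"] == pytest.approx(np.sqrt(2))

    def test_global_rescaling_leaves_relative_factors(self, rng):
        # the per-feature geometric mean rescales with the counts, so the
        # median-of-ratios factors are invariant under a global rescale;
        # scaling a single sample scales only its own factor direction
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 4)),
                              columns=list("abcd"))
        f1 = size_factors(counts)
        f2 = size_factors(counts * 3)
        assert f2.to_numpy() == pytest.approx(f1.to_numpy())

    def test_no_common_nonzero_feature_errors(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)


class TestLog2FC:
    def make(self):
        return pd.DataFrame({
            "t1": [100.0, 400.0], "t2": [100.0, 400.0],
            "b1": [100.0, 100.0], "b2": [100.0, 100.0],
        }, index=["flat", "up"])

    def test_equal_means_zero(self):
        v = log2fc(self.make(), ["t1", "t2"], ["b1", "b2"], pseudocount=1)
        assert v["flat"] == 0.0

    def test_fourfold_shift(self):
        v = log2fc(self.make(), ["t1", "t2"], ["b1", "b2"], pseudocount=0.01)
        assert v["up"] == pytest.approx(2.0, abs=0.01)

    def test_antisymmetry(self):
        m = self.make()
        a = log2fc(m, ["t1", "t2"], ["b1", "b2"], pseudocount=1)
        b = log2fc(m, ["b1", "b2"], ["t1", "t2"], pseudocount=1)
        assert a.to_numpy() == pytest.approx(-b.to_numpy())


class TestDETest:
    def test_identical_groups_not_significant(self, rng):
        x = rng.integers(50, 150, size=(40, 3)).astype(float)
        counts = pd.DataFrame(np.hstack([x, x]),
                              columns=["t1", "t2", "t3", "b1", "b2", "b3"])
        padj = de_test(counts, ["t1", "t2", "t3"], ["b1", "b2", "b3"])
        assert (padj > 0.5).all()

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"t1": [1.0], "b1": [1.0], "b2": [2.0]})
        with pytest.raises(ValueError, match="replicates"):
            de_test(counts, ["t1"], ["b1", "b2"])

    def test_planted_eightfold_shift_detected(self):
        """An 8-fold shift with NB dispersion 0.1 and n=3 reaches BH
        significance in >= 95% of seeded simulations."""
        hits = 0
        n_sims = 40
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            n, disp = 60, 0.1
            base_mean = np.full(n, 100.0)
            trt_mean = base_mean.copy()
            trt_mean[0] *= 8.0
            r = 1.0 / disp
            base = rng.negative_binomial(r, r / (r + base_mean[:, None]), size=(n, 3))
            trt = rng.negative_binomial(r, r / (r + trt_mean[:, None]), size=(n, 3))
            counts = pd.DataFrame(
                np.hstack([trt, base]).astype(float),
                columns=["t1", "t2", "t3", "b1", "b2", "b3"],
            )
            padj = de_test(counts, ["t1", "t2", "t3"], ["b1", "b2", "b3"])
            hits += padj.iloc[0] < 0.05
        assert hits / n_sims >= 0.95

    def test_bh_adjustment_matches_reference(self, rng):
        p = rng.random(200) ** 2
        _r, ref, _a, _b = multipletests(p, method="fdr_bh")
        # BH never reports adjusted p below the raw p
        assert (ref >= p - 1e-12).all()


class TestCallDE:
    def fake(self, lfc_profile, padj_profile):
        tps = ("1h", "3h", "6h", "12h")
        lfc = {tp: pd.Series({"f": v}) for tp, v in zip(tps, lfc_profile)}
        padj = {tp: pd.Series({"f": v}) for tp, v in zip(tps, padj_profile)}
        return call_de(lfc, padj)[0]

    def test_single_timepoint_hit_suffices(self):
        r = self.fake([0.1, 2.0, 0.2, 0.0], [0.9, 0.01, 0.9, 0.9])
        assert r.is_de and r.direction == "up"

    def test_effect_size_gate(self):
        r = self.fake([0.9, 0.9, 0.9, 0.9], [1e-6] * 4)
        assert not r.is_de

    def test_two_sided_default_catches_downregulation(self):
        r = self.fake([-2.0, -1.5, 0.0, 0.0], [0.001, 0.01, 0.9, 0.9])
        assert r.is_de and r.direction == "down"

    def test_one_sided_mode_ignores_downregulation(self):
        tps = ("1h", "3h", "6h", "12h")
        lfc = {tp: pd.Series({"f": -2.0}) for tp in tps}
        padj = {tp: pd.Series({"f": 0.001}) for tp in tps}
        cfg = AnalysisConfig(de_two_sided=False)
        assert not call_de(lfc, padj, cfg)[0].is_de

    def test_external_de_table_port(self, tmp_path):
        df = pd.DataFrame({
            "feature": ["f", "f", "f", "f"],
            "timepoint": ["1h", "3h", "6h", "12h"],
            "lfc": [0.0, 3.0, 0.0, 0.0],
            "padj": [1.0, 0.001, 1.0, 1.0],
        })
        path = tmp_path / "de.tsv"
        df.to_csv(path, sep="\t", index=False)
        lfc, padj = read_external_de(path)
        assert call_de(lfc, padj)[0].is_de


class TestClustering:
    def test_identical_profiles_share_cluster(self):
        m = pd.DataFrame([[2, 2, 1, 0], [2, 2, 1, 0], [-2, -2, -1, 0]],
                         index=["a", "b", "c"], columns=["1h", "3h", "6h", "12h"])
        labels, _names = cluster_patterns(m, k=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_opposite_profiles_split(self):
        m = pd.DataFrame([[2, 2, 2, 2], [-2, -2, -2, -2]], index=["a", "b"])
        labels, _ = cluster_patterns(m, k=2)
        assert labels["a"] != labels["b"]

    def test_k_larger_than_cohort_rejected(self):
        m = pd.DataFrame([[1, 1, 1, 1], [0, 0, 0, 0]])
        with pytest.raises(ValueError):
            cluster_patterns(m, k=5)

    def test_pattern_names(self):
        assert name_pattern([1.5, 2.5, 1.0, 0.0]) == "up-back"
        assert name_pattern([0.8, 1.6, 2.2, 2.6]) == "up"
        assert name_pattern([-0.8, -1.6, -2.2, -2.6]) == "down"
        assert name_pattern([0.1, -0.2, 0.0, 0.3]) == "flat"

    def test_planted_archetypes_recovered(self):
        """Three planted fold-change archetypes with sigma=0.3 noise cluster
        at adjusted Rand index >= 0.9."""
        rng = np.random.default_rng(5)
        archs = list(DE_ARCHETYPES)[:3]
        truth, rows = [], []
        for i in range(300):
            a = archs[i % 3]
            truth.append(a)
            rows.append(np.array(DE_ARCHETYPES[a]) + rng.normal(0, 0.3, 4))
        m = pd.DataFrame(rows, index=[f"f{i}" for i in range(300)])
        labels, _ = cluster_patterns(m, k=3)
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9


class TestPipelineRecovery:
    def test_planted_de_sensitivity_and_fdr(self):
        """Planted archetypes recovered at sensitivity >= 0.9 with empirical
        FDR <= 0.1 across seeded cohorts."""
        tps, fps, fns = 0, 0, 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            plan, _truth = concordance_count_plan(30, 0.9, rng)
            counts, design = simulate_counts(plan, seed=200 + seed)
            res = run_timecourse_de(counts, design, "treated", "mock")
            planted = {f for f, a in plan.feature_archetype.items() if a != "flat"}
            called = {r.feature_id for r in res if r.is_de}
            tps += len(planted & called)
            fps += len(called - planted)
            fns += len(planted - called)
        assert tps / (tps + fns) >= 0.9
        assert fps / max(tps + fps, 1) <= 0.1

    def test_null_counts_rarely_called(self):
        """Pure-noise counts produce DE calls for at most 5% of features."""
        rates = []
        for seed in range(5):
            plan = CountPlan(feature_archetype={f"f{i}": "flat" for i in range(100)})
            counts, design = simulate_counts(plan, seed=300 + seed)
            res = run_timecourse_de(counts, design, "treated", "mock")
            rates.append(sum(r.is_de for r in res) / len(res))
        assert float(np.mean(rates)) <= 0.05


class TestConcordance:
    def make_pairs(self, n_pairs=30, rate=0.9, seed=0):
        rng = np.random.default_rng(seed)
        plan, truth = concordance_count_plan(n_pairs, rate, rng)
        counts, design = simulate_counts(plan, seed=seed + 1)
        res = run_timecourse_de(counts, design, "treated", "mock")
        paired = {f for f in plan.feature_archetype if not f.startswith("bg")}
        mat = lfc_matrix(res, only_de=False).loc[sorted(paired)]
        labels, _ = cluster_patterns(mat, k=3)
        assignments = [
            CompartmentAssignment(locus_id=f"te{i+1}", region="genic",
                                  location="intron", gene_id=f"gene{i+1}")
            for i in range(n_pairs)
        ]
        dete = [f"te{i+1}" for i in range(n_pairs)]
        deg = [f"gene{i+1}" for i in range(n_pairs)]
        return truth, pair_and_concordance(dete, deg, assignments, labels)

    def test_identical_profiles_concordant(self):
        labels = pd.Series({"te1": 1, "gene1": 1})
        a = [CompartmentAssignment(locus_id="te1", region="genic",
                                   location="intron", gene_id="gene1")]
        pairs, frac = pair_and_concordance(["te1"], ["gene1"], a, labels)
        assert frac == 1.0 and pairs[0].concordant

    def test_opposite_profiles_discordant(self):
        labels = pd.Series({"te1": 1, "gene1": 2})
        a = [CompartmentAssignment(locus_id="te1", region="genic",
                                   location="intron", gene_id="gene1")]
        _pairs, frac = pair_and_concordance(["te1"], ["gene1"], a, labels)
        assert frac == 0.0

    def test_multi_deg_dete_yields_multiple_pairs(self):
        labels = pd.Series({"te1": 1, "geneA": 1, "geneB": 2})
        a = [
            CompartmentAssignment(locus_id="te1", region="genic",
                                  location="N-flank", gene_id="geneA"),
            CompartmentAssignment(locus_id="te1", region="genic",
                                  location="C-flank", gene_id="geneB"),
        ]
        pairs, frac = pair_and_concordance(["te1"], ["geneA", "geneB"], a, labels)
        assert len(pairs) == 2 and frac == 0.5

    def test_concordance_invariant_to_cluster_relabelling(self):
        labels = pd.Series({"te1": 1, "gene1": 1, "te2": 2, "gene2": 3})
        relabeled = labels.map({1: 9, 2: 7, 3: 5})
        a = [
            CompartmentAssignment(locus_id="te1", region="genic",
                                  location="intron", gene_id="gene1"),
            CompartmentAssignment(locus_id="te2", region="genic",
                                  location="intron", gene_id="gene2"),
        ]
        _p1, f1 = pair_and_concordance(["te1", "te2"], ["gene1", "gene2"], a, labels)
        _p2, f2 = pair_and_concordance(["te1", "te2"], ["gene1", "gene2"], a, relabeled)
        assert f1 == f2 == 0.5

    def test_planted_concordance_estimated_within_tolerance(self):
        """Mean estimated concordant fraction over seeded cohorts lands
        within 5 points of the planted 90% sharing rate."""
        fracs = []
        for seed in range(8):
            _truth, (pairs, frac) = self.make_pairs(seed=10 * seed)
            assert len(pairs) == 30
            fracs.append(frac)
        assert float(np.mean(fracs)) == pytest.approx(0.9, abs=0.05)
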