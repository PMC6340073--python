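import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

import lipi
from lipi.errors import DegenerateDataError, EvaluationError

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def cp_oracle(x, n, alpha=0.05):
    """Exact binomial CI by inverting the binomial tail with a root finder
    (independent of the beta-quantile route)."""
    lo = 0.0 if x == 0 else brentq(
        lambda p: binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-13)
    hi = 1.0 if x == n else brentq(
        lambda p: binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-13)
    return lo, hi


def auc_oracle(scores, labels):
    """Brute-force pair counting with ties counted one half."""
    cases = [s for s, l in zip(scores, labels) if l]
    controls = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else 0.5 if c == d else 0.0
    return total / (len(cases) * len(controls))


class TestClopperPearson:
    @pytest.mark.parametrize("x,n", [(3, 8), (1, 14), (10, 31), (7, 20)])
    def test_matches_binomial_tail_inversion(self, x, n):
        lo, hi = lipi.clopper_pearson(x, n)
        olo, ohi = cp_oracle(x, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)

    @pytest.mark.parametrize("n", [5, 10, 14, 37])
    def test_boundary_closed_forms(self, n):
        lo, hi = lipi.clopper_pearson(n, n)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / n), abs=1e-10)
        lo0, hi0 = lipi.clopper_pearson(0, n)
        assert lo0 == 0.0
        assert hi0 == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-10)


class TestDiagnosticMetrics:
    def test_published_cyc_th17_row(self):
        # 13 true positives, no false negatives, 2 false positives, 9 true
        # negatives: sens 100 (75.29-100), spec 81.82 (48.22-97.72),
        # LR+ 5.5, LR- 0.
        rep = lipi.diagnostic_metrics(lipi.ConfusionCounts(13, 0, 2, 9))
        assert rep.sens == 100.0
        assert rep.sens_ci[0] == pytest.approx(75.29, abs=5e-3)
        assert rep.spec == pytest.approx(81.82, abs=5e-3)
        assert rep.spec_ci == (pytest.approx(48.22, abs=5e-3),
                               pytest.approx(97.72, abs=5e-3))
        assert rep.lr_pos == pytest.approx(5.5)
        assert rep.lr_neg == 0.0

    def test_perfect_classifier_flags(self):
        rep = lipi.diagnostic_metrics(lipi.ConfusionCounts(5, 0, 0, 5))
        assert rep.sens == rep.spec == 100.0
        assert math.isinf(rep.lr_pos)
        assert rep.lr_neg == 0.0

    def test_symmetric_counts_with_oracle_cis(self):
        rep = lipi.diagnostic_metrics(lipi.ConfusionCounts(3, 1, 1, 3))
        assert rep.sens == rep.spec == 75.0
        assert rep.lr_pos == pytest.approx(3.0)
        assert rep.lr_neg == pytest.approx(1 / 3)
        lo, hi = cp_oracle(3, 4)
        assert rep.sens_ci[0] == pytest.approx(100 * lo, abs=1e-4)
        assert rep.sens_ci[1] == pytest.approx(100 * hi, abs=1e-4)

    def test_zero_specificity_lr_neg_undefined(self):
        rep = lipi.diagnostic_metrics(lipi.ConfusionCounts(3, 1, 4, 0))
        assert math.isnan(rep.lr_neg)

    def test_continuity_correction_gives_finite_lrs(self):
        rep = lipi.diagnostic_metrics(lipi.ConfusionCounts(5, 0, 0, 5),
                                      continuity=True)
        assert math.isfinite(rep.lr_pos)
        assert rep.lr_pos == pytest.approx((5.5 / 6) / (1 - 5.5 / 6))


class TestAucWithCi:
    def test_perfect_separation(self):
        res = lipi.auc_with_ci([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert res["auc"] == 1.0

    def test_four_pair_enumeration(self):
        # Pairs: 3>1, 3<4, 5>1, 5>4 -> 3 of 4 concordant.
        res = lipi.auc_with_ci([3, 5, 1, 4], [1, 1, 0, 0])
        assert res["auc"] == pytest.approx(auc_oracle([3, 5, 1, 4],
                                                      [1, 1, 0, 0]))
        assert res["auc"] == pytest.approx(3 / 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        scores = rng.integers(0, 6, n).astype(float)  # ties likely
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = lipi.auc_with_ci(scores, labels)
        assert res["auc"] == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, 30).astype(float)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = lipi.auc_with_ci(scores, labels)["auc"]
        b = lipi.auc_with_ci(-scores, labels)["auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_normal_approx_may_exceed_unit_interval(self):
        res = lipi.auc_with_ci([3, 4, 5, 9, 0, 1, 2, 3.5],
                               [1, 1, 1, 1, 0, 0, 0, 0],
                               method="normal-approx")
        assert res["ci"][1] > 1.0
        assert res["untruncated"]

    def test_single_class_errors(self):
        with pytest.raises(DegenerateDataError):
            lipi.auc_with_ci([1, 2], [1, 1])


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestDeLongAgainstPROC:
    def test_ci_and_paired_test_match_pROC(self, tmp_path):
        rng = np.random.default_rng(12)
        labels = np.r_[np.ones(12, bool), np.zeros(15, bool)]
        a = rng.standard_normal(27) + labels * 1.2
        b = rng.standard_normal(27) + labels * 0.5
        csv = tmp_path / "d.csv"
        pd.DataFrame({"label": labels.astype(int), "a": a, "b": b}).to_csv(
            csv, index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text(
            'suppressMessages(library(pROC))\n'
            'd <- read.csv(commandArgs(trailingOnly=TRUE)[1])\n'
            'r1 <- roc(d$label, d$a, quiet=TRUE, direction="<")\n'
            'r2 <- roc(d$label, d$b, quiet=TRUE, direction="<")\n'
            'ci1 <- ci.auc(r1, method="delong")\n'
            'tt <- roc.test(r1, r2, method="delong", paired=TRUE)\n'
            'cat(sprintf("%.12f %.12f %.12f", ci1[2], ci1[1], tt$p.value))\n')
        out = subprocess.run(["Rscript", str(rscript), str(csv)],
                             capture_output=True, text=True, check=True)
        r_auc, r_lo, r_p = map(float, out.stdout.split())
        res = lipi.auc_with_ci(a, labels)
        cmp = lipi.compare_auc(a, b, labels)
        assert res["auc"] == pytest.approx(r_auc, abs=1e-10)
        assert res["ci"][0] == pytest.approx(r_lo, abs=1e-10)
        assert cmp["p"] == pytest.approx(r_p, abs=1e-10)


class TestCompareAuc:
    def test_identical_scores(self):
        s = [1.0, 2.0, 3.0, 4.0]
        res = lipi.compare_auc(s, s, [1, 0, 1, 0])
        assert res["delta"] == 0.0
        assert res["p"] == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        labels = rng.random(40) < 0.5
        a = rng.standard_normal(40) + labels
        b = rng.standard_normal(40)
        r1 = lipi.compare_auc(a, b, labels)
        r2 = lipi.compare_auc(b, a, labels)
        assert r1["delta"] == pytest.approx(-r2["delta"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_agrees_with_permutation_reference(self):
        # Moderate-n sanity check: the asymptotic DeLong p should land near
        # a subject-swap permutation p.
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(25, bool), np.zeros(35, bool)]
        a = rng.standard_normal(60) + labels * 1.0
        b = rng.standard_normal(60) + labels * 0.6
        res = lipi.compare_auc(a, b, labels)
        obs = abs(res["delta"])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            swap = rng.random(60) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            d = (lipi.auc_with_ci(aa, labels)["auc"]
                 - lipi.auc_with_ci(bb, labels)["auc"])
            count += abs(d) >= obs - 1e-12
        assert abs(res["p"] - count / n_perm) < 0.1

    def test_unpaired_variant(self):
        rng = np.random.default_rng(9)
        la = rng.random(50) < 0.5
        lb = rng.random(60) < 0.5
        a = rng.standard_normal(50) + la
        b = rng.standard_normal(60) + lb
        res = lipi.compare_auc(a, b, la, labels_b=lb)
        assert 0 <= res["p"] <= 1


class TestEvaluateModels:
    def test_single_model_single_dataset(self, strong_cohort, published_index):
        reports = lipi.evaluate_models(strong_cohort, [published_index],
                                       datasets=("baseline",))
        assert len(reports) == 1
        rep = reports[0]
        assert rep.model == "lipi_v1"
        assert 0 <= rep.auc <= 1
        assert rep.sens_ci[0] <= rep.sens <= rep.sens_ci[1]

    def test_both_datasets_all_models(self, strong_cohort, published_index):
        single = lipi.IndexDefinition(
            name="th17_only", threshold=0.5,
            rules=[lipi.ScoreRule(feature="th17",
                                  kind="dichotomized-continuous",
                                  direction="greater", cutoff=8.0, points=1)])
        reports = lipi.evaluate_models(strong_cohort, [published_index, single])
        assert {(r.model, r.dataset) for r in reports} == {
            ("lipi_v1", "baseline"), ("lipi_v1", "nested"),
            ("th17_only", "baseline"), ("th17_only", "nested")}

    def test_compound_index_beats_single_rules(self, strong_cohort,
                                               published_index):
        singles = [
            lipi.IndexDefinition(name=r.feature, threshold=0.5, rules=[
                lipi.ScoreRule(feature=r.feature, kind=r.kind,
                               direction=r.direction, cutoff=r.cutoff,
                               points=1)])
            for r in published_index.rules]
        reports = lipi.evaluate_models(strong_cohort,
                                       [published_index] + singles,
                                       datasets=("baseline",))
        aucs = {r.model: r.auc for r in reports}
        assert aucs["lipi_v1"] > max(v for k, v in aucs.items()
                                     if k != "lipi_v1")

    def test_zero_infection_cohort_errors(self, tiny_cohort, published_index):
        cohort = lipi.Cohort(patients=tiny_cohort.patients[1:])
        with pytest.raises(EvaluationError):
            lipi.evaluate_models(cohort, [published_index],
                                 datasets=("baseline",))

    def test_report_frame_column_order(self, strong_cohort, published_index):
        reports = lipi.evaluate_models(strong_cohort, [published_index],
                                       datasets=("baseline",))
        frame = lipi.reports_to_frame(reports)
        assert list(frame.columns)[:6] == ["model", "dataset", "cutoff",
                                           "lr_pos", "lr_neg", "auc"]
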