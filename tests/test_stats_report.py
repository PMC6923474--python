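"""Group statistics and the end-to-end pipeline report."""

import json

import numpy as np
import pytest

from nmdarblock.exceptions import InsufficientDataError, ValidationError
from nmdarblock.stats_report import (
    anova_bonferroni,
    compare_groups,
    run_pipeline,
    significance_stars,
)


class TestTTest:
    def test_closed_form_example(self):
        """{1,2,3} vs {4,5,6}: pooled-variance t = −3/√(2/3) ≈ −3.674, 4 df."""
        cmp = compare_groups([1, 2, 3], [4, 5, 6])
        assert cmp.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert cmp.p == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups(self):
        cmp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.statistic == 0.0
        assert cmp.p == pytest.approx(1.0)

    def test_large_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        cmp = compare_groups(a, b)
        assert cmp.p < 1e-4
        assert cmp.stars == "****"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([2.0, 2.0], [3.0, 3.0])

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0])


class TestAnova:
    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0, 1, 8),
            "c": rng.normal(5, 1, 8),
        }
        res = anova_bonferroni(groups)
        assert res.p < 1e-4
        flagged = res.pairwise[res.pairwise["significant"]]
        assert set(flagged["group_b"]) | set(flagged["group_a"]) >= {"c"}

    def test_null_calibration(self):
        """Identically distributed groups: no pair flagged at family α=0.05
        in ≥90% of 100 seeds."""
        clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {k: rng.normal(0, 1, 6) for k in "abcd"}
            res = anova_bonferroni(groups)
            if not res.pairwise["significant"].any():
                clean += 1
        assert clean >= 90

    def test_needs_three_groups(self):
        with pytest.raises(InsufficientDataError):
            anova_bonferroni({"a": [1, 2], "b": [3, 4]})


def test_stars_convention():
    assert significance_stars(5e-5) == "****"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(0.02) == ""


@pytest.fixture(scope="module")
def small_report():
    return run_pipeline({"study": {"n_cells": 2, "noise_sd": 5.0}}, seed=3)


class TestPipeline:
    def test_deterministic_report(self, small_report):
        again = run_pipeline({"study": {"n_cells": 2, "noise_sd": 5.0}}, seed=3)
        assert json.dumps(small_report, sort_keys=True) == json.dumps(
            again, sort_keys=True
        )

    def test_report_serializable_and_complete(self, small_report):
        json.dumps(small_report)
        for stage in (
            "simulate", "dose_response", "kinetics", "ca_dependence",
            "woodhull", "surface", "trapping", "stats",
        ):
            assert small_report["stages"][stage]["status"] == "ok", stage

    def test_ic50_ordering_and_trapping_mode(self, small_report):
        stats = small_report["stages"]["stats"]["result"]
        assert stats["ic50_strictly_decreasing_in_ca"] is True
        assert (
            small_report["stages"]["trapping"]["result"]["mode"]
            == "partial_trapping"
        )

    def test_pure_block_config_has_flat_ca_dependence(self):
        """Negative control: without desensitization the Ca²⁺ stage reports a
        flat dependence (IC₅₀ ratio < 1.2 across the full Ca range)."""
        rep = run_pipeline(
            {
                "study": {
                    "n_cells": 2, "noise_sd": 2.0,
                    "include": ("dose_response",),
                    "ca_levels": (0.25, 1.0, 4.0),
                },
                "rates": {"k_des0": 0.0, "k_escape": 0.0},
            },
            seed=5,
        )
        dose = rep["stages"]["dose_response"]["result"]
        ics = [dose[k]["ic50_mean"] for k in sorted(dose, key=float)]
        assert max(ics) / min(ics) < 1.2
        ca_fit = rep["stages"]["ca_dependence"]["result"]
        flatness = np.exp(-0.25 / ca_fit["b_mM"]) / np.exp(-4.0 / ca_fit["b_mM"])
        assert flatness < 1.2
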