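"""Quantile ranking, hit calling, report assembly and Bland-Altman."""

import numpy as np
import pandas as pd
import pytest

from dspscreen import (
    CohortTable,
    DrugLibrary,
    DrugMetrics,
    DrugRecord,
    DrugStatus,
    HitCallConfig,
    ScoringError,
    bland_altman,
    build_report,
    call_hits,
    cohort_quantile,
    quantile_heatmap_order,
    waterfall_order,
)

GRID = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)


def _drug(drug_id="d1", status=DrugStatus.APPROVED, drug_class="kinase inhibitor",
          cmax=1e-6, name=None):
    return DrugRecord(drug_id=drug_id, name=name or drug_id, drug_class=drug_class,
                      concentrations=GRID, cmax=cmax, status=status)


def _metrics(drug_id="d1", **overrides):
    base = dict(
        drug_id=drug_id, dss_asym=30.0, sdss=15.0, inhibition_at_cmax=85.0,
        ic50_abs=1e-7, max_effect=92.0, r2=0.97,
    )
    base.update(overrides)
    return DrugMetrics(**base)


def _cohort_for(drug_id="d1", values=None, sample_id="s1", sample_value=30.0):
    values = values if values is not None else list(np.linspace(0.0, 10.0, 11))
    idx = [f"c{i}" for i in range(len(values))] + [sample_id]
    return CohortTable(pd.DataFrame({drug_id: values + [sample_value]}, index=idx))


class TestCohortQuantile:
    @pytest.mark.parametrize(
        "value,comparison,expected",
        [
            (5.0, [1, 2, 3, 4], 100.0),
            (0.0, [1, 2, 3, 4], 0.0),
            (2.0, [2, 2, 2], 0.0),        # ties are not 'lower'
            (2.5, [1, 2, 3, 4], 50.0),
        ],
    )
    def test_strict_counting(self, value, comparison, expected):
        q = cohort_quantile(value, [float(v) for v in comparison])
        assert q.quantile_pct == expected
        assert q.n_compared == len(comparison)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ScoringError):
            cohort_quantile(1.0, [])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            comparison = list(np.round(rng.normal(10, 5, n), 1))  # rounding makes ties
            value = float(np.round(rng.normal(10, 5), 1))
            brute = 100.0 * sum(1 for v in comparison if v < value) / n
            assert cohort_quantile(value, comparison).quantile_pct == pytest.approx(brute)

    def test_bounds_and_cohort_max(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 50, 20)
        for v in values:
            q = cohort_quantile(float(v), [float(u) for u in values if u != v])
            assert 0.0 <= q.quantile_pct <= 100.0
        top = float(values.max())
        q = cohort_quantile(top, [float(u) for u in values if u != top])
        assert q.quantile_pct == 100.0


class TestHitCalling:
    def test_planted_sensitive_profile_is_hit(self):
        lib = DrugLibrary(drugs=(_drug(),))
        cohort = _cohort_for()
        calls = call_hits([_metrics()], cohort, lib, sample_id="s1")
        assert calls[0].is_hit
        assert all(calls[0].flags.values())

    @pytest.mark.parametrize(
        "override,flag",
        [
            ({"max_effect": 60.0}, "max_effect_ge_75"),
            ({"r2": 0.7}, "r2_ge_080"),
            ({"ic50_abs": 5e-6}, "ic50_below_cmax"),
            ({"ic50_abs": None}, "ic50_below_cmax"),
            ({"inhibition_at_cmax": 40.0}, "inhibition_at_cmax_ge_50"),
            ({"sdss": -1.0}, "sdss_positive"),
        ],
    )
    def test_single_failing_criterion_blocks_hit(self, override, flag):
        lib = DrugLibrary(drugs=(_drug(),))
        calls = call_hits([_metrics(**override)], _cohort_for(), lib, sample_id="s1")
        assert not calls[0].is_hit
        failing = [k for k, v in calls[0].flags.items() if not v]
        assert failing == [flag]

    def test_below_quantile_threshold_blocks_hit(self):
        cohort = _cohort_for(values=list(np.linspace(0, 100, 11)))  # sample mid-pack
        lib = DrugLibrary(drugs=(_drug(),))
        calls = call_hits([_metrics(dss_asym=50.0)], cohort, lib, sample_id="s1")
        assert not calls[0].is_hit
        assert not calls[0].flags["quantile_ge_75"]

    def test_venetoclax_pattern_cmax_cutoff_only(self):
        """A BCL2-class approved drug failing only the 50%-at-Cmax cutoff is
        not reported as a hit."""
        lib = DrugLibrary(drugs=(_drug(drug_class="apoptotic modulator"),))
        calls = call_hits([_metrics(inhibition_at_cmax=42.0)], _cohort_for(), lib,
                          sample_id="s1")
        assert not calls[0].is_hit
        assert [k for k, v in calls[0].flags.items() if not v] == ["inhibition_at_cmax_ge_50"]

    def test_investigational_never_hit_but_supports_in_class(self):
        lib = DrugLibrary(drugs=(
            _drug("d1", DrugStatus.APPROVED, "apoptotic modulator"),
            _drug("d2", DrugStatus.INVESTIGATIONAL, "apoptotic modulator", name="inv-2"),
        ))
        cohort = CohortTable(pd.DataFrame(
            {"d1": list(range(11)) + [30], "d2": list(range(11)) + [30]},
            index=[f"c{i}" for i in range(11)] + ["s1"],
        ))
        calls = call_hits([_metrics("d1"), _metrics("d2")], cohort, lib, sample_id="s1")
        by_id = {c.drug_id: c for c in calls}
        assert by_id["d1"].is_hit
        assert not by_id["d2"].is_hit
        assert not by_id["d2"].flags["reportable_status"]
        assert by_id["d1"].in_class_support == ["inv-2"]

    def test_monotone_improvement_never_revokes_hit(self):
        lib = DrugLibrary(drugs=(_drug(),))
        cohort = _cohort_for()
        base = _metrics()
        assert call_hits([base], cohort, lib, sample_id="s1")[0].is_hit
        improved = [
            _metrics(max_effect=99.0),
            _metrics(ic50_abs=1e-9),
            _metrics(r2=0.999),
            _metrics(sdss=40.0),
            _metrics(inhibition_at_cmax=99.0),
        ]
        for m in improved:
            assert call_hits([m], cohort, lib, sample_id="s1")[0].is_hit

    def test_small_cohort_blocks_quantile_flag(self):
        lib = DrugLibrary(drugs=(_drug(),))
        cohort = CohortTable(pd.DataFrame({"d1": [1.0, 2.0]}, index=["c0", "s1"]))
        calls = call_hits([_metrics()], cohort, lib, sample_id="s1",
                          config=HitCallConfig(min_cohort=10))
        assert not calls[0].is_hit
        assert calls[0].quantile_pct is None


class TestWaterfall:
    def test_descending_with_alphabetical_ties(self):
        assert waterfall_order([("a", 3.0), ("b", 9.0), ("c", 9.0)]) == [
            ("b", 9.0), ("c", 9.0), ("a", 3.0)
        ]

    def test_single_drug(self):
        assert waterfall_order([("only", 1.0)]) == [("only", 1.0)]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(8)
        pairs = [(f"d{i}", float(np.round(rng.uniform(0, 50), 1))) for i in range(30)]
        ours = waterfall_order(pairs)
        oracle = sorted(sorted(pairs), key=lambda kv: -kv[1])
        assert ours == oracle


class TestHeatmapClustering:
    def test_identical_rows_are_adjacent(self):
        df = pd.DataFrame(
            [[90, 88], [10, 12], [90, 88], [50, 40]],
            index=["s1", "s2", "s3", "s4"], columns=["mdm2i_a", "mdm2i_b"],
        )
        rows, _ = quantile_heatmap_order(df)
        i1, i3 = rows.index("s1"), rows.index("s3")
        assert abs(i1 - i3) == 1

    def test_planted_groups_separate(self):
        rng = np.random.default_rng(12)
        sensitive = rng.uniform(80, 100, size=(5, 2))
        resistant = rng.uniform(0, 20, size=(5, 2))
        df = pd.DataFrame(
            np.vstack([sensitive, resistant]),
            index=[f"hi{i}" for i in range(5)] + [f"lo{i}" for i in range(5)],
            columns=["mdm2i_a", "mdm2i_b"],
        )
        rows, _ = quantile_heatmap_order(df)
        labels = ["hi" if r.startswith("hi") else "lo" for r in rows]
        # leaf order keeps the two planted response groups contiguous
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_single_row_trivial(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["s1"], columns=["a", "b"])
        assert quantile_heatmap_order(df)[0] == ["s1"]

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["s1"], columns=["a", "b"])
        with pytest.raises(ScoringError, match="missing"):
            quantile_heatmap_order(df)


class TestBlandAltman:
    def test_identical_vectors(self):
        stats = bland_altman([(1.0, 1.0), (5.0, 5.0), (9.0, 9.0)])
        assert stats.bias == 0.0
        assert stats.loa_lower == stats.loa_upper == 0.0

    def test_constant_offset(self):
        stats = bland_altman([(1.0, 3.0), (5.0, 7.0), (9.0, 11.0)])
        assert stats.bias == pytest.approx(-2.0)  # difference is a - b
        assert stats.sd_diff == 0.0

    def test_matches_formula_recomputation(self):
        rng = np.random.default_rng(13)
        pairs = [(float(a), float(b)) for a, b in rng.normal(20, 5, size=(50, 2))]
        stats = bland_altman(pairs)
        diff = np.array([a - b for a, b in pairs])
        assert stats.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert stats.sd_diff == pytest.approx(diff.std(ddof=1), abs=1e-12)
        assert stats.loa_lower == pytest.approx(diff.mean() - 1.96 * diff.std(ddof=1), abs=1e-12)
        assert stats.loa_upper == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1), abs=1e-12)

    def test_loa_coverage_on_normal_differences(self):
        rng = np.random.default_rng(14)
        a = rng.normal(20, 5, 1000)
        b = a + rng.normal(0.5, 2.0, 1000)
        stats = bland_altman(list(zip(a.tolist(), b.tolist())))
        inside = np.mean((stats.differences >= stats.loa_lower)
                         & (stats.differences <= stats.loa_upper))
        assert inside == pytest.approx(0.95, abs=0.03)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ScoringError):
            bland_altman([(1.0, 2.0)])


class TestReport:
    def _report(self, n_hits):
        lib = DrugLibrary(drugs=tuple(
            _drug(f"d{i}", name=f"drug-{i:02d}") for i in range(10)
        ))
        cohort = CohortTable(pd.DataFrame(
            {f"d{i}": list(range(11)) + [30] for i in range(10)},
            index=[f"c{i}" for i in range(11)] + ["s1"],
        ))
        metrics = []
        for i in range(10):
            if i < n_hits:
                metrics.append(_metrics(f"d{i}"))
            else:
                metrics.append(_metrics(f"d{i}", max_effect=30.0, dss_asym=2.0, sdss=-1.0))
        calls = call_hits(metrics, cohort, lib, sample_id="s1")
        return build_report("s1", calls, metrics, {"screen_type": "full"})

    def test_ranked_hit_table(self):
        report = self._report(7)
        assert report["n_hits"] == 7
        assert [row["ranking"] for row in report["hits"]] == list(range(1, 8))
        assert report["no_hits_statement"] is None

    def test_zero_hits_statement(self):
        report = self._report(0)
        assert report["n_hits"] == 0
        assert report["no_hits_statement"] == "no drug hits identified"

    def test_low_dss_footnote_flag(self):
        report = self._report(3)
        flagged = [r for r in report["all_drugs"] if r["dss_asym"] < 5.0]
        assert flagged  # resistant drugs carry low scores
        for row in report["hits"]:
            assert row["low_dss_flag"] == (row["dss_asym"] < 5.0)

    def test_report_round_trips_through_json(self, tmp_path):
        import json

        from dspscreen.cohort import write_report

        report = self._report(2)
        path = tmp_path / "report.json"
        write_report(report, path)
        loaded = json.loads(path.read_text())
        assert loaded["n_hits"] == 2
        assert loaded["sample_id"] == "s1"
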