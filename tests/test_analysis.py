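"""End-to-end cohort analysis: counts, determinism, report round trips,
facility comparison, configuration."""

import math

import pytest

from psqakit import (
    AnalysisConfig,
    CohortReport,
    facility_comparison,
    generate_cohort,
    load_config,
    run_analysis,
    showa2016_specs,
    write_report,
)
from psqakit.synthetic import SITE_COUNTS_SHOWA2016
from psqakit import vocab


@pytest.fixture(scope="module")
def preset_report():
    records, _ = generate_cohort(showa2016_specs(), seed=1)
    return run_analysis(records, AnalysisConfig(), seed=1)


class TestRunAnalysis:
    def test_empty_cohort(self):
        report = run_analysis([], AnalysisConfig())
        assert report.total == 0
        assert sum(report.site_counts.values()) == 0
        assert all(not s for ch in report.limits.values() for s in ch.values())
        assert report.alerts == []

    def test_preset_site_counts_sum_to_total(self, preset_report):
        assert preset_report.site_counts == SITE_COUNTS_SHOWA2016
        assert sum(preset_report.site_counts.values()) == preset_report.total == 835

    def test_rerun_is_byte_identical(self):
        records, _ = generate_cohort(showa2016_specs(), seed=4)
        a = run_analysis(records, AnalysisConfig(), seed=4).to_json()
        b = run_analysis(records, AnalysisConfig(), seed=4).to_json()
        assert a == b

    def test_every_counted_stratum_has_limits_or_is_small(self, preset_report):
        site_limits = preset_report.limits["site"]["3%/3mm"]
        for site, n in preset_report.site_counts.items():
            key = f"site={site}"
            assert key in site_limits
            if n < preset_report.config["min_n"]:
                assert "provisional" in site_limits[key].flags

    def test_end_to_end_al_recovery_against_generator_parameters(self):
        # On an unclipped preset cohort every large per-site stratum's AL
        # must land near the analytic value from the generator's mixture
        # moments: AL = 100 - 3*sqrt(var + (mean-100)^2).
        specs = showa2016_specs()
        records, _ = generate_cohort(specs, seed=8, clip=False)
        report = run_analysis(records, AnalysisConfig())
        for site, n_site in SITE_COUNTS_SHOWA2016.items():
            if n_site < 150:
                continue
            w = ev = e2 = 0.0
            for s in specs:
                if s.site != site:
                    continue
                mu, sd = s.channels["gamma_3_3"]
                w += s.n
                ev += s.n * mu
                e2 += s.n * (sd**2 + mu**2)
            mean = ev / w
            var = e2 / w - mean**2
            analytic = 100 - 3 * math.sqrt(var + (mean - 100) ** 2)
            ls = report.limits["site"]["3%/3mm"][f"site={site}"]
            assert ls.al == pytest.approx(analytic, abs=0.3), site


class TestFacilityComparison:
    def test_four_facility_preset_gives_four_rows(self, preset_report):
        table = facility_comparison(preset_report, "Pelvis", "3/3")
        assert len(table) == 4
        assert list(table["facility"]) == sorted(vocab.FACILITIES)

    def test_orders_facilities_consistently_with_spread(self, preset_report):
        table = facility_comparison(preset_report, "Pelvis", "3/3").set_index("facility")
        assert table.loc["NorthernYokohama", "al"] > table.loc["KotoToyosu", "al"]
        assert table.loc["KotoToyosu", "al"] > table.loc["UniversityHospital", "al"]
        assert table.loc["UniversityHospital", "al"] > table.loc["Fujigaoka", "al"]

    def test_single_facility_cohort_matches_pooled_limits(self):
        specs = [s for s in showa2016_specs() if s.facility == "Fujigaoka"]
        records, _ = generate_cohort(specs, seed=2)
        report = run_analysis(records, AnalysisConfig())
        table = facility_comparison(report, "Pelvis", "3/3")
        assert len(table) == 1
        pooled = report.limits["site"]["3%/3mm"]["site=Pelvis"]
        assert table.loc[0, "al"] == pytest.approx(pooled.al)

    def test_small_stratum_row_flagged_provisional(self):
        specs = showa2016_specs()
        small = [
            s if s.facility != "Fujigaoka" or s.site != "Pelvis"
            else type(s)(facility=s.facility, site=s.site, n=5, channels=s.channels)
            for s in specs
        ]
        records, _ = generate_cohort(small, seed=3)
        report = run_analysis(records, AnalysisConfig())
        table = facility_comparison(report, "Pelvis", "3/3").set_index("facility")
        assert "provisional" in table.loc["Fujigaoka", "flags"]


class TestWriteReport:
    def test_json_round_trip(self, tmp_path, preset_report):
        path = tmp_path / "report.json"
        write_report(preset_report, path, "json")
        back = CohortReport.from_json(path)
        assert back.to_json() == preset_report.to_json()

    def test_csv_bundle_writes_three_files(self, tmp_path, preset_report):
        written = write_report(preset_report, tmp_path / "bundle", "csv-bundle")
        assert sorted(p.name for p in written) == ["alerts.csv", "charts.csv", "limits.csv"]
        assert all(p.exists() for p in written)

    def test_text_report_of_empty_cohort(self, tmp_path):
        report = run_analysis([], AnalysisConfig())
        (path,) = write_report(report, tmp_path / "report.txt", "text")
        assert "0 records" in path.read_text()

    def test_unknown_format_is_hard_failure(self, tmp_path, preset_report):
        with pytest.raises(ValueError, match="format"):
            write_report(preset_report, tmp_path / "x", "pdf")


class TestConfig:
    def test_defaults_validate(self):
        cfg = AnalysisConfig()
        assert cfg.validate() is cfg
        assert cfg.beta == 6.0
        assert cfg.fence_k == 1.5

    def test_yaml_load_with_overrides(self, tmp_path):
        path = tmp_path / "analysis.yaml"
        path.write_text("grouping: site\nbeta: 4.0\n")
        cfg = load_config(path, fence_k=2.0)
        assert (cfg.grouping, cfg.beta, cfg.fence_k) == ("site", 4.0, 2.0)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "analysis.yaml"
        path.write_text("betta: 4.0\n")
        with pytest.raises(ValueError, match="betta"):
            load_config(path)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(grouping="ward").validate()
        with pytest.raises(ValueError):
            AnalysisConfig(beta=-1).validate()
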