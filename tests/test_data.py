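import numpy as np
import pandas as pd
import pytest

from scalechron import (
    AnalysisDataset,
    assign_growth_years,
    exclude_rare_life_histories,
    filter_increments,
    read_increment_csv,
    validate_dataset,
    write_increment_csv,
)
from scalechron.ages import AgeCode
from scalechron.data import DataError


def _fish_row(fid, age_code="1.1+", capture_year=2010, **kw):
    row = {
        "fish_id": fid,
        "group": "wild",
        "sex": "female",
        "capture_year": capture_year,
        "age_code": age_code,
        "fork_length_cm": 55.0,
        "scale_radius_um": 3300.0,
        "circulus_count": 100,
        "repeat_spawner": False,
    }
    row.update(kw)
    return row


def _inc_row(fid, index, age_class, **kw):
    row = {
        "fish_id": fid,
        "group": "wild",
        "sex": "female",
        "capture_year": 2010,
        "age_code": "1.1+",
        "increment_index": index,
        "age_class": age_class,
        "width_um": 800.0,
        "is_marginal": False,
        "is_spawning_zone": False,
    }
    row.update(kw)
    return row


def _toy_dataset(fish_rows, inc_rows):
    return AnalysisDataset(
        fish=pd.DataFrame(fish_rows),
        increments=pd.DataFrame(inc_rows),
        provenance={"rows_in": len(inc_rows)},
    )


class TestRareLifeHistoryExclusion:
    def test_default_exclusion_retains_1596_of_1603(self, default_cohort):
        dataset, _, _ = default_cohort
        assert dataset.n_fish == 1603
        out = exclude_rare_life_histories(dataset)
        assert out.n_fish == 1596
        assert out.provenance["rare_life_history_fish_removed"] == 7

    def test_counts_logged_on_small_fixture(self):
        codes = ["2.0+"] * 2 + ["3.1+"] * 2 + ["1.1+"] * 6
        fish = [_fish_row(f"F{i}", age_code=c) for i, c in enumerate(codes)]
        incs = [_inc_row(f"F{i}", 1, "FW1") for i in range(10)]
        out = exclude_rare_life_histories(_toy_dataset(fish, incs))
        assert out.n_fish == 6
        assert out.provenance["rare_life_history_fish_removed"] == 4
        assert out.provenance["rare_life_history_increments_removed"] == 4

    def test_empty_exclusion_set_is_identity(self):
        fish = [_fish_row("F1", age_code="2.0+")]
        incs = [_inc_row("F1", 1, "FW1")]
        ds = _toy_dataset(fish, incs)
        out = exclude_rare_life_histories(ds, excluded_codes=set())
        assert out.n_fish == 1
        assert out.provenance["rare_life_history_fish_removed"] == 0

    def test_custom_code_set(self):
        fish = [_fish_row("F1", age_code="1.1+"), _fish_row("F2", age_code="1.2+")]
        incs = [_inc_row("F1", 1, "FW1"), _inc_row("F2", 1, "FW1")]
        out = exclude_rare_life_histories(
            _toy_dataset(fish, incs), excluded_codes={AgeCode(1, 2, True)}
        )
        assert list(out.fish["fish_id"]) == ["F1"]


class TestIncrementFiltering:
    def test_marginal_and_spawning_zones_removed(self):
        fish = [_fish_row("F1")]
        incs = [
            _inc_row("F1", 1, "FW1"),
            _inc_row("F1", 2, "SW1"),
            _inc_row("F1", 3, "SW1", is_marginal=True),
        ]
        out = filter_increments(_toy_dataset(fish, incs))
        assert list(out.increments["age_class"]) == ["FW1", "SW1"]
        assert not out.increments["is_marginal"].any()

    def test_spawning_eroded_zone_removed(self):
        fish = [_fish_row("F1", age_code="1.2+", repeat_spawner=True)]
        incs = [
            _inc_row("F1", 1, "FW1"),
            _inc_row("F1", 2, "SW1"),
            _inc_row("F1", 3, "SW2", is_spawning_zone=True),
        ]
        out = filter_increments(_toy_dataset(fish, incs))
        assert "SW2" not in set(out.increments["age_class"])
        assert out.provenance["spawning_increments_removed"] == 1

    def test_fractions_reported_on_constructed_fixture(self):
        # 1,000 zones: 287 marginal, 30 spawning -> 683 retained
        fish = [_fish_row(f"F{i}") for i in range(1000)]
        incs = []
        for i in range(1000):
            marginal = i < 287
            spawning = 287 <= i < 317
            incs.append(
                _inc_row(f"F{i}", 1, "SW1", is_marginal=marginal, is_spawning_zone=spawning)
            )
        out = filter_increments(_toy_dataset(fish, incs))
        assert len(out.increments) == 683
        assert out.provenance["marginal_fraction"] == pytest.approx(0.287)
        assert out.provenance["spawning_fraction"] == pytest.approx(0.030)

    def test_idempotent(self, default_cohort):
        dataset, _, _ = default_cohort
        once = filter_increments(dataset)
        twice = filter_increments(once)
        pd.testing.assert_frame_equal(once.increments, twice.increments)

    def test_provenance_conservation(self, default_cohort):
        dataset, _, _ = default_cohort
        out = filter_increments(exclude_rare_life_histories(dataset))
        p = out.provenance
        assert p["rows_in"] == (
            p["increments_retained"]
            + p["rare_life_history_increments_removed"]
            + p["marginal_increments_removed"]
            + p["spawning_increments_removed"]
        )


class TestGrowthYearAssignment:
    def _assign(self, capture_year, zones):
        fish = pd.DataFrame([_fish_row("F1", capture_year=capture_year)])
        incs = pd.DataFrame(
            [
                _inc_row("F1", k + 1, ac, is_marginal=marg, capture_year=capture_year)
                for k, (ac, marg) in enumerate(zones)
            ]
        )
        out = assign_growth_years(fish, incs)
        return list(out["growth_year"])

    def test_one_one_plus_caught_2007(self):
        years = self._assign(2007, [("FW1", False), ("SW1", False), ("SW1", True)])
        assert years == [2005, 2006, 2007]

    def test_two_two_plus_caught_2007_starts_2003(self):
        zones = [("FW1", False), ("FW2", False), ("SW1", False), ("SW2", False), ("SW2", True)]
        years = self._assign(2007, zones)
        assert years[0] == 2003

    def test_latest_completed_year_is_2015(self):
        years = self._assign(2016, [("FW1", False), ("SW1", False), ("SW1", True)])
        assert years[1] == 2015

    def test_non_contiguous_index_rejected(self):
        fish = pd.DataFrame([_fish_row("F1")])
        incs = pd.DataFrame([_inc_row("F1", 1, "FW1"), _inc_row("F1", 3, "SW1")])
        with pytest.raises(DataError, match="non-contiguous"):
            assign_growth_years(fish, incs)

    def test_study_span_2003_2015(self, default_cohort):
        """Retained completed zones of the study composition span 2003-2015."""
        dataset, _, _ = default_cohort
        out = filter_increments(exclude_rare_life_histories(dataset))
        years = out.increments["growth_year"]
        assert years.min() == 2003
        assert years.max() == 2015


class TestCsvInterface:
    def test_round_trip_is_identity(self, tmp_path, small_filtered):
        dataset, _, _ = small_filtered
        write_increment_csv(dataset, tmp_path / "inc.csv", tmp_path / "fish.csv")
        back = read_increment_csv(tmp_path / "inc.csv", tmp_path / "fish.csv")
        pd.testing.assert_frame_equal(back.fish, dataset.fish.reset_index(drop=True))
        pd.testing.assert_frame_equal(
            back.increments, dataset.increments.reset_index(drop=True)
        )

    def test_minimal_single_fish_file(self, tmp_path):
        ds = _toy_dataset([_fish_row("F1")], [_inc_row("F1", 1, "FW1")])
        write_increment_csv(ds, tmp_path / "inc.csv", tmp_path / "fish.csv")
        back = read_increment_csv(tmp_path / "inc.csv", tmp_path / "fish.csv")
        assert back.n_fish == 1
        assert back.n_increments == 1

    def test_negative_width_rejected_with_location(self, tmp_path):
        ds = _toy_dataset([_fish_row("F1")], [_inc_row("F1", 1, "FW1", width_um=-5.0)])
        write_increment_csv(ds, tmp_path / "inc.csv", tmp_path / "fish.csv")
        with pytest.raises(DataError, match="width_um"):
            read_increment_csv(tmp_path / "inc.csv", tmp_path / "fish.csv")

    def test_missing_column_named(self, tmp_path):
        ds = _toy_dataset([_fish_row("F1")], [_inc_row("F1", 1, "FW1")])
        write_increment_csv(ds, tmp_path / "inc.csv", tmp_path / "fish.csv")
        broken = pd.read_csv(tmp_path / "inc.csv").drop(columns=["width_um"])
        broken.to_csv(tmp_path / "inc.csv", index=False)
        with pytest.raises(DataError, match="width_um"):
            read_increment_csv(tmp_path / "inc.csv", tmp_path / "fish.csv")

    def test_unparseable_cell_named(self, tmp_path):
        ds = _toy_dataset([_fish_row("F1")], [_inc_row("F1", 1, "FW1")])
        write_increment_csv(ds, tmp_path / "inc.csv", tmp_path / "fish.csv")
        df = pd.read_csv(tmp_path / "inc.csv")
        df["width_um"] = df["width_um"].astype(object)
        df.loc[0, "width_um"] = "oops"
        df.to_csv(tmp_path / "inc.csv", index=False)
        with pytest.raises(DataError, match="row 0"):
            read_increment_csv(tmp_path / "inc.csv", tmp_path / "fish.csv")


class TestValidation:
    def test_generated_dataset_passes(self, default_cohort):
        dataset, _, _ = default_cohort
        validate_dataset(dataset, capture_years=(2007, 2016))

    def test_duplicate_fish_rejected(self):
        ds = _toy_dataset([_fish_row("F1"), _fish_row("F1")], [_inc_row("F1", 1, "FW1")])
        with pytest.raises(DataError, match="duplicate"):
            validate_dataset(ds)

    def test_unresolved_increment_rejected(self):
        ds = _toy_dataset([_fish_row("F1")], [_inc_row("F2", 1, "FW1")])
        with pytest.raises(DataError, match="unknown fish_id"):
            validate_dataset(ds)

    def test_two_marginal_zones_rejected(self):
        incs = [
            _inc_row("F1", 1, "SW1", is_marginal=True),
            _inc_row("F1", 2, "SW1", is_marginal=True),
        ]
        ds = _toy_dataset([_fish_row("F1")], incs)
        with pytest.raises(DataError, match="marginal"):
            validate_dataset(ds)

    def test_filtered_flag_checks_marginals_gone(self):
        ds = _toy_dataset(
            [_fish_row("F1")], [_inc_row("F1", 1, "SW1", is_marginal=True)]
        )
        with pytest.raises(DataError, match="marginal"):
            validate_dataset(ds, filtered=True)
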