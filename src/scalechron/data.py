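"""Increment datasets: validation, exclusion rules, calendar anchoring, CSV IO.

The analysis container is a pair of pandas DataFrames — one row per fish and
one row per annual scale growth zone — plus a provenance log that records how
many rows each filtering rule removed.  All interchange is plain CSV (UTF-8,
comma separator, ``.`` decimal).

Filtering follows the standard sclerochronology rules for spawning-run
samples: marginal ("plus") growth zones do not represent a full year and are
dropped, as are zones eroded by a spawning event in repeat spawners; fish
with rare life histories are removed wholesale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import AgeCode, environment_of, parse_age_code

FISH_COLUMNS = [
    "fish_id",
    "group",
    "sex",
    "capture_year",
    "age_code",
    "fork_length_cm",
    "scale_radius_um",
    "circulus_count",
    "repeat_spawner",
]

INCREMENT_COLUMNS = [
    "fish_id",
    "group",
    "sex",
    "capture_year",
    "age_code",
    "increment_index",
    "age_class",
    "width_um",
    "is_marginal",
    "is_spawning_zone",
]

TEMPERATURE_COLUMNS = ["environment", "year", "temperature_c"]

GROUPS = ("wild", "hatchery")
SEXES = ("female", "male", "unknown")
AGE_CLASSES = ("FW1", "FW2", "FW3", "SW1", "SW2", "SW3")

#: Life histories removed by default: the rare codes observed in the study.
DEFAULT_RARE_CODES = frozenset({AgeCode(2, 0, True), AgeCode(2, 3, True), AgeCode(3, 1, True)})


class DataError(ValueError):
    """Raised when a dataset violates schema or invariants."""


@dataclass
class AnalysisDataset:
    """Fish table + increment table + provenance filter log.

    ``provenance`` maps rule names to removed-row counts; ``rows_in`` is the
    increment count when the dataset was first assembled, so that
    rows_in == rows retained + sum(rows removed per rule).
    """

    fish: pd.DataFrame
    increments: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_fish(self) -> int:
        return len(self.fish)

    @property
    def n_increments(self) -> int:
        return len(self.increments)

    def copy(self) -> "AnalysisDataset":
        return AnalysisDataset(self.fish.copy(), self.increments.copy(), dict(self.provenance))


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_dataset(
    dataset: AnalysisDataset,
    capture_years: tuple[int, int] | None = None,
    filtered: bool = False,
) -> None:
    """Check schema and invariants; raise :class:`DataError` on violation.

    With ``filtered=True`` additionally require that no marginal or spawning
    zones remain.  ``capture_years`` bounds the admissible capture window.
    """
    fish, inc = dataset.fish, dataset.increments
    _require_columns(fish, FISH_COLUMNS, "fish table")
    _require_columns(inc, INCREMENT_COLUMNS, "increment table")

    if fish["fish_id"].duplicated().any():
        dupes = fish.loc[fish["fish_id"].duplicated(), "fish_id"].tolist()
        raise DataError(f"duplicate fish_id(s): {dupes[:5]}")
    bad_group = set(fish["group"]) - set(GROUPS)
    if bad_group:
        raise DataError(f"unknown group value(s): {sorted(bad_group)}")
    bad_sex = set(fish["sex"]) - set(SEXES)
    if bad_sex:
        raise DataError(f"unknown sex value(s): {sorted(bad_sex)}")
    if (fish["fork_length_cm"] <= 0).any():
        row = fish.index[fish["fork_length_cm"] <= 0][0]
        raise DataError(f"non-positive fork_length_cm at fish row {row}")
    if (fish["scale_radius_um"] <= 0).any():
        row = fish.index[fish["scale_radius_um"] <= 0][0]
        raise DataError(f"non-positive scale_radius_um at fish row {row}")
    if capture_years is not None:
        lo, hi = capture_years
        out = ~fish["capture_year"].between(lo, hi)
        if out.any():
            raise DataError(
                f"capture_year outside study window [{lo}, {hi}] "
                f"for fish {fish.loc[out, 'fish_id'].iloc[0]!r}"
            )
    for code in fish["age_code"].unique():
        parse_age_code(code)  # raises AgeCodeError on malformed codes

    if (inc["width_um"] <= 0).any():
        row = inc.index[inc["width_um"] <= 0][0]
        raise DataError(f"non-positive width_um at increment row {row}")
    unknown = set(inc["fish_id"]) - set(fish["fish_id"])
    if unknown:
        raise DataError(f"increments reference unknown fish_id(s): {sorted(unknown)[:5]}")
    bad_class = set(inc["age_class"]) - set(AGE_CLASSES)
    if bad_class:
        raise DataError(f"unknown age_class value(s): {sorted(bad_class)}")

    marginal_per_fish = inc.groupby("fish_id")["is_marginal"].sum()
    if (marginal_per_fish > 1).any():
        fid = marginal_per_fish.index[marginal_per_fish > 1][0]
        raise DataError(f"fish {fid!r} has more than one marginal zone")

    for fid, sub in inc.groupby("fish_id", sort=False):
        idx = np.sort(sub["increment_index"].to_numpy())
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise DataError(f"fish {fid!r} has non-contiguous increment_index {idx.tolist()}")

    if "growth_year" in inc.columns:
        cap = inc["fish_id"].map(fish.set_index("fish_id")["capture_year"])
        if (inc["growth_year"] > cap).any():
            fid = inc.loc[inc["growth_year"] > cap, "fish_id"].iloc[0]
            raise DataError(f"fish {fid!r} has a growth_year after its capture_year")

    if filtered:
        if inc["is_marginal"].any():
            raise DataError("marginal zones remain after filtering")
        if inc["is_spawning_zone"].any():
            raise DataError("spawning zones remain after filtering")


def exclude_rare_life_histories(
    dataset: AnalysisDataset,
    excluded_codes: frozenset[AgeCode] | set[AgeCode] = DEFAULT_RARE_CODES,
) -> AnalysisDataset:
    """Drop fish (and their increments) whose age code is in ``excluded_codes``.

    Removal counts are appended to the provenance log.  An empty exclusion
    set returns the dataset unchanged (copied).
    """
    out = dataset.copy()
    excluded_strs = {str(c) for c in excluded_codes}
    drop_fish = out.fish["age_code"].isin(excluded_strs)
    dropped_ids = set(out.fish.loc[drop_fish, "fish_id"])
    drop_inc = out.increments["fish_id"].isin(dropped_ids)

    out.provenance.setdefault("rows_in", len(dataset.increments))
    out.provenance["rare_life_history_fish_removed"] = int(drop_fish.sum())
    out.provenance["rare_life_history_increments_removed"] = int(drop_inc.sum())

    out.fish = out.fish.loc[~drop_fish].reset_index(drop=True)
    out.increments = out.increments.loc[~drop_inc].reset_index(drop=True)
    if out.n_fish == 0:
        import warnings

        warnings.warn("rare-life-history exclusion removed every fish", stacklevel=2)
    return out


def filter_increments(dataset: AnalysisDataset) -> AnalysisDataset:
    """Remove marginal (plus-growth) and spawning-eroded zones.

    Fractions removed (relative to the increments present on entry) are
    recorded in the provenance log.  Idempotent: a second application
    removes nothing.
    """
    out = dataset.copy()
    inc = out.increments
    n_in = len(inc)
    marginal = inc["is_marginal"].astype(bool)
    spawning = inc["is_spawning_zone"].astype(bool) & ~marginal

    out.provenance.setdefault("rows_in", n_in)
    out.provenance["marginal_increments_removed"] = int(marginal.sum())
    out.provenance["spawning_increments_removed"] = int(spawning.sum())
    if n_in > 0:
        out.provenance["marginal_fraction"] = float(marginal.sum() / n_in)
        out.provenance["spawning_fraction"] = float(spawning.sum() / n_in)

    out.increments = inc.loc[~(marginal | spawning)].reset_index(drop=True)
    out.provenance["increments_retained"] = len(out.increments)
    return out


def assign_growth_years(fish: pd.DataFrame, increments: pd.DataFrame) -> pd.DataFrame:
    """Anchor each growth zone to a calendar year.

    Fish are caught in autumn, after the growing season, so the last
    completed annulus delimits growth in ``capture_year - 1`` and the
    marginal zone is growth in the capture year itself.  Completed zone
    ``k`` of ``m`` (ordered from the scale focus) therefore gets

        growth_year = capture_year - 1 - (m - k)

    Returns a copy of ``increments`` with a ``growth_year`` column.
    Raises :class:`DataError` on non-contiguous increment indices.
    """
    cap = fish.set_index("fish_id")["capture_year"]
    inc = increments.copy()
    growth_year = np.empty(len(inc), dtype=int)

    for fid, sub in inc.groupby("fish_id", sort=False):
        sub = sub.sort_values("increment_index")
        idx = sub["increment_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise DataError(f"fish {fid!r} has non-contiguous increment_index {idx.tolist()}")
        capture_year = int(cap.loc[fid])
        completed = ~sub["is_marginal"].to_numpy(dtype=bool)
        m = int(completed.sum())
        years = np.empty(len(sub), dtype=int)
        k = 0
        for j, is_completed in enumerate(completed):
            if is_completed:
                k += 1
                years[j] = capture_year - 1 - (m - k)
            else:
                years[j] = capture_year
        growth_year[sub.index.to_numpy()] = years

    inc["growth_year"] = growth_year
    inc["environment"] = inc["age_class"].map(environment_of)
    return inc


# ---------------------------------------------------------------------------
# CSV interfaces


def _read_csv(path: str | Path, columns: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface the parse failure with context
        raise DataError(f"could not read {what} from {path}: {exc}") from exc
    _require_columns(df, columns, what)
    return df


def read_increment_csv(
    increments_path: str | Path,
    fish_path: str | Path,
    validate: bool = True,
) -> AnalysisDataset:
    """Read the two-table CSV interface into an :class:`AnalysisDataset`.

    Numeric cells are checked eagerly so that a bad value is reported with
    its row and column rather than surfacing later as a numpy error.
    """
    fish = _read_csv(fish_path, FISH_COLUMNS, "fish table")
    inc = _read_csv(increments_path, INCREMENT_COLUMNS, "increment table")

    for df, cols, what in (
        (fish, ["capture_year", "fork_length_cm", "scale_radius_um", "circulus_count"], "fish"),
        (inc, ["capture_year", "increment_index", "width_um"], "increments"),
    ):
        for col in cols:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(df.index[bad][0])
                raise DataError(
                    f"unparseable value {df.loc[row, col]!r} in {what} column {col!r}, row {row}"
                )
            df[col] = coerced
    for df, flags in ((fish, ["repeat_spawner"]), (inc, ["is_marginal", "is_spawning_zone"])):
        for col in flags:
            df[col] = df[col].astype(bool)

    dataset = AnalysisDataset(fish=fish, increments=inc, provenance={"rows_in": len(inc)})
    if validate:
        validate_dataset(dataset)
    return dataset


def write_increment_csv(
    dataset: AnalysisDataset,
    increments_path: str | Path,
    fish_path: str | Path,
) -> None:
    """Write the dataset back to the two-table CSV interface (lossless)."""
    dataset.fish.to_csv(fish_path, index=False)
    dataset.increments.to_csv(increments_path, index=False)


def read_temperature_csv(path: str | Path) -> pd.DataFrame:
    """Read a yearly temperature series table (environment, year, temperature_c)."""
    df = _read_csv(path, TEMPERATURE_COLUMNS, "temperature table")
    for env, sub in df.groupby("environment"):
        if sub["year"].duplicated().any():
            year = sub.loc[sub["year"].duplicated(), "year"].iloc[0]
            raise DataError(f"duplicate year {year} in temperature series for {env!r}")
    return df


def write_provenance(dataset: AnalysisDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.provenance, indent=2, sort_keys=True))
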