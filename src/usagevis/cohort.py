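"""Cohort filtering and export: the bridge from visual pattern to statistics.

Participants are selected either by page-group exposure (seen / not seen /
reused / not reused a group of intervention pages) or by predicates on user
variables (age >= 50, arm in {web, web+nurse}, ...).  Filters combine by
conjunction; the resulting cohort can be exported with all user data, one
indicator column per exposure filter, and total viewing time, ready for a
two-group moderator analysis.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import pandas as pd

from .dataio import Dataset, UsageDataError
from .sequences import (
    OCCASION_GAP_MINUTES,
    build_sequences,
    reusers_of_group,
    viewers_of_group,
)

EXPOSURE_MODES = ("seen", "not_seen", "reused", "not_reused")

_OPS = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


@dataclass(frozen=True)
class ExposureFilter:
    """Select users by whether they saw / reused a page group."""

    group_label: str
    mode: str = "seen"

    def __post_init__(self):
        if self.mode not in EXPOSURE_MODES:
            raise ValueError(f"mode must be one of {EXPOSURE_MODES}, got {self.mode!r}")

    def describe(self) -> str:
        return f"{self.mode}({self.group_label})"

    def matching_users(self, dataset: Dataset, gap_minutes=OCCASION_GAP_MINUTES) -> set[str]:
        if self.group_label not in set(dataset.coding.labels):
            raise UsageDataError(f"unknown group label {self.group_label!r}")
        universe = set(dataset.users.index)
        if self.mode in ("seen", "not_seen"):
            hit = viewers_of_group(dataset, self.group_label) & universe
        else:
            hit = reusers_of_group(dataset, self.group_label, gap_minutes) & universe
        if self.mode.startswith("not_"):
            return universe - hit
        return hit


@dataclass(frozen=True)
class VariableFilter:
    """Select users by a comparison on a user-table attribute.

    ``op`` is one of ==, !=, <, <=, >, >= or ``in`` (value is then a
    collection of admissible values).
    """

    attribute: str
    op: str
    value: object

    def __post_init__(self):
        if self.op not in _OPS and self.op != "in":
            raise ValueError(f"unsupported operator {self.op!r}")

    def describe(self) -> str:
        return f"{self.attribute} {self.op} {self.value!r}"

    def matching_users(self, dataset: Dataset, **_) -> set[str]:
        if self.attribute not in dataset.users.columns:
            raise UsageDataError(f"unknown attribute {self.attribute!r}")
        col = dataset.users[self.attribute]
        if self.op == "in":
            try:
                mask = col.isin(list(self.value))
            except TypeError:
                raise UsageDataError(
                    f"'in' predicate needs an iterable value, got {self.value!r}"
                ) from None
        else:
            try:
                mask = _OPS[self.op](col, self.value)
            except TypeError as exc:
                raise UsageDataError(
                    f"predicate {self.describe()} does not apply to column "
                    f"dtype {col.dtype}: {exc}"
                ) from None
        return set(dataset.users.index[mask.fillna(False)])


@dataclass
class Cohort:
    """An ordered set of user ids plus the provenance of how it was made."""

    user_ids: tuple[str, ...]
    provenance: list[str] = field(default_factory=list)
    filters: tuple = ()

    def __len__(self):
        return len(self.user_ids)

    def __contains__(self, user_id):
        return user_id in set(self.user_ids)


def apply_filters(
    dataset: Dataset,
    filters: list,
    gap_minutes: float = OCCASION_GAP_MINUTES,
) -> Cohort:
    """Conjunction (AND) of all filters; order-independent result.

    With an empty filter list every user is returned and provenance stays
    empty.  User order follows the user table, so exports are stable.
    """
    selected = set(dataset.users.index)
    provenance = []
    for f in filters:
        selected &= f.matching_users(dataset, gap_minutes=gap_minutes)
        provenance.append(f.describe())
    ordered = tuple(u for u in dataset.users.index if u in selected)
    return Cohort(user_ids=ordered, provenance=provenance, filters=tuple(filters))


def usage_indicator(
    dataset: Dataset,
    exposure: ExposureFilter,
    name: str | None = None,
    gap_minutes: float = OCCASION_GAP_MINUTES,
) -> str:
    """Add a 0/1 usage-variable column to the user table.

    The new variable records who did / did not exhibit the exposure (e.g.
    ``reused(steps diary)``) and is the grouping variable for moderator
    tests.  Returns the column name; colliding with an existing attribute
    is an error.
    """
    name = name or f"{exposure.mode}_{exposure.group_label}".replace(" ", "_")
    if name in dataset.users.columns:
        raise UsageDataError(f"attribute {name!r} already exists in user table")
    matching = exposure.matching_users(dataset, gap_minutes=gap_minutes)
    dataset.users[name] = [int(u in matching) for u in dataset.users.index]
    return name


def cohort_frame(dataset: Dataset, cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame: user_id, all user-data columns, one indicator
    column per exposure filter applied, and total_blocks."""
    df = dataset.users.loc[list(cohort.user_ids)].copy()
    for f in cohort.filters:
        if isinstance(f, ExposureFilter):
            col = f"filter_{f.mode}_{f.group_label}".replace(" ", "_")
            matching = f.matching_users(dataset)
            df[col] = [int(u in matching) for u in df.index]
    totals = {s.user_id: s.total_blocks for s in build_sequences(dataset)}
    df["total_blocks"] = [totals.get(u, 0) for u in df.index]
    df.index.name = "user_id"
    return df


def export_cohort(dataset: Dataset, cohort: Cohort, path, format: str = "csv") -> None:
    """Write the cohort with its user data.

    CSV is the canonical, bit-stable format; XLSX is offered for parity
    with spreadsheet-based follow-up analysis.
    """
    df = cohort_frame(dataset, cohort)
    if format == "csv":
        df.to_csv(path, index=True)
    elif format == "xlsx":
        df.to_excel(path, index=True)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_cohort_csv(path) -> list[str]:
    """User ids from an exported cohort CSV (round-trip helper)."""
    return list(pd.read_csv(path, dtype={"user_id": str})["user_id"])
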