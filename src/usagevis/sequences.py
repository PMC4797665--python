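"""Per-participant binned usage sequences and page-group summaries.

The plotted object is a :class:`BinnedSequence`: each participant's page
views, sorted by start time, are quantized into 30-second blocks (every
visited page occupies at least one block so it stays visible), mapped to
page-group codes, and adjacent views with equal code are merged into runs.
The x-axis of every plot is cumulative viewing time in blocks — calendar
gaps between logins carry no width.

Summaries reproduce the two percentage conventions used when reporting
usage tables for these trials: one-decimal percentages are *truncated*
(104/132 prints as 78.7, not 78.8) while in-text integer percentages are
rounded half away from zero (120/132 prints as 91%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dataio import Dataset

BLOCK_SECONDS = 30
#: A gap longer than this between consecutive views starts a new occasion
#: (login session) for reuse counting.
OCCASION_GAP_MINUTES = 60


@dataclass(frozen=True)
class BinnedSequence:
    """Ordered runs of (code, 30-s block count) for one participant."""

    user_id: str
    runs: tuple[tuple[int, int], ...]
    total_blocks: int

    def __post_init__(self):
        if self.total_blocks != sum(b for _, b in self.runs):
            raise ValueError("total_blocks must equal the sum of run blocks")


@dataclass(frozen=True)
class UsageSummary:
    """Distinct-user view count for one page group, with both percentage
    conventions."""

    group_label: str
    code: int
    n_viewed: int
    denominator: int
    pct_1dp: float
    pct_int: int


def blocks_for(duration_s: float, block_seconds: int = BLOCK_SECONDS) -> int:
    """Number of blocks a view of ``duration_s`` seconds occupies.

    Partial blocks round up, with a one-block floor so that every visited
    page is visible in the plot: 75 s -> 3 blocks, 30 s -> 1, 0 s -> 1.
    """
    if duration_s < 0:
        raise ValueError(f"duration must be >= 0, got {duration_s}")
    return max(1, math.ceil(duration_s / block_seconds))


def _sorted_views(dataset: Dataset):
    """Flow grouped by user, each user's views sorted by start time with
    file order as the tie-break."""
    per_user: dict[str, list] = {}
    for idx, rec in enumerate(dataset.flow):
        per_user.setdefault(rec.user_id, []).append((rec.start, idx, rec))
    for views in per_user.values():
        views.sort(key=lambda t: (t[0], t[1]))
    return per_user


def build_sequences(
    dataset: Dataset, block_seconds: int = BLOCK_SECONDS
) -> list[BinnedSequence]:
    """One binned sequence per user with at least one view.

    Views are sorted by start time (ties broken by file order), binned with
    :func:`blocks_for`, coded through the coding map, and adjacent runs with
    equal code merged.  Users absent from the flow yield no sequence.
    Sequences are returned in first-appearance order of the user in the flow.
    """
    per_user = _sorted_views(dataset)
    out: list[BinnedSequence] = []
    for user_id, views in per_user.items():
        runs: list[list[int]] = []
        for _, _, rec in views:
            code = dataset.coding.code_for(rec.page_id)
            blocks = blocks_for(rec.duration_s, block_seconds)
            if runs and runs[-1][0] == code:
                runs[-1][1] += blocks
            else:
                runs.append([code, blocks])
        total = sum(b for _, b in runs)
        out.append(
            BinnedSequence(
                user_id=user_id,
                runs=tuple((c, b) for c, b in runs),
                total_blocks=total,
            )
        )
    return out


def order_participants(
    sequences: list[BinnedSequence], direction: str = "ascending"
) -> list[BinnedSequence]:
    """Sort by sequence length (total viewing time in blocks).

    Ascending puts the participants who spent least time first — they are
    drawn nearest the bottom of the plot.  Ties break lexicographically by
    user id in both directions.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    reverse = direction == "descending"
    return sorted(
        sequences,
        key=lambda s: (-s.total_blocks if reverse else s.total_blocks, s.user_id),
    )


def pct_truncated_1dp(n: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (1000 * n // denominator) / 10


def pct_rounded_int(n: int, denominator: int) -> int:
    """Percentage rounded half away from zero to an integer."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * n + denominator) // (2 * denominator)


def viewers_of_group(dataset: Dataset, group_label: str) -> set[str]:
    """Distinct users with at least one view of any page in the group."""
    codes = dataset.coding.codes_for_label(group_label)
    frame = dataset.flow_frame()
    return set(frame.loc[frame["code"].isin(codes), "user_id"])


def usage_summary(
    dataset: Dataset,
    group_labels: list[str] | None = None,
    denominator: int | None = None,
) -> list[UsageSummary]:
    """Per-group count of distinct users with >= 1 page view in the group.

    ``denominator`` defaults to the number of users in the user table.
    Counting is distinct-user, so repeated views never inflate it.
    """
    if group_labels is None:
        group_labels = dataset.coding.labels
    if denominator is None:
        denominator = len(dataset.users)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    out = []
    for label in group_labels:
        codes = dataset.coding.codes_for_label(label)
        n = len(viewers_of_group(dataset, label))
        out.append(
            UsageSummary(
                group_label=label,
                code=min(codes),
                n_viewed=n,
                denominator=denominator,
                pct_1dp=pct_truncated_1dp(n, denominator),
                pct_int=pct_rounded_int(n, denominator),
            )
        )
    return out


def occasions(dataset: Dataset, gap_minutes: float = OCCASION_GAP_MINUTES):
    """Assign each view an occasion index per user.

    A new occasion (login session) starts when the gap between the end of
    one view (start + duration) and the start of the next exceeds
    ``gap_minutes``.  Returns {user_id: list of (occasion_index, record)}
    in temporal order.
    """
    per_user = _sorted_views(dataset)
    gap = gap_minutes * 60
    out: dict[str, list] = {}
    for user_id, views in per_user.items():
        occ = 0
        prev_end = None
        tagged = []
        for start, _, rec in views:
            if prev_end is not None and (start - prev_end).total_seconds() > gap:
                occ += 1
            tagged.append((occ, rec))
            prev_end = start + pd.Timedelta(seconds=rec.duration_s)
        out[user_id] = tagged
    return out


def reusers_of_group(
    dataset: Dataset, group_label: str, gap_minutes: float = OCCASION_GAP_MINUTES
) -> set[str]:
    """Users who viewed a group's pages on an occasion *after* the occasion
    of first exposure — the operational definition of reuse."""
    codes = dataset.coding.codes_for_label(group_label)
    reusers = set()
    for user_id, tagged in occasions(dataset, gap_minutes).items():
        occs = {
            occ
            for occ, rec in tagged
            if dataset.coding.code_for(rec.page_id) in codes
        }
        if len(occs) >= 2:
            reusers.add(user_id)
    return reusers


def reuse_summary(
    dataset: Dataset,
    group_labels: list[str] | None = None,
    denominator: int | None = None,
    gap_minutes: float = OCCASION_GAP_MINUTES,
) -> list[UsageSummary]:
    """Per-group count of users who *reused* the group (viewed it on at
    least two distinct occasions)."""
    if group_labels is None:
        group_labels = dataset.coding.labels
    if denominator is None:
        denominator = len(dataset.users)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    out = []
    for label in group_labels:
        codes = dataset.coding.codes_for_label(label)
        n = len(reusers_of_group(dataset, label, gap_minutes))
        out.append(
            UsageSummary(
                group_label=label,
                code=min(codes),
                n_viewed=n,
                denominator=denominator,
                pct_1dp=pct_truncated_1dp(n, denominator),
                pct_int=pct_rounded_int(n, denominator),
            )
        )
    return out


def sequences_to_frame(sequences: list[BinnedSequence]):
    """Flatten sequences to a DataFrame (user_id, run_index, code, blocks)
    for CSV export / external plotting."""
    rows = [
        (s.user_id, i, code, blocks)
        for s in sequences
        for i, (code, blocks) in enumerate(s.runs)
    ]
    return pd.DataFrame(rows, columns=["user_id", "run_index", "code", "blocks"])


def summary_to_frame(summaries: list[UsageSummary]):
    return pd.DataFrame(
        [
            (s.group_label, s.code, s.n_viewed, s.denominator, s.pct_1dp, s.pct_int)
            for s in summaries
        ],
        columns=["group_label", "code", "n_viewed", "denominator", "pct_1dp", "pct_int"],
    )
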