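"""Readers, writers and validation for the four usage-log input files.

A usage analysis starts from four delimited text files exported from the
intervention platform:

* **page flow** — one row per page view: which participant viewed which page,
  when, and for how long (``user_id, page_id, start, duration_s``);
* **user data** — one row per participant with characteristics and outcomes
  (``user_id`` plus free columns such as age, BMI, trial arm, weight change);
* **coding** — maps each page to a numeric code and a page-group label
  (``page_id, code, group_label``); many pages usually share one code;
* **colors** — maps each code to a hex color used in the plots
  (``code, hex``).

Everything downstream operates on the :class:`Dataset` assembled from these
four parts.  Pages missing from the coding file are mapped to the reserved
code ``0`` / group ``"uncoded"`` (drawn in gray) so that coding-file gaps are
visible in plots instead of silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger("usagevis")

#: Reserved code for pages absent from the coding file.
UNCODED_CODE = 0
UNCODED_LABEL = "uncoded"
UNCODED_COLOR = "#CCCCCC"

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")

PAGE_FLOW_COLUMNS = ["user_id", "page_id", "start", "duration_s"]
CODING_COLUMNS = ["page_id", "code", "group_label"]
COLOR_COLUMNS = ["code", "hex"]


class UsageDataError(Exception):
    """Base class for input-data problems."""


class SchemaError(UsageDataError):
    """A file is missing a required column or has a malformed header."""


class RowError(UsageDataError):
    """A specific row violates the schema; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


@dataclass(frozen=True)
class PageFlowRecord:
    """One page view: an opaque user id, a page id, a UTC start time and a
    non-negative dwell duration in seconds."""

    user_id: str
    page_id: str
    start: pd.Timestamp
    duration_s: float

    def __post_init__(self):
        if not self.user_id:
            raise ValueError("user_id must be non-empty")
        if not self.page_id:
            raise ValueError("page_id must be non-empty")
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")


class CodingMap:
    """page_id -> (code, group_label); codes are shared across pages within a
    group, and each code has exactly one group label."""

    def __init__(self, entries: dict[str, tuple[int, str]]):
        labels: dict[int, str] = {}
        for page, (code, label) in entries.items():
            if code in labels and labels[code] != label:
                raise UsageDataError(
                    f"code {code} maps to two group labels: "
                    f"{labels[code]!r} and {label!r} (page {page!r})"
                )
            labels[code] = label
        self.entries = dict(entries)
        self._label_for_code = labels

    def code_for(self, page_id: str) -> int:
        """Code for a page; unknown pages get the reserved uncoded code."""
        entry = self.entries.get(page_id)
        return entry[0] if entry is not None else UNCODED_CODE

    def label_for_code(self, code: int) -> str:
        if code == UNCODED_CODE and code not in self._label_for_code:
            return UNCODED_LABEL
        return self._label_for_code[code]

    def codes_for_label(self, label: str) -> set[int]:
        codes = {c for c, lb in self._label_for_code.items() if lb == label}
        if not codes and label == UNCODED_LABEL:
            return {UNCODED_CODE}
        if not codes:
            raise KeyError(f"unknown group label {label!r}")
        return codes

    def pages_for_label(self, label: str) -> set[str]:
        codes = self.codes_for_label(label)
        return {p for p, (c, _) in self.entries.items() if c in codes}

    @property
    def labels(self) -> list[str]:
        """Group labels ordered by ascending code."""
        return [self._label_for_code[c] for c in sorted(self._label_for_code)]

    @property
    def codes(self) -> list[int]:
        return sorted(self._label_for_code)

    def __contains__(self, page_id: str) -> bool:
        return page_id in self.entries

    def __eq__(self, other):
        return isinstance(other, CodingMap) and self.entries == other.entries


class ColorMap:
    """code -> hex color, one color per code."""

    def __init__(self, entries: dict[int, str]):
        for code, color in entries.items():
            if not _HEX_RE.match(color):
                raise UsageDataError(f"invalid hex color {color!r} for code {code}")
        self.entries = dict(entries)

    def color_for(self, code: int, strict: bool = False) -> str:
        if code in self.entries:
            return self.entries[code]
        if strict:
            raise UsageDataError(f"no color defined for code {code}")
        return UNCODED_COLOR

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __eq__(self, other):
        return isinstance(other, ColorMap) and self.entries == other.entries


@dataclass
class Dataset:
    """The assembled in-memory dataset all downstream modules consume.

    ``users`` is a DataFrame indexed by ``user_id`` (opaque strings);
    ``flow`` preserves file order, which is the tie-break for simultaneous
    views.
    """

    flow: list[PageFlowRecord]
    coding: CodingMap
    colors: ColorMap
    users: pd.DataFrame
    n_uncoded_views: int = 0
    unknown_users: list[str] = field(default_factory=list)

    _flow_frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def flow_frame(self) -> pd.DataFrame:
        """Flow as a DataFrame with a ``code`` column; cached."""
        if self._flow_frame is None:
            self._flow_frame = pd.DataFrame(
                {
                    "user_id": [r.user_id for r in self.flow],
                    "page_id": [r.page_id for r in self.flow],
                    "start": [r.start for r in self.flow],
                    "duration_s": [r.duration_s for r in self.flow],
                    "code": [self.coding.code_for(r.page_id) for r in self.flow],
                }
            )
        return self._flow_frame

    @property
    def user_ids(self) -> list[str]:
        return list(self.users.index)

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.flow == other.flow
            and self.coding == other.coding
            and self.colors == other.colors
            and self.users.equals(other.users)
        )


# ---------------------------------------------------------------------------
# readers


def _read_table(path, dialect: str, required: list[str] | None) -> pd.DataFrame:
    sep = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header row)") from None
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_page_flow(path, dialect: str = "comma") -> list[PageFlowRecord]:
    """Parse a page-flow file into records, preserving file order.

    Timestamps are parsed as ISO 8601 and coerced to UTC; durations must be
    non-negative reals.  Malformed rows raise :class:`RowError` with the
    1-based data line number (header = line 1).
    """
    df = _read_table(path, dialect, PAGE_FLOW_COLUMNS)
    records: list[PageFlowRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            start = pd.Timestamp(row.start)
        except (ValueError, TypeError):
            raise RowError(f"unparsable timestamp {row.start!r}", line) from None
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        else:
            start = start.tz_convert("UTC")
        try:
            duration = float(row.duration_s)
        except ValueError:
            raise RowError(f"unparsable duration {row.duration_s!r}", line) from None
        try:
            records.append(
                PageFlowRecord(
                    user_id=row.user_id,
                    page_id=row.page_id,
                    start=start,
                    duration_s=duration,
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return records


def write_page_flow(records: list[PageFlowRecord], path, dialect: str = "comma") -> None:
    sep = "," if dialect == "comma" else "\t"
    df = pd.DataFrame(
        {
            "user_id": [r.user_id for r in records],
            "page_id": [r.page_id for r in records],
            "start": [r.start.isoformat() for r in records],
            "duration_s": [r.duration_s for r in records],
        },
        columns=PAGE_FLOW_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def read_coding(path, dialect: str = "comma") -> CodingMap:
    """Parse a coding file; duplicate page ids are an error, but many pages
    may share one code/group."""
    df = _read_table(path, dialect, CODING_COLUMNS)
    entries: dict[str, tuple[int, str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.page_id in entries:
            raise RowError(f"duplicate page_id {row.page_id!r} in coding file", line)
        try:
            code = int(row.code)
        except ValueError:
            raise RowError(f"unparsable code {row.code!r}", line) from None
        if code <= 0:
            raise RowError(f"code must be a positive integer, got {code}", line)
        entries[row.page_id] = (code, row.group_label)
    if not entries:
        raise SchemaError(f"{path}: coding file has no entries")
    return CodingMap(entries)


def read_colors(path, dialect: str = "comma") -> ColorMap:
    df = _read_table(path, dialect, COLOR_COLUMNS)
    entries: dict[int, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            code = int(row.code)
        except ValueError:
            raise RowError(f"unparsable code {row.code!r}", line) from None
        if code in entries:
            raise RowError(f"duplicate code {code} in color file", line)
        if not _HEX_RE.match(row.hex):
            raise RowError(f"invalid hex color {row.hex!r}", line)
        entries[code] = row.hex
    if not entries:
        raise SchemaError(f"{path}: color file has no entries")
    return ColorMap(entries)


def read_users(path, dialect: str = "comma") -> pd.DataFrame:
    """Parse a user-data file into a DataFrame indexed by user_id.

    Columns other than ``user_id`` keep their names and are coerced to
    numeric where every non-empty value parses as a number.
    """
    df = _read_table(path, dialect, ["user_id"])
    if df["user_id"].duplicated().any():
        dup = df["user_id"][df["user_id"].duplicated()].iloc[0]
        raise UsageDataError(f"{path}: duplicate user_id {dup!r}")
    df = df.set_index("user_id")
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
        nonempty = df[col] != ""
        if nonempty.any() and converted[nonempty].notna().all():
            df[col] = converted
    return df


def write_users(users: pd.DataFrame, path, dialect: str = "comma") -> None:
    users.to_csv(path, sep="," if dialect == "comma" else "\t", index=True)


def assemble_dataset(
    flow: list[PageFlowRecord],
    coding: CodingMap,
    colors: ColorMap,
    users: pd.DataFrame,
    strict: bool = False,
) -> Dataset:
    """Join the four parts into one :class:`Dataset`.

    In strict mode any page id missing from the coding map, or flow user
    absent from the user table, raises.  Otherwise unknown pages count as
    uncoded (code 0) and unknown users are flagged on the dataset; both are
    logged so gaps surface rather than vanish.
    """
    n_uncoded = 0
    for rec in flow:
        if rec.page_id not in coding:
            if strict:
                raise UsageDataError(
                    f"page {rec.page_id!r} not present in coding file (strict mode)"
                )
            n_uncoded += 1
    known_users = set(users.index)
    unknown = sorted({r.user_id for r in flow} - known_users)
    if unknown and strict:
        raise UsageDataError(f"flow user(s) absent from user table: {unknown}")
    if n_uncoded:
        logger.warning("%d page view(s) had no coding entry; mapped to code 0", n_uncoded)
    if unknown:
        logger.warning("%d flow user(s) absent from user table: %s", len(unknown), unknown)
    return Dataset(
        flow=list(flow),
        coding=coding,
        colors=colors,
        users=users,
        n_uncoded_views=n_uncoded,
        unknown_users=unknown,
    )


def load_dataset(
    flow_path,
    users_path,
    coding_path,
    colors_path,
    dialect: str = "comma",
    strict: bool = False,
) -> Dataset:
    """Read all four files and assemble them."""
    return assemble_dataset(
        read_page_flow(flow_path, dialect),
        read_coding(coding_path, dialect),
        read_colors(colors_path, dialect),
        read_users(users_path, dialect),
        strict=strict,
    )


def reassemble(dataset: Dataset, strict: bool = False) -> Dataset:
    """Assemble a dataset from an already-assembled dataset's parts
    (idempotence entry point)."""
    ds = assemble_dataset(
        dataset.flow, dataset.coding, dataset.colors, dataset.users, strict=strict
    )
    return replace(ds)
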