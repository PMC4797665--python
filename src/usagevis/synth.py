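"""Synthetic usage-log generator for a tunneled weight-management
intervention.

The generator emits the four input files (page flow, user data, coding,
colors) plus a ground-truth record, with the statistical structure the
analyses assume:

* three **core sessions** unlock weekly in sequence (session 1 split into
  two parts, with a final page so "completed the session" is observable);
* from week 2 every login opens with a **goal and weight review**; after
  the core weeks a user may pick one of nine **optional sessions** per week;
* **tools** (food diary, steps diary, getting-support tools) are exposed
  during their core session and may be *reused* on later login occasions;
* users drop out week-to-week with constant hazard 1−q, with an extra
  "rapid early drop" multiplier on the transition into week 2 — the
  high-then-stable nonusage-attrition shape typical of these trials;
* dwell times per page are log-normal (median ≈ 30 s by default);
* the outcome follows weight_change = β0 + β1·reused(steps diary) + N(0, σ_w),
  so moderator tests have a known signal to recover.

Default tool-reuse rates are calibrated so the expected reuse fractions
match the magnitudes reported for this class of intervention (food diary
reused by over half of users, steps diary by roughly an eighth).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    CodingMap,
    ColorMap,
    Dataset,
    PageFlowRecord,
    assemble_dataset,
    write_page_flow,
    write_users,
)
from .sequences import viewers_of_group
from .stats import pooled_t_from_samples

OPTIONAL_SESSIONS = [
    "cravings",
    "slipups",
    "stretching physical activity",
    "tough times",
    "busy lives",
    "setting up your environment",
    "drinks",
    "eating out",
    "maintaining weight loss",
]

CORE_LABELS = [
    "eating plan part 1",
    "eating plan part 2",
    "support",
    "physical activity",
]

TOOL_LABELS = ["food diary", "steps diary", "getting support tools"]

#: week in which each tools group is first exposed (with its core session)
TOOL_EXPOSURE_WEEK = {"food diary": 1, "steps diary": 3, "getting support tools": 2}

REVIEW_LABEL = "goal and weight review"

_PALETTE = [
    "#1F77B4", "#AEC7E8", "#FF7F0E", "#FFBB78", "#2CA02C", "#98DF8A",
    "#D62728", "#FF9896", "#9467BD", "#C5B0D5", "#8C564B", "#C49C94",
    "#E377C2", "#F7B6D2", "#7F7F7F", "#C7C7C7", "#BCBD22", "#DBDB8D",
]


def default_coding() -> CodingMap:
    """Page universe: codes 1–4 core, 5–13 optional, 14 review, 15–17 tools."""
    entries: dict[str, tuple[int, str]] = {}
    for i in range(4):
        entries[f"s1p1_{i}"] = (1, "eating plan part 1")
    for i in range(4):  # s1p2_3 is the last page of session 1
        entries[f"s1p2_{i}"] = (2, "eating plan part 2")
    for i in range(4):
        entries[f"s2_{i}"] = (3, "support")
    for i in range(4):
        entries[f"s3_{i}"] = (4, "physical activity")
    for k, name in enumerate(OPTIONAL_SESSIONS):
        for i in range(3):
            entries[f"opt{k}_{i}"] = (5 + k, name)
    for i in range(2):
        entries[f"gwr_{i}"] = (14, REVIEW_LABEL)
    for i in range(2):
        entries[f"tool_fd_{i}"] = (15, "food diary")
    for i in range(2):
        entries[f"tool_sd_{i}"] = (16, "steps diary")
    for i in range(2):
        entries[f"tool_gs_{i}"] = (17, "getting support tools")
    return CodingMap(entries)


def default_colors() -> ColorMap:
    return ColorMap({code: _PALETTE[(code - 1) % len(_PALETTE)] for code in range(1, 18)})


@dataclass
class SimConfig:
    """Study conditions for one simulated trial cohort.

    ``q`` is the weekly continuation probability; ``early_drop`` multiplies
    it on the week-1 → week-2 transition only.  ``reuse_rate`` gives the
    expected number of reuse occasions per exposed user for each tools
    group (Poisson, truncated by the user's remaining active weeks).
    """

    n_users: int = 132
    n_weeks: int = 12
    q: float = 0.9
    early_drop: float = 0.8
    p_opt: float = 0.5
    p_part2: float = 0.91  # continue from part 1 to part 2 of session 1
    p_complete_s1: float = 0.96  # reach the last page of session 1 given part 2
    dwell_mu_log: float = 3.4
    dwell_sigma_log: float = 0.8
    reuse_rate: dict[str, float] = field(
        default_factory=lambda: {
            "food diary": 0.86,
            "steps diary": 0.21,
            "getting support tools": 1.05,
        }
    )
    beta0: float = 2.63
    beta1: float = 3.15
    sigma_w: float = 5.73
    seed: int = 0

    def __post_init__(self):
        for name in ("q", "early_drop"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("p_opt", "p_part2", "p_complete_s1"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dwell_sigma_log <= 0 or self.sigma_w <= 0:
            raise ValueError("scale parameters must be > 0")
        if isinstance(self.reuse_rate, (int, float)):
            self.reuse_rate = {g: float(self.reuse_rate) for g in TOOL_LABELS}
        if self.n_users < 1 or self.n_weeks < 3:
            raise ValueError("need n_users >= 1 and n_weeks >= 3")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Latent per-user state consistent with the emitted files."""

    users: dict[str, dict]
    beta0: float
    beta1: float
    sigma_w: float
    attrition: list[float]  # realized fraction reaching core weeks 1..3

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _pages_for(coding: CodingMap, label: str) -> list[str]:
    return sorted(coding.pages_for_label(label))


def generate(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate the cohort and return the assembled dataset plus truth.

    Weekly sessions happen on a fixed weekday evening; tool-reuse occasions
    are separate logins three days later, so the >60-minute occasion rule
    recovers the latent reuse flags exactly.
    """
    rng = np.random.default_rng(config.seed)
    coding = default_coding()
    colors = default_colors()
    width = max(3, len(str(config.n_users)))
    user_ids = [f"u{i + 1:0{width}d}" for i in range(config.n_users)]

    flow: list[PageFlowRecord] = []
    truth_users: dict[str, dict] = {}
    reached = np.zeros(3, dtype=int)

    base = pd.Timestamp("2011-06-01 18:00:00", tz="UTC")

    def dwell() -> float:
        return float(np.round(rng.lognormal(config.dwell_mu_log, config.dwell_sigma_log), 1))

    def view_pages(user, start, pages):
        t = start
        for page in pages:
            d = dwell()
            flow.append(PageFlowRecord(user, page, t, d))
            t = t + pd.Timedelta(seconds=d + float(rng.integers(1, 6)))
        return t

    for user in user_ids:
        offset = pd.Timedelta(days=int(rng.integers(0, 60)), minutes=int(rng.integers(0, 120)))
        # survive the transition into week w+1
        last_week = 1
        while last_week < config.n_weeks:
            p = config.q * (config.early_drop if last_week == 1 else 1.0)
            if rng.random() < p:
                last_week += 1
            else:
                break
        for k in range(3):  # core weeks reached
            if last_week >= k + 1:
                reached[k] += 1

        sessions_completed = 0
        n_reviews = 0
        opt_pool = list(range(len(OPTIONAL_SESSIONS)))
        optional_used: list[str] = []
        for week in range(1, last_week + 1):
            start = base + offset + pd.Timedelta(days=7 * (week - 1))
            if week >= 2:
                start = view_pages(user, start, _pages_for(coding, REVIEW_LABEL))
                n_reviews += 1
            if week == 1:
                start = view_pages(user, start, _pages_for(coding, "eating plan part 1"))
                if rng.random() < config.p_part2:
                    part2 = _pages_for(coding, "eating plan part 2")
                    if rng.random() >= config.p_complete_s1:
                        part2 = part2[:-1]  # dropped before the last page
                    start = view_pages(user, start, part2)
                start = view_pages(user, start, _pages_for(coding, "food diary"))
                sessions_completed += 1
            elif week == 2:
                start = view_pages(user, start, _pages_for(coding, "support"))
                start = view_pages(user, start, _pages_for(coding, "getting support tools"))
                sessions_completed += 1
            elif week == 3:
                start = view_pages(user, start, _pages_for(coding, "physical activity"))
                start = view_pages(user, start, _pages_for(coding, "steps diary"))
                sessions_completed += 1
            else:
                if opt_pool and rng.random() < config.p_opt:
                    k = int(opt_pool.pop(int(rng.integers(0, len(opt_pool)))))
                    name = OPTIONAL_SESSIONS[k]
                    start = view_pages(user, start, _pages_for(coding, name))
                    optional_used.append(name)

        reused: dict[str, bool] = {}
        for label in TOOL_LABELS:
            w0 = TOOL_EXPOSURE_WEEK[label]
            slots = list(range(w0, last_week + 1))
            if last_week < w0 or not slots:
                reused[label] = False
                continue
            n_reuse = min(int(rng.poisson(config.reuse_rate[label])), len(slots))
            weeks = rng.choice(slots, size=n_reuse, replace=False) if n_reuse else []
            for w in sorted(int(w) for w in np.atleast_1d(weeks)):
                start = base + offset + pd.Timedelta(days=7 * (w - 1) + 3, hours=-6)
                view_pages(user, start, _pages_for(coding, label))
            reused[label] = n_reuse >= 1

        truth_users[user] = {
            "last_week": last_week,
            "sessions_completed": sessions_completed,
            "n_reviews": n_reviews,
            "optional_used": optional_used,
            "reused": reused,
        }

    # user table: characteristics + outcome tied to steps-diary reuse
    n = config.n_users
    age = np.round(rng.normal(51.56, 12.96, n), 1)
    edu = np.round(rng.normal(17.82, 2.93, n), 1)
    bmi = np.round(np.clip(rng.normal(35.49, 5.70, n), 28, None), 1)
    weight = np.round(rng.normal(100.66, 21.02, n), 1)
    sex = np.where(rng.random(n) < 0.338, "male", "female")
    arm = rng.choice(["web", "web_basic_nurse", "web_regular_nurse"], size=n)
    plan = rng.choice(["low_calorie", "low_carbohydrate"], size=n)
    reused_steps = np.array(
        [truth_users[u]["reused"]["steps diary"] for u in user_ids], dtype=float
    )
    weight_change = np.round(
        config.beta0 + config.beta1 * reused_steps + rng.normal(0, config.sigma_w, n), 2
    )
    users = pd.DataFrame(
        {
            "age": age,
            "age_left_education": edu,
            "bmi": bmi,
            "weight_kg": weight,
            "sex": sex,
            "arm": arm,
            "eating_plan": plan,
            "n_reviews": [truth_users[u]["n_reviews"] for u in user_ids],
            "weight_change_kg": weight_change,
        },
        index=pd.Index(user_ids, name="user_id"),
    )

    truth = GroundTruth(
        users=truth_users,
        beta0=config.beta0,
        beta1=config.beta1,
        sigma_w=config.sigma_w,
        attrition=[float(r) / n for r in reached],
    )
    dataset = assemble_dataset(flow, coding, colors, users, strict=True)
    return dataset, truth


def write_files(dataset: Dataset, truth: GroundTruth, outdir) -> dict[str, str]:
    """Write page_flow.csv, users.csv, coding.csv, colors.csv and truth.json;
    returns the path map.  Byte-identical for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: str(outdir / f"{name}.csv")
             for name in ("page_flow", "users", "coding", "colors")}
    write_page_flow(dataset.flow, paths["page_flow"])
    write_users(dataset.users, paths["users"])
    coding_rows = sorted(
        (page, code, label) for page, (code, label) in dataset.coding.entries.items()
    )
    pd.DataFrame(coding_rows, columns=["page_id", "code", "group_label"]).to_csv(
        paths["coding"], index=False
    )
    color_rows = sorted(dataset.colors.entries.items())
    pd.DataFrame(color_rows, columns=["code", "hex"]).to_csv(paths["colors"], index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = str(truth_path)
    return paths


def attrition_curve(dataset: Dataset, session_labels: list[str] | None = None) -> pd.Series:
    """Fraction of users with >= 1 view of each session group.

    Defaults to the core session groups in tunnel order, where the curve is
    non-increasing by construction.  Empty flow yields an empty curve.
    """
    if not dataset.flow:
        return pd.Series(dtype=float)
    if session_labels is None:
        session_labels = CORE_LABELS
    n = len(dataset.users)
    return pd.Series(
        {label: len(viewers_of_group(dataset, label)) / n for label in session_labels},
        name="retention",
    )[session_labels]


# ---------------------------------------------------------------------------
# Monte-Carlo studies of the moderator test under the outcome model


def simulate_rejection_rate(
    n0: int,
    n1: int,
    delta: float,
    sigma: float,
    reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the pooled t test rejects at
    ``alpha``, under weight_change = β0 + delta·group + N(0, sigma).

    With ``delta=0`` this estimates the type-I error; with a nonzero delta
    it estimates power at the given group sizes.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        x = rng.normal(0.0, sigma, n0)
        y = rng.normal(delta, sigma, n1)
        if pooled_t_from_samples(x, y).p < alpha:
            hits += 1
    return hits / reps
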