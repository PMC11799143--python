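"""Measurement pipeline for the waiting-time mouse-tracking experiment.

Participants judge whether black tiles exceed 50% of a grid stimulus by
clicking a "yes"/"no" button; three between-participant groups wait 0 s,
1 s or 2.5 s before the buttons appear.  This module turns the raw trial,
trajectory and block-rating tables into the quantities the analysis is
built on:

* outlier filtering (responses over 6 s are excluded),
* per-participant accuracy, overall and within response-time categories,
* cumulative response-time distributions in 0.1-s bins,
* time-normalized mouse-trajectory AUC as an index of cognitive conflict,
* irritation scores (maximum of nine block ratings on a 0–100 scale),
* effect sizes: Cliff's delta, eta-squared, Holm-adjusted pairwise p-values.

Tables are plain pandas DataFrames with the column schemas documented on
each function; ``analyze_dataset`` runs the whole pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RT_CATEGORY_LABELS",
    "annotate_trials",
    "filter_trials",
    "time_normalize",
    "auc",
    "trajectory_auc",
    "trial_aucs",
    "rt_category",
    "accuracy_by",
    "participant_accuracy",
    "rt_cdf",
    "irritation_scores",
    "cliffs_delta",
    "holm_adjust",
    "group_compare",
    "analyze_dataset",
    "AnalysisResults",
]

#: Response-time category edges in seconds.  Bins are right-open except the
#: last, which is closed at the 6-s outlier boundary: [0,1), [1,2.5),
#: [2.5,4), [4,6].
RT_CATEGORY_EDGES = (0.0, 1.0, 2.5, 4.0, 6.0)
RT_CATEGORY_LABELS = ("~1.0 s", "1.0–2.5 s", "2.5–4.0 s", "4.0 s ~")

DIFFICULT_PROPORTIONS = frozenset({0.45, 0.55})
EASY_PROPORTIONS = frozenset({0.35, 0.65})


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty table it cannot summarize."""


def annotate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive ``correct`` and ``difficulty`` columns from a raw trial table.

    Expects columns ``participant_id, group, proportion, response, rt_s``
    (``response`` in {"yes", "no"}).  A response is correct when it matches
    the side of 0.5 the true proportion lies on; 0.45/0.55 stimuli are
    difficult, 0.35/0.65 easy.
    """
    required = {"participant_id", "group", "proportion", "response", "rt_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    out = trials.copy()
    prop = out["proportion"].astype(float)
    out["correct"] = ((out["response"] == "yes") & (prop > 0.5)) | (
        (out["response"] == "no") & (prop < 0.5)
    )
    out["difficulty"] = np.where(
        prop.round(2).isin([0.45, 0.55]), "difficult", "easy"
    )
    return out


def filter_trials(
    trials: pd.DataFrame, rt_max: float = 6.0
) -> tuple[pd.DataFrame, float]:
    """Drop outlier trials with response time strictly over ``rt_max`` seconds.

    Returns the kept trials and the excluded fraction.  Trials at exactly
    ``rt_max`` are kept ("over 6 s" is strict).
    """
    if len(trials) == 0:
        raise EmptyInputError("cannot filter an empty trial table")
    if (trials["rt_s"] < 0).any():
        raise ValueError("negative response times in trial table")
    keep = trials["rt_s"] <= rt_max
    return trials.loc[keep].reset_index(drop=True), float(1.0 - keep.mean())


def time_normalize(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    n_points: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a trajectory to ``n_points`` equal time fractions.

    x and y are linearly interpolated, independently, at fractions
    0, 1/(n-1), ..., 1 of the total duration; endpoints are preserved
    exactly.  Duplicate timestamps are collapsed to their last sample.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("trajectory needs at least two samples")
    if np.any(np.diff(t) < 0):
        raise ValueError("trajectory timestamps must be non-decreasing")
    if t[-1] - t[0] <= 0:
        raise ValueError("trajectory has zero duration")
    if t.size != x.size or t.size != y.size:
        raise ValueError("t, x, y must have equal length")
    # collapse duplicated timestamps (keep the last sample at each time)
    keep = np.append(np.diff(t) > 0, True)
    t, x, y = t[keep], x[keep], y[keep]
    grid = t[0] + (t[-1] - t[0]) * np.linspace(0.0, 1.0, n_points)
    xn = np.interp(grid, t, x)
    yn = np.interp(grid, t, y)
    xn[0], yn[0], xn[-1], yn[-1] = x[0], y[0], x[-1], y[-1]
    return xn, yn


def auc(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area between a trajectory and the straight start→end line.

    Coordinates are rotated so the direct path is the horizontal axis with
    the start at the origin; the perpendicular deviation is integrated
    along the direct-path coordinate with the trapezoidal rule.  Deviations
    to the *left* of the start→end direction count positive (flip the sign
    with :func:`trajectory_auc` for a task-specific convention); excursions
    on the opposite side subtract.  Units are squared input units (px²).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    length = float(np.hypot(dx, dy))
    if length == 0.0:
        raise ValueError("start and end points coincide; direct path undefined")
    ux, uy = dx / length, dy / length
    rx, ry = x - x[0], y - y[0]
    s = rx * ux + ry * uy  # along-path coordinate
    d = ux * ry - uy * rx  # perpendicular deviation, left positive
    return float(np.trapezoid(d, s))


def trajectory_auc(
    x: np.ndarray,
    y: np.ndarray,
    toward: tuple[float, float] | None = None,
) -> float:
    """AUC with deviation toward a reference point counted positive.

    ``toward`` is a point on the side that should count positive — in the
    choice task, the non-chosen button.  When omitted, the non-chosen
    button is taken as the mirror image of the endpoint across the vertical
    line through the start (buttons are laid out symmetrically about the
    screen centre).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if toward is None:
        toward = (2.0 * x[0] - x[-1], y[-1])
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    side = dx * (toward[1] - y[0]) - dy * (toward[0] - x[0])  # cross product
    if side == 0.0:
        raise ValueError("reference point lies on the direct path")
    return float(np.sign(side)) * auc(x, y)


def trial_aucs(
    trajectories: pd.DataFrame,
    n_points: int = 101,
) -> pd.DataFrame:
    """Per-trial time-normalized trajectory AUC.

    ``trajectories`` is long-format with columns
    ``participant_id, trial_id, t_s, x_px, y_px``.  Returns one row per
    (participant_id, trial_id) with the signed AUC (positive toward the
    non-chosen button) in px².
    """
    rows = []
    for (pid, tid), g in trajectories.groupby(
        ["participant_id", "trial_id"], sort=False
    ):
        g = g.sort_values("t_s")
        xn, yn = time_normalize(
            g["t_s"].to_numpy(), g["x_px"].to_numpy(), g["y_px"].to_numpy(), n_points
        )
        rows.append((pid, tid, trajectory_auc(xn, yn)))
    return pd.DataFrame(rows, columns=["participant_id", "trial_id", "auc_px2"])


def rt_category(rt) -> np.ndarray | str:
    """Response-time category of a filtered trial.

    Bins: [0, 1.0) → "~1.0 s", [1.0, 2.5) → "1.0–2.5 s", [2.5, 4.0) →
    "2.5–4.0 s", [4.0, 6.0] → "4.0 s ~".  Times over 6 s must have been
    filtered out first.
    """
    arr = np.asarray(rt, dtype=float)
    if np.any(arr > 6.0):
        raise ValueError("response times over 6 s must be filtered before binning")
    if np.any(arr < 0.0):
        raise ValueError("negative response time")
    idx = np.clip(np.digitize(arr, RT_CATEGORY_EDGES[1:-1], right=False), 0, 3)
    labels = np.asarray(RT_CATEGORY_LABELS, dtype=object)[idx]
    return str(labels) if arr.ndim == 0 else labels


def accuracy_by(
    trials: pd.DataFrame,
    keys: Sequence[str] = ("group", "difficulty"),
) -> pd.DataFrame:
    """Trial counts and mean accuracy per cell of a grouping.

    ``keys`` may include the derived column ``rt_category``, which is
    computed on the fly.  Cells with no trials are reported with ``n = 0``
    and missing accuracy rather than silently dropped.
    """
    df = trials.copy()
    if "rt_category" in keys and "rt_category" not in df.columns:
        df["rt_category"] = rt_category(df["rt_s"].to_numpy())
    if "rt_category" in df.columns:
        df["rt_category"] = pd.Categorical(
            df["rt_category"], categories=RT_CATEGORY_LABELS, ordered=True
        )
    grouped = df.groupby(list(keys), observed=True)["correct"]
    table = grouped.agg(n="size", accuracy="mean").reset_index()
    empty = table["n"] == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty cell(s) in accuracy table", stacklevel=2
        )
        table.loc[empty, "accuracy"] = np.nan
    return table


def participant_accuracy(
    trials: pd.DataFrame,
    keys: Sequence[str] = ("group", "difficulty"),
) -> pd.DataFrame:
    """Per-participant accuracy — the unit of analysis for group tests."""
    grouped = trials.groupby(["participant_id", *keys], observed=False)["correct"]
    return grouped.agg(n="size", accuracy="mean").reset_index()


def rt_cdf(
    trials: pd.DataFrame,
    bin_width: float = 0.1,
    rt_max: float = 6.0,
) -> pd.DataFrame:
    """Cumulative response-time distributions per group × difficulty × correctness.

    The [0, 6] s range is divided into bins of ``bin_width`` (60 bins by
    default, with edges at 0.1, 0.2, ..., 6.0); each row gives the fraction of
    a stratum's trials with rt ≤ the bin's upper edge.  Values are
    non-decreasing and reach 1 at the last edge.  Empty strata are omitted
    with a warning.
    """
    n_bins = int(round(rt_max / bin_width))
    edges = bin_width * np.arange(1, n_bins + 1)
    rows = []
    strata = trials.groupby(["group", "difficulty", "correct"], observed=False)
    for (group, difficulty, correct), g in strata:
        if len(g) == 0:
            warnings.warn(
                f"empty stratum ({group}, {difficulty}, correct={correct}) "
                "omitted from RT CDF",
                stacklevel=2,
            )
            continue
        cum = np.searchsorted(np.sort(g["rt_s"].to_numpy()), edges, side="right")
        frame = pd.DataFrame(
            {
                "group": group,
                "difficulty": difficulty,
                "correct": correct,
                "bin_upper_s": edges,
                "cumulative_prob": cum / len(g),
            }
        )
        rows.append(frame)
    if not rows:
        raise EmptyInputError("no non-empty strata for RT CDF")
    return pd.concat(rows, ignore_index=True)


def irritation_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant irritation: the maximum of the nine block ratings.

    ``ratings`` has columns ``participant_id, group, block, rating`` with
    ratings on the 0–100 visual-analog scale.  Participants who rated 0 in
    every block are flagged ``excluded`` (judged inattentive) and should not
    enter group comparisons.
    """
    if ((ratings["rating"] < 0) | (ratings["rating"] > 100)).any():
        raise ValueError("ratings must lie in [0, 100]")
    rows = []
    for (pid, group), g in ratings.groupby(["participant_id", "group"]):
        if len(g) != 9:
            raise ValueError(
                f"participant {pid!r} has {len(g)} block ratings; expected 9"
            )
        score = int(g["rating"].max())
        rows.append((pid, group, score, score == 0))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "irritation", "excluded"]
    )


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size: P(x > y) − P(x < y) over all pairs.

    Ranges over [−1, 1]; 0 means stochastic equality, ±1 complete
    separation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires two non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    The i-th smallest p-value is multiplied by (m − i), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _eta_squared(groups: Sequence[np.ndarray]) -> float:
    """eta² = SS_between / SS_total for a one-way layout."""
    allvals = np.concatenate(groups)
    grand = allvals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(np.sum((allvals - grand) ** 2))
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "anova+holm",
) -> dict:
    """Omnibus and pairwise comparison of per-participant values across groups.

    ``design="anova+holm"`` (accuracy analyses): one-way ANOVA F and p,
    eta-squared, and Holm-adjusted Welch pairwise t-tests.
    ``design="ranksum"`` (irritation, two groups): Mann–Whitney U statistic
    and p with Cliff's delta.  The F/W/p machinery is delegated to scipy;
    eta-squared, Cliff's delta and the Holm adjustment are computed here.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    if design == "anova+holm":
        f_stat, p = stats.f_oneway(*groups)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        raw_p = [
            stats.ttest_ind(
                values_by_group[a], values_by_group[b], equal_var=False
            ).pvalue
            for a, b in pairs
        ]
        adj = holm_adjust(raw_p)
        return {
            "design": design,
            "F": float(f_stat),
            "p": float(p),
            "eta_squared": _eta_squared(groups),
            "pairwise": [
                {"groups": list(pair), "p_raw": float(pr), "p_holm": float(pa)}
                for pair, pr, pa in zip(pairs, raw_p, adj)
            ],
        }
    if design == "ranksum":
        if len(groups) != 2:
            raise ValueError("ranksum design compares exactly two groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return {
            "design": design,
            "groups": names,
            "W": float(res.statistic),
            "p": float(res.pvalue),
            "cliffs_delta": cliffs_delta(groups[0], groups[1]),
        }
    raise ValueError(f"unknown design {design!r}")


@dataclass
class AnalysisResults:
    """Container for the full pipeline output.

    Attributes hold the intermediate and final tables; ``stats`` holds the
    omnibus/pairwise test results keyed by analysis name.
    """

    excluded_fraction: float
    accuracy_by_group: pd.DataFrame
    accuracy_by_time_category: pd.DataFrame
    participant_accuracy: pd.DataFrame
    rt_cdf: pd.DataFrame
    auc_by_time_category: pd.DataFrame | None
    irritation: pd.DataFrame | None
    stats: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Trials excluded (> 6 s): {100 * self.excluded_fraction:.1f}%",
            "",
            "Per-group accuracy:",
            self.accuracy_by_group.to_string(index=False),
        ]
        if self.auc_by_time_category is not None:
            lines += [
                "",
                "Mean trajectory AUC by RT category (px²):",
                self.auc_by_time_category.to_string(index=False),
            ]
        if self.irritation is not None:
            kept = self.irritation.loc[~self.irritation["excluded"]]
            means = kept.groupby("group")["irritation"].mean()
            lines += ["", "Irritation (max of 9 block ratings), group means:"]
            lines += [f"  {g}: {m:.2f}" for g, m in means.items()]
        for name, res in self.stats.items():
            if res["design"] == "anova+holm":
                lines.append(
                    f"{name}: F = {res['F']:.2f}, p = {res['p']:.4g}, "
                    f"eta² = {res['eta_squared']:.3f}"
                )
            else:
                lines.append(
                    f"{name}: W = {res['W']:.1f}, p = {res['p']:.4g}, "
                    f"Cliff's delta = {res['cliffs_delta']:.3f}"
                )
        return "\n".join(lines)


def analyze_dataset(
    trials: pd.DataFrame,
    trajectories: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    rt_max: float = 6.0,
) -> AnalysisResults:
    """Run the full measurement pipeline on one dataset.

    Steps: annotate and filter trials; per-group and per-RT-category
    accuracy (with one-way ANOVA + Holm pairwise tests on per-participant
    accuracy within each difficulty); cumulative RT distributions; per-trial
    trajectory AUC averaged by RT category; irritation scoring with a
    rank-sum comparison of the 1 s and 2.5 s groups.
    """
    df = annotate_trials(trials)
    df, excluded = filter_trials(df, rt_max=rt_max)
    df["rt_category"] = pd.Categorical(
        rt_category(df["rt_s"].to_numpy()),
        categories=RT_CATEGORY_LABELS,
        ordered=True,
    )

    acc_group = accuracy_by(df, ["group", "difficulty"])
    acc_cat = accuracy_by(df, ["group", "difficulty", "rt_category"])
    per_part = participant_accuracy(df, ["group", "difficulty"])

    stats_out: dict = {}
    for difficulty, sub in per_part.groupby("difficulty"):
        by_group = {
            g: s["accuracy"].to_numpy() for g, s in sub.groupby("group", sort=True)
        }
        stats_out[f"accuracy_{difficulty}"] = group_compare(by_group, "anova+holm")

    cdf = rt_cdf(df, rt_max=rt_max)

    auc_cat = None
    if trajectories is not None and len(trajectories):
        aucs = trial_aucs(trajectories)
        keep_ids = df["trial_id"] if "trial_id" in df.columns else None
        merged = df.merge(aucs, on=["participant_id", "trial_id"], how="inner")
        auc_cat = (
            merged.groupby(["group", "difficulty", "rt_category"], observed=True)[
                "auc_px2"
            ]
            .agg(n="size", mean_auc="mean")
            .reset_index()
        )

    irritation = None
    if ratings is not None and len(ratings):
        irritation = irritation_scores(ratings)
        kept = irritation.loc[~irritation["excluded"]]
        waited = kept.loc[kept["group"].isin(["1s", "2.5s"])]
        if waited["group"].nunique() == 2:
            # delta > 0 means the longer wait is the more irritating one
            by_group = {
                g: waited.loc[waited["group"] == g, "irritation"].to_numpy()
                for g in ("2.5s", "1s")
            }
            stats_out["irritation_2.5s_vs_1s"] = group_compare(by_group, "ranksum")

    return AnalysisResults(
        excluded_fraction=excluded,
        accuracy_by_group=acc_group,
        accuracy_by_time_category=acc_cat,
        participant_accuracy=per_part,
        rt_cdf=cdf,
        auc_by_time_category=auc_cat,
        irritation=irritation,
        stats=stats_out,
    )
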