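"""Synthetic behavioral datasets with the waiting-time experiment's structure.

The generator emulates the design the measurement pipeline expects: three
between-participant waiting-time groups (0 s, 1 s, 2.5 s), 9 blocks of 40
grid-judgment trials per participant, four stimulus proportions (35/45/55/65%
black, 90 trials each), mouse trajectories from screen centre to the chosen
button, and nine per-block irritation ratings for the groups that waited.

Injected effects are chosen so the pipeline has something real to recover:
group-dependent accuracy (waiting helps, strongly on difficult stimuli),
response times offset by the group's enforced waiting time, trajectory AUC
growing linearly with response time, and higher irritation under the longer
wait.  Default effect sizes follow the means the original experiment reports;
see ``SynthConfig``.  The trajectory generator is deliberately simple — a
single smooth excursion whose integrated area equals a requested conflict
value — so per-trial AUC has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_trajectory",
    "generate_grid_stimulus",
]


def _default_accuracy() -> dict[tuple[str, str], float]:
    return {
        ("0s", "difficult"): 0.67,
        ("1s", "difficult"): 0.75,
        ("2.5s", "difficult"): 0.78,
        ("0s", "easy"): 0.91,
        ("1s", "easy"): 0.99,
        ("2.5s", "easy"): 0.99,
    }


def _default_waits() -> dict[str, float]:
    return {"0s": 0.0, "1s": 1.0, "2.5s": 2.5}


def _default_irritation() -> dict[str, float]:
    return {"1s": 26.0, "2.5s": 39.0}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study design: 40 participants per group, 360
    trials each (9 blocks × 40), 90 trials per stimulus proportion, and a
    2.1% outlier rate of responses over 6 s.  ``accuracy_targets`` are the
    per-(group, difficulty) correct-response probabilities; ``rt_log_median``
    / ``rt_log_sigma`` parameterize the log-normal decision-time component
    added to the group's waiting time; ``auc_slope`` injects the
    conflict-grows-with-time effect (px² of trajectory AUC per second of
    RT); ``irritation_level`` sets per-group mean irritation on the 0–100
    scale, with the longer wait the more irritating.
    """

    n_per_group: int = 40
    blocks: int = 9
    trials_per_block: int = 40
    proportions: tuple[float, ...] = (0.35, 0.45, 0.55, 0.65)
    group_wait: Mapping[str, float] = field(default_factory=_default_waits)
    accuracy_targets: Mapping[tuple[str, str], float] = field(
        default_factory=_default_accuracy
    )
    rt_log_median: float = 1.1  # s, decision-time median past the wait
    rt_log_sigma: float = 0.55  # log-space SD
    outlier_rate: float = 0.021
    auc_slope: float = 60.0  # px² per second of RT
    auc_noise: float = 15.0  # px² trial-to-trial SD around the slope line
    irritation_level: Mapping[str, float] = field(default_factory=_default_irritation)
    irritation_between_sd: float = 16.0  # participant-level spread
    irritation_block_sd: float = 7.0  # block-to-block spread below the max
    zero_rater_rate: float = 0.05  # chance a participant rates 0 everywhere
    button_offset: tuple[float, float] = (300.0, 300.0)  # px from centre (|x|, y)
    sample_hz: float = 60.0
    jitter_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.accuracy_targets.values()):
            raise ValueError("accuracy targets must be probabilities")
        if any(w < 0 for w in self.group_wait.values()):
            raise ValueError("waiting times must be non-negative")
        n_trials = self.blocks * self.trials_per_block
        if n_trials % len(self.proportions):
            raise ValueError(
                f"{n_trials} trials not divisible across {len(self.proportions)} "
                "proportions"
            )
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def trials_per_participant(self) -> int:
        return self.blocks * self.trials_per_block


@dataclass
class SyntheticDataset:
    """The three tables the analysis pipeline consumes."""

    trials: pd.DataFrame
    trajectories: pd.DataFrame
    ratings: pd.DataFrame
    config: SynthConfig


def generate_trajectory(
    rt: float,
    conflict: float,
    chosen_side: str,
    rng: np.random.Generator,
    button_offset: tuple[float, float] = (300.0, 300.0),
    sample_hz: float = 60.0,
    jitter_px: float = 0.0,
) -> pd.DataFrame:
    """One cursor path from screen centre to the chosen button.

    The path moves at constant speed along the straight line to the button at
    (±``button_offset[0]``, ``button_offset[1]``) with a half-sine
    perpendicular excursion toward the *non-chosen* button whose integrated
    area equals ``conflict`` px² — so the time-normalized AUC of the
    trajectory recovers ``conflict`` up to discretization.  Optional Gaussian
    jitter is added to interior samples; endpoints are exact.  Sampled at
    ``sample_hz``; columns ``t_s, x_px, y_px``.
    """
    t, x, y = _trajectory_arrays(
        rt, conflict, chosen_side, rng, button_offset, sample_hz, jitter_px
    )
    return pd.DataFrame({"t_s": t, "x_px": x, "y_px": y})


def _trajectory_arrays(
    rt: float,
    conflict: float,
    chosen_side: str,
    rng: np.random.Generator,
    button_offset: tuple[float, float],
    sample_hz: float,
    jitter_px: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if rt <= 0:
        raise ValueError("rt must be positive")
    if chosen_side not in ("left", "right"):
        raise ValueError("chosen_side must be 'left' or 'right'")
    bx, by = button_offset
    sign = 1.0 if chosen_side == "right" else -1.0
    end = np.array([sign * bx, by])
    n = max(int(round(rt * sample_hz)), 2) + 1
    t = np.linspace(0.0, rt, n)
    frac = t / rt
    base = frac[:, None] * end[None, :]
    length = float(np.hypot(*end))
    u = end / length
    # perpendicular pointing toward the mirrored (non-chosen) button
    perp = np.array([-u[1], u[0]])
    toward = np.array([-end[0], end[1]])
    if np.dot(perp, toward) < 0:
        perp = -perp
    amplitude = conflict * np.pi / (2.0 * length)
    path = base + (amplitude * np.sin(np.pi * frac))[:, None] * perp[None, :]
    if jitter_px > 0 and n > 2:
        path[1:-1] += rng.normal(0.0, jitter_px, size=(n - 2, 2))
    return t, path[:, 0], path[:, 1]


def generate_grid_stimulus(
    proportion: float,
    rows: int = 50,
    cols: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary grid with exactly round(proportion · rows · cols) black tiles.

    Black tiles (1) are placed uniformly at random; 0 is white.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = rows * cols
    n_black = int(round(proportion * n))
    flat = np.zeros(n, dtype=np.int8)
    flat[rng.permutation(n)[:n_black]] = 1
    return flat.reshape(rows, cols)


def _draw_rts(
    n: int, wait: float, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Wait offset + log-normal decision time, truncated to 6 s except for a
    small injected outlier fraction pushed past 6 s."""
    mu = np.log(config.rt_log_median)
    rts = wait + rng.lognormal(mu, config.rt_log_sigma, size=n)
    # resample the in-range component so the only >6 s trials are the
    # deliberately injected outliers
    for _ in range(100):
        over = rts > 6.0
        if not over.any():
            break
        rts[over] = wait + rng.lognormal(mu, config.rt_log_sigma, size=int(over.sum()))
    np.clip(rts, None, 6.0, out=rts)
    outlier = rng.random(n) < config.outlier_rate
    rts[outlier] = 6.0 + rng.exponential(1.0, size=int(outlier.sum()))
    return rts


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic experiment; bit-identical under one seed.

    Returns trial, trajectory and rating tables in the pipeline's input
    schemas.  Ratings are produced only for groups with a positive waiting
    time (the 0 s group was never asked about waiting).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    trial_rows = []
    traj_parts: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray]] = []
    rating_rows = []
    n_props = len(config.proportions)
    reps = config.trials_per_participant // n_props
    pid_counter = 0
    for group, wait in config.group_wait.items():
        for _ in range(config.n_per_group):
            pid = f"p{pid_counter:03d}"
            pid_counter += 1
            props = rng.permutation(np.repeat(config.proportions, reps))
            difficulty = np.where(np.isin(props.round(2), (0.45, 0.55)),
                                  "difficult", "easy")
            p_correct = np.array(
                [config.accuracy_targets[(group, d)] for d in difficulty]
            )
            correct = rng.random(props.size) < p_correct
            majority_black = props > 0.5
            resp_yes = correct == majority_black
            rts = _draw_rts(props.size, wait, config, rng)
            conflict = np.maximum(
                config.auc_slope * rts
                + rng.normal(0.0, config.auc_noise, size=props.size),
                0.0,
            )
            for k in range(props.size):
                trial_id = f"{pid}_t{k:03d}"
                side = "right" if resp_yes[k] else "left"
                t, x, y = _trajectory_arrays(
                    rts[k],
                    conflict[k],
                    side,
                    rng,
                    config.button_offset,
                    config.sample_hz,
                    config.jitter_px,
                )
                traj_parts.append((pid, trial_id, t, x, y))
                trial_rows.append(
                    (
                        pid,
                        group,
                        float(props[k]),
                        "yes" if resp_yes[k] else "no",
                        float(rts[k]),
                        trial_id,
                    )
                )
            if wait > 0:
                if rng.random() < config.zero_rater_rate:
                    block_ratings = np.zeros(config.blocks, dtype=int)
                else:
                    level = rng.normal(
                        config.irritation_level[group], config.irritation_between_sd
                    )
                    block_ratings = np.clip(
                        np.round(
                            rng.normal(
                                level - config.irritation_block_sd,
                                config.irritation_block_sd,
                                size=config.blocks,
                            )
                        ),
                        0,
                        100,
                    ).astype(int)
                for b, r in enumerate(block_ratings, start=1):
                    rating_rows.append((pid, group, b, int(r)))
    trials = pd.DataFrame(
        trial_rows,
        columns=["participant_id", "group", "proportion", "response", "rt_s",
                 "trial_id"],
    )
    lengths = [t.size for _, _, t, _, _ in traj_parts]
    trajectories = pd.DataFrame(
        {
            "participant_id": np.repeat([p for p, _, _, _, _ in traj_parts], lengths),
            "trial_id": np.repeat([tid for _, tid, _, _, _ in traj_parts], lengths),
            "t_s": np.concatenate([t for _, _, t, _, _ in traj_parts]),
            "x_px": np.concatenate([x for _, _, _, x, _ in traj_parts]),
            "y_px": np.concatenate([y for _, _, _, _, y in traj_parts]),
        }
    )
    ratings = pd.DataFrame(
        rating_rows, columns=["participant_id", "group", "block", "rating"]
    )
    return SyntheticDataset(
        trials=trials, trajectories=trajectories, ratings=ratings, config=config
    )
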