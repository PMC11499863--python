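"""SART trial schedules, signal-detection scoring, and condition/block/ASRS
analyses.

The Sustained Attention to Response Task (SART) presents a digit stream
(250 ms digit + 900 ms mask = 1150 ms onset asynchrony); participants press
on every digit except 0 (10% of trials) and withhold on 0. Sensitivity is
d' = z(hit rate) - z(false-alarm rate), computed with the log-linear
correction (+0.5 to each count, +1 to each trial total) so blocks with
perfect rates stay finite.

The headline analysis is a per-subject interaction contrast: quadratic over
modulation rate (8/16/32 Hz, weights -1/+2/-1), linear over trial block
(early/late, weights -1/+1), applied to d' differences relative to the
no-modulation baseline. The contrast is regressed on centered ASRS score,
with significance assessed by permutation of the ASRS labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    ScheduleInfeasibleError,
)

__all__ = [
    "TrialSchedule",
    "SDTSummary",
    "ContrastResult",
    "generate_schedule",
    "SCHEDULE_PRESETS",
    "dprime",
    "score_responses",
    "score_log_table",
    "rt_variability",
    "condition_block_summary",
    "within_subject_sem",
    "interaction_contrast",
]

# Trial-count presets. The first follows the 6-block x 200-trial design with
# three acoustic conditions; the second the 4-block x 270-trial design with
# four modulation conditions.
SCHEDULE_PRESETS = {
    "exp1": dict(n_trials=1200, n_blocks=6),
    "exp4": dict(n_trials=1080, n_blocks=4),
}

DIGIT_DUR_S = 0.250
MASK_DUR_S = 0.900


@dataclass(frozen=True)
class TrialSchedule:
    """A SART digit sequence with block structure.

    ``trials`` columns: trial (0-based), digit, is_target, onset_s, block.
    """

    trials: pd.DataFrame
    digit_dur_s: float
    mask_dur_s: float
    n_blocks: int
    condition_per_block: tuple[str, ...] | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onset_asynchrony_s(self) -> float:
        return self.digit_dur_s + self.mask_dur_s

    @property
    def trials_per_block(self) -> int:
        return self.n_trials // self.n_blocks

    @property
    def n_targets(self) -> int:
        return int(self.trials["is_target"].sum())

    @property
    def all_go(self) -> bool:
        """True for degenerate schedules with no withhold targets (d'
        cannot be computed from them)."""
        return self.n_targets == 0

    def with_conditions(self, labels: tuple[str, ...]) -> "TrialSchedule":
        if len(labels) != self.n_blocks:
            raise InvalidInputError("one condition label per block required")
        return TrialSchedule(
            trials=self.trials, digit_dur_s=self.digit_dur_s,
            mask_dur_s=self.mask_dur_s, n_blocks=self.n_blocks,
            condition_per_block=tuple(labels),
        )


def generate_schedule(
    n_trials: int,
    target_prop: float = 0.10,
    digit_dur: float = DIGIT_DUR_S,
    mask_dur: float = MASK_DUR_S,
    n_blocks: int = 6,
    seed: int | None = None,
    no_consecutive_targets: bool = True,
) -> TrialSchedule:
    """Random SART schedule with an exact target count.

    Exactly ``round(n_trials * target_prop)`` trials show the digit 0;
    by default no two targets are adjacent (the non-adjacent positions are
    drawn uniformly via the stars-and-bars bijection, so the draw is exact,
    not rejection-sampled). Non-target digits are uniform over 1-9.
    """
    if n_trials <= 0 or n_trials % n_blocks != 0:
        raise InvalidParameterError("n_trials must be a positive multiple of n_blocks")
    if not 0.0 <= target_prop < 0.5:
        raise InvalidParameterError("target_prop must be in [0, 0.5)")
    k = int(round(n_trials * target_prop))
    rng = np.random.default_rng(seed)
    if no_consecutive_targets:
        if k > (n_trials + 1) // 2:
            raise ScheduleInfeasibleError(
                f"{k} non-adjacent targets do not fit in {n_trials} trials"
            )
        # choose k from n-k+1 slots, then spread: guarantees non-adjacency
        pos = np.sort(rng.choice(n_trials - k + 1, size=k, replace=False)) + np.arange(k)
    else:
        pos = np.sort(rng.choice(n_trials, size=k, replace=False))
    digits = rng.integers(1, 10, size=n_trials)
    digits[pos] = 0
    idx = np.arange(n_trials)
    trials = pd.DataFrame(
        {
            "trial": idx,
            "digit": digits,
            "is_target": digits == 0,
            "onset_s": idx * (digit_dur + mask_dur),
            "block": idx // (n_trials // n_blocks),
        }
    )
    return TrialSchedule(
        trials=trials, digit_dur_s=digit_dur, mask_dur_s=mask_dur, n_blocks=n_blocks
    )


def dprime(hits: int, misses: int, fas: int, crs: int, correction: str = "loglinear") -> float:
    """Sensitivity d' = z(hit rate) - z(FA rate).

    The default log-linear correction adds 0.5 to each count and 1 to each
    trial total, keeping d' finite at perfect rates. ``correction="none"``
    uses raw rates (infinite at 0 or 1).
    """
    n_go = hits + misses
    n_nogo = fas + crs
    if n_go == 0 or n_nogo == 0:
        raise InsufficientDataError("need at least one go and one no-go trial")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_go + 1.0)
        fr = (fas + 0.5) / (n_nogo + 1.0)
    elif correction == "none":
        hr = hits / n_go
        fr = fas / n_nogo
    else:
        raise InvalidParameterError(f"unknown correction {correction!r}")
    return float(norm.ppf(hr) - norm.ppf(fr))


@dataclass(frozen=True)
class SDTSummary:
    """Signal-detection counts and d' per block (and condition when the
    schedule carries block condition labels).

    ``table`` columns: block, condition, hits, misses, fas, crs, dprime.
    """

    table: pd.DataFrame
    correction_tag: str = "loglinear"

    @property
    def overall_dprime(self) -> float:
        tot = self.table[["hits", "misses", "fas", "crs"]].sum()
        return dprime(tot.hits, tot.misses, tot.fas, tot.crs, self.correction_tag)


def score_responses(schedule: TrialSchedule, log: pd.DataFrame) -> SDTSummary:
    """Score a response log against its schedule.

    ``log`` needs one row per trial, in order, with a boolean ``pressed``
    column (and optionally ``rt_s``, present iff pressed). Go trials
    (digit 1-9): press = hit, no press = miss. No-go trials (digit 0):
    press = false alarm, no press = correct rejection.
    """
    if len(log) != schedule.n_trials:
        raise InvalidInputError(
            f"log has {len(log)} rows for a {schedule.n_trials}-trial schedule"
        )
    df = schedule.trials.copy()
    df["pressed"] = np.asarray(log["pressed"], dtype=bool)
    if schedule.condition_per_block is not None:
        df["condition"] = [schedule.condition_per_block[b] for b in df["block"]]
    else:
        df["condition"] = "all"
    return SDTSummary(table=_count_and_dprime(df, ["block", "condition"]))


def _count_and_dprime(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    go = ~df["is_target"]
    agg = df.assign(
        hits=(go & df["pressed"]).astype(int),
        misses=(go & ~df["pressed"]).astype(int),
        fas=(~go & df["pressed"]).astype(int),
        crs=(~go & ~df["pressed"]).astype(int),
    ).groupby(by, as_index=False)[["hits", "misses", "fas", "crs"]].sum()
    agg["dprime"] = [
        dprime(r.hits, r.misses, r.fas, r.crs) for r in agg.itertuples()
    ]
    return agg


def score_log_table(logs: pd.DataFrame) -> pd.DataFrame:
    """Tidy d' table from a long trial log.

    ``logs`` columns: subject, condition, block, is_target, pressed.
    Returns one row per subject x condition x block with SDT counts and d'.
    """
    return _count_and_dprime(logs, ["subject", "condition", "block"])


def rt_variability(log: pd.DataFrame, window: int = 10) -> np.ndarray:
    """RT coefficient of variation (sample SD / mean) per consecutive
    ``window``-trial block; windows with fewer than 2 RTs yield NaN."""
    rts = np.asarray(log["rt_s"], dtype=float)
    if not np.isfinite(rts).any():
        raise InsufficientDataError("no response times in log")
    n_win = len(rts) // window
    out = np.full(n_win, np.nan)
    for w in range(n_win):
        chunk = rts[w * window : (w + 1) * window]
        chunk = chunk[np.isfinite(chunk)]
        if chunk.size >= 2:
            out[w] = np.std(chunk, ddof=1) / np.mean(chunk)
    return out


def within_subject_sem(pivot: pd.DataFrame) -> pd.Series:
    """Cousineau-Morey within-subject SEM per cell.

    ``pivot``: rows = subjects, columns = within-subject cells. Each
    subject's scores are centered on their own mean (plus the grand mean);
    the per-cell SEM of the centered data is inflated by sqrt(m/(m-1)) for
    m cells (Morey's bias correction).
    """
    m = pivot.shape[1]
    if m < 2:
        raise InsufficientDataError("need >= 2 within-subject cells")
    centered = pivot.sub(pivot.mean(axis=1), axis=0) + pivot.values.mean()
    sem = centered.std(ddof=1) / np.sqrt(pivot.shape[0])
    return sem * np.sqrt(m / (m - 1.0))


def condition_block_summary(
    dprime_table: pd.DataFrame, baseline_condition: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """d' differences relative to the baseline condition, with group stats.

    ``dprime_table`` columns: subject, condition, block, dprime (one row per
    cell). Returns ``(delta, group)``: ``delta`` has per-subject
    ``delta_dprime`` = d'(condition, block) - d'(baseline, block) for every
    non-baseline condition; ``group`` adds per condition x block the group
    mean and the Cousineau-Morey within-subject SEM.
    """
    if baseline_condition not in set(dprime_table["condition"]):
        raise InvalidInputError(f"baseline condition {baseline_condition!r} missing")
    base = dprime_table[dprime_table["condition"] == baseline_condition]
    missing = set(dprime_table["subject"]) - set(base["subject"])
    if missing:
        raise InvalidInputError(f"subjects lacking baseline condition: {sorted(missing)}")
    rest = dprime_table[dprime_table["condition"] != baseline_condition]
    delta = rest.merge(
        base[["subject", "block", "dprime"]].rename(columns={"dprime": "dprime_base"}),
        on=["subject", "block"],
    )
    delta["delta_dprime"] = delta["dprime"] - delta["dprime_base"]
    delta = delta[["subject", "condition", "block", "delta_dprime"]]

    pivot = delta.pivot_table(
        index="subject", columns=["condition", "block"], values="delta_dprime"
    )
    sem = within_subject_sem(pivot)
    group = (
        delta.groupby(["condition", "block"], as_index=False)["delta_dprime"]
        .mean()
        .rename(columns={"delta_dprime": "mean_delta_dprime"})
    )
    group["within_subject_sem"] = [
        sem[(c, b)] for c, b in zip(group["condition"], group["block"])
    ]
    return delta, group


@dataclass(frozen=True)
class ContrastResult:
    """Per-subject rate x block contrast regressed on centered ASRS."""

    slope: float
    p_perm: float
    per_subject: pd.DataFrame = field(repr=False)
    n_subjects: int = 0
    n_perm: int = 0


def interaction_contrast(
    delta_table: pd.DataFrame,
    profiles: pd.DataFrame,
    rate_levels: tuple = (8, 16, 32),
    quad_weights: tuple[float, ...] = (-1.0, 2.0, -1.0),
    block_weights: tuple[float, ...] | None = None,
    n_perm: int = 2000,
    seed: int | None = None,
) -> ContrastResult:
    """Quadratic(rate) x linear(block) contrast, regressed on ASRS.

    Per subject, ``c = sum_r sum_b q(r) l(b) delta_dprime(r, b)`` with
    quadratic weights q = (-1, +2, -1) over the rate levels and linear
    weights l = (-1, +1) over (early, late) blocks. The statistic is the OLS
    slope of c on mean-centered ASRS score; its two-sided p-value comes from
    ``n_perm`` seeded permutations of the ASRS labels. Subjects with missing
    cells are excluded listwise (with a warning).
    """
    blocks = sorted(delta_table["block"].unique())
    if len(blocks) < 2:
        raise InsufficientDataError("need >= 2 blocks")
    if block_weights is None:
        block_weights = tuple(np.linspace(-1.0, 1.0, len(blocks)))
    qmap = dict(zip(rate_levels, quad_weights))
    lmap = dict(zip(blocks, block_weights))

    sub = delta_table[delta_table["condition"].isin(rate_levels)].copy()
    sub["w"] = [qmap[c] * lmap[b] for c, b in zip(sub["condition"], sub["block"])]
    sub["wc"] = sub["w"] * sub["delta_dprime"]
    n_cells = len(rate_levels) * len(blocks)
    per = sub.groupby("subject").agg(c=("wc", "sum"), n=("wc", "size")).reset_index()
    incomplete = per[per["n"] != n_cells]["subject"].tolist()
    if incomplete:
        warnings.warn(f"excluding subjects with missing cells: {incomplete}")
        per = per[per["n"] == n_cells]
    per = per.merge(profiles[["subject", "asrs_score"]], on="subject")
    if len(per) < 3:
        raise InsufficientDataError("fewer than 3 complete subjects")

    c = per["c"].to_numpy(dtype=float)
    z = per["asrs_score"].to_numpy(dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise InsufficientDataError("no variance in ASRS scores")
    slope = float(z @ c) / denom

    rng = np.random.default_rng(seed)
    n = len(c)
    perm_slopes = np.empty(n_perm)
    for i in range(n_perm):
        zp = z[rng.permutation(n)]
        perm_slopes[i] = float(zp @ c) / denom
    p = (1.0 + np.sum(np.abs(perm_slopes) >= abs(slope) - 1e-12)) / (n_perm + 1.0)
    return ContrastResult(
        slope=slope, p_perm=float(p), per_subject=per,
        n_subjects=n, n_perm=n_perm,
    )
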