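"""Model-free behavioral statistics for reversal-task sessions.

Performance is the percentage of *optimal responses* — risky choice on the
currently positive cue, safe choice on the negative cue — collapsed across
cues and averaged within consecutive bins of 10 trials inside each block.
The binned curves feed a three-way repeated-measures ANOVA
(bin x block x condition, subjects as the random factor) and targeted
last-bin contrasts: a paired test between drug conditions and one-sample
tests of each condition against the probability-matching benchmark
(100 * p_good percent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .task import Session

__all__ = [
    "BIN_SIZE",
    "bin_performance",
    "bin_cohort",
    "rm_anova",
    "compare_final_bin",
    "LastBinComparison",
]

logger = logging.getLogger(__name__)

BIN_SIZE = 10


def bin_performance(session: Session, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Percentage of optimal responses per (block, bin of consecutive trials).

    Optimality of a *response* is judged against the block's true
    contingency (risky iff the presented cue is currently positive) and
    collapsed across the two cues. A final partial bin (block length not
    divisible by ``bin_size``) is dropped with a warning.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    cfg = session.config
    n_bins, rem = divmod(cfg.block_len, bin_size)
    if rem:
        warnings.warn(
            f"block length {cfg.block_len} not divisible by {bin_size}; "
            f"dropping the final partial bin of {rem} trials per block",
            UserWarning,
        )
    opt = session.optimal_choice.astype(float)
    t = session.trials
    pos_in_block = t["trial"].to_numpy() - t["block"].to_numpy() * cfg.block_len
    records = []
    for b in range(cfg.n_blocks):
        in_block = t["block"].to_numpy() == b
        for k in range(n_bins):
            sel = in_block & (pos_in_block // bin_size == k)
            records.append(
                {
                    "subject_id": session.subject_id,
                    "condition": session.condition,
                    "block": b,
                    "bin": k,
                    "pct_optimal": 100.0 * float(opt[sel].mean()),
                }
            )
    return pd.DataFrame.from_records(records)


def bin_cohort(
    sessions: Iterable[Session], bin_size: int = BIN_SIZE
) -> pd.DataFrame:
    """Concatenated binned performance for many sessions."""
    return pd.concat(
        [bin_performance(s, bin_size) for s in sessions], ignore_index=True
    )


def rm_anova(binned: pd.DataFrame) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA on binned performance.

    Factors are bin, block and condition (all within subject); each effect
    is tested against its own subject-by-effect interaction, so e.g. the bin
    main effect has df = (n_bins - 1, (n_bins - 1) * (N - 1)). The design
    must be complete and balanced — a missing cell raises rather than being
    silently imputed. Degenerate inputs with zero error variance yield NaN
    F ratios rather than an exception.
    """
    required = {"subject_id", "condition", "block", "bin", "pct_optimal"}
    missing = required - set(binned.columns)
    if missing:
        raise ValueError(f"binned table lacks columns {sorted(missing)}")
    cells = binned.groupby(
        ["subject_id", "condition", "block", "bin"], observed=True
    ).size()
    if cells.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    n_cells = (
        binned["condition"].nunique()
        * binned["block"].nunique()
        * binned["bin"].nunique()
    )
    per_subject = cells.groupby(level="subject_id").size()
    if (per_subject != n_cells).any():
        bad = per_subject[per_subject != n_cells].index.tolist()
        raise ValueError(f"incomplete design for subjects {bad}")
    df = binned.copy()
    if cells.iloc[0] > 1:
        df = (
            df.groupby(["subject_id", "condition", "block", "bin"])
            .mean()
            .reset_index()
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = AnovaRM(
            df,
            depvar="pct_optimal",
            subject="subject_id",
            within=["bin", "block", "condition"],
        ).fit()
    return res.anova_table


@dataclass
class LastBinComparison:
    """Last-bin performance contrasts between conditions.

    ``t`` / ``p`` are the paired test between conditions (placebo minus
    ketamine, collapsed over blocks); ``F = t**2`` restates the contrast in
    ANOVA form. ``vs_reference`` holds per-condition one-sample tests of the
    last-bin mean against the probability-matching level.
    """

    n_pairs: int
    means: dict[str, float]
    t: float
    df: int
    p: float
    F: float
    reference: float
    vs_reference: dict[str, tuple[float, int, float]]


def compare_final_bin(
    binned: pd.DataFrame,
    p_good: float = 0.8,
    conditions: tuple[str, str] = ("placebo", "ketamine"),
) -> LastBinComparison:
    """Paired condition contrast in the final bin, plus one-sample tests
    against the 100 * ``p_good`` matching benchmark.

    The final bin is collapsed (averaged) over blocks within each subject
    and condition. Subjects lacking either condition are excluded from the
    paired test (logged, not an error).
    """
    last = binned[binned["bin"] == binned["bin"].max()]
    per = (
        last.groupby(["subject_id", "condition"])["pct_optimal"]
        .mean()
        .unstack("condition")
    )
    for c in conditions:
        if c not in per.columns:
            raise ValueError(f"no sessions for condition {c!r}")
    paired = per.dropna(subset=list(conditions))
    dropped = per.index.difference(paired.index)
    if len(dropped):
        logger.info(
            "excluding unpaired subjects from last-bin contrast: %s",
            list(dropped),
        )
    a = paired[conditions[0]].to_numpy()
    b = paired[conditions[1]].to_numpy()
    diff = a - b
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    vs_ref = {}
    ref = 100.0 * p_good
    for c in conditions:
        vals = per[c].dropna().to_numpy()
        if np.allclose(vals, vals[0]) and np.isclose(vals[0], ref):
            tc, pc = 0.0, 1.0
        else:
            tc, pc = sps.ttest_1samp(vals, ref)
        vs_ref[c] = (float(tc), len(vals) - 1, float(pc))
    return LastBinComparison(
        n_pairs=len(paired),
        means={c: float(np.mean(per[c].dropna())) for c in conditions},
        t=float(t),
        df=len(paired) - 1,
        p=float(p),
        F=float(t) ** 2,
        reference=ref,
        vs_reference=vs_ref,
    )
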