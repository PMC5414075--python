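"""Probabilistic reversal task: environment, agent simulation, session I/O.

Two abstract cues (A and B) are shown one per trial. The subject bets either
a high stake ("risky") or a low stake ("safe"). One cue is currently
*positive*: following it, the outcome carries a favourable sign with
probability ``p_good`` (win the chosen stake), otherwise an unfavourable
sign (lose the chosen stake); for the negative cue the probabilities are
swapped. The positive/negative roles reverse, unannounced, after every block
of trials. Default geometry: 4 blocks of 60 trials (3 reversals, 240 trials
total), 80/20 contingencies, stakes of 1.0 and 0.1 pounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine
from .models import (
    DEFAULT_MODULATION_FORM,
    LatentTrajectory,
    ModelSpec,
    ParamSet,
)

__all__ = [
    "TaskConfig",
    "Trial",
    "Session",
    "draw_outcome",
    "make_cue_sequence",
    "simulate_agent",
    "write_session_csv",
    "read_session_csv",
]

CUES = ("A", "B")
CHOICES = ("safe", "risky")

_VARIANT_CODE = {"money": 0, "valence": 1, "coupled": 2}
_SIGNAL_CODE = {"none": 0, "abspe": 1, "optimality": 2}
_FORM_CODE = {"exponential": 0, "linear": 1}

SESSION_COLUMNS = [
    "subject_id", "condition", "trial", "block", "cue", "is_positive",
    "choice", "outcome", "optimality",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and contingencies of the reversal task."""

    n_blocks: int = 4
    block_len: int = 60
    p_good: float = 0.8
    stake_high: float = 1.0
    stake_low: float = 0.1
    first_positive_cue: str = "A"
    #: When True each cue appears equally often (within 1) in every block;
    #: whether the original task enforced this is unknown, so it is a switch.
    balanced_cues: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_len < 1:
            raise ValueError("n_blocks and block_len must be >= 1")
        if not 0.0 < self.p_good < 1.0:
            raise ValueError("p_good must lie strictly in (0, 1)")
        if self.stake_high <= 0 or self.stake_low <= 0:
            raise ValueError("stakes must be strictly positive")
        if self.first_positive_cue not in CUES:
            raise ValueError("first_positive_cue must be 'A' or 'B'")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_len

    @property
    def stakes(self) -> tuple[float, float]:
        return (self.stake_high, self.stake_low)


@dataclass(frozen=True)
class Trial:
    """A single trial record with derived outcome descriptors."""

    index: int
    block: int
    cue: str
    is_positive: bool
    choice: str
    outcome: float

    @property
    def valence(self) -> int:
        return 1 if self.outcome > 0 else -1

    @property
    def optimal_choice(self) -> bool:
        """Risky on the positive cue, safe on the negative cue."""
        return (self.choice == "risky") == self.is_positive

    @property
    def optimality(self) -> int:
        """1 when the outcome was favourable: winning the high stake or
        losing only the low one."""
        risky = self.choice == "risky"
        won = self.outcome > 0
        return 1 if (risky and won) or (not risky and not won) else 0


@dataclass
class Session:
    """One subject-condition run of the task.

    ``trials`` is a tidy DataFrame with columns trial, block, cue,
    is_positive, choice, outcome, optimality. ``seed`` records the RNG seed
    of simulated sessions (None for external data).
    """

    subject_id: str
    condition: str
    trials: pd.DataFrame
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trials)

    def __post_init__(self) -> None:
        if len(self.trials) != self.config.n_trials:
            raise ValueError(
                f"session has {len(self.trials)} trials but config implies "
                f"{self.config.n_trials}"
            )

    def iter_trials(self):
        for row in self.trials.itertuples(index=False):
            yield Trial(
                index=int(row.trial),
                block=int(row.block),
                cue=str(row.cue),
                is_positive=bool(row.is_positive),
                choice=str(row.choice),
                outcome=float(row.outcome),
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(cue_idx, choice_idx, outcome, optimality) as compact arrays for
        the compiled kernels; cue 0=A/1=B, choice 0=safe/1=risky."""
        t = self.trials
        cue = (t["cue"].to_numpy() == "B").astype(np.int64)
        choice = (t["choice"].to_numpy() == "risky").astype(np.int64)
        outcome = t["outcome"].to_numpy(dtype=np.float64)
        optim = t["optimality"].to_numpy(dtype=np.float64)
        return cue, choice, outcome, optim

    @property
    def optimal_choice(self) -> np.ndarray:
        """Boolean array: risky on the positive cue, safe on the negative."""
        t = self.trials
        return (t["choice"].to_numpy() == "risky") == t[
            "is_positive"
        ].to_numpy(dtype=bool)


def draw_outcome(
    cue_is_positive: bool,
    choice: str,
    p_good: float,
    stakes: tuple[float, float] = (1.0, 0.1),
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Sample one monetary outcome.

    The outcome's sign is favourable with probability ``p_good`` after the
    positive cue (and with ``1 - p_good`` after the negative cue); its
    magnitude is the high stake for a risky choice, the low stake otherwise.
    """
    if choice not in CHOICES:
        raise ValueError(f"choice must be one of {CHOICES}, got {choice!r}")
    if not 0.0 < p_good < 1.0:
        raise ValueError("p_good must lie strictly in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    p_gain = p_good if cue_is_positive else 1.0 - p_good
    gain = rng.random() < p_gain
    stake = stakes[0] if choice == "risky" else stakes[1]
    return stake if gain else -stake


def make_cue_sequence(
    config: TaskConfig, rng: np.random.Generator
) -> list[tuple[str, bool]]:
    """Build the per-trial (cue, is_positive) sequence.

    Cue identity is shuffled within each block (balanced counts when
    ``config.balanced_cues``); the positive role alternates between blocks,
    starting from ``config.first_positive_cue``, which yields exactly
    ``n_blocks - 1`` unannounced reversals.
    """
    seq: list[tuple[str, bool]] = []
    for b in range(config.n_blocks):
        if config.balanced_cues:
            half = config.block_len // 2
            cues = ["A"] * half + ["B"] * (config.block_len - half)
            if config.block_len % 2 == 1 and b % 2 == 1:
                # alternate which cue receives the odd extra trial
                cues = ["A"] * (config.block_len - half) + ["B"] * half
            cues = list(rng.permutation(np.array(cues)))
        else:
            cues = list(rng.choice(np.array(CUES), size=config.block_len))
        first_pos = config.first_positive_cue
        pos_cue = first_pos if b % 2 == 0 else ("B" if first_pos == "A" else "A")
        seq.extend((str(c), str(c) == pos_cue) for c in cues)
    return seq


def _kernel_args(
    spec: ModelSpec, theta: ParamSet, form: str = DEFAULT_MODULATION_FORM
) -> tuple:
    """Scalar kernel arguments (codes + full parameter vector) for a spec."""
    theta.validate_for(spec)
    if spec.modulation == "both_separate":
        ka, kb = theta.kappa_alpha, theta.kappa_beta
    else:
        ka = kb = theta.kappa if theta.kappa is not None else 0.0
    return (
        _VARIANT_CODE[spec.rl_variant],
        _SIGNAL_CODE[spec.confidence_signal],
        spec.modulates_alpha,
        spec.modulates_beta,
        _FORM_CODE[form],
        float(theta.alpha0),
        float(theta.beta0),
        float(theta.C0) if theta.C0 is not None else 0.0,
        float(theta.gamma) if theta.gamma is not None else 0.0,
        float(ka),
        float(kb),
    )


def simulate_agent(
    spec: ModelSpec,
    theta: ParamSet,
    config: Optional[TaskConfig] = None,
    seed: int = 0,
    subject_id: str = "sim",
    condition: str = "placebo",
    form: str = DEFAULT_MODULATION_FORM,
) -> tuple[Session, LatentTrajectory]:
    """Forward-run a model as an agent in the task.

    Each trial samples a choice from the model's softmax policy, the
    environment draws the outcome, and the model's latent variables are
    updated by its learning rules. A single seeded stream drives cue order,
    choices and outcomes; identical (spec, theta, config, seed) reproduce
    the session bit for bit.
    """
    config = TaskConfig() if config is None else config
    rng = np.random.default_rng(seed)
    seq = make_cue_sequence(config, rng)
    n = config.n_trials
    cue = np.array([c == "B" for c, _ in seq], dtype=np.int64)
    is_pos = np.array([p for _, p in seq], dtype=np.int64)
    u_choice = rng.random(n)
    u_env = rng.random(n)

    choice = np.empty(n, dtype=np.int64)
    outcome = np.empty(n, dtype=np.float64)
    optim = np.empty(n, dtype=np.int64)
    lat = [np.empty(n) for _ in range(7)]
    _engine.simulate_session(
        cue, is_pos, u_choice, u_env,
        config.p_good, config.stake_high, config.stake_low,
        *_kernel_args(spec, theta, form),
        choice, outcome, optim, *lat,
    )

    block = np.repeat(np.arange(config.n_blocks), config.block_len)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": block,
            "cue": np.where(cue == 1, "B", "A"),
            "is_positive": is_pos.astype(bool),
            "choice": np.where(choice == 1, "risky", "safe"),
            "outcome": outcome,
            "optimality": optim,
        }
    )
    session = Session(subject_id, condition, trials, config, seed=seed)
    return session, LatentTrajectory(*lat)


def write_session_csv(session: Session, path: str | Path) -> None:
    """Write a session as delimited text with the canonical column set."""
    df = session.trials.copy()
    df.insert(0, "subject_id", session.subject_id)
    df.insert(1, "condition", session.condition)
    df[SESSION_COLUMNS].to_csv(path, index=False)


def read_session_csv(
    path: str | Path, config: Optional[TaskConfig] = None
) -> Session:
    """Read a session written by :func:`write_session_csv` (lossless
    round-trip). Block geometry is inferred from the data unless a config
    is supplied."""
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session file {path} lacks columns {missing}")
    subject_id = str(df["subject_id"].iloc[0])
    condition = str(df["condition"].iloc[0])
    if config is None:
        n_blocks = int(df["block"].nunique())
        block_len = int(len(df) // n_blocks)
        first_pos = df.loc[df["is_positive"], "cue"].iloc[0] if df[
            "is_positive"
        ].any() else "A"
        config = TaskConfig(
            n_blocks=n_blocks, block_len=block_len,
            first_positive_cue=str(first_pos),
        )
    trials = df[
        ["trial", "block", "cue", "is_positive", "choice", "outcome",
         "optimality"]
    ].reset_index(drop=True)
    trials["is_positive"] = trials["is_positive"].astype(bool)
    return Session(subject_id, condition, trials, config)
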