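"""Group-level random-effects Bayesian model selection.

Subjects are allowed to use different models: model identity is treated as a
random effect drawn from an unknown population distribution over models,
with a Dirichlet prior on the model frequencies. A variational fixed-point
iteration alternates between subject-wise posterior model assignments
(softmax of log evidence plus expected log frequency) and Dirichlet count
updates. Exceedance probabilities — the posterior probability that a model
is the most frequent in the population — are estimated by Monte-Carlo
sampling of the Dirichlet posterior. Family-level inference aggregates model
evidence within families (uniform prior mass split across a family's
members) and runs the same machinery over families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "BMSResult",
    "rfx_bms",
    "family_bms",
    "exceedance_probability",
    "RandomEffectsBMS",
]


@dataclass
class BMSResult:
    """Posterior over model (or family) frequencies."""

    dirichlet_alpha: pd.Series
    expected_freq: pd.Series
    xp: pd.Series
    n_mc_samples: int
    n_iter: int

    @property
    def best(self) -> str:
        """Label with the highest exceedance probability."""
        return str(self.xp.idxmax())


def _as_frame(evidence) -> pd.DataFrame:
    if isinstance(evidence, pd.DataFrame):
        return evidence
    arr = np.asarray(evidence, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"m{j}" for j in range(arr.shape[1])],
    )


def _validate(E: pd.DataFrame) -> None:
    if E.shape[1] < 2:
        raise ValueError("need at least 2 models")
    if E.shape[0] < 1:
        raise ValueError("need at least 1 subject")
    bad = ~np.isfinite(E.to_numpy())
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-finite log evidence at subject {E.index[i]!r}, "
            f"model {E.columns[j]!r}"
        )


def exceedance_probability(
    alpha: np.ndarray,
    rng: np.random.Generator,
    n_samples: int = 1_000_000,
    chunk: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo P(model k is the most frequent) under Dirichlet(alpha).

    Samples gamma variates (equivalent to Dirichlet draws up to the
    normaliser, which argmax ignores) in chunks to bound memory.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = len(alpha)
    counts = np.zeros(K, dtype=np.int64)
    left = int(n_samples)
    while left > 0:
        m = min(chunk, left)
        g = rng.standard_gamma(alpha, size=(m, K))
        winners = np.argmax(g, axis=1)
        counts += np.bincount(winners, minlength=K)
        left -= m
    return counts / float(n_samples)


def rfx_bms(
    evidence,
    prior_counts: float = 1.0,
    seed: Optional[int] = None,
    n_mc_samples: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix.

    Parameters
    ----------
    evidence : DataFrame or 2-D array
        Rows are subjects, columns models, entries log evidence (finite).
    prior_counts : float
        Symmetric Dirichlet prior concentration per model (1 = uniform).
    seed : int, optional
        Seed for the exceedance-probability Monte-Carlo.
    """
    E = _as_frame(evidence)
    _validate(E)
    lnE = E.to_numpy(dtype=float)
    N, K = lnE.shape
    alpha0 = np.full(K, float(prior_counts))
    alpha = alpha0.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ln_u = lnE + (digamma(alpha) - digamma(alpha.sum()))
        z = np.exp(ln_u - logsumexp(ln_u, axis=1, keepdims=True))
        alpha_new = alpha0 + z.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    xp = exceedance_probability(alpha, rng, n_mc_samples)
    return BMSResult(
        dirichlet_alpha=pd.Series(alpha, index=E.columns),
        expected_freq=pd.Series(alpha / alpha.sum(), index=E.columns),
        xp=pd.Series(xp, index=E.columns),
        n_mc_samples=int(n_mc_samples),
        n_iter=n_iter,
    )


def family_evidence(
    evidence, partition: Mapping[str, str]
) -> pd.DataFrame:
    """Per-subject family log evidence under a uniform within-family prior:
    ``log mean_k exp(lnE_k)`` over a family's members."""
    E = _as_frame(evidence)
    missing = [m for m in E.columns if m not in partition]
    if missing:
        raise ValueError(f"models missing from partition: {missing}")
    fams: dict[str, list[str]] = {}
    for m in E.columns:
        fams.setdefault(partition[m], []).append(m)
    out = {}
    for fam, members in fams.items():
        sub = E[members].to_numpy(dtype=float)
        out[fam] = logsumexp(sub, axis=1) - np.log(len(members))
    return pd.DataFrame(out, index=E.index)


def family_bms(
    evidence,
    partition: Mapping[str, str],
    prior_counts: float = 1.0,
    seed: Optional[int] = None,
    n_mc_samples: int = 1_000_000,
) -> BMSResult:
    """Family-level random-effects BMS.

    Aggregates model evidence within each family (uniform prior mass split
    across members), then applies :func:`rfx_bms` at the family level. With a
    single family the result is trivially frequency 1.
    """
    F = family_evidence(evidence, partition)
    if F.shape[1] == 1:
        fam = F.columns
        one = pd.Series([1.0], index=fam)
        return BMSResult(
            dirichlet_alpha=pd.Series(
                [prior_counts + F.shape[0]], index=fam
            ),
            expected_freq=one,
            xp=one.copy(),
            n_mc_samples=0,
            n_iter=0,
        )
    return rfx_bms(
        F, prior_counts=prior_counts, seed=seed, n_mc_samples=n_mc_samples
    )


class RandomEffectsBMS(BaseEstimator):
    """Sklearn-style estimator for random-effects BMS.

    Parameters
    ----------
    prior_counts : float
        Symmetric Dirichlet prior concentration.
    partition : mapping model -> family, optional
        When given, inference is run at the family level.
    n_mc_samples : int
        Monte-Carlo draws for exceedance probabilities.
    random_state : int, optional

    Attributes (after ``fit``)
    --------------------------
    dirichlet_alpha_, expected_freq_, xp_ : pd.Series
    best_ : str
    result_ : BMSResult
    """

    def __init__(
        self,
        prior_counts: float = 1.0,
        partition: Optional[Mapping[str, str]] = None,
        n_mc_samples: int = 1_000_000,
        random_state: Optional[int] = None,
    ):
        self.prior_counts = prior_counts
        self.partition = partition
        self.n_mc_samples = n_mc_samples
        self.random_state = random_state

    def fit(self, evidence, y=None) -> "RandomEffectsBMS":
        if self.partition is not None:
            result = family_bms(
                evidence,
                self.partition,
                prior_counts=self.prior_counts,
                seed=self.random_state,
                n_mc_samples=self.n_mc_samples,
            )
        else:
            result = rfx_bms(
                evidence,
                prior_counts=self.prior_counts,
                seed=self.random_state,
                n_mc_samples=self.n_mc_samples,
            )
        self.result_ = result
        self.dirichlet_alpha_ = result.dirichlet_alpha
        self.expected_freq_ = result.expected_freq
        self.xp_ = result.xp
        self.best_ = result.best
        return self
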