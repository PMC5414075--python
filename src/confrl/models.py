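"""Model space for confidence-modulated reinforcement learning.

The space is a factorial of three choices made by a candidate learner in a
two-cue probabilistic reversal task:

* **RL variant** — what the reinforcer is: the raw monetary amount
  (``money``), its sign (``valence``), or its sign with anti-symmetric
  updating of both cue values on every trial (``coupled``).
* **Confidence signal** — how a meta-cognitive confidence level is monitored:
  not at all (``none``), from the unsigned prediction error (``abspe``), or
  from outcome optimality (``optimality``, i.e. whether the outcome was
  favourable: winning the large stake or losing only the small one).
* **Modulation** — which low-level parameters confidence down-regulates:
  the learning rate (``alpha``), the choice temperature (``beta``), or both
  with a shared (``both_shared``) or separate (``both_separate``) weight.

Plain RL corresponds to signal ``none`` + modulation ``none``; 3 plain
variants plus 3 x 2 x 4 hierarchical variants give 27 models in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "RL_VARIANTS",
    "CONFIDENCE_SIGNALS",
    "MODULATIONS",
    "ModelSpec",
    "ParamSet",
    "LatentTrajectory",
    "enumerate_models",
    "best_model",
    "outcome_signal",
    "update_values",
    "update_confidence",
    "modulate_parameters",
    "choice_probability",
    "classify_outcome",
    "PE_MAX",
    "BETA_FLOOR",
    "DEFAULT_MODULATION_FORM",
    "MODULATION_FORMS",
]

RL_VARIANTS = ("money", "valence", "coupled")
CONFIDENCE_SIGNALS = ("none", "abspe", "optimality")
MODULATIONS = ("none", "alpha", "beta", "both_shared", "both_separate")

#: Largest attainable |prediction error|: reinforcers and cue values are both
#: bounded in [-1, 1] under every variant's coding.
PE_MAX = 2.0

#: Floor applied to the modulated choice temperature so the softmax stays
#: defined when confidence drives the temperature toward zero.
BETA_FLOOR = 1e-3

#: Functional form of the confidence weight w used by
#: :func:`modulate_parameters`. ``exponential`` (w = 1 - exp(-kappa*C)) is
#: the default: it satisfies the same limits as the clamped-linear form
#: (w = 0 at zero confidence, w -> 1 at high confidence-weight products,
#: temperature monotonically decreasing in confidence) while keeping the
#: likelihood twice differentiable, which the Laplace evidence requires.
#: ``linear`` (w = clip(kappa*C, 0, 1)) remains available as a switch.
DEFAULT_MODULATION_FORM = "exponential"
MODULATION_FORMS = ("exponential", "linear")

_ID_VARIANT = {"money": "money", "valence": "valence", "coupled": "coupled"}
_ID_SIGNAL = {"abspe": "abspe", "optimality": "optim"}
_ID_MOD = {
    "alpha": "alpha",
    "beta": "beta",
    "both_shared": "bothshared",
    "both_separate": "bothsep",
}


@dataclass(frozen=True)
class ModelSpec:
    """One point in the 27-model factorial space.

    Parameters
    ----------
    rl_variant : {"money", "valence", "coupled"}
        Reinforcer coding of the low-level delta rule.
    confidence_signal : {"none", "abspe", "optimality"}
        Teaching signal of the confidence delta rule; ``none`` marks a plain
        (non-hierarchical) RL model.
    modulation : {"none", "alpha", "beta", "both_shared", "both_separate"}
        Which low-level parameters confidence modulates.
    """

    rl_variant: str
    confidence_signal: str = "none"
    modulation: str = "none"

    def __post_init__(self) -> None:
        if self.rl_variant not in RL_VARIANTS:
            raise ValueError(f"unknown rl_variant {self.rl_variant!r}")
        if self.confidence_signal not in CONFIDENCE_SIGNALS:
            raise ValueError(
                f"unknown confidence_signal {self.confidence_signal!r}"
            )
        if self.modulation not in MODULATIONS:
            raise ValueError(f"unknown modulation {self.modulation!r}")
        if (self.confidence_signal == "none") != (self.modulation == "none"):
            raise ValueError(
                "confidence_signal is 'none' iff modulation is 'none'; got "
                f"({self.confidence_signal!r}, {self.modulation!r})"
            )

    @property
    def is_hierarchical(self) -> bool:
        """True when the model carries a confidence level above plain RL."""
        return self.confidence_signal != "none"

    @property
    def model_id(self) -> str:
        """Short string identifier, e.g. ``coupled.optim.bothshared``."""
        if not self.is_hierarchical:
            return f"{_ID_VARIANT[self.rl_variant]}.flat"
        return ".".join(
            (
                _ID_VARIANT[self.rl_variant],
                _ID_SIGNAL[self.confidence_signal],
                _ID_MOD[self.modulation],
            )
        )

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        parts = model_id.split(".")
        rev_sig = {v: k for k, v in _ID_SIGNAL.items()}
        rev_mod = {v: k for k, v in _ID_MOD.items()}
        if len(parts) == 2 and parts[1] == "flat":
            return cls(parts[0])
        if len(parts) == 3 and parts[1] in rev_sig and parts[2] in rev_mod:
            return cls(parts[0], rev_sig[parts[1]], rev_mod[parts[2]])
        raise ValueError(f"unparseable model id {model_id!r}")

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters licensed by this spec, in the order
        used by the optimiser."""
        if not self.is_hierarchical:
            return ("alpha0", "beta0")
        base = ("alpha0", "beta0", "C0", "gamma")
        if self.modulation == "both_separate":
            return base + ("kappa_alpha", "kappa_beta")
        return base + ("kappa",)

    @property
    def modulates_alpha(self) -> bool:
        return self.modulation in ("alpha", "both_shared", "both_separate")

    @property
    def modulates_beta(self) -> bool:
        return self.modulation in ("beta", "both_shared", "both_separate")


def enumerate_models() -> list[ModelSpec]:
    """Return the full factorial model space (exactly 27 unique specs)."""
    specs = [ModelSpec(v) for v in RL_VARIANTS]
    specs += [
        ModelSpec(v, s, m)
        for v, s, m in itertools.product(
            RL_VARIANTS, ("abspe", "optimality"), MODULATIONS[1:]
        )
    ]
    return specs


def best_model() -> ModelSpec:
    """The winning model of the group-level comparison: valence-coded RL with
    coupled cue updates, optimality-based confidence modulating both the
    learning rate and the choice temperature with a shared weight."""
    return ModelSpec("coupled", "optimality", "both_shared")


@dataclass
class ParamSet:
    """Free parameters of a model.

    Attributes
    ----------
    alpha0 : float
        Learning rate when confidence is zero, in (0, 1).
    beta0 : float
        Choice temperature when confidence is zero, > 0 (lower = more
        deterministic).
    C0 : float, optional
        Initial confidence, in [0, 1]; hierarchical models only.
    gamma : float, optional
        Confidence learning rate, in (0, 1); hierarchical models only.
    kappa : float, optional
        Weight of confidence on the modulated parameter(s), >= 0; shared
        across learning rate and temperature except for ``both_separate``
        models, which use `kappa_alpha` and `kappa_beta` instead.
    """

    alpha0: float
    beta0: float
    C0: Optional[float] = None
    gamma: Optional[float] = None
    kappa: Optional[float] = None
    kappa_alpha: Optional[float] = None
    kappa_beta: Optional[float] = None

    def validate_for(self, spec: ModelSpec) -> None:
        """Raise ``ValueError`` unless exactly the licensed fields are set
        and lie within their native bounds."""
        licensed = set(spec.free_params)
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in licensed:
                if v is None:
                    raise ValueError(
                        f"model {spec.model_id} requires parameter {f.name}"
                    )
            elif v is not None:
                raise ValueError(
                    f"parameter {f.name} is not licensed by model "
                    f"{spec.model_id}"
                )
        if not 0.0 < self.alpha0 < 1.0:
            raise ValueError("alpha0 must lie in (0, 1)")
        if not self.beta0 > 0.0:
            raise ValueError("beta0 must be positive")
        if self.C0 is not None and not 0.0 <= self.C0 <= 1.0:
            raise ValueError("C0 must lie in [0, 1]")
        if self.gamma is not None and not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        for k in ("kappa", "kappa_alpha", "kappa_beta"):
            v = getattr(self, k)
            if v is not None and v < 0.0:
                raise ValueError(f"{k} must be non-negative")

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in spec.free_params}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParamSet":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class LatentTrajectory:
    """Per-trial latent variables, aligned 1:1 with a session's trials.

    ``q_a``, ``q_b`` and ``conf`` are the values *used* on each trial (i.e.
    before that trial's update); ``alpha_m`` / ``beta_m`` are the modulated
    parameters applied on the trial; ``pe`` is the prediction error of the
    trial; ``p_choice`` is the probability the model assigned to the choice
    actually made (observed or simulated).
    """

    q_a: np.ndarray
    q_b: np.ndarray
    conf: np.ndarray
    alpha_m: np.ndarray
    beta_m: np.ndarray
    pe: np.ndarray
    p_choice: np.ndarray

    def __len__(self) -> int:
        return len(self.q_a)

    def __iter__(self) -> Iterator[np.ndarray]:
        yield from (
            self.q_a, self.q_b, self.conf, self.alpha_m, self.beta_m,
            self.pe, self.p_choice,
        )


# ---------------------------------------------------------------------------
# Trial-wise update equations (scalar reference forms)
# ---------------------------------------------------------------------------

def outcome_signal(variant: str, outcome: float) -> float:
    """Reinforcer value implied by a monetary outcome under an RL variant.

    ``money`` keeps the signed amount; ``valence`` and ``coupled`` reduce it
    to its sign (+1 or -1). A zero outcome is rejected: every trial pays or
    costs one of the two stakes.
    """
    if outcome == 0.0:
        raise ValueError("outcome must be non-zero")
    if variant == "money":
        return float(outcome)
    if variant in ("valence", "coupled"):
        return 1.0 if outcome > 0 else -1.0
    raise ValueError(f"unknown rl_variant {variant!r}")


def update_values(
    variant: str,
    q_a: float,
    q_b: float,
    cue: str,
    reinforcer: float,
    alpha_m: float,
) -> tuple[float, float]:
    """Delta-rule value update.

    The presented cue moves toward the reinforcer in proportion to the
    prediction error; under ``coupled`` the unpresented cue moves toward the
    *negated* reinforcer with the same rate (the two cues always have
    opposite roles, so one outcome informs both).
    """
    if not 0.0 <= alpha_m <= 1.0:
        raise ValueError("alpha_m must lie in [0, 1]")
    if cue == "A":
        q_a = q_a + alpha_m * (reinforcer - q_a)
        if variant == "coupled":
            q_b = q_b + alpha_m * (-reinforcer - q_b)
    elif cue == "B":
        q_b = q_b + alpha_m * (reinforcer - q_b)
        if variant == "coupled":
            q_a = q_a + alpha_m * (-reinforcer - q_a)
    else:
        raise ValueError(f"unknown cue {cue!r}")
    return q_a, q_b


def update_confidence(
    signal: str,
    conf: float,
    gamma: float,
    optimality: Optional[int] = None,
    pe: Optional[float] = None,
    pe_max: float = PE_MAX,
) -> float:
    """Delta-rule confidence update.

    ``optimality`` tracks the running rate of favourable outcomes (target 0
    or 1); ``abspe`` tracks how small prediction errors have been (target
    ``1 - |pe| / pe_max``, normalised so confidence remains a [0, 1] level
    across reinforcer codings).
    """
    if signal == "optimality":
        if optimality not in (0, 1):
            raise ValueError("optimality must be 0 or 1")
        target = float(optimality)
    elif signal == "abspe":
        if pe is None:
            raise ValueError("abspe confidence requires a prediction error")
        target = 1.0 - abs(pe) / pe_max
    else:
        raise ValueError(f"no confidence update for signal {signal!r}")
    return conf + gamma * (target - conf)


def modulate_parameters(
    alpha0: float,
    beta0: float,
    conf: float,
    outcome_is_confirmatory: bool,
    modulation: str = "both_shared",
    kappa: Optional[float] = None,
    kappa_alpha: Optional[float] = None,
    kappa_beta: Optional[float] = None,
    form: str = DEFAULT_MODULATION_FORM,
) -> tuple[float, float]:
    """Confidence-weighted modulation of the learning rate and temperature.

    With confidence weight ``w`` (see below):

    * confirmatory outcomes: ``alpha_m = alpha0 + w * (1 - alpha0)``
    * contradictory outcomes: ``alpha_m = alpha0 * (1 - w)``
    * ``beta_m = beta0 * (1 - w)``, floored at ``BETA_FLOOR``

    so at zero confidence both outcome categories learn at ``alpha0`` and
    choices use ``beta0``, while at high confidence confirmatory learning
    saturates toward 1, contradictory learning toward 0, and choice becomes
    near-deterministic exploitation. The default ``exponential`` form uses
    ``w = 1 - exp(-kappa * C)``, smooth everywhere (the curvature-based
    evidence approximation needs a differentiable likelihood); the
    ``linear`` form ``w = clip(kappa * C, 0, 1)`` reaches its limits at
    finite ``kappa * C`` but is kinked at the clip.

    Only the targets licensed by ``modulation`` are modulated; the other
    parameter passes through unchanged.
    """
    if not 0.0 <= conf <= 1.0:
        raise ValueError("confidence must lie in [0, 1]")
    if modulation in ("alpha", "beta", "both_shared"):
        if kappa is None:
            raise ValueError("kappa required")
        ka = kb = kappa
    elif modulation == "both_separate":
        if kappa_alpha is None or kappa_beta is None:
            raise ValueError("kappa_alpha and kappa_beta required")
        ka, kb = kappa_alpha, kappa_beta
    elif modulation == "none":
        return alpha0, beta0
    else:
        raise ValueError(f"unknown modulation {modulation!r}")

    def weight(k: float) -> float:
        if form == "linear":
            return min(max(k * conf, 0.0), 1.0)
        if form == "exponential":
            return 1.0 - float(np.exp(-k * conf))
        raise ValueError(f"unknown modulation form {form!r}")

    alpha_m, beta_m = alpha0, beta0
    if modulation in ("alpha", "both_shared", "both_separate"):
        w = weight(ka)
        if outcome_is_confirmatory:
            alpha_m = alpha0 + w * (1.0 - alpha0)
        else:
            alpha_m = alpha0 * (1.0 - w)
    if modulation in ("beta", "both_shared", "both_separate"):
        beta_m = max(beta0 * (1.0 - weight(kb)), BETA_FLOOR)
    return alpha_m, beta_m


def choice_probability(q_cue: float, beta_m: float) -> float:
    """Softmax (logistic) probability of the risky choice given the presented
    cue's value and the trial's choice temperature."""
    if not beta_m > 0.0:
        raise ValueError("beta_m must be positive")
    x = q_cue / beta_m
    if x >= 0:
        return 1.0 / (1.0 + float(np.exp(-x)))
    e = float(np.exp(x))
    return e / (1.0 + e)


def classify_outcome(q_cue: float, outcome_valence: int) -> str:
    """Confirmatory iff the outcome's valence matches the sign of the current
    cue value estimate; an exactly zero estimate counts as confirmatory for a
    positive outcome (fixed tie rule — a measure-zero event under continuous
    updating, pinned down for determinism)."""
    if outcome_valence not in (-1, 1):
        raise ValueError("outcome_valence must be +1 or -1")
    if q_cue > 0:
        return "confirmatory" if outcome_valence == 1 else "contradictory"
    if q_cue < 0:
        return "confirmatory" if outcome_valence == -1 else "contradictory"
    return "confirmatory" if outcome_valence == 1 else "contradictory"
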