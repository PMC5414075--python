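import numpy as np
import pandas as pd
import pytest

from confrl import ParamSet, Session, TaskConfig, best_model, simulate_agent


def make_manual_session(choices, outcomes, cues=None, subject="toy"):
    """Hand-build a 1-block session from explicit choice/outcome lists."""
    n = len(choices)
    cues = cues or ["A"] * n
    trials = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": np.zeros(n, dtype=int),
            "cue": cues,
            "is_positive": [c == "A" for c in cues],
            "choice": choices,
            "outcome": outcomes,
            "optimality": [
                1 if (ch == "risky") == (o > 0) else 0
                for ch, o in zip(choices, outcomes)
            ],
        }
    )
    return Session(subject, "placebo", trials,
                   TaskConfig(n_blocks=1, block_len=n))


@pytest.fixture(scope="session")
def best_spec():
    return best_model()


@pytest.fixture(scope="session")
def best_theta():
    """A representative parameter set for the winning model (native scale)."""
    return ParamSet(alpha0=0.6, beta0=2.7, C0=0.2, gamma=0.4, kappa=3.3)


@pytest.fixture(scope="session")
def example_session(best_spec, best_theta):
    """One 240-trial session simulated from the winning model."""
    session, traj = simulate_agent(best_spec, best_theta, seed=11)
    return session, traj


def make_session(spec, theta, seed=0, **cfg_kwargs):
    config = TaskConfig(**cfg_kwargs) if cfg_kwargs else None
    return simulate_agent(spec, theta, config=config, seed=seed)
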