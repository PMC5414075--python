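"""Compiled trial-loop kernels.

Scalar reference forms of the update equations live in :mod:`confrl.models`;
the kernels here replicate them over whole sessions for speed (model fitting
evaluates the likelihood thousands of times). Tests assert trial-by-trial
agreement between the two paths.

Codes: rl_variant money=0 / valence=1 / coupled=2; confidence signal
none=0 / abspe=1 / optimality=2; modulation form exponential=0 / linear=1.
Choices are 0=safe, 1=risky; cues 0=A, 1=B.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .models import BETA_FLOOR, PE_MAX

_P_CLIP = 1e-12


@njit(cache=True, inline="always")
def _clip01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True, inline="always")
def _weight(k, conf, form):
    if form == 1:
        return _clip01(k * conf)
    return 1.0 - np.exp(-k * conf)


@njit(cache=True, inline="always")
def _p_risky(q, beta_m):
    x = q / beta_m
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def run_session(
    cue, choice, outcome, optim,
    variant, signal, mod_alpha, mod_beta, form,
    a0, b0, c0, g, ka, kb,
    qa_t, qb_t, c_t, am_t, bm_t, pe_t, pc_t,
):
    """Replay observed trials; fill latent arrays, return log-likelihood."""
    n = cue.shape[0]
    qa = 0.0
    qb = 0.0
    conf = c0
    ll = 0.0
    for t in range(n):
        q = qb if cue[t] == 1 else qa
        # temperature uses pre-outcome confidence
        bm = b0
        if mod_beta:
            bm = b0 * (1.0 - _weight(kb, conf, form))
            if bm < BETA_FLOOR:
                bm = BETA_FLOOR
        p = _p_risky(q, bm)
        pc = p if choice[t] == 1 else 1.0 - p
        if pc < _P_CLIP:
            pc = _P_CLIP
        elif pc > 1.0 - _P_CLIP:
            pc = 1.0 - _P_CLIP
        ll += np.log(pc)

        r = outcome[t]
        if variant != 0:
            r = 1.0 if r > 0.0 else -1.0
        val_pos = outcome[t] > 0.0
        # zero q counts as confirmatory for a positive outcome (tie rule)
        confirm = (q > 0.0 and val_pos) or (q < 0.0 and not val_pos) or (
            q == 0.0 and val_pos
        )
        am = a0
        if mod_alpha:
            w = _weight(ka, conf, form)
            am = a0 + w * (1.0 - a0) if confirm else a0 * (1.0 - w)
        pe = r - q

        qa_t[t] = qa
        qb_t[t] = qb
        c_t[t] = conf
        am_t[t] = am
        bm_t[t] = bm
        pe_t[t] = pe
        pc_t[t] = pc

        if cue[t] == 1:
            qb = qb + am * pe
            if variant == 2:
                qa = qa + am * (-r - qa)
        else:
            qa = qa + am * pe
            if variant == 2:
                qb = qb + am * (-r - qb)

        if signal == 2:
            conf = conf + g * (optim[t] - conf)
        elif signal == 1:
            conf = conf + g * ((1.0 - np.abs(pe) / PE_MAX) - conf)
    return ll


@njit(cache=True)
def simulate_session(
    cue, is_pos, u_choice, u_env,
    p_good, stake_high, stake_low,
    variant, signal, mod_alpha, mod_beta, form,
    a0, b0, c0, g, ka, kb,
    choice, outcome, optim,
    qa_t, qb_t, c_t, am_t, bm_t, pe_t, pc_t,
):
    """Forward-simulate an agent; fill choice/outcome/latent arrays."""
    n = cue.shape[0]
    qa = 0.0
    qb = 0.0
    conf = c0
    for t in range(n):
        q = qb if cue[t] == 1 else qa
        bm = b0
        if mod_beta:
            bm = b0 * (1.0 - _weight(kb, conf, form))
            if bm < BETA_FLOOR:
                bm = BETA_FLOOR
        p = _p_risky(q, bm)
        risky = u_choice[t] < p
        choice[t] = 1 if risky else 0
        pc = p if risky else 1.0 - p

        # favourable sign arrives with probability p_good on the positive cue
        gain = u_env[t] < p_good if is_pos[t] == 1 else u_env[t] < 1.0 - p_good
        stake = stake_high if risky else stake_low
        out = stake if gain else -stake
        outcome[t] = out
        # favourable outcome: winning the large stake or losing the small one
        optim[t] = 1 if (risky and gain) or (not risky and not gain) else 0

        r = out
        if variant != 0:
            r = 1.0 if r > 0.0 else -1.0
        confirm = (q > 0.0 and gain) or (q < 0.0 and not gain) or (
            q == 0.0 and gain
        )
        am = a0
        if mod_alpha:
            w = _weight(ka, conf, form)
            am = a0 + w * (1.0 - a0) if confirm else a0 * (1.0 - w)
        pe = r - q

        qa_t[t] = qa
        qb_t[t] = qb
        c_t[t] = conf
        am_t[t] = am
        bm_t[t] = bm
        pe_t[t] = pe
        pc_t[t] = pc

        if cue[t] == 1:
            qb = qb + am * pe
            if variant == 2:
                qa = qa + am * (-r - qa)
        else:
            qa = qa + am * pe
            if variant == 2:
                qb = qb + am * (-r - qb)

        if signal == 2:
            conf = conf + g * (optim[t] - conf)
        elif signal == 1:
            conf = conf + g * ((1.0 - np.abs(pe) / PE_MAX) - conf)
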