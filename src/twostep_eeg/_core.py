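"""Single-source state recursion of the hybrid RL agent (numba kernel).

The same compiled routine runs both forward simulation (consuming pre-drawn
uniforms to sample choices, transitions and feedback) and likelihood replay
(consuming observed choices/outcomes and emitting choice probabilities), so
the simulator and the likelihood literally share one implementation of the
update equations.

State per block (everything resets at block boundaries):
  q2[set, pic]        model-free second-stage stimulus values
  q1[set, action]     model-free first-stage action values
  counters[set, a, p] set-specific transition counts
  last[set]           last first-stage action taken in that set (-1 = none)

Per-trial order of operations:
  infer beliefs from counters -> choose (softmax with perseveration) ->
  transition -> feedback -> stage-2 TD update (emits the RPE) ->
  stage-1 update (both deltas reference the pre-update stage-2 value) ->
  forgetting decay of all non-visited entries -> counter increment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_SIMULATE = 0
MODE_REPLAY = 1

#: transition labels emitted by the kernel
TRANS_COMMON = 0
TRANS_RARE = 1
TRANS_UNDEFINED = 2


@njit(cache=True)
def _beliefs(counters):
    """Diagonal transition belief P(pic == a | action a) for each set.

    d_s = (n[a0->p0] + n[a1->p1]) - (n[a0->p1] + n[a1->p0]); the set with
    the strictly larger |d| is tagged predictable and receives 0.75/0.25
    beliefs oriented by sign(d); ties (including the all-zero start) and the
    other set stay at 0.5/0.5.  Returns (p_diag0, p_diag1, predictable_set).
    """
    d0 = counters[0, 0, 0] + counters[0, 1, 1] \
        - counters[0, 0, 1] - counters[0, 1, 0]
    d1 = counters[1, 0, 0] + counters[1, 1, 1] \
        - counters[1, 0, 1] - counters[1, 1, 0]
    pred = -1
    if abs(d0) > abs(d1):
        pred = 0
    elif abs(d1) > abs(d0):
        pred = 1
    p0 = 0.5
    p1 = 0.5
    if pred == 0:
        if d0 > 0:
            p0 = 0.75
        elif d0 < 0:
            p0 = 0.25
    elif pred == 1:
        if d1 > 0:
            p1 = 0.75
        elif d1 < 0:
            p1 = 0.25
    return p0, p1, pred


@njit(cache=True)
def run_block(mode, set_seq,
              env_pred_set, common_pic, high_pic, p_common, p_reward_high,
              alpha, lam, beta, omega, rho,
              actions, pics, rewards,
              u_choice, u_trans, u_rew):
    """Run one block of trials.

    In MODE_SIMULATE, `actions`, `pics`, `rewards` are outputs and the
    uniforms drive sampling; in MODE_REPLAY they are the observed inputs and
    the uniforms are ignored.  Returns per-trial arrays:
    (transitions, p_action0, p_chosen, rpe, qnet (n,2), inferred_pred_set).
    """
    n = set_seq.shape[0]
    transitions = np.empty(n, dtype=np.int64)
    p_action0 = np.empty(n)
    p_chosen = np.empty(n)
    rpe = np.empty(n)
    qnet = np.empty((n, 2))
    inferred = np.empty(n, dtype=np.int64)

    q2 = np.zeros((2, 2))
    q1 = np.zeros((2, 2))
    counters = np.zeros((2, 2, 2))
    last = np.full(2, -1, dtype=np.int64)

    for i in range(n):
        s = set_seq[i]

        pd0, pd1, pred = _beliefs(counters)
        p_diag = pd0 if s == 0 else pd1
        inferred[i] = pred

        qmb0 = p_diag * q2[s, 0] + (1.0 - p_diag) * q2[s, 1]
        qmb1 = (1.0 - p_diag) * q2[s, 0] + p_diag * q2[s, 1]
        qn0 = omega * qmb0 + (1.0 - omega) * q1[s, 0]
        qn1 = omega * qmb1 + (1.0 - omega) * q1[s, 1]
        qnet[i, 0] = qn0
        qnet[i, 1] = qn1

        l0 = beta * qn0
        l1 = beta * qn1
        if last[s] == 0:
            l0 += rho
        elif last[s] == 1:
            l1 += rho
        m = l0 if l0 > l1 else l1
        e0 = np.exp(l0 - m)
        e1 = np.exp(l1 - m)
        p0 = e0 / (e0 + e1)
        p_action0[i] = p0

        if mode == MODE_SIMULATE:
            a = 0 if u_choice[i] < p0 else 1
            actions[i] = a
        else:
            a = actions[i]
        p_chosen[i] = p0 if a == 0 else 1.0 - p0

        if mode == MODE_SIMULATE:
            if s == env_pred_set:
                cp = common_pic[a]
                if u_trans[i] < p_common:
                    pic = cp
                    transitions[i] = TRANS_COMMON
                else:
                    pic = 1 - cp
                    transitions[i] = TRANS_RARE
            else:
                pic = 0 if u_trans[i] < 0.5 else 1
                transitions[i] = TRANS_UNDEFINED
            pics[i] = pic
            if pic == high_pic[s]:
                r = 1.0 if u_rew[i] < p_reward_high else -1.0
            else:
                r = -1.0 if u_rew[i] < p_reward_high else 1.0
            rewards[i] = r
        else:
            pic = pics[i]
            r = rewards[i]
            if s == env_pred_set:
                transitions[i] = TRANS_COMMON if pic == common_pic[a] \
                    else TRANS_RARE
            else:
                transitions[i] = TRANS_UNDEFINED

        # stage-2 TD update; both stage-1 deltas use the pre-update q2
        q2_old = q2[s, pic]
        delta = r - q2_old
        rpe[i] = delta
        q2[s, pic] = q2_old + alpha * delta
        q1[s, a] = q1[s, a] + alpha * (q2_old - q1[s, a]) + alpha * lam * delta

        # forgetting: decay every entry of both sets except the chosen
        # action and the presented picture
        for ss in range(2):
            for k in range(2):
                if not (ss == s and k == a):
                    q1[ss, k] *= (1.0 - alpha)
                if not (ss == s and k == pic):
                    q2[ss, k] *= (1.0 - alpha)

        counters[s, a, pic] += 1.0
        last[s] = a

    return transitions, p_action0, p_chosen, rpe, qnet, inferred


@njit(cache=True)
def replay_session(block_starts, set_seq, actions, pics, rewards,
                   alpha, lam, beta, omega, rho):
    """Replay observed trials block by block (state resets per block).

    Returns (p_chosen, rpe) over the whole session.  `block_starts` holds
    the start index of each block plus the total length as final element.
    """
    n = set_seq.shape[0]
    p_all = np.empty(n)
    rpe_all = np.empty(n)
    dummy_u = np.empty(0)
    common_pic = np.zeros(2, dtype=np.int64)
    high_pic = np.zeros(2, dtype=np.int64)
    for b in range(block_starts.shape[0] - 1):
        lo = block_starts[b]
        hi = block_starts[b + 1]
        _, _, p_chosen, rpe, _, _ = run_block(
            MODE_REPLAY, set_seq[lo:hi],
            -1, common_pic, high_pic, 0.75, 0.7,
            alpha, lam, beta, omega, rho,
            actions[lo:hi], pics[lo:hi], rewards[lo:hi],
            dummy_u, dummy_u, dummy_u)
        p_all[lo:hi] = p_chosen
        rpe_all[lo:hi] = rpe
    return p_all, rpe_all


@njit(cache=True)
def nll_session(block_starts, set_seq, actions, pics, rewards,
                alpha, lam, beta, omega, rho):
    """Negative log-likelihood of the observed first-stage choices."""
    p_chosen, _ = replay_session(block_starts, set_seq, actions, pics,
                                 rewards, alpha, lam, beta, omega, rho)
    nll = 0.0
    for i in range(p_chosen.shape[0]):
        p = p_chosen[i]
        if p < 1e-12:
            p = 1e-12
        nll -= np.log(p)
    return nll


@njit(cache=True)
def loglik_pointwise(block_starts, set_seq, actions, pics, rewards,
                     alpha, lam, beta, omega, rho):
    """Per-trial log-likelihood of the observed first-stage choices."""
    p_chosen, _ = replay_session(block_starts, set_seq, actions, pics,
                                 rewards, alpha, lam, beta, omega, rho)
    out = np.empty(p_chosen.shape[0])
    for i in range(p_chosen.shape[0]):
        p = p_chosen[i]
        if p < 1e-12:
            p = 1e-12
        out[i] = np.log(p)
    return out
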