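"""Hybrid model-free/model-based reinforcement-learning agent.

The agent learns second-stage stimulus values by temporal-difference
updates, propagates reward prediction errors (RPEs) to first-stage action
values through an eligibility trace, decays non-visited values
(forgetting), and maintains set-specific transition counters from which it
infers which stimulus set carries the predictable transition structure.
Model-based action values follow from the inferred transition beliefs via
the one-step Bellman backup; choices arise from a softmax over the
omega-weighted mixture of model-based and model-free values with a
perseveration bonus for repeating the previous same-set choice.

Rewards are coded r in {+1, -1} inside the model (the inverse temperature
absorbs scale); the +/-3 ct payoffs are kept for bonus accounting only.

The documented step functions below operate on an :class:`AgentState` and
define the update rules at unit granularity; full-session simulation and
likelihood replay share the compiled recursion in :mod:`twostep_eeg._core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _core
from .task import (ACTIONS, CONDITIONS, STAGE2, TRANSITIONS, BlockLayout,
                   TaskConfig, generate_condition_sequence, label_expectancy)


@dataclass
class AgentParams:
    """Free parameters of the hybrid model.

    alpha : learning rate in [0, 1]
    lam   : eligibility trace in [0, 1]
    beta  : softmax inverse temperature >= 0
    omega : model-basedness weight in [0, 1]
    rho   : perseveration (> 0) / switching (< 0) bias, unbounded
    """

    alpha: float
    lam: float
    beta: float
    omega: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha, self.lam, self.beta, self.omega, self.rho)

    def to_dict(self) -> dict:
        return asdict(self)


#: reference group-level parameter means (predictable condition),
#: used throughout as the canonical generating parameters for recovery
#: studies (alpha, lambda, beta, omega, rho)
REFERENCE_PARAMS = AgentParams(alpha=0.21, lam=0.96, beta=1.95,
                               omega=0.33, rho=0.73)


class RPERecord(NamedTuple):
    trial: int
    rpe: float
    abs_rpe: float


@dataclass
class TransitionBeliefs:
    """Inferred transition structure.

    ``p_diag[s]`` is P(picture j | action j) in set s, one of
    {0.75, 0.5, 0.25}; ``predictable_set`` is the set currently tagged as
    predictable (None while tied).
    """

    p_diag: np.ndarray
    predictable_set: int | None

    def p_matrix(self, set_id: int) -> np.ndarray:
        """Row-stochastic matrix P(picture | action) for one set."""
        p = self.p_diag[set_id]
        return np.array([[p, 1.0 - p], [1.0 - p, p]])


@dataclass
class AgentState:
    """Mutable learning state (one block; everything starts at zero)."""

    q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    q1: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    counters: np.ndarray = field(default_factory=lambda: np.zeros((2, 2, 2)))
    last_action: np.ndarray = field(
        default_factory=lambda: np.full(2, -1, dtype=np.int64))


def stage2_update(state: AgentState, set_id: int, picture: int, r: float,
                  alpha: float) -> RPERecord:
    """TD update of the presented second-stage stimulus value.

    q2 <- q2 + alpha * (r - q2); the bracketed delta is the RPE.
    Mutates ``state`` and returns the RPE record.
    """
    old = state.q2[set_id, picture]
    delta = r - old
    state.q2[set_id, picture] = old + alpha * delta
    return RPERecord(trial=-1, rpe=delta, abs_rpe=abs(delta))


def stage1_update(state: AgentState, set_id: int, action: int, picture: int,
                  r: float, alpha: float, lam: float,
                  q2_prev: float | None = None) -> None:
    """Eligibility-trace update of the chosen first-stage action value.

    q1 <- q1 + alpha*(q2 - q1) + alpha*lam*(r - q2), where q2 is the
    second-stage value *before* this trial's stage-2 update.  Call this
    before :func:`stage2_update`, or pass the pre-update value as
    ``q2_prev``.
    """
    q2 = state.q2[set_id, picture] if q2_prev is None else q2_prev
    old = state.q1[set_id, action]
    state.q1[set_id, action] = old + alpha * (q2 - old) + alpha * lam * (r - q2)


def apply_forgetting(state: AgentState, set_id: int, action: int,
                     picture: int, alpha: float) -> None:
    """Decay every q1/q2 entry of both sets by (1 - alpha) except the
    chosen action's and the presented picture's."""
    for ss in range(2):
        for k in range(2):
            if not (ss == set_id and k == action):
                state.q1[ss, k] *= (1.0 - alpha)
            if not (ss == set_id and k == picture):
                state.q2[ss, k] *= (1.0 - alpha)


def infer_beliefs(counters: np.ndarray) -> TransitionBeliefs:
    """Infer the predictable set and transition beliefs from the counters."""
    p0, p1, pred = _core._beliefs(counters)
    return TransitionBeliefs(p_diag=np.array([p0, p1]),
                             predictable_set=None if pred < 0 else int(pred))


def update_and_infer_model(state: AgentState, set_id: int, action: int,
                           picture: int) -> TransitionBeliefs:
    """Increment the (set, action, picture) transition counter and return
    the beliefs inferred from the updated counters."""
    state.counters[set_id, action, picture] += 1.0
    return infer_beliefs(state.counters)


def net_action_values(state: AgentState, beliefs: TransitionBeliefs,
                      set_id: int, omega: float) -> np.ndarray:
    """Q_net(a) = omega * Q_MB(a) + (1 - omega) * Q_MF(a) for both actions,
    with Q_MB(a) = sum_p P(p | a) q2(p) (Bellman backup)."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    q_mb = beliefs.p_matrix(set_id) @ state.q2[set_id]
    return omega * q_mb + (1.0 - omega) * state.q1[set_id]


def choice_probabilities(q_net: np.ndarray, last_action: int | None,
                         beta: float, rho: float) -> np.ndarray:
    """Softmax choice rule P(a) proportional to exp(beta*Q_net(a) +
    rho*rep(a)), overflow-safe; rep(a) = 1 iff a repeats the previous
    same-set choice."""
    q_net = np.asarray(q_net, dtype=float)
    if not np.all(np.isfinite(q_net)):
        raise ValueError("q_net must be finite")
    if beta < 0.0:
        raise ValueError("beta must be >= 0")
    logits = beta * q_net
    if last_action is not None and last_action >= 0:
        logits = logits.copy()
        logits[last_action] += rho
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def step_trial(state: AgentState, params: AgentParams, set_id: int,
               action: int, picture: int, r: float) -> RPERecord:
    """Apply one trial's full update sequence to ``state`` (reference
    implementation mirroring the compiled kernel)."""
    q2_prev = state.q2[set_id, picture]
    rec = stage2_update(state, set_id, picture, r, params.alpha)
    stage1_update(state, set_id, action, picture, r, params.alpha,
                  params.lam, q2_prev=q2_prev)
    apply_forgetting(state, set_id, action, picture, params.alpha)
    update_and_infer_model(state, set_id, action, picture)
    state.last_action[set_id] = action
    return rec


def simulate_agent(params: AgentParams, config: TaskConfig, seed: int,
                   subject: int = 0) -> tuple[pd.DataFrame, list[RPERecord]]:
    """Simulate a full session of the task.

    Returns the trial table (one row per trial, in presentation order) and
    the trial-wise RPE records.  The environment layout (which set is
    predictable, transition direction, high-reward picture) is
    re-randomized per block, and the agent's state resets at block
    boundaries.  Identical seed and parameters give identical output.
    """
    ss = np.random.SeedSequence(seed)
    cond_seed = int(ss.generate_state(1)[0] % (2**31))
    conditions = generate_condition_sequence(config, cond_seed)
    children = ss.spawn(config.n_blocks)

    rows = []
    rpes: list[RPERecord] = []
    npb = config.trials_per_block
    for b in range(config.n_blocks):
        rng = np.random.default_rng(children[b])
        layout = BlockLayout.random(rng)
        cond_block = conditions[b * npb:(b + 1) * npb]
        set_seq = np.array(
            [layout.predictable_set if c == "predictable"
             else 1 - layout.predictable_set for c in cond_block],
            dtype=np.int64)
        actions = np.zeros(npb, dtype=np.int64)
        pics = np.zeros(npb, dtype=np.int64)
        rewards = np.zeros(npb)
        u = rng.random((3, npb))
        trans, p0, p_chosen, rpe, qnet, inferred = _core.run_block(
            _core.MODE_SIMULATE, set_seq,
            layout.predictable_set, layout.common_pic, layout.high_pic,
            config.p_common, config.p_reward_high,
            params.alpha, params.lam, params.beta, params.omega, params.rho,
            actions, pics, rewards, u[0], u[1], u[2])

        correct_a = layout.correct_action()
        for i in range(npb):
            cond = cond_block[i]
            s = int(set_seq[i])
            pic = int(pics[i])
            win = rewards[i] > 0
            stage2_lab = "high_reward" if pic == layout.high_pic[s] \
                else "low_reward"
            valence = "win" if win else "loss"
            t = b * npb + i
            rows.append({
                "subject": subject,
                "block": b,
                "trial": i,
                "condition": cond,
                "set_id": s,
                "action_idx": int(actions[i]),
                "stage2_idx": pic,
                "action": ACTIONS[int(actions[i])],
                "stage2": stage2_lab,
                "transition": TRANSITIONS[int(trans[i])],
                "valence": valence,
                "expectancy": label_expectancy(stage2_lab, valence),
                "payoff": config.reward_win if win else config.reward_loss,
                "reward": float(rewards[i]),
                "choice_prob": float(p_chosen[i]),
                "q_net_A": float(qnet[i, 0]),
                "q_net_B": float(qnet[i, 1]),
                "rpe": float(rpe[i]),
                "abs_rpe": float(abs(rpe[i])),
                "inferred_predictable_set": int(inferred[i]),
                "correct": (int(actions[i]) == correct_a)
                if cond == "predictable" else np.nan,
            })
            rpes.append(RPERecord(trial=t, rpe=float(rpe[i]),
                                  abs_rpe=float(abs(rpe[i]))))
    return pd.DataFrame(rows), rpes


def simulate_cohort(params_list, config: TaskConfig,
                    seed: int) -> pd.DataFrame:
    """Simulate one session per subject; returns the stacked trial table."""
    tables = []
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(params_list)) % (2**31)
    for subj, (p, s) in enumerate(zip(params_list, child_seeds)):
        df, _ = simulate_agent(p, config, int(s), subject=subj)
        tables.append(df)
    return pd.concat(tables, ignore_index=True)
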