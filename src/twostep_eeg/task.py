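"""Two-stage Markov task environment with predictable and random transition sets.

The task interleaves two conditions within each block.  In the *predictable*
condition each first-stage action leads to one of the two second-stage
stimuli with probability ``p_common`` (common transition) and to the other
with ``1 - p_common`` (rare transition).  In the *random* condition both
second-stage stimuli are equally likely and the common/rare distinction is
undefined.  The reward structure is identical in both conditions: one
second-stage stimulus yields a win with probability ``p_reward_high`` (the
high-reward stimulus), the other yields a loss with the same probability.
Payoffs are +3/-3 ct.

Outcome *expectancy* is defined from the fixed reward structure alone:
wins after the high-reward stimulus and losses after the low-reward stimulus
are *expected*; the complementary two cells are *unexpected*.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np
import yaml

CONDITIONS = ("predictable", "random")
ACTIONS = ("A", "B")
STAGE2 = ("high_reward", "low_reward")
TRANSITIONS = ("common", "rare", "undefined")

#: Column order used when trial tables are serialized to CSV.
TRIAL_COLUMNS = [
    "subject", "block", "trial", "condition", "set_id",
    "action_idx", "stage2_idx", "action", "stage2", "transition",
    "valence", "expectancy", "payoff", "reward",
]


class ConstraintError(ValueError):
    """Raised when the interleaving constraint cannot be satisfied."""


@dataclass
class TaskConfig:
    """Design parameters of the modified two-stage task."""

    p_common: float = 0.75
    p_random: float = 0.5
    p_reward_high: float = 0.7
    reward_win: int = 3
    reward_loss: int = -3
    trials_per_block: int = 100
    trials_per_condition: int = 50
    max_run: int = 3
    n_blocks: int = 4

    def __post_init__(self) -> None:
        for name in ("p_common", "p_random", "p_reward_high"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.trials_per_condition * 2 != self.trials_per_block:
            raise ValueError(
                "trials_per_condition * 2 must equal trials_per_block"
            )
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class BlockLayout:
    """Per-block randomization of the environment.

    ``predictable_set`` is the set id (0 or 1) carrying the predictable
    transition structure this block.  ``common_pic[a]`` is the second-stage
    picture index the predictable set's action ``a`` commonly leads to.
    ``high_pic[s]`` is the picture index of the high-reward stimulus in
    set ``s``.
    """

    predictable_set: int
    common_pic: np.ndarray  # shape (2,), int
    high_pic: np.ndarray    # shape (2,), int

    @classmethod
    def random(cls, rng: np.random.Generator) -> "BlockLayout":
        c = int(rng.integers(2))
        return cls(
            predictable_set=int(rng.integers(2)),
            common_pic=np.array([c, 1 - c], dtype=np.int64),
            high_pic=rng.integers(2, size=2).astype(np.int64),
        )

    def correct_action(self) -> int:
        """First-stage action of the predictable set whose common transition
        leads to the high-reward picture."""
        hp = int(self.high_pic[self.predictable_set])
        return int(np.argmax(self.common_pic == hp))


def _constrained_shuffle(counts: list[int], max_run: int,
                         rng: np.random.Generator) -> list[int]:
    """Random interleaving of two labels with run lengths capped at max_run.

    Greedy with a feasibility lookahead; for two labels the arrangement
    ``max(counts) <= max_run * (min(counts) + 1)`` is achievable, and keeping
    that invariant after every placement guarantees no dead ends.
    """
    remaining = list(counts)
    seq: list[int] = []
    run_label, run_len = -1, 0
    total = sum(remaining)
    for _ in range(total):
        feasible = []
        for lab in (0, 1):
            if remaining[lab] == 0:
                continue
            if lab == run_label and run_len >= max_run:
                continue
            rem = remaining.copy()
            rem[lab] -= 1
            other = 1 - lab
            nr = run_len + 1 if lab == run_label else 1
            # after placing `lab` a run of length nr is open: at most
            # (max_run - nr) more `lab`s fit before an `other` must break it,
            # then max_run per gap; `other`s fit in runs of max_run separated
            # by the remaining `lab`s
            if rem[lab] > (max_run - nr) + max_run * rem[other]:
                continue
            if rem[other] > max_run * (rem[lab] + 1):
                continue
            feasible.append(lab)
        if not feasible:
            raise ConstraintError(
                f"cannot interleave counts {counts} with max_run={max_run}"
            )
        lab = feasible[int(rng.integers(len(feasible)))] \
            if len(feasible) > 1 else feasible[0]
        seq.append(lab)
        remaining[lab] -= 1
        if lab == run_label:
            run_len += 1
        else:
            run_label, run_len = lab, 1
    return seq


def generate_condition_sequence(config: TaskConfig, seed: int) -> list[str]:
    """Condition labels for a full session (n_blocks x trials_per_block).

    Each block contains exactly ``trials_per_condition`` trials of each
    condition, with no more than ``max_run`` identical labels in a row
    (the constraint is enforced within each block independently).
    """
    counts = [config.trials_per_condition, config.trials_per_condition]
    if max(counts) > config.max_run * (min(counts) + 1):
        raise ConstraintError(
            f"counts {counts} cannot satisfy max_run={config.max_run}"
        )
    seqs = []
    for child in np.random.SeedSequence(seed).spawn(config.n_blocks):
        rng = np.random.default_rng(child)
        seqs.extend(_constrained_shuffle(counts, config.max_run, rng))
    return [CONDITIONS[i] for i in seqs]


def sample_transition(condition: str, action: int,
                      direction_map: Mapping[int, int] | Sequence[int],
                      rng: np.random.Generator,
                      p_common: float = 0.75) -> tuple[int, str]:
    """Draw the second-stage picture index and transition label for one trial.

    ``direction_map[action]`` is the picture the action commonly leads to
    (required for the predictable condition only).
    """
    if condition == "predictable":
        mapped = direction_map[action]
        if rng.random() < p_common:
            return int(mapped), "common"
        return int(1 - mapped), "rare"
    if condition == "random":
        return int(rng.integers(2)), "undefined"
    raise ValueError(f"unknown condition {condition!r}")


def sample_feedback(stage2: str, config: TaskConfig,
                    rng: np.random.Generator) -> tuple[str, int]:
    """Draw (valence, payoff in ct) from the fixed reward structure."""
    if stage2 not in STAGE2:
        raise ValueError(f"unknown stage-2 label {stage2!r}")
    p_win = config.p_reward_high if stage2 == "high_reward" \
        else 1.0 - config.p_reward_high
    if rng.random() < p_win:
        return "win", config.reward_win
    return "loss", config.reward_loss


def label_expectancy(stage2: str, valence: str) -> str:
    """Expectancy cell of an outcome, from the reward structure alone."""
    if stage2 not in STAGE2 or valence not in ("win", "loss"):
        raise ValueError(f"invalid labels ({stage2!r}, {valence!r})")
    expected = (stage2 == "high_reward") == (valence == "win")
    return "expected" if expected else "unexpected"


def expected_random_payoff(config: TaskConfig) -> float:
    """Expected payoff per trial (ct) of a uniformly random policy in the
    random condition.

    Each picture is reached with probability 1/2; analytic value
    0.5*(p*w + (1-p)*l) + 0.5*((1-p)*w + p*l), which is exactly 0 for the
    symmetric +3/-3 structure.
    """
    p, w, l = config.p_reward_high, config.reward_win, config.reward_loss
    return 0.5 * (p * w + (1 - p) * l) + 0.5 * ((1 - p) * w + p * l)
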