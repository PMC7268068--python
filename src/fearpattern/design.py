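"""Experimental design for a two-context discriminative fear-conditioning task.

The task crosses three within-subject factors: stimulus (the two members of a
sound pair, S1/S2), complexity (simple monophones vs. complex triads), and
context (a reinforcement context in which one sound, the CS+, is partially
paired with an aversive unconditioned stimulus, vs. an instructed
nonreinforcement context with neutral sounds NS1/NS2).  The experiment is
organised in blocks of alternating context; within each block, the first half
of the trials is one complexity and the second half the other, and within each
half the two pair members appear equally often in a randomly permuted order.

`generate_design` builds the full trial table deterministically from a
parameter set and a seed; `assign_reinforcement` flags which CS+ trials carry
the unconditioned stimulus.  Designs round-trip through a BIDS-style events
TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "COMPLEXITIES",
    "PAIR_ROLES",
    "StimulusId",
    "ALL_STIMULI",
    "TrialSpec",
    "DesignParams",
    "ExperimentDesign",
    "generate_design",
    "assign_reinforcement",
]

CONTEXTS = ("reinforcement", "nonreinforcement")
COMPLEXITIES = ("simple", "complex")
PAIR_ROLES = ("S1", "S2")


@dataclass(frozen=True, order=True)
class StimulusId:
    """One of the eight stimuli: pair role x context x complexity.

    In the reinforcement context S1 is the CS- (never reinforced) and S2 the
    CS+ (partially reinforced); in the nonreinforcement context the same roles
    are the neutral sounds NS1 and NS2.
    """

    pair_role: str
    context: str
    complexity: str

    def __post_init__(self) -> None:
        if self.pair_role not in PAIR_ROLES:
            raise ValueError(f"pair_role must be one of {PAIR_ROLES}, got {self.pair_role!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.complexity not in COMPLEXITIES:
            raise ValueError(
                f"complexity must be one of {COMPLEXITIES}, got {self.complexity!r}"
            )

    @property
    def label(self) -> str:
        """Conventional name: CS-/CS+ in the reinforcement context, NS1/NS2 otherwise."""
        if self.context == "reinforcement":
            return "CS-" if self.pair_role == "S1" else "CS+"
        return "NS1" if self.pair_role == "S1" else "NS2"

    @property
    def required_response(self) -> str:
        """Key assignment is tied to pair role, matched across context and complexity."""
        return "key1" if self.pair_role == "S1" else "key2"

    @property
    def is_cs_plus(self) -> bool:
        return self.context == "reinforcement" and self.pair_role == "S2"


ALL_STIMULI = tuple(
    StimulusId(role, ctx, cx) for ctx in CONTEXTS for cx in COMPLEXITIES for role in PAIR_ROLES
)


@dataclass
class TrialSpec:
    """A single trial: chronological index, block, stimulus, timing, US flag."""

    index: int
    block: int
    stimulus: StimulusId
    onset: float
    iti_after: float
    reinforced: bool = False

    @property
    def required_response(self) -> str:
        return self.stimulus.required_response


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the block design.

    Defaults reproduce the reference task: 8 blocks of 24 trials, 4 s sounds,
    inter-trial intervals drawn from {7, 9, 11} s, and half of the CS+ trials
    reinforced.  ``start_context`` and ``simple_first`` are the
    counterbalancing flags (which context opens block 1 and which complexity
    fills the first half of each block); ``block_gap`` is an optional pause
    appended after each block.
    """

    n_blocks: int = 8
    trials_per_block: int = 24
    stimulus_duration: float = 4.0
    iti_set: tuple[float, ...] = (7.0, 9.0, 11.0)
    reinforcement_rate: float = 0.5
    seed: int = 0
    start_context: str = "reinforcement"
    simple_first: bool = True
    block_gap: float = 0.0

    def validate(self) -> None:
        if self.n_blocks <= 0 or self.n_blocks % 2 != 0:
            raise ValueError(f"n_blocks must be a positive even number, got {self.n_blocks}")
        if self.trials_per_block <= 0 or self.trials_per_block % 4 != 0:
            raise ValueError(
                f"trials_per_block must be a positive multiple of 4, got {self.trials_per_block}"
            )
        if len(self.iti_set) == 0:
            raise ValueError("iti_set must not be empty")
        if any(t < 0 for t in self.iti_set):
            raise ValueError("inter-trial intervals must be non-negative")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ValueError("reinforcement_rate must lie in [0, 1]")
        if self.start_context not in CONTEXTS:
            raise ValueError(f"start_context must be one of {CONTEXTS}")
        n_csplus = self.cs_plus_per_complexity
        n_reinf = self.reinforcement_rate * n_csplus
        if abs(n_reinf - round(n_reinf)) > 1e-9:
            raise ValueError(
                "reinforcement_rate x CS+ trials per complexity must be an integer; "
                f"got {self.reinforcement_rate} x {n_csplus} = {n_reinf}"
            )

    @property
    def cs_plus_per_complexity(self) -> int:
        """CS+ presentations per complexity condition (= per-stimulus count)."""
        return (self.n_blocks // 2) * (self.trials_per_block // 4)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class ExperimentDesign:
    """Ordered trial list plus the parameters that generated it."""

    trials: list[TrialSpec]
    params: DesignParams

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def stimulus_counts(self) -> dict[StimulusId, int]:
        counts: dict[StimulusId, int] = {s: 0 for s in ALL_STIMULI}
        for t in self.trials:
            counts[t.stimulus] += 1
        return counts

    def select(self, **criteria) -> list[TrialSpec]:
        """Trials whose stimulus attributes (or 'reinforced') match all criteria."""
        out = []
        for t in self.trials:
            ok = True
            for key, val in criteria.items():
                if key == "reinforced":
                    ok = ok and (t.reinforced == val)
                else:
                    ok = ok and (getattr(t.stimulus, key) == val)
            if ok:
                out.append(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.onset,
                    "duration": self.params.stimulus_duration,
                    "trial_type": t.stimulus.label,
                    "block": t.block,
                    "context": t.stimulus.context,
                    "complexity": t.stimulus.complexity,
                    "pair_role": t.stimulus.pair_role,
                    "reinforced": int(t.reinforced),
                    "required_response": t.required_response,
                    "iti_after": t.iti_after,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, params: DesignParams | None = None) -> "ExperimentDesign":
        df = pd.read_csv(path, sep="\t")
        trials = []
        for i, row in df.iterrows():
            stim = StimulusId(row["pair_role"], row["context"], row["complexity"])
            trials.append(
                TrialSpec(
                    index=i,
                    block=int(row["block"]),
                    stimulus=stim,
                    onset=float(row["onset"]),
                    iti_after=float(row["iti_after"]),
                    reinforced=bool(row["reinforced"]),
                )
            )
        if params is None:
            n_blocks = int(df["block"].max())
            params = DesignParams(
                n_blocks=n_blocks,
                trials_per_block=len(df) // n_blocks,
                stimulus_duration=float(df["duration"].iloc[0]),
                iti_set=tuple(sorted(df["iti_after"].unique())),
            )
        return cls(trials=trials, params=params)


def _block_context(block: int, start_context: str) -> str:
    """Contexts alternate block to block, starting from ``start_context``."""
    first = CONTEXTS.index(start_context)
    return CONTEXTS[(first + block - 1) % 2]


def generate_design(params: DesignParams) -> ExperimentDesign:
    """Build the full trial table from parameters and seed.

    Within each half-block the two pair members each appear half the time in a
    seeded random permutation; inter-trial intervals are drawn uniformly from
    ``params.iti_set``.  Reinforcement flags are all False; use
    :func:`assign_reinforcement` to set them.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    half = params.trials_per_block // 2
    per_role = half // 2

    trials: list[TrialSpec] = []
    onset = 0.0
    index = 0
    for block in range(1, params.n_blocks + 1):
        context = _block_context(block, params.start_context)
        complexity_order = (
            ("simple", "complex") if params.simple_first else ("complex", "simple")
        )
        for complexity in complexity_order:
            roles = np.array(["S1"] * per_role + ["S2"] * per_role)
            roles = roles[rng.permutation(half)]
            for role in roles:
                iti = float(rng.choice(params.iti_set))
                trials.append(
                    TrialSpec(
                        index=index,
                        block=block,
                        stimulus=StimulusId(str(role), context, complexity),
                        onset=onset,
                        iti_after=iti,
                    )
                )
                onset += params.stimulus_duration + iti
                index += 1
        onset += params.block_gap
    return ExperimentDesign(trials=trials, params=params)


def assign_reinforcement(design: ExperimentDesign, seed: int) -> ExperimentDesign:
    """Flag a seeded random subset of CS+ trials, per complexity, as reinforced.

    Exactly ``reinforcement_rate`` x (CS+ count per complexity) trials are
    flagged within each complexity condition; no CS- or neutral-sound trial is
    ever flagged.  Returns a new design; the input is left untouched.
    """
    params = design.params
    cs_plus = [t for t in design.trials if t.stimulus.is_cs_plus]
    if not cs_plus:
        raise ValueError("design contains no CS+ trials")
    rng = np.random.default_rng(seed)
    flagged: set[int] = set()
    for complexity in COMPLEXITIES:
        idx = [t.index for t in cs_plus if t.stimulus.complexity == complexity]
        n_reinf = round(params.reinforcement_rate * len(idx))
        chosen = rng.choice(len(idx), size=n_reinf, replace=False)
        flagged.update(idx[i] for i in chosen)
    new_trials = [replace(t, reinforced=(t.index in flagged)) for t in design.trials]
    return ExperimentDesign(trials=new_trials, params=params)
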