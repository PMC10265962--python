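"""Rule-based vocalization task design.

The experiment crosses two binary variables — the *content* of a vocalization
(vowel /u/ vs. /ə/) and its *production* form (vocalized vs. imagined) — and
instructs them sequentially with two visual cues (a forward or backward slash).
Which variable the first cue instructs, and which glyph maps onto which value,
is fixed within a recording block and changes between blocks, giving four
rules (2 cue orders x 2 glyph assignments) and hence 16 distinct conditions
(4 rules x 4 vowel-production cells). A session holds one block per rule,
80 trials per block, 20 per cell; the second session replays the first
session's block order reversed.

Timing within a trial (ms relative to first-cue onset): each cue lasts 100 ms
and is followed by a 2-s delay, so the go cue comes 4200 ms after cue 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

VOWELS = ("u", "schwa")
PRODUCTIONS = ("vocalized", "imagined")
ORDERS = ("content_first", "production_first")
GLYPHS = ("forward_slash", "backward_slash")

# Event arithmetic (ms): 100 ms cue, 2000 ms delay, 100 ms cue, 2000 ms delay, go.
CUE_MS = 100
DELAY_MS = 2000
CUE1_ONSET_MS = 0
CUE1_OFFSET_MS = CUE1_ONSET_MS + CUE_MS
CUE2_ONSET_MS = CUE1_OFFSET_MS + DELAY_MS
CUE2_OFFSET_MS = CUE2_ONSET_MS + CUE_MS
GO_ONSET_MS = CUE2_OFFSET_MS + DELAY_MS
RESPONSE_MS = 1500
TRIAL_END_MS = GO_ONSET_MS + RESPONSE_MS

#: Base cell codes for the vowel x production factorial.
BASE_CELLS = {
    ("u", "vocalized"): 1,
    ("u", "imagined"): 2,
    ("schwa", "vocalized"): 3,
    ("schwa", "imagined"): 4,
}


@dataclass(frozen=True)
class Rule:
    """One block rule: cue order plus the glyph-to-meaning assignment.

    ``cue_map[position][glyph]`` gives the instructed value (a vowel for the
    content cue, a production form for the production cue). ``assignment``
    distinguishes the two glyph assignments per order.
    """

    order: str
    assignment: int
    cue_map: dict = field(hash=False, compare=False, default=None)

    def __post_init__(self):
        if self.order not in ORDERS:
            raise ValueError(f"unknown cue order {self.order!r}")
        if self.assignment not in (0, 1):
            raise ValueError("assignment must be 0 or 1")
        variables = (
            ("vowel", VOWELS) if self.order == "content_first" else ("production", PRODUCTIONS),
            ("production", PRODUCTIONS) if self.order == "content_first" else ("vowel", VOWELS),
        )
        cue_map = {}
        for position, (_, values) in enumerate(variables, start=1):
            glyphs = GLYPHS if self.assignment == 0 else GLYPHS[::-1]
            cue_map[position] = dict(zip(glyphs, values))
        object.__setattr__(self, "cue_map", cue_map)

    @property
    def index(self) -> int:
        """Lexicographic rule index 0-3 over (order, assignment)."""
        return 2 * ORDERS.index(self.order) + self.assignment

    def glyph_for(self, position: int, value: str) -> str:
        """Glyph shown at cue ``position`` (1 or 2) to instruct ``value``."""
        for glyph, meaning in self.cue_map[position].items():
            if meaning == value:
                return glyph
        raise KeyError(f"{value!r} is not instructed at position {position}")


@dataclass(frozen=True)
class TrialSpec:
    """Labels and event timings of one trial."""

    block_index: int
    rule: Rule
    vowel: str
    production: str
    cue1_onset: int = CUE1_ONSET_MS
    cue1_offset: int = CUE1_OFFSET_MS
    cue2_onset: int = CUE2_ONSET_MS
    cue2_offset: int = CUE2_OFFSET_MS
    go_onset: int = GO_ONSET_MS
    trial_end: int = TRIAL_END_MS

    @property
    def condition_id(self) -> int:
        return condition_code(self)

    @property
    def cue1_glyph(self) -> str:
        first = self.vowel if self.rule.order == "content_first" else self.production
        return self.rule.glyph_for(1, first)

    @property
    def cue2_glyph(self) -> str:
        second = self.production if self.rule.order == "content_first" else self.vowel
        return self.rule.glyph_for(2, second)


@dataclass
class SessionDesign:
    """All trials of one recording session in presentation order."""

    participant_id: str
    session_index: int
    block_rules: list  # list[Rule], presentation order
    trials: list  # list[list[TrialSpec]], one inner list per block
    rng_seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.trials)

    def flat_trials(self) -> list:
        return [t for block in self.trials for t in block]

    def to_frame(self) -> pd.DataFrame:
        """Tidy trial table (one row per trial, presentation order)."""
        rows = []
        for block_pos, block in enumerate(self.trials):
            for trial_pos, t in enumerate(block):
                rows.append(
                    dict(
                        participant=self.participant_id,
                        session=self.session_index,
                        block=block_pos,
                        trial=trial_pos,
                        condition_id=t.condition_id,
                        vowel=t.vowel,
                        production=t.production,
                        order=t.rule.order,
                        cue_assignment=t.rule.assignment,
                        cue1_glyph=t.cue1_glyph,
                        cue2_glyph=t.cue2_glyph,
                        cue1_onset_ms=t.cue1_onset,
                        cue1_offset_ms=t.cue1_offset,
                        cue2_onset_ms=t.cue2_onset,
                        cue2_offset_ms=t.cue2_offset,
                        go_onset_ms=t.go_onset,
                        trial_end_ms=t.trial_end,
                        production_correct=True,
                        vowel_correct=True,
                    )
                )
        return pd.DataFrame(rows)


def enumerate_rules() -> list:
    """The four block rules: 2 cue orders x 2 glyph assignments."""
    return [Rule(order, a) for order in ORDERS for a in (0, 1)]


def enumerate_block_orders() -> list:
    """All 24 permutations of the four rule blocks (tuples of rule indices)."""
    return list(itertools.permutations(range(4)))


def condition_code(trial: TrialSpec) -> int:
    """Bijective condition code 1-16.

    Codes 1-4 are the (vowel x production) cells of the first rule
    (content-first, assignment 0); each further rule shifts the base cell by 4,
    ordered lexicographically by (order, assignment).
    """
    base = BASE_CELLS[(trial.vowel, trial.production)]
    return base + 4 * trial.rule.index


def build_session_design(participant_id: str, session_index: int, seed: int) -> SessionDesign:
    """Build one session: 4 rule blocks x 80 trials, 20 per cell, seeded shuffle.

    The block order is drawn per participant from the 24 permutations using the
    participant-level seed; session 2 reverses session 1's order. Trial order
    within a block is an unconstrained seeded shuffle of the balanced multiset
    and differs between sessions.
    """
    if session_index not in (1, 2):
        raise ValueError(f"session_index must be 1 or 2, got {session_index}")
    rules = enumerate_rules()
    participant_rng = np.random.default_rng([seed, _stable_hash(participant_id)])
    order = list(enumerate_block_orders()[participant_rng.integers(24)])
    if session_index == 2:
        order = order[::-1]
    session_rng = np.random.default_rng(
        [seed, _stable_hash(participant_id), session_index]
    )
    blocks = []
    cells = [(v, p) for v in VOWELS for p in PRODUCTIONS]
    for block_pos, rule_idx in enumerate(order):
        rule = rules[rule_idx]
        multiset = [cell for cell in cells for _ in range(20)]
        session_rng.shuffle(multiset)
        blocks.append(
            [TrialSpec(block_index=block_pos, rule=rule, vowel=v, production=p) for v, p in multiset]
        )
    return SessionDesign(
        participant_id=participant_id,
        session_index=session_index,
        block_rules=[rules[i] for i in order],
        trials=blocks,
        rng_seed=seed,
    )


def write_design_tsv(design: SessionDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _stable_hash(text: str) -> int:
    """Deterministic small-int hash of a string (process-independent)."""
    h = 0
    for ch in str(text):
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


def condition_table() -> pd.DataFrame:
    """Static lookup of all 16 conditions and their factor levels."""
    rows = []
    for rule in enumerate_rules():
        for v in VOWELS:
            for p in PRODUCTIONS:
                t = TrialSpec(block_index=0, rule=rule, vowel=v, production=p)
                rows.append(
                    dict(
                        condition_id=t.condition_id,
                        vowel=v,
                        production=p,
                        order=rule.order,
                        cue_assignment=rule.assignment,
                    )
                )
    return pd.DataFrame(rows).sort_values("condition_id").reset_index(drop=True)
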