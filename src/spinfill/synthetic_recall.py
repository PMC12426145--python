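"""Generative model of serial recall for pipeline testing.

The analysis stages of this package (scoring, lag-CRP, contrasts) need
trial-level data with the statistical structure of spin-list serial
learning: six-item lists recalled in order, anticipation / fill-in / infill
/ repeat / omission / intrusion errors, a fill-in tendency whose magnitude
shrinks as recall comes to rely on item-dependent (chaining-like) cues,
elevated wrap-around (-5 lag) transitions in spun lists, slow first
responses, and occasional false starts.  This module provides a small
generative model with exactly those signatures.  It makes no claim of
cognitive fidelity beyond them and is never fitted to data.

Retrieval combines three cues, mirroring the item-independent /
item-dependent dichotomy that the spin-list procedure dissociates:

* a *positional* cue for the current output position, generalising to
  neighbouring input positions with exponential decay ``lambda_pos``
  (item-independent, available immediately);
* a learned *position-to-item* association ``P`` (item-independent,
  accumulated across repetitions);
* a learned *item-to-item* association ``C`` cued by the previously
  recalled item (item-dependent chaining, accumulated across repetitions).

The cue mixture is modulated by a primacy gradient (early input positions
are more active, decay ``lambda_prim``) and response suppression (already
recalled items are attenuated by ``s``).  The primacy gradient plus
suppression is what yields a fill-in tendency even without chaining; a
positive chaining weight adds infill and, in spun lists, wrap transitions,
because the adjacency structure of rotated lists is consistent across
repetitions.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .list_design import ListSet, make_same_set, make_scrambled_set, make_spun_set

__all__ = [
    "OMIT",
    "INTRUSION_ALPHABET",
    "SimParams",
    "Response",
    "Trial",
    "AssocState",
    "candidate_activation",
    "simulate_trial",
    "simulate_session",
    "simulate_experiment",
]

#: Token recorded for an omitted response (maps to an empty CSV cell).
OMIT = ""

#: Reserved extra-list symbols used for intrusions; disjoint from every
#: letter-based list set.
INTRUSION_ALPHABET = ("1", "2", "3", "4", "5", "6")

LIST_LENGTH = 6


@dataclass(frozen=True)
class SimParams:
    """Weights, gradients, noise, RT and false-start parameters.

    Defaults are tuned once to the task regime the pipeline targets:
    six-letter lists recalled after a brief retention interval, ten
    repetitions per list, recall accuracy well above chance with errors
    dominated by order errors, a roughly 2:1 fill-in to infill ratio when
    chaining is absent, first responses several times slower than later
    ones, and a few percent of trials starting with a false start.

    Parameters
    ----------
    w_pos, w_chain, w_posmem
        Non-negative weights of the current-trial positional cue, the
        learned item-item (chaining) cue, and the learned position-item
        cue.
    lambda_pos
        Positional generalisation decay per position: the positional cue
        for output position p activates the item from input position q
        proportionally to exp(-lambda_pos * |q - p|).
    lambda_prim
        Primacy-gradient decay per input position.
    s
        Response-suppression strength in [0, 1]; 1 removes recalled items.
    eta
        Associative learning rate per presentation.
    temperature
        Luce choice noise; activations are raised to 1/temperature before
        normalisation, and 0 means deterministic argmax (ties broken
        toward the lowest input position).
    p_omit, p_intrude
        Per-response probabilities of omitting (which ends the trial) and
        of emitting an extra-list intrusion symbol.
    rt_first_mu, rt_later_mu, rt_sigma
        Log-scale lognormal RT parameters (ms); first responses are slower.
    p_false_start
        Probability that a trial begins with a swapped, fast first
        response (a motor error, not a memory error).
    n_reps
        Repetitions of each list in a session.
    seed
        Base seed; per-participant substreams are derived from it.
    """

    w_pos: float = 1.0
    w_chain: float = 0.16
    w_posmem: float = 0.2
    lambda_pos: float = 1.3
    lambda_prim: float = 0.30
    s: float = 0.6
    eta: float = 0.05
    temperature: float = 0.6
    p_omit: float = 0.02
    p_intrude: float = 0.02
    rt_first_mu: float = math.log(1100.0)
    rt_later_mu: float = math.log(380.0)
    rt_sigma: float = 0.35
    p_false_start: float = 0.03
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_pos", "w_chain", "w_posmem", "lambda_pos",
                     "lambda_prim", "eta", "temperature", "rt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("s", "p_omit", "p_intrude", "p_false_start"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass(frozen=True)
class Response:
    output_position: int  # 1-based, strictly increasing within a trial
    symbol: str           # list item, intrusion symbol, or OMIT
    rt_ms: float | None   # positive; None for omissions

    def __post_init__(self) -> None:
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


@dataclass(frozen=True)
class Trial:
    participant: str
    list_type: str
    input_list: tuple[str, ...]
    responses: tuple[Response, ...]
    experiment: str = "sim"
    site: str = "sim"
    list_id: str = "L1"
    repetition: int = 1
    trial_index: int = 1

    def __post_init__(self) -> None:
        positions = [r.output_position for r in self.responses]
        if positions != sorted(set(positions)) or (positions and positions[0] < 1):
            raise ValueError("output positions must be strictly increasing from 1")


@dataclass
class AssocState:
    """Accumulated item-item (C) and position-item (P) association strengths."""

    C: dict[str, dict[str, float]] = field(default_factory=dict)
    P: dict[int, dict[str, float]] = field(default_factory=dict)

    def normalized_C(self, prev_item: str) -> dict[str, float]:
        row = self.C.get(prev_item, {})
        total = sum(row.values())
        return {k: v / total for k, v in row.items()} if total > 0 else {}

    def normalized_P(self, position: int) -> dict[str, float]:
        row = self.P.get(position, {})
        total = sum(row.values())
        return {k: v / total for k, v in row.items()} if total > 0 else {}

    def learn(self, input_list: Sequence[str], eta: float) -> None:
        """One presentation: strengthen adjacent item pairs and position-item pairs."""
        for x, y in zip(input_list, input_list[1:]):
            self.C.setdefault(x, {})[y] = self.C.get(x, {}).get(y, 0.0) + eta
        for pos, item in enumerate(input_list, start=1):
            self.P.setdefault(pos, {})[item] = self.P.get(pos, {}).get(item, 0.0) + eta


def candidate_activation(
    item: str,
    output_position: int,
    prev_item: str | None,
    recalled_set: frozenset | set,
    input_list: Sequence[str],
    state: AssocState,
    params: SimParams,
) -> float:
    """Activation of ``item`` as the candidate response at ``output_position``.

    activation = primacy(item) * [positional + position-memory + chaining]
                 * suppression(item), all terms as documented in the module
    docstring.  An allowed intrusion symbol has no input position and hence
    zero activation (intrusions enter through a separate noise channel).
    """
    if output_position < 1 or output_position > len(input_list):
        raise ValueError("output_position out of range")
    if item not in input_list:
        if item in INTRUSION_ALPHABET:
            return 0.0
        raise ValueError(f"{item!r} is neither a list item nor an intrusion symbol")
    inpos = input_list.index(item) + 1
    primacy = math.exp(-params.lambda_prim * (inpos - 1))
    positional = params.w_pos * math.exp(
        -params.lambda_pos * abs(inpos - output_position)
    )
    posmem = params.w_posmem * state.normalized_P(output_position).get(item, 0.0)
    chain = 0.0
    if prev_item is not None:
        chain = params.w_chain * state.normalized_C(prev_item).get(item, 0.0)
    suppression = 1.0 - params.s * (item in recalled_set)
    return primacy * (positional + posmem + chain) * suppression


def _activations(
    output_position: int,
    prev_item: str | None,
    recalled: set,
    input_list: Sequence[str],
    state: AssocState,
    params: SimParams,
) -> np.ndarray:
    """Vectorised candidate_activation over all list items (same formula)."""
    n = len(input_list)
    inpos = np.arange(1, n + 1, dtype=float)
    primacy = np.exp(-params.lambda_prim * (inpos - 1))
    positional = params.w_pos * np.exp(
        -params.lambda_pos * np.abs(inpos - output_position)
    )
    prow = state.normalized_P(output_position)
    posmem = params.w_posmem * np.array([prow.get(i, 0.0) for i in input_list])
    if prev_item is not None:
        crow = state.normalized_C(prev_item)
        chain = params.w_chain * np.array([crow.get(i, 0.0) for i in input_list])
    else:
        chain = np.zeros(n)
    supp = 1.0 - params.s * np.array([i in recalled for i in input_list])
    return primacy * (positional + posmem + chain) * supp


def _choose(act: np.ndarray, temperature: float, rng: np.random.Generator) -> int:
    if temperature == 0.0:
        return int(np.argmax(act))  # argmax; ties -> lowest input position
    total = act.sum()
    if total <= 0.0:
        p = np.full(len(act), 1.0 / len(act))
    else:
        logits = np.where(act > 0, np.log(np.where(act > 0, act, 1.0)), -np.inf)
        logits = logits / temperature
        logits -= logits.max()
        w = np.exp(logits)
        p = w / w.sum()
    return int(rng.choice(len(act), p=p))


def simulate_trial(
    input_list: Sequence[str],
    state: AssocState,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[Response, ...]:
    """Generate one recall attempt and update the associative state.

    Per output position: omit (and stop) with ``p_omit``; emit a uniform
    extra-list intrusion with ``p_intrude``; otherwise Luce-sample a list
    item from the candidate activations.  RTs are lognormal, slower for the
    first response.  With ``p_false_start`` the first two responses are
    swapped and the new first RT resampled fast, emulating a motor false
    start.  After the recall attempt the associations learn from this
    presentation.
    """
    input_list = tuple(input_list)
    n = len(input_list)
    responses: list[Response] = []
    recalled: set[str] = set()
    prev: str | None = None
    for outpos in range(1, n + 1):
        u = rng.random()
        if u < params.p_omit:
            responses.append(Response(outpos, OMIT, None))
            break
        mu = params.rt_first_mu if outpos == 1 else params.rt_later_mu
        rt = float(rng.lognormal(mu, params.rt_sigma))
        if u < params.p_omit + params.p_intrude:
            symbol = str(rng.choice(INTRUSION_ALPHABET))
        else:
            act = _activations(outpos, prev, recalled, input_list, state, params)
            symbol = input_list[_choose(act, params.temperature, rng)]
        responses.append(Response(outpos, symbol, rt))
        recalled.add(symbol)
        prev = symbol
    if (
        len(responses) >= 2
        and responses[0].symbol != OMIT
        and responses[1].symbol != OMIT
        and rng.random() < params.p_false_start
    ):
        # Motor error: the second item's keystroke lands first.  The first
        # emitted RT is resampled fast — typically below the second-response
        # median — so the false-start screen has something to catch.
        fast_rt = float(
            rng.lognormal(params.rt_later_mu - params.rt_sigma, params.rt_sigma)
        )
        r0, r1 = responses[0], responses[1]
        responses[0] = Response(1, r1.symbol, fast_rt)
        responses[1] = Response(2, r0.symbol, r1.rt_ms)
    state.learn(input_list, params.eta)
    return tuple(responses)


def _participant_rng(seed: int, participant: str) -> np.random.Generator:
    digest = hashlib.sha256(participant.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def simulate_session(
    schedule: Sequence[tuple[ListSet, int]],
    params: SimParams,
    participant: str,
    experiment: str = "sim",
    site: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[Trial]:
    """Simulate one participant's session.

    ``schedule`` pairs each list set with its repetition count.  Lists are
    presented in cycles: each cycle presents every list of every still
    active set once, in an order shuffled per cycle.  Associative state is
    maintained separately per list set (the sets use nonoverlapping items).
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    if rng is None:
        rng = _participant_rng(params.seed, participant)
    states = {id(ls): AssocState() for ls, _ in schedule}
    trials: list[Trial] = []
    trial_index = 0
    max_reps = max(n for _, n in schedule)
    for rep in range(1, max_reps + 1):
        active = [
            (ls, k)
            for ls, n_reps in schedule
            if rep <= n_reps
            for k in range(len(ls.lists))
        ]
        order = rng.permutation(len(active))
        for idx in order:
            ls, k = active[idx]
            responses = simulate_trial(ls.lists[k], states[id(ls)], params, rng)
            trial_index += 1
            trials.append(
                Trial(
                    participant=participant,
                    experiment=experiment,
                    site=site,
                    list_type=ls.list_type,
                    list_id=f"{ls.set_id}:{k + 1}",
                    repetition=rep,
                    trial_index=trial_index,
                    input_list=tuple(ls.lists[k]),
                    responses=responses,
                )
            )
    return trials


_LETTERS = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def simulate_experiment(
    n_participants: int,
    params: SimParams | None = None,
    list_types: Sequence[str] = ("same", "spun", "scrambled"),
    experiment: str = "sim",
    site: str = "sim",
) -> list[Trial]:
    """Simulate a whole experiment: every participant recalls one set per
    list type, each set built from a nonoverlapping group of six letters
    drawn at random for that participant."""
    if params is None:
        params = SimParams()
    makers = {
        "same": lambda it: make_same_set(it, n_lists=LIST_LENGTH, set_id="same"),
        "spun": lambda it: make_spun_set(it, set_id="spun"),
        "scrambled": lambda it: make_scrambled_set(it, set_id="scrambled"),
    }
    trials: list[Trial] = []
    for p in range(1, n_participants + 1):
        label = f"P{p:03d}"
        rng = _participant_rng(params.seed, label)
        letters = [str(x) for x in rng.permutation(np.array(_LETTERS))]
        schedule = []
        for i, lt in enumerate(list_types):
            items = tuple(letters[i * LIST_LENGTH:(i + 1) * LIST_LENGTH])
            schedule.append((makers[lt](items), params.n_reps))
        trials.extend(
            simulate_session(schedule, params, label, experiment, site, rng=rng)
        )
    return trials
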