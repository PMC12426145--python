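"""Response classification and the false-start screen.

Each response of a trial receives exactly one label:

``omission``       the omit token (or, for rate summaries, an unattempted
                   trailing position);
``intrusion``      a symbol not in the trial's input list;
``repeat``         a symbol already emitted earlier in this trial's output;
``correct``        the input-list item of the current output position;
``anticipation``   a list item reported earlier than its input position;
``postponement``   a list item reported later than its input position.

The labels are assigned in that order of precedence, so a re-report of an
item that happens to land on its correct position counts as a repeat (an
item is credited at most once per trial).

Postanticipation eligibility marks the trials that feed the
postanticipation lag-CRP: every response before the first anticipation must
be correct, the anticipation must not be a false start, and at least one
response must follow it.  Only that first following response is scored.

The false-start screen removes motor artifacts: for each participant, an
anticipation in the *first* output position whose RT is strictly shorter
than the 75th percentile of that participant's second-response RTs is
flagged and its trial withdrawn from postanticipation scoring.  First
responses are ordinarily much slower than second responses, so a fast first
anticipation is more plausibly a mistimed keystroke than a memory error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_recall import OMIT, Trial

__all__ = [
    "LABELS",
    "ScoredTrial",
    "score_trial",
    "detect_false_starts",
    "score_participant",
    "score_dataset",
    "summarize_errors",
]

logger = logging.getLogger(__name__)

LABELS = ("correct", "anticipation", "postponement", "repeat", "intrusion", "omission")

#: Second-response RT sample below which the percentile cutoff is not
#: estimated and no false starts are flagged.
MIN_SECOND_RESPONSES = 4


@dataclass(frozen=True)
class ScoredTrial:
    trial: Trial
    labels: tuple[str, ...]
    prefix_correct_len: int
    first_error_is_anticipation: bool
    false_start: bool
    pa_eligible: bool
    pa_anticipation_index: int | None  # output position of the first anticipation
    pa_response_index: int | None      # output position of the scored pa response


def score_trial(trial: Trial) -> ScoredTrial:
    """Label every response and compute postanticipation eligibility.

    ``false_start`` is initially False; :func:`detect_false_starts` sets it
    from the participant-level RT distribution.
    """
    n = len(trial.input_list)
    labels: list[str] = []
    emitted: set[str] = set()
    for r in trial.responses:
        if not 1 <= r.output_position <= n:
            raise ValueError(
                f"output position {r.output_position} outside 1..{n}"
            )
        if r.symbol == OMIT:
            labels.append("omission")
        elif r.symbol not in trial.input_list:
            labels.append("intrusion")
        elif r.symbol in emitted:
            labels.append("repeat")
        else:
            inpos = trial.input_list.index(r.symbol) + 1
            if inpos == r.output_position:
                labels.append("correct")
            elif inpos > r.output_position:
                labels.append("anticipation")
            else:
                labels.append("postponement")
        if r.symbol != OMIT:
            emitted.add(r.symbol)

    prefix = 0
    while prefix < len(labels) and labels[prefix] == "correct":
        prefix += 1
    first_error_is_anticipation = (
        prefix < len(labels) and labels[prefix] == "anticipation"
    )

    pa_eligible = False
    pa_anticipation_index = None
    pa_response_index = None
    if "anticipation" in labels:
        i = labels.index("anticipation")
        # Every response before the first anticipation must be correct, and
        # a response must actually follow it.
        if i == prefix and i + 1 < len(trial.responses):
            pa_eligible = True
            pa_anticipation_index = trial.responses[i].output_position
            pa_response_index = trial.responses[i + 1].output_position

    return ScoredTrial(
        trial=trial,
        labels=tuple(labels),
        prefix_correct_len=prefix,
        first_error_is_anticipation=first_error_is_anticipation,
        false_start=False,
        pa_eligible=pa_eligible,
        pa_anticipation_index=pa_anticipation_index,
        pa_response_index=pa_response_index,
    )


def detect_false_starts(scored: Sequence[ScoredTrial]) -> list[ScoredTrial]:
    """Apply the per-participant false-start screen.

    The cutoff is the 75th percentile (linear interpolation between closest
    ranks) of all second-response RTs of the participant; a first-position
    anticipation with RT strictly below it is flagged and made ineligible
    for postanticipation scoring.  With fewer than ``MIN_SECOND_RESPONSES``
    second-response RTs the cutoff is not estimated and nothing is flagged.
    """
    participants = {st.trial.participant for st in scored}
    if len(participants) > 1:
        raise ValueError(
            f"detect_false_starts expects one participant, got {sorted(participants)}"
        )
    second_rts = [
        r.rt_ms
        for st in scored
        for r in st.trial.responses
        if r.output_position == 2 and r.rt_ms is not None
    ]
    if len(second_rts) < MIN_SECOND_RESPONSES:
        logger.warning(
            "participant %s: only %d second-response RTs; false-start cutoff "
            "not estimated, no trials flagged",
            next(iter(participants), "?"), len(second_rts),
        )
        return list(scored)
    cutoff = float(np.percentile(second_rts, 75))
    out = []
    for st in scored:
        flag = (
            len(st.labels) >= 1
            and st.trial.responses[0].output_position == 1
            and st.labels[0] == "anticipation"
            and st.trial.responses[0].rt_ms is not None
            and st.trial.responses[0].rt_ms < cutoff
        )
        if flag:
            st = replace(st, false_start=True, pa_eligible=False,
                         pa_anticipation_index=None, pa_response_index=None)
        out.append(st)
    return out


def score_participant(trials: Sequence[Trial]) -> list[ScoredTrial]:
    """Score one participant's trials and apply the false-start screen."""
    return detect_false_starts([score_trial(t) for t in trials])


def score_dataset(trials: Iterable[Trial]) -> list[ScoredTrial]:
    """Score a multi-participant dataset, screening per participant."""
    by_participant: dict[str, list[Trial]] = {}
    for t in trials:
        by_participant.setdefault(t.participant, []).append(t)
    out: list[ScoredTrial] = []
    for p in by_participant:
        out.extend(score_participant(by_participant[p]))
    return out


def summarize_errors(scored: Iterable[ScoredTrial]) -> pd.DataFrame:
    """Response-level correct/order-error/item-error rates.

    One row per participant x list type.  Every trial contributes a
    denominator equal to its list length; unattempted trailing positions
    count as omissions.  Order errors are anticipations, postponements and
    repeats of list items; item errors are intrusions, omissions and
    repeats of extra-list symbols.
    """
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for st in scored:
        key = (st.trial.participant, st.trial.list_type)
        acc = rows.setdefault(key, {"correct": 0, "order": 0, "item": 0, "total": 0})
        n = len(st.trial.input_list)
        acc["total"] += n
        for r, lab in zip(st.trial.responses, st.labels):
            if lab == "correct":
                acc["correct"] += 1
            elif lab in ("anticipation", "postponement"):
                acc["order"] += 1
            elif lab == "repeat":
                if r.symbol in st.trial.input_list:
                    acc["order"] += 1
                else:
                    acc["item"] += 1
            else:  # intrusion, omission
                acc["item"] += 1
        acc["item"] += n - len(st.trial.responses)  # unattempted tail
    records = [
        {
            "participant": p,
            "list_type": lt,
            "correct_rate": acc["correct"] / acc["total"],
            "order_error_rate": acc["order"] / acc["total"],
            "item_error_rate": acc["item"] / acc["total"],
        }
        for (p, lt), acc in sorted(rows.items())
    ]
    return pd.DataFrame(records)
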