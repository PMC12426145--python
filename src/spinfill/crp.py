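"""Lag-conditional response probability (lag-CRP) and derived summaries.

The *lag* of a recall transition is the signed difference between the input
positions of consecutively recalled items.  For input ABCDEF and output
ABDC the transitions are A->B (+1), B->D (+2) and D->C (-1).  The lag-CRP
at lag L divides the number of transitions of lag L by the number of
opportunities for such a transition — an opportunity exists whenever the
target position inpos(prev) + L lies inside the list — which removes the
structural advantage of short lags.

Two conditioning modes are computed:

* **overall**: every transition between consecutively emitted list items
  counts; lags run -5..+5 for six-item lists.
* **postanticipation**: only the first response after an anticipation, on
  trials whose responses before the anticipation were all correct and that
  survived the false-start screen; lags run -5..+4 (the anticipated item
  can never occupy input position 1).  At this conditioning, a -1 lag is a
  *fill-in* (going back for the skipped item) and +1 an *infill*
  (continuing forward); their ratio P(fill-in)/P(infill) is the error
  ratio, and a ratio above 1 is the fill-in tendency.  A -5 lag is the
  wrap transition from the final to the first item, which in spun lists
  follows the trained cyclic order.

Two repeat policies are supported.  Under ``scored``, transitions into
already-recalled items count like any other.  Under ``excluded``, a repeat
response increments no numerator and every denominator skips the lags that
would land on an already-recalled item (lags that cannot produce a
non-repeat response are not opportunities).  Because a postanticipation -1
or +1 transition can
never be a repeat (the prefix was correct), fill-in and infill
probabilities are identical under both policies; distal lags differ.

Numerators and denominators are pooled within participant x list type
before dividing (ratio of sums); one lag-CRP per participant x list type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import ScoredTrial
from .synthetic_recall import OMIT

__all__ = [
    "LagCRPTable",
    "ErrorRatioSummary",
    "transition_lags",
    "overall_lag_crp",
    "postanticipation_lag_crp",
    "crp_by_participant",
    "participant_crp_frame",
    "error_ratio",
    "error_ratio_summary",
    "position_counts",
    "group_position_counts",
    "aggregate_crp",
]

logger = logging.getLogger(__name__)

REPEAT_POLICIES = ("scored", "excluded")


def _lag_range(n_items: int, mode: str) -> tuple[int, int]:
    if mode == "overall":
        return -(n_items - 1), n_items - 1
    return -(n_items - 1), n_items - 2


@dataclass
class LagCRPTable:
    """Per participant x list type lag-CRP counts for one mode and policy.

    ``crp(lag)`` is numerator/denominator, or NaN when the denominator is
    zero (no opportunity observed).
    """

    participant: str
    list_type: str
    mode: str                    # "overall" | "postanticipation"
    repeat_policy: str           # "scored" | "excluded"
    lag_min: int
    lag_max: int
    numerator: dict[int, int] = field(default_factory=dict)
    denominator: dict[int, int] = field(default_factory=dict)
    experiment: str = "sim"
    site: str = "sim"

    @property
    def lags(self) -> list[int]:
        return [l for l in range(self.lag_min, self.lag_max + 1) if l != 0]

    def crp(self, lag: int) -> float:
        den = self.denominator.get(lag, 0)
        if den == 0:
            return float("nan")
        return self.numerator.get(lag, 0) / den

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "list_type": self.list_type,
                "experiment": self.experiment,
                "site": self.site,
                "mode": self.mode,
                "repeat_policy": self.repeat_policy,
                "lag": self.lags,
                "numerator": [self.numerator.get(l, 0) for l in self.lags],
                "denominator": [self.denominator.get(l, 0) for l in self.lags],
                "crp": [self.crp(l) for l in self.lags],
            }
        )


@dataclass(frozen=True)
class ErrorRatioSummary:
    """P(fill-in), P(infill) and their ratio at a stated aggregation level."""

    p_fill_in: float
    p_infill: float
    error_ratio: float  # NaN when undefined (p_infill 0 or missing inputs)
    aggregation_level: str
    list_type: str | None = None


def _is_item(symbol: str, input_list: Sequence[str]) -> bool:
    return symbol != OMIT and symbol in input_list


def transition_lags(scored: ScoredTrial) -> list[int]:
    """Signed lags of all transitions between consecutively emitted list items.

    A transition exists only between *consecutive* responses; an intervening
    intrusion or omission voids both adjacent transitions.  Immediate
    same-item repeats yield lag 0, which the CRP tables ignore.
    """
    inp = scored.trial.input_list
    lags = []
    for prev, cur in zip(scored.trial.responses, scored.trial.responses[1:]):
        if _is_item(prev.symbol, inp) and _is_item(cur.symbol, inp):
            lags.append(inp.index(cur.symbol) - inp.index(prev.symbol))
    return lags


def _check_policy(repeat_policy: str) -> None:
    if repeat_policy not in REPEAT_POLICIES:
        raise ValueError(f"repeat_policy must be one of {REPEAT_POLICIES}")


def _counting_meta(trials: Sequence[ScoredTrial]) -> dict:
    if not trials:
        return {"participant": "", "list_type": "", "experiment": "", "site": ""}
    t = trials[0].trial
    for st in trials:
        if (st.trial.participant, st.trial.list_type) != (t.participant, t.list_type):
            raise ValueError(
                "lag-CRP tables are computed per participant x list type; "
                "got mixed trials"
            )
    return {
        "participant": t.participant,
        "list_type": t.list_type,
        "experiment": t.experiment,
        "site": t.site,
    }


def overall_lag_crp(
    trials: Sequence[ScoredTrial], repeat_policy: str = "scored"
) -> LagCRPTable:
    """Overall lag-CRP over all transitions between emitted list items.

    For every transition the numerator of the observed lag is incremented
    and the denominator of every lag whose target position exists is
    incremented.  Under ``excluded``, denominators skip lags whose target
    item was already recalled before the current response, and a repeat
    response increments no numerator.
    """
    _check_policy(repeat_policy)
    meta = _counting_meta(trials)
    n_items = len(trials[0].trial.input_list) if trials else 6
    lag_min, lag_max = _lag_range(n_items, "overall")
    table = LagCRPTable(
        mode="overall", repeat_policy=repeat_policy,
        lag_min=lag_min, lag_max=lag_max, **meta,
    )
    for st in trials:
        inp = st.trial.input_list
        recalled_before: set[str] = set()
        for prev, cur in zip(st.trial.responses, st.trial.responses[1:]):
            if _is_item(prev.symbol, inp):
                recalled_before.add(prev.symbol)
            if not (_is_item(prev.symbol, inp) and _is_item(cur.symbol, inp)):
                continue
            is_repeat = cur.symbol in recalled_before
            prev_pos = inp.index(prev.symbol) + 1
            for lag in range(lag_min, lag_max + 1):
                if lag == 0:
                    continue
                target = prev_pos + lag
                if not 1 <= target <= n_items:
                    continue
                if (
                    repeat_policy == "excluded"
                    and inp[target - 1] in recalled_before
                ):
                    continue
                table.denominator[lag] = table.denominator.get(lag, 0) + 1
            if repeat_policy == "excluded" and is_repeat:
                continue  # a repeat response never increments a numerator
            lag = (inp.index(cur.symbol) + 1) - prev_pos
            if lag != 0 and lag_min <= lag <= lag_max:
                table.numerator[lag] = table.numerator.get(lag, 0) + 1
    return table


def postanticipation_lag_crp(
    trials: Sequence[ScoredTrial], repeat_policy: str = "scored"
) -> LagCRPTable:
    """Postanticipation lag-CRP: one scored response per eligible trial.

    Only false-start-screened, eligible trials contribute (all responses
    before the first anticipation correct, at least one response after it).
    The scored response is the first after the anticipation and its lag is
    measured from the *anticipated item's* input position.  A scored
    response that is an intrusion or omission has no lag and the trial
    contributes nothing.
    """
    _check_policy(repeat_policy)
    meta = _counting_meta(trials)
    n_items = len(trials[0].trial.input_list) if trials else 6
    lag_min, lag_max = _lag_range(n_items, "postanticipation")
    table = LagCRPTable(
        mode="postanticipation", repeat_policy=repeat_policy,
        lag_min=lag_min, lag_max=lag_max, **meta,
    )
    for st in trials:
        if not st.pa_eligible:
            continue
        inp = st.trial.input_list
        idx = {r.output_position: i for i, r in enumerate(st.trial.responses)}
        a_i = idx[st.pa_anticipation_index]
        r_i = idx[st.pa_response_index]
        anticipated = st.trial.responses[a_i].symbol
        response = st.trial.responses[r_i].symbol
        if not _is_item(response, inp):
            continue
        recalled_before = {
            r.symbol
            for r in st.trial.responses[: a_i + 1]
            if _is_item(r.symbol, inp)
        }
        anti_pos = inp.index(anticipated) + 1
        for lag in range(lag_min, lag_max + 1):
            if lag == 0:
                continue
            target = anti_pos + lag
            if not 1 <= target <= n_items:
                continue
            if repeat_policy == "excluded" and inp[target - 1] in recalled_before:
                continue
            table.denominator[lag] = table.denominator.get(lag, 0) + 1
        if repeat_policy == "excluded" and response in recalled_before:
            continue  # repeat response: opportunities counted, no numerator
        lag = (inp.index(response) + 1) - anti_pos
        if lag != 0 and lag_min <= lag <= lag_max:
            table.numerator[lag] = table.numerator.get(lag, 0) + 1
    return table


def crp_by_participant(
    scored: Iterable[ScoredTrial],
    mode: str = "postanticipation",
    repeat_policy: str = "scored",
) -> list[LagCRPTable]:
    """One lag-CRP table per participant x list type over a dataset."""
    fn = {"overall": overall_lag_crp, "postanticipation": postanticipation_lag_crp}
    if mode not in fn:
        raise ValueError(f"mode must be one of {tuple(fn)}")
    groups: dict[tuple[str, str], list[ScoredTrial]] = {}
    for st in scored:
        groups.setdefault((st.trial.participant, st.trial.list_type), []).append(st)
    return [fn[mode](groups[k], repeat_policy) for k in sorted(groups)]


def participant_crp_frame(tables: Sequence[LagCRPTable]) -> pd.DataFrame:
    """Tidy frame of participant-level CRPs (one row per participant,
    list type and lag)."""
    if not tables:
        return pd.DataFrame(
            columns=["participant", "list_type", "experiment", "site",
                     "mode", "repeat_policy", "lag", "numerator",
                     "denominator", "crp"]
        )
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def error_ratio(table: LagCRPTable) -> ErrorRatioSummary:
    """Fill-in / infill probabilities and their ratio for one table."""
    if table.mode != "postanticipation":
        raise ValueError("error ratios are defined on postanticipation tables")
    p_fill = table.crp(-1)
    p_infill = table.crp(+1)
    if np.isnan(p_fill) or np.isnan(p_infill) or p_infill == 0:
        if p_infill == 0:
            logger.warning(
                "participant %s %s: P(infill)=0, error ratio undefined",
                table.participant, table.list_type,
            )
        ratio = float("nan")
    else:
        ratio = p_fill / p_infill
    return ErrorRatioSummary(p_fill, p_infill, ratio, "participant", table.list_type)


def error_ratio_summary(
    tables: Sequence[LagCRPTable], level: str = "group"
) -> pd.DataFrame:
    """Fill-in/infill rates and error ratios at a stated aggregation level.

    ``group`` (and ``experiment``, which additionally splits by experiment
    label) computes the ratio of the *mean* probabilities over participants
    with a defined value; ``participant`` returns per-participant ratios.
    """
    if level not in ("participant", "experiment", "group"):
        raise ValueError(f"unknown aggregation level {level!r}")
    logger.info("error ratios aggregated at level=%s", level)
    frame = participant_crp_frame(tables)
    frame = frame[frame["lag"].isin([-1, 1])]
    wide = frame.pivot_table(
        index=["participant", "list_type", "experiment"],
        columns="lag", values="crp",
    ).rename(columns={-1: "p_fill_in", 1: "p_infill"}).rename_axis(
        columns=None
    ).reset_index()
    for col in ("p_fill_in", "p_infill"):
        if col not in wide:
            wide[col] = float("nan")
    if level == "participant":
        wide["error_ratio"] = np.where(
            wide["p_infill"] > 0, wide["p_fill_in"] / wide["p_infill"], np.nan
        )
        return wide[["participant", "list_type", "experiment",
                     "p_fill_in", "p_infill", "error_ratio"]]
    keys = ["list_type"] if level == "group" else ["experiment", "list_type"]
    agg = wide.groupby(keys, as_index=False)[["p_fill_in", "p_infill"]].mean()
    agg["error_ratio"] = np.where(
        agg["p_infill"] > 0, agg["p_fill_in"] / agg["p_infill"], np.nan
    )
    return agg


def position_counts(scored: Iterable[ScoredTrial]) -> pd.DataFrame:
    """Fill-in and infill counts by the anticipation's output position.

    For each postanticipation-scored response, a -1 lag increments the
    fill-in count and a +1 lag the infill count at the serial (output)
    position where the anticipation occurred.  Totals per participant x
    list type; average over participants with :func:`group_position_counts`.
    """
    acc: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    n_items = 6
    for st in scored:
        n_items = len(st.trial.input_list)
        key = (st.trial.participant, st.trial.list_type)
        entry = acc.setdefault(
            key,
            {"fill_in": np.zeros(n_items, dtype=int),
             "infill": np.zeros(n_items, dtype=int)},
        )
        if not st.pa_eligible:
            continue
        inp = st.trial.input_list
        idx = {r.output_position: i for i, r in enumerate(st.trial.responses)}
        anticipated = st.trial.responses[idx[st.pa_anticipation_index]].symbol
        response = st.trial.responses[idx[st.pa_response_index]].symbol
        if not _is_item(response, inp):
            continue
        lag = inp.index(response) - inp.index(anticipated)
        if lag == -1:
            entry["fill_in"][st.pa_anticipation_index - 1] += 1
        elif lag == +1:
            entry["infill"][st.pa_anticipation_index - 1] += 1
    rows = [
        {
            "participant": p,
            "list_type": lt,
            "position": pos,
            "fill_in_count": int(entry["fill_in"][pos - 1]),
            "infill_count": int(entry["infill"][pos - 1]),
        }
        for (p, lt), entry in sorted(acc.items())
        for pos in range(1, len(entry["fill_in"]) + 1)
    ]
    return pd.DataFrame(rows)


def group_position_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Average per-participant fill-in/infill counts by serial position."""
    return counts.groupby(["list_type", "position"], as_index=False)[
        ["fill_in_count", "infill_count"]
    ].mean()


def aggregate_crp(tables: Sequence[LagCRPTable]) -> pd.DataFrame:
    """Group curve: per-lag mean and SEM over participants with data.

    Participants without a defined CRP at a lag are excluded at that lag
    only.  All tables must share mode, repeat policy and list type.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    keys = {(t.mode, t.repeat_policy, t.list_type) for t in tables}
    if len(keys) > 1:
        raise ValueError(f"tables mix mode/policy/list_type: {sorted(keys)}")
    mode, policy, list_type = next(iter(keys))
    rows = []
    for lag in tables[0].lags:
        values = np.array([t.crp(lag) for t in tables], dtype=float)
        values = values[~np.isnan(values)]
        n = len(values)
        rows.append(
            {
                "list_type": list_type,
                "mode": mode,
                "repeat_policy": policy,
                "lag": lag,
                "mean_crp": values.mean() if n else float("nan"),
                "sem_crp": (
                    values.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
                ),
                "n_participants": n,
            }
        )
    return pd.DataFrame(rows)
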