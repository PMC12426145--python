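"""Trial CSV dialect and table writers.

The long trial format has one row per emitted response:

participant, site, experiment, list_type, list_id, repetition, trial_index,
input_list (6 characters in presentation order), output_position (1..6),
response (single character, empty for an omission), rt_ms (positive, empty
for an omission).

Files are UTF-8 with a header row.  Malformed rows are reported with their
line numbers; duplicated (participant, trial_index, output_position) keys
and unknown list types are hard errors.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .list_design import LIST_TYPES
from .scoring import ScoredTrial
from .synthetic_recall import OMIT, Response, Trial

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "scored_to_frame",
    "write_scored",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant", "site", "experiment", "list_type", "list_id",
    "repetition", "trial_index", "input_list", "output_position",
    "response", "rt_ms",
]


class TrialFormatError(ValueError):
    pass


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for r in t.responses:
            rows.append(
                {
                    "participant": t.participant,
                    "site": t.site,
                    "experiment": t.experiment,
                    "list_type": t.list_type,
                    "list_id": t.list_id,
                    "repetition": t.repetition,
                    "trial_index": t.trial_index,
                    "input_list": "".join(t.input_list),
                    "output_position": r.output_position,
                    "response": r.symbol,
                    "rt_ms": r.rt_ms if r.rt_ms is not None else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: Iterable[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def _row_error(line: int, message: str) -> TrialFormatError:
    return TrialFormatError(f"line {line}: {message}")


def frame_to_trials(frame: pd.DataFrame, source: str = "<frame>") -> list[Trial]:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialFormatError(f"{source}: missing columns {missing}")
    frame = frame.copy()
    # +2: header row plus 1-based numbering of the first data row.
    frame["_line"] = np.arange(2, len(frame) + 2)
    dup = frame.duplicated(
        subset=["participant", "trial_index", "output_position"], keep=False
    )
    if dup.any():
        lines = frame.loc[dup, "_line"].tolist()[:5]
        raise TrialFormatError(
            f"{source}: duplicated (participant, trial_index, output_position) "
            f"at lines {lines}"
        )
    bad_type = ~frame["list_type"].isin(LIST_TYPES)
    if bad_type.any():
        row = frame[bad_type].iloc[0]
        raise _row_error(
            int(row["_line"]),
            f"unknown list_type {row['list_type']!r}",
        )
    trials = []
    keys = ["participant", "trial_index"]
    for (participant, trial_index), grp in frame.groupby(keys, sort=True):
        grp = grp.sort_values("output_position")
        first = grp.iloc[0]
        input_list = tuple(str(first["input_list"]))
        if len(input_list) != 6 or len(set(input_list)) != 6:
            raise _row_error(
                int(first["_line"]),
                f"input_list must be 6 unique characters, got "
                f"{first['input_list']!r}",
            )
        responses = []
        for _, row in grp.iterrows():
            sym = row["response"]
            sym = OMIT if pd.isna(sym) or sym == "" else str(sym)
            rt = None if pd.isna(row["rt_ms"]) else float(row["rt_ms"])
            if sym != OMIT and len(sym) != 1:
                raise _row_error(
                    int(row["_line"]), f"response must be one character, got {sym!r}"
                )
            if rt is not None and rt <= 0:
                raise _row_error(int(row["_line"]), f"rt_ms must be positive, got {rt}")
            try:
                responses.append(Response(int(row["output_position"]), sym, rt))
            except ValueError as err:
                raise _row_error(int(row["_line"]), str(err)) from err
        try:
            trials.append(
                Trial(
                    participant=str(participant),
                    site=str(first["site"]),
                    experiment=str(first["experiment"]),
                    list_type=str(first["list_type"]),
                    list_id=str(first["list_id"]),
                    repetition=int(first["repetition"]),
                    trial_index=int(trial_index),
                    input_list=input_list,
                    responses=tuple(responses),
                )
            )
        except ValueError as err:
            raise _row_error(int(first["_line"]), str(err)) from err
    return trials


def read_trials(path) -> list[Trial]:
    frame = pd.read_csv(path, dtype={"input_list": str, "response": str},
                        keep_default_na=True, float_precision="round_trip")
    return frame_to_trials(frame, source=str(path))


def scored_to_frame(scored: Iterable[ScoredTrial]) -> pd.DataFrame:
    """Long scored-trials table: trial rows plus label and screening columns."""
    rows = []
    for st in scored:
        t = st.trial
        for r, lab in zip(t.responses, st.labels):
            rows.append(
                {
                    "participant": t.participant,
                    "site": t.site,
                    "experiment": t.experiment,
                    "list_type": t.list_type,
                    "list_id": t.list_id,
                    "repetition": t.repetition,
                    "trial_index": t.trial_index,
                    "input_list": "".join(t.input_list),
                    "output_position": r.output_position,
                    "response": r.symbol,
                    "rt_ms": r.rt_ms if r.rt_ms is not None else np.nan,
                    "label": lab,
                    "false_start": st.false_start,
                    "pa_eligible": st.pa_eligible,
                }
            )
    return pd.DataFrame(rows)


def write_scored(scored: Iterable[ScoredTrial], path) -> None:
    scored_to_frame(scored).to_csv(path, index=False)
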