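from __future__ import annotations

import pytest

from spinfill.synthetic_recall import Response, Trial


def make_trial(
    output: str,
    input_list: str = "ABCDEF",
    rts: list[float] | None = None,
    participant: str = "p1",
    list_type: str = "scrambled",
    trial_index: int = 1,
) -> Trial:
    """Build a trial from compact strings, e.g. output 'ABDC'."""
    if rts is None:
        rts = [900.0] + [400.0] * (len(output) - 1)
    responses = tuple(
        Response(i + 1, sym, rt) for i, (sym, rt) in enumerate(zip(output, rts))
    )
    return Trial(
        participant=participant,
        list_type=list_type,
        input_list=tuple(input_list),
        responses=responses,
        trial_index=trial_index,
    )


@pytest.fixture
def worked_example():
    """The canonical ABCDEF -> ABDC trial (anticipation then fill-in)."""
    return make_trial("ABDC")
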