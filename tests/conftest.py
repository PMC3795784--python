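import numpy as np
import pytest

from survsig import ExpressionMatrix, SurvivalData


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        probe_ids=["p1", "p2", "p3"],
        sample_ids=["A", "B", "C", "D"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [0.5, -1.25, 2.75, 0.0],
                [10.0, 11.0, 9.5, 12.25],
            ]
        ),
    )


@pytest.fixture
def tiny_surv():
    return SurvivalData(
        sample_ids=["A", "B", "C", "D"],
        time=np.array([5.0, 10.0, 2.0, 7.0]),
        event=np.array([1, 0, 1, 1]),
    )


def hand_logrank(time, event, group1):
    """Independent O-E/V evaluation over explicit risk sets (2 groups).

    Deliberately a plain double loop over distinct event times: this is the
    spreadsheet-style oracle, kept free of any package internals.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group1 = np.asarray(group1, bool)
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & group1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return None
    return (O - E) ** 2 / V


@pytest.fixture
def logrank_oracle():
    return hand_logrank
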