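from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from groomtrade import datasets
from groomtrade.matrices import symmetrize
from groomtrade.obslog import LOG_COLUMNS, build_event_log


def make_log(rows, sample_length_s=900.0):
    """Build a validated EventLog from terse row tuples.

    Rows are ``(event_type, actor, recipient, start, duration)`` with
    optional leading ``period`` and are assigned to the actor's focal
    sample by default.
    """
    full = []
    for row in rows:
        if len(row) == 6:
            period, etype, actor, recipient, start, dur = row
        else:
            etype, actor, recipient, start, dur = row
            period = "one"
        full.append(
            {
                "period_id": period,
                "focal_id": actor,
                "sample_start_s": (start // sample_length_s) * sample_length_s,
                "event_type": etype,
                "actor_id": actor,
                "recipient_id": recipient,
                "start_s": start,
                "duration_s": dur,
            }
        )
    return build_event_log(pd.DataFrame(full, columns=list(LOG_COLUMNS)))


@pytest.fixture
def period_one_binary():
    return datasets.partner_matrix("one")


@pytest.fixture
def period_two_binary():
    return datasets.partner_matrix("two")


@pytest.fixture
def period_one_network(period_one_binary):
    return symmetrize(period_one_binary)


@pytest.fixture
def period_two_network(period_two_binary):
    return symmetrize(period_two_binary)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_directed_matrix(rng, n, labels=None, integers=False, zero_frac=0.0):
    if integers:
        x = rng.integers(0, 6, size=(n, n)).astype(float)
    else:
        x = rng.uniform(0, 100, size=(n, n))
    if zero_frac:
        x[rng.random((n, n)) < zero_frac] = 0.0
    np.fill_diagonal(x, 0.0)
    labels = labels or [f"a{i}" for i in range(n)]
    return pd.DataFrame(x, index=labels, columns=labels)
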