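"""Shared fixtures: reference weight sets and instance streams."""

import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the five benchmark weight sets plus the I = 2G boundary and two sets with
#: unusual geometry (mid below zero / wide zone C)
TABLE_WEIGHTS = [(0, -1, -1), (2, -3, -5), (3, -4, -6), (4, -5, -9), (4, -7, -11)]
EXTRA_WEIGHTS = [(1, -2, -1), (5, -1, -2), (2, -5, -3), (3, -8, -4)]
ALL_WEIGHTS = TABLE_WEIGHTS + EXTRA_WEIGHTS


@pytest.fixture(scope="session")
def table_weights():
    return list(TABLE_WEIGHTS)


@pytest.fixture(scope="session")
def all_weights():
    return list(ALL_WEIGHTS)


@pytest.fixture()
def rng():
    return random.Random(20240517)


def all_modes():
    from bitalign import AlignmentMode

    return [
        AlignmentMode(fr, fc, site)
        for fr in ("gap", "free")
        for fc in ("gap", "free")
        for site in ("last_cell", "best_in_last_row", "best_in_last_column")
    ]
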