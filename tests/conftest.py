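"""Shared fixtures: rendered phantoms and pipeline runs reused across tests.

The heavier artifacts (multiscale vesselness maps, full pipeline runs,
the double suite execution) are session-scoped so each is computed once.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from ctaseg import multiscale_vesselness, segment_pipeline
from ctaseg.cli import run_suite
from ctaseg.phantoms import get_case, render

logging.getLogger("ctaseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def aorta_run():
    """Aorta-analogue phantom at SNR 10, segmented end to end."""
    case = get_case("aorta_branches_snr10")
    volume, truth = render(case.spec)
    result = segment_pipeline(volume, params=case.params, grow=case.grow,
                              seed=case.seed, seeding=case.seeding)
    return {"case": case, "volume": volume, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def hollow_run():
    """Hollow thick-tube phantom at SNR 10, segmented end to end."""
    case = get_case("hollow_tube_snr10")
    volume, truth = render(case.spec)
    result = segment_pipeline(volume, params=case.params, grow=case.grow,
                              seed=case.seed, seeding=case.seeding)
    return {"case": case, "volume": volume, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def two_tube_vesselness():
    """Multiscale vesselness of the two-radius tube phantom at SNR 10."""
    case = get_case("two_radius_tubes_snr10")
    volume, truth = render(case.spec)
    vmap = multiscale_vesselness(volume, case.params)
    return {"case": case, "volume": volume, "truth": truth, "vmap": vmap}


@pytest.fixture(scope="session")
def discrimination_vesselness():
    """Multiscale vesselness of the tube+blob+plate phantom at SNR 10."""
    case = get_case("tube_blob_plate_snr10")
    volume, truth = render(case.spec)
    vmap = multiscale_vesselness(volume, case.params)
    return {"case": case, "volume": volume, "truth": truth, "vmap": vmap}


@pytest.fixture(scope="session")
def suite_runs(tmp_path_factory):
    """The full standard suite executed twice into separate directories."""
    first = tmp_path_factory.mktemp("suite_first")
    second = tmp_path_factory.mktemp("suite_second")
    table_first = run_suite(str(first))
    table_second = run_suite(str(second))
    return {"dirs": (first, second), "tables": (table_first, table_second)}
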