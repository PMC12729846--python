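"""Shared fixtures: the calibrated synthetic log and derived artifacts."""

from __future__ import annotations

import pytest

from pm2pim.conformance import align_log, classify_deviations
from pm2pim.normative_model import default_model
from pm2pim.pim import run_scenario, scenario_defaults
from pm2pim.synthetic_log import DEFAULT_SEED, GeneratorConfig, generate_log


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_log(default_config):
    return generate_log(default_config, DEFAULT_SEED)


@pytest.fixture(scope="session")
def alignments(default_log, model):
    return align_log(default_log, model)


@pytest.fixture(scope="session")
def records(alignments, default_log, model):
    return classify_deviations(alignments, default_log, model)


@pytest.fixture(scope="session")
def scenario_results(default_log, records, model):
    current, full = scenario_defaults()
    return {
        "current": run_scenario(default_log, records, current, model),
        "full": run_scenario(default_log, records, full, model),
    }
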