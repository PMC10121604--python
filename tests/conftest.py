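import numpy as np
import pytest

from nigracircuit import (SimConfig, build_circuit, classify_session,
                          simulate_ostim_session, simulate_task_session)
from nigracircuit.synth import default_layouts


@pytest.fixture(scope="session")
def layouts():
    return default_layouts()


@pytest.fixture(scope="session")
def small_config():
    """Cheap config for structural tests (few units, short session)."""
    return SimConfig(seed=1, n_units={"amy": 2, "gaba": 2, "da": 2},
                     trials_per_condition=12, n_stim_events=60)


@pytest.fixture(scope="session")
def task_session(layouts):
    """Default-condition task session, shared across tests (seed 1)."""
    cfg = SimConfig(seed=1)
    graph = build_circuit(cfg, layouts)
    trains, events, manifest = simulate_task_session(cfg, graph, layouts)
    return cfg, graph, trains, events, manifest


@pytest.fixture(scope="session")
def task_classification(task_session):
    _, _, trains, events, _ = task_session
    results, errors = classify_session(trains, events)
    assert not errors
    return results


@pytest.fixture(scope="session")
def ostim_session(task_session, layouts):
    """Nigra-terminal stimulation session for the same circuit (seed 1)."""
    cfg, graph, _, _, _ = task_session
    trains, events, manifest = simulate_ostim_session(cfg, graph, layouts,
                                                      "nigra_terminals")
    return trains, events, manifest


def true_class_of(manifest):
    return {uid: info["cls"] for uid, info in manifest["units"].items()}
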