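"""Shared fixtures: frozen default parameters and protocol runs.

The full five-phase runs are session-scoped — they are deterministic and
several test modules slice the same traces.
"""

import pytest

import cardioloop as cl


@pytest.fixture(scope="session")
def default_params():
    return cl.load_params()


@pytest.fixture(scope="session")
def full_run_a():
    """Complete 550 s five-phase protocol, syncope variant (a)."""
    return cl.run(cl.builtin_scenario("paper_full_a"))


@pytest.fixture(scope="session")
def full_runs_all(full_run_a):
    """All four syncope variants of the five-phase protocol."""
    runs = {"a": full_run_a}
    runs.update({v: cl.run(cl.builtin_scenario(f"paper_full_{v}"))
                 for v in "bcd"})
    return runs


@pytest.fixture(scope="session")
def baseline_run():
    """Sedentary normal heart, 70.5 s (the settle-in plus baseline phase)."""
    return cl.run(cl.builtin_scenario("baseline"))


@pytest.fixture(scope="session")
def phase_beats(full_run_a):
    """Per-phase beat metrics of the five-phase protocol."""
    from cardioloop.beat import phase_metrics

    return phase_metrics(full_run_a)
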