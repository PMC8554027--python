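import pytest

from alleleforge.design import DesignResult, design_task
from alleleforge.fixtures import Fixture, FixtureSpec, build_fixture
from alleleforge.params import DesignParameters


@pytest.fixture(scope="session")
def fx() -> Fixture:
    """Small mixed-kind fixture shared by read-only tests."""
    return build_fixture(FixtureSpec(
        seed=11, genome_length=60_000, n_tasks=9,
        task_kinds=("substitution", "insertion", "deletion")))


@pytest.fixture(scope="session")
def designed(fx):
    """Design every fixture task once; (successes, failures)."""
    results, failures = [], []
    for task in fx.tasks:
        out = design_task(task, fx.genome, fx.vector)
        (results if isinstance(out, DesignResult) else failures).append(out)
    assert results, "fixture produced no successful design"
    return results, failures


@pytest.fixture(scope="session")
def one_result(designed) -> DesignResult:
    return designed[0][0]


@pytest.fixture(scope="session")
def by_kind(fx, designed):
    """kind -> (task, successful DesignResult); kinds without a designable
    fixture task are absent (no admissible anchored primer there)."""
    tasks = {t.id: t for t in fx.tasks}
    out = {}
    for res in designed[0]:
        task = tasks[res.task_id]
        out.setdefault(task.kind, (task, res))
    return out


@pytest.fixture(scope="session")
def default_params() -> DesignParameters:
    return DesignParameters()
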