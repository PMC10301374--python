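import pytest

from pkstereo.report import predict
from pkstereo.synth import mld_fixture


@pytest.fixture()
def mld_line():
    line, _ = mld_fixture()
    return line


@pytest.fixture()
def marinolide_a():
    """(report, graph, linear) for product A, bioinformatic-only plan."""
    line, plan = mld_fixture("A", experimental=False)
    return predict(line, plan)


@pytest.fixture()
def marinolide_b_experimental():
    """(report, graph, linear) for product B with the experimental configs."""
    line, plan = mld_fixture("B", experimental=True)
    return predict(line, plan)
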