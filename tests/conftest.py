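import pytest

from shieldframe import (FixtureSpec, PrivacyProfile, ServerNode,
                         builtin_profile, generate_fixture)

MTCARS_COLUMNS = ["mpg", "cyl", "disp", "hp", "drat", "wt", "qsec",
                  "vs", "am", "gear", "carb"]

# the four-bin fuel-efficiency recoding, as a client would send it
CASE_WHEN_EXPR = ("list(mtcars$mpg < 15 ~ 0, "
                  "mtcars$mpg >= 15 & mtcars$mpg < 20 ~ 1, "
                  "mtcars$mpg >= 20 & mtcars$mpg < 25 ~ 2, "
                  "mtcars$mpg >= 25 ~ 3)")

FILTER_EXPR = "cyl > 6 & hp > 150 & wt < 3.5"


@pytest.fixture
def mtcars():
    """Synthetic 32-row motor-trend-style table."""
    return generate_fixture(FixtureSpec(n_rows=32, seed=42))


@pytest.fixture
def default_profile():
    return builtin_profile("default")


@pytest.fixture
def make_server(mtcars):
    def _make(node_id="server1", profile=None, frame=None):
        node = ServerNode(node_id=node_id, profile=profile or PrivacyProfile())
        node.workspace.assign("mtcars", frame if frame is not None else mtcars)
        return node
    return _make
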