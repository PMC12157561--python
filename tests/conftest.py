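import matplotlib
matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from cvkmap import ElementCount
from cvkmap.fixtures import aminosugar_demo, caffeine_demo

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def chnops_counts(draw, max_c=60, max_hetero=40):
    """Random C-containing element counts over the CHNOPS alphabet."""
    counts = {"C": draw(st.integers(1, max_c))}
    for elem in ("H", "N", "O", "P", "S"):
        n = draw(st.integers(0, max_hetero))
        if n:
            counts[elem] = n
    return ElementCount(counts)


@st.composite
def any_counts(draw):
    """Element counts over a wider alphabet including isotopes."""
    symbols = draw(
        st.lists(
            st.sampled_from(
                ["C", "H", "N", "O", "P", "S", "Na", "Cl", "Fe", "Se", "D", "T", "13C", "15N"]
            ),
            min_size=1,
            max_size=6,
            unique=True,
        )
    )
    return ElementCount({s: draw(st.integers(1, 99)) for s in symbols})


@pytest.fixture
def caffeine_graph():
    return caffeine_demo()


@pytest.fixture
def aminosugar_graph():
    return aminosugar_demo()


@pytest.fixture
def toy_tables(tmp_path):
    """Smallest valid pathway: two compounds, one reaction."""
    cpath = tmp_path / "compounds.tsv"
    rpath = tmp_path / "reactions.tsv"
    cpath.write_text(
        "id\tname\tformula\nA\tAlpha\tC6H12O6\nB\tBeta\tC6H13O9P\n",
        encoding="utf-8",
    )
    rpath.write_text("id\tsubstrate\tproduct\nr1\tA\tB\n", encoding="utf-8")
    return cpath, rpath
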