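import pytest

from pedigrowth import ChartShape, make_chart


@pytest.fixture(scope="session")
def preterm_chart():
    """Default synthetic preterm weight chart: logistic M, L=1, S=0.13,
    weekly knots 22-50 postmenstrual weeks."""
    return make_chart()


@pytest.fixture(scope="session")
def linear_chart():
    """Weight chart whose median grows exactly 200 g/week (L=1, S=0.12)."""
    return make_chart(
        ChartShape(
            name="synthetic_linear_weight",
            m_curve=("linear", -3900.0, 200.0),  # M(22) = 500 g, M(50) = 6100 g
            s_curve=("constant", 0.12),
        )
    )


@pytest.fixture(scope="session")
def flat_chart():
    """Weight chart with a constant median: zero growth holds any centile."""
    return make_chart(
        ChartShape(
            name="synthetic_flat_weight",
            m_curve=("linear", 2000.0, 0.0),
            s_curve=("constant", 0.10),
        )
    )


@pytest.fixture(scope="session")
def fenton_like_chart():
    """Weekly preterm chart with midweek centering: the table row labelled
    w completed weeks represents exact age w + 3/7 weeks."""
    return make_chart(
        ChartShape(name="synthetic_midweek_weight", centering_offset=3.0 / 7.0)
    )
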