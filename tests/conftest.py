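import math

import pytest

from pathprocnet.annotation_io import load_incidence_fixture


@pytest.fixture(scope="session")
def incidence():
    return load_incidence_fixture()


@pytest.fixture
def write_obo_text(tmp_path):
    """Write raw OBO text to a temp file and return its path."""

    def _write(text: str, name: str = "test.obo"):
        path = tmp_path / name
        path.write_text("format-version: 1.2\nontology: test\n\n" + text)
        return path

    return _write


def hypergeom_upper_tail_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: P(X >= a) by direct factorial arithmetic.

    X counts overlap when drawing a+b elements from a universe of
    n = a+b+c+d containing a+c marked elements.
    """
    n = a + b + c + d
    k_marked = a + c
    n_draw = a + b
    denom = math.comb(n, n_draw)
    lo = max(0, n_draw + k_marked - n)
    hi = min(n_draw, k_marked)
    total = 0
    for x in range(max(a, lo), hi + 1):
        total += math.comb(k_marked, x) * math.comb(n - k_marked, n_draw - x)
    return total / denom
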