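import numpy as np
import pytest

from altej.references import ReferenceLocus, build_derivative


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_locus():
    # "AAAATTTTCCCC" cut with a 4-nt 5' overhang between positions 4 and 8
    return ReferenceLocus(name="toy", sequence="AAAATTTTCCCC", nick_top=4, nick_bottom=8)


@pytest.fixture
def toy_der():
    """Homology-free toy derivative with distinctive flanks."""
    left = ReferenceLocus(
        name="L",
        sequence="ATTCGAGGCTTACGATCTGGTTCAGACCATGCAATGGCCG",
        nick_top=24,
        nick_bottom=28,
    )
    right = ReferenceLocus(
        name="R",
        sequence="TTGACCGTAGGACTCGAGTTCAAGCTCCAGATAACGTGCA",
        nick_top=12,
        nick_bottom=16,
    )
    return build_derivative(left, right, name="der_toy")


def make_random_derivative(rng, length=600, overhang=4, variable_terminal_bases=0):
    from altej.synthetic import random_locus

    left = random_locus(rng, name="locusA", length=length, overhang=overhang)
    right = random_locus(
        rng,
        name="locusB",
        length=length,
        overhang=overhang,
        variable_terminal_bases=variable_terminal_bases,
    )
    return build_derivative(left, right, name="der_rand")
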