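"""Expected-by-chance microhomology length distribution for random joining.

When two unrelated DNA ends are joined, apparent junctional microhomology
arises purely by chance: each base flanking the breakpoint matches the
opposite reference with probability ``m = sum_b p_b**2`` (``p_b`` the base
composition), so the run of coincidental identity on each side of the joint
is geometric.  Two variants are provided:

* ``one_sided``:  P(k) = (1 - m) * m**k — a single geometric run.
* ``two_sided``:  P(k) = (k + 1) * (1 - m)**2 * m**k — the convolution of
  two independent geometric runs, one on each side of the breakpoint.  This
  is the variant consistent with the annotation convention used here, which
  scores maximal exact overlap on both sides of a direct joint.

With an unbiased (uniform) composition ``m = 1/4``, giving P(0) = 3/4
(one-sided) and 9/16 = 0.5625 (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ChanceNullModel",
    "UNIFORM_COMPOSITION",
    "chance_pmf",
    "simulate_chance_mh",
    "goodness_of_fit",
]

UNIFORM_COMPOSITION: dict[str, float] = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

_BASES = "ACGT"


def _validate_composition(composition: dict[str, float]) -> np.ndarray:
    probs = np.array([float(composition.get(b, 0.0)) for b in _BASES])
    if set(composition) - set(_BASES):
        raise ValueError(f"composition keys must be A/C/G/T, got {sorted(composition)}")
    if (probs < 0).any():
        raise ValueError("composition probabilities must be >= 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1 (+-1e-9), got {probs.sum()!r}")
    return probs


@dataclass(frozen=True)
class ChanceNullModel:
    """Analytic pmf of chance microhomology length.

    ``pmf[k]`` for ``k < max_len`` is P(mh_len == k); the final entry
    ``pmf[max_len]`` is the open tail P(mh_len >= max_len).  The pmf sums
    to 1 within 1e-12.
    """

    base_composition: dict[str, float]
    variant: str                  # "one_sided" | "two_sided"
    max_len: int
    pmf: np.ndarray = field(repr=False)

    @property
    def match_prob(self) -> float:
        probs = _validate_composition(self.base_composition)
        return float((probs**2).sum())


def chance_pmf(
    base_composition: dict[str, float] | None = None,
    variant: str = "two_sided",
    max_len: int = 10,
) -> ChanceNullModel:
    """Analytic chance-microhomology pmf with an open tail bin at ``max_len``."""
    if base_composition is None:
        base_composition = UNIFORM_COMPOSITION
    probs = _validate_composition(base_composition)
    if variant not in ("one_sided", "two_sided"):
        raise ValueError(f"variant must be 'one_sided' or 'two_sided', got {variant!r}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    m = float((probs**2).sum())
    k = np.arange(max_len)
    if variant == "one_sided":
        body = (1.0 - m) * m**k
    else:
        body = (k + 1) * (1.0 - m) ** 2 * m**k
    pmf = np.empty(max_len + 1)
    pmf[:max_len] = body
    pmf[max_len] = 1.0 - body.sum()   # open tail holds the remaining mass
    return ChanceNullModel(
        base_composition=dict(base_composition),
        variant=variant,
        max_len=max_len,
        pmf=pmf,
    )


def simulate_chance_mh(
    n: int,
    base_composition: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = 0,
    flank_len: int = 60,
    max_len: int = 10,
) -> np.ndarray:
    """Monte-Carlo oracle for the two-sided chance model.

    Draws ``n`` independent pairs of random reference sequences, joins each
    pair at a fixed interior point, and scores maximal two-sided junctional
    overlap exactly as the annotator does (forward run of the junction
    continuation matching the left reference past its end, plus backward run
    matching the right reference before its start).  Returns counts per
    microhomology length with an open tail bin at ``max_len``, matching the
    :func:`chance_pmf` binning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_composition is None:
        base_composition = UNIFORM_COMPOSITION
    probs = _validate_composition(base_composition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # left reference continuation vs. incoming right bases, and vice versa
    def _run_lengths(k: int) -> np.ndarray:
        a = rng.choice(4, size=(k, flank_len), p=probs)
        b = rng.choice(4, size=(k, flank_len), p=probs)
        mismatch = a != b
        # first mismatch position = run length; all-match rows run to flank_len
        first = np.argmax(mismatch, axis=1)
        first[~mismatch.any(axis=1)] = flank_len
        return first

    mh = _run_lengths(n) + _run_lengths(n)
    counts = np.zeros(max_len + 1, dtype=int)
    clipped = np.minimum(mh, max_len)
    np.add.at(counts, clipped, 1)
    return counts


def goodness_of_fit(counts: np.ndarray, model: ChanceNullModel) -> tuple[float, float]:
    """Chi-square goodness of fit of observed mh counts against the model.

    ``counts`` must use the model's binning (len ``max_len + 1`` with an
    open tail).  Low-expectation bins (< 5 expected) are pooled into the
    tail before testing.  Returns ``(chi2, p)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != model.pmf.shape:
        raise ValueError(
            f"counts shape {counts.shape} does not match model bins {model.pmf.shape}"
        )
    n = counts.sum()
    expected = model.pmf * n
    # pool sparse trailing bins so the chi-square approximation is valid
    keep = len(expected)
    while keep > 2 and expected[keep - 1 :].sum() < 5:
        keep -= 1
    obs = np.concatenate([counts[: keep - 1], [counts[keep - 1 :].sum()]])
    exp = np.concatenate([expected[: keep - 1], [expected[keep - 1 :].sum()]])
    chi2, p = sps.chisquare(obs, exp)
    return float(chi2), float(p)
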