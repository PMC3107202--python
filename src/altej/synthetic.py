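"""Generative stand-in for sequenced translocation junctions and plate assays.

The generator embodies the end-joining picture the package analyzes: after
a two-locus DSB, each end undergoes resection (modeled as a minimum extent
plus a geometric-tailed excess — memoryless nibbling), exposing
single-stranded windows.  A joint then forms either directly at the
resected ends (unbiased, "Lig1-like") or, with probability
``mh_bias_weight / (1 + mh_bias_weight)``, at the offset within the
resected windows exposing the longest annealable microhomology
(microhomology-driven, "Lig3-like").  A junction may instead carry an
insertion: untemplated random bases, or a segment copied — possibly
inverted — from near one of the cuts (templated), with a separate rate for
long (>50 nt) templated inserts mimicking genotypes where they are
elevated.

Ground truth is emitted pre-canonicalized with the annotation conventions
(the constructed sequence is passed through :func:`altej.annotate.annotate_junction`),
so round-trip checks are exact string/integer comparisons; the intended
generative parameters of each junction are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotate import Junction, JunctionAnnotation, annotate_junction
from .references import DerivativeReference, ReferenceLocus, build_derivative, revcomp
from .stats import PlateAssay

__all__ = [
    "SimulationConfig",
    "GENOTYPE_PRESETS",
    "SimulatedJunction",
    "simulate_junctions",
    "simulate_plate",
    "random_locus",
    "random_derivative",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """End-joining parameters for the junction generator.

    resection_min + Geometric(resection_p) nucleotides are resected per end
    (mean excess ``(1 - p) / p``); ``mh_bias_weight`` sets the odds that a
    joint anneals at the longest exposed microhomology rather than joining
    the resected ends directly; ``insertion_prob`` is the total probability
    a junction carries an insertion, of which ``long_insert_rate`` (an
    absolute probability, <= insertion_prob) are long templated inserts of
    > 50 nt; short inserts are templated with ``templated_insertion_prob``
    (copied within ``templated_window`` nt of a cut, inverted half the
    time) and untemplated otherwise, with geometric length parameter
    ``insert_len_p`` (length >= 1, mean ``1/p``).
    """

    resection_p: float = 0.05
    resection_min: int = 5
    mh_bias_weight: float = 4.0
    insertion_prob: float = 0.20
    templated_insertion_prob: float = 0.5
    insert_len_p: float = 0.25
    long_insert_rate: float = 0.028
    long_insert_min: int = 51
    long_insert_excess_mean: float = 24.0
    templated_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.resection_p <= 1.0):
            raise ValueError("resection_p must be in (0, 1]")
        if self.resection_min < 0:
            raise ValueError("resection_min must be >= 0")
        if self.mh_bias_weight < 0:
            raise ValueError("mh_bias_weight must be >= 0")
        for name in ("insertion_prob", "templated_insertion_prob", "long_insert_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.insert_len_p <= 1.0):
            raise ValueError("insert_len_p must be in (0, 1]")
        if self.long_insert_rate > self.insertion_prob:
            raise ValueError("long_insert_rate cannot exceed insertion_prob")


#: Parameterizations echoing the study conditions: microhomology-driven
#: joining in Lig3-proficient cells, chance-level microhomology without
#: nuclear Lig3, and an elevated long-insert class with the ZnF deletion.
GENOTYPE_PRESETS: dict[str, SimulationConfig] = {
    "lig3_proficient": SimulationConfig(mh_bias_weight=4.0),
    "nuclear_lig3_deficient": SimulationConfig(mh_bias_weight=0.0),
    "lig3_znf_delta": SimulationConfig(
        mh_bias_weight=4.0, insertion_prob=0.25, long_insert_rate=0.135
    ),
}


@dataclass(frozen=True)
class SimulatedJunction:
    junction: Junction
    truth: JunctionAnnotation
    # intended generative quantities (pre-canonicalization)
    resection_left: int
    resection_right: int
    annealed_mh: int
    intended_insertion: str


def random_locus(
    rng: np.random.Generator,
    name: str = "locus",
    length: int = 600,
    overhang: int = 4,
    variable_terminal_bases: int = 0,
) -> ReferenceLocus:
    """A random uniform-composition locus cut at its midpoint."""
    seq = "".join(rng.choice(_BASES, size=length))
    nick_top = length // 2 - overhang // 2
    return ReferenceLocus(
        name=name,
        sequence=seq,
        nick_top=nick_top,
        nick_bottom=nick_top + overhang,
        variable_terminal_bases=variable_terminal_bases,
    )


def random_derivative(
    rng: np.random.Generator,
    length: int = 600,
    overhang: int = 4,
    name: str = "der_sim",
) -> DerivativeReference:
    left = random_locus(rng, name="locusA", length=length, overhang=overhang)
    right = random_locus(rng, name="locusB", length=length, overhang=overhang)
    return build_derivative(left, right, name=name)


def _geometric0(rng: np.random.Generator, p: float) -> int:
    """Geometric on {0, 1, 2, ...} with success probability p."""
    return int(rng.geometric(p)) - 1


def _longest_exposed_mh(
    lfrag: str, rfrag: str, e_lo: int, e_hi: int, s_lo: int, s_hi: int
) -> tuple[int, int, int]:
    """Longest annealable microhomology over joint offsets in the windows.

    Returns ``(k, e, s)``: joining the ends as ``lfrag[:e] + rfrag[s:]``
    leaves ``k`` bases of identity ``lfrag[e-k:e] == rfrag[s-k:s]`` at the
    joint.  Ties prefer the joint closest to the unresected ends (smallest
    combined deletion), then the left-most loss on the right end.
    """
    best = (0, e_hi, s_lo)
    best_key = (0, -((e_hi - e_hi) + s_lo), -s_lo)
    for e in range(e_lo, e_hi + 1):
        for s in range(s_lo, s_hi + 1):
            k = 0
            while k < e and k < s and lfrag[e - 1 - k] == rfrag[s - 1 - k] \
                    and lfrag[e - 1 - k] != "N":
                k += 1
            key = (k, -((e_hi - e) + s), -s)
            if key > best_key:
                best_key = key
                best = (k, e, s)
    return best


def _draw_insert(
    rng: np.random.Generator,
    config: SimulationConfig,
    der: DerivativeReference,
    long: bool,
) -> str:
    if long:
        length = config.long_insert_min + _geometric0(
            rng, 1.0 / config.long_insert_excess_mean
        )
        templated = True
    else:
        length = 1 + _geometric0(rng, config.insert_len_p)
        templated = rng.random() < config.templated_insertion_prob
    if not templated:
        return "".join(rng.choice(_BASES, size=length))
    locus = der.left if rng.random() < 0.5 else der.right
    cut = (locus.nick_top + locus.nick_bottom) // 2
    lo = max(0, cut - config.templated_window)
    hi = min(len(locus.sequence), cut + config.templated_window)
    if hi - lo < length:          # window narrower than the insert: widen
        lo, hi = 0, len(locus.sequence)
    start = int(rng.integers(lo, hi - length + 1))
    segment = locus.sequence[start : start + length]
    return revcomp(segment) if rng.random() < 0.5 else segment


def simulate_junctions(
    config: SimulationConfig,
    der: DerivativeReference,
    n: int,
    genotype: str = "synthetic",
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
) -> list[SimulatedJunction]:
    """Generate ``n`` junction reads with canonicalized ground truth.

    Reproducible given ``config.seed`` (or an explicit ``rng``).  A
    resection draw exceeding the available reference is resampled up to
    ``max_retries`` times, then raises.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lfrag, rfrag = der.left_fragment, der.right_fragment
    left_end, right_len = len(lfrag), len(rfrag)
    # both flanks must keep enough intact sequence to anchor a read
    min_keep = 25

    out: list[SimulatedJunction] = []
    bias_p = (
        config.mh_bias_weight / (1.0 + config.mh_bias_weight)
        if config.mh_bias_weight > 0
        else 0.0
    )
    for idx in range(n):
        for attempt in range(max_retries + 1):
            r_l = config.resection_min + _geometric0(rng, config.resection_p)
            r_r = config.resection_min + _geometric0(rng, config.resection_p)
            if left_end - r_l >= min_keep and right_len - r_r >= min_keep:
                break
        else:
            raise ValueError(
                f"resection repeatedly exceeded the reference length "
                f"(left_end={left_end}, right_len={right_len}); supply longer loci"
            )

        e0, s0 = left_end - r_l, r_r
        u = rng.random()
        insert = ""
        annealed = 0
        if u < config.long_insert_rate:
            insert = _draw_insert(rng, config, der, long=True)
            e, s = e0, s0
        elif u < config.insertion_prob:
            insert = _draw_insert(rng, config, der, long=False)
            e, s = e0, s0
        elif bias_p > 0.0 and rng.random() < bias_p:
            annealed, e, s = _longest_exposed_mh(lfrag, rfrag, e0, left_end, 0, s0)
        else:
            e, s = e0, s0

        seq = lfrag[:e] + insert + rfrag[s:]
        junction = Junction(
            id=f"sim{idx:05d}", genotype=genotype, derivative=der.name, sequence=seq
        )
        truth = annotate_junction(junction, der)
        out.append(
            SimulatedJunction(
                junction=junction,
                truth=truth,
                resection_left=r_l,
                resection_right=r_r,
                annealed_mh=annealed,
                intended_insertion=insert,
            )
        )
    return out


def simulate_plate(
    true_frequency: float,
    wells: int = 96,
    cells_per_well: int = 208,
    seed: int | np.random.Generator | None = 0,
) -> PlateAssay:
    """Simulate a multiwell translocation assay.

    Events per well are Poisson with mean ``true_frequency * cells_per_well``,
    so each well is positive with probability ``1 - exp(-frequency * cells)``.
    """
    if not (0.0 <= true_frequency <= 1.0):
        raise ValueError("true_frequency must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_positive = 1.0 - np.exp(-true_frequency * cells_per_well)
    positives = int(rng.binomial(wells, p_positive))
    return PlateAssay(wells=wells, cells_per_well=cells_per_well, positive_wells=positives)
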