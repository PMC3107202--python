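"""Junction annotation: deletions, microhomology, insertions.

Each translocation junction amplicon is decomposed against the perfect-join
derivative reference into

* ``del_left`` — nucleotides lost from the left (filled-in) end,
* ``del_right`` — nucleotides lost from the right end,
* ``mh_len``/``mh_seq`` — junctional microhomology: bases at a direct joint
  that match both the retained left and the retained right reference, so the
  exact breakpoint is ambiguous,
* ``insertion_seq`` — bases at the joint matching neither reference.

Conventions
-----------
Matching is exact (Sanger-grade amplicon reads): the left match is the
maximal exact extension of the junction prefix along the left fragment
(never past the blunt end), the right match the maximal exact extension of
the junction suffix back along the right fragment (never before its blunt
start).  ``N`` never matches anything.  If the two matches overlap by ``m``
junction positions, ``mh_len = m`` and deletions are measured to the outer
edges of the microhomology, charging the shared bases to neither end; this
canonicalizes the breakpoint-position ambiguity inside the microhomology.
If the matches leave a gap, the gap is the insertion and ``mh_len = 0``
(microhomology is scored only at direct joints).

A right locus may declare ``variable_terminal_bases = v``: a putative
insertion consisting solely of <= v copies of the right fragment's terminal
base is attributed to variable nuclease cleavage, not polymerase action, and
is absorbed rather than scored as an insertion.

The decomposition maximizes total matched length, then the left match, and
is checked by an exact reconstruction invariant: re-concatenating the
annotated parts must reproduce the input junction byte-for-byte.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .references import DerivativeReference, revcomp

__all__ = [
    "Junction",
    "JunctionAnnotation",
    "InsertionDerivation",
    "GenotypeSummary",
    "AnchorResult",
    "UnalignableJunction",
    "AnnotationError",
    "anchor",
    "annotate_junction",
    "derive_insertion",
    "summarize_genotype",
    "read_junctions_fasta",
    "read_junctions_tsv",
    "annotations_to_frame",
    "summaries_to_frame",
]

DEFAULT_SEED_LEN = 15
DEFAULT_MIN_DERIVATION_LEN = 7
DEFAULT_LONG_INSERT_THRESHOLD = 50


class UnalignableJunction(ValueError):
    """Neither orientation of the read anchors to both reference flanks."""


class AnnotationError(RuntimeError):
    """Internal consistency failure (reconstruction mismatch)."""


@dataclass(frozen=True)
class Junction:
    id: str
    genotype: str
    derivative: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"junction {self.id!r}: empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"junction {self.id!r}: disallowed character(s) {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class AnchorResult:
    orientation: str          # "forward" | "reverse"
    left_start: int           # start of the prefix match in the left fragment
    left_match_len: int       # junction prefix length matching the left fragment
    right_match_start: int    # start of the suffix match in the right fragment
    right_match_len: int      # junction suffix length matching the right fragment


@dataclass(frozen=True)
class JunctionAnnotation:
    junction_id: str
    genotype: str
    derivative: str
    del_left: int
    del_right: int
    mh_len: int
    mh_seq: str
    insertion_seq: str
    junction_class: str       # "perfect" | "simple_deletion" | "insertion"
    terminal_rule_applied: bool
    orientation: str
    # internal coordinates (left/right fragment coordinate systems)
    left_start: int
    left_match_end: int
    right_match_start: int
    right_match_len: int
    absorbed_seq: str = ""

    @property
    def del_total(self) -> int:
        return self.del_left + self.del_right

    @property
    def insertion_len(self) -> int:
        return len(self.insertion_seq)

    def reconstruct(self, der: DerivativeReference) -> str:
        """Re-concatenate the annotated parts (microhomology written once)."""
        left = der.left_fragment[self.left_start : self.left_match_end]
        right_end = self.right_match_start + self.right_match_len
        if self.mh_len > 0:
            right = der.right_fragment[self.right_match_start + self.mh_len : right_end]
            middle = ""
        else:
            right = der.right_fragment[self.right_match_start : right_end]
            middle = self.insertion_seq or self.absorbed_seq
        return left + middle + right


@dataclass(frozen=True)
class InsertionDerivation:
    junction_id: str
    source: str               # "left_locus" | "right_locus" | "unknown"
    source_start: int | None
    source_end: int | None
    inverted: bool
    flanking_mh: int
    flanking_mh_left: int
    flanking_mh_right: int


@dataclass(frozen=True)
class GenotypeSummary:
    genotype: str
    n: int
    pct_without_mh: float
    pct_with_insertions: float
    pct_long_insertions: float
    mh_distribution: dict[int, int]
    n_simple_deletion: int
    median_del_total: float | None
    n_with_insertion: int
    median_insertion_len: float | None


# ---------------------------------------------------------------------------
# exact matching primitives (N never matches)
# ---------------------------------------------------------------------------

_CHUNK = 64


def _common_prefix_len(s: str, t: str) -> int:
    n = min(len(s), len(t))
    lo = 0
    while lo < n:
        hi = min(lo + _CHUNK, n)
        a, b = s[lo:hi], t[lo:hi]
        if a == b and "N" not in a:
            lo = hi
            continue
        for k in range(lo, hi):
            if s[k] != t[k] or s[k] == "N":
                return k
        lo = hi
    return lo


def _common_suffix_len(s: str, t: str) -> int:
    n = min(len(s), len(t))
    lo = 0
    while lo < n:
        hi = min(lo + _CHUNK, n)
        a = s[len(s) - hi : len(s) - lo]
        b = t[len(t) - hi : len(t) - lo]
        if a == b and "N" not in a:
            lo = hi
            continue
        for k in range(lo, hi):
            if s[-k - 1] != t[-k - 1] or s[-k - 1] == "N":
                return k
        lo = hi
    return lo


def _occurrences(haystack: str, needle: str) -> list[int]:
    if "N" in needle:          # N never matches, so an N-bearing seed cannot anchor
        return []
    out = []
    start = haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _best_left_anchor(seq: str, left_frag: str, seed_len: int):
    """(match_len, start) of the maximal prefix match, or None."""
    if len(seq) < seed_len:
        return None
    seed = seq[:seed_len]
    best = None
    for a in _occurrences(left_frag, seed):
        i = seed_len + _common_prefix_len(seq[seed_len:], left_frag[a + seed_len :])
        if best is None or i > best[0]:
            best = (i, a)
    return best


def _best_right_anchor(seq: str, right_frag: str, seed_len: int):
    """(match_len, start) of the maximal suffix match, or None."""
    if len(seq) < seed_len:
        return None
    seed = seq[-seed_len:]
    best = None
    for b in _occurrences(right_frag, seed):
        ext = _common_suffix_len(seq[: len(seq) - seed_len], right_frag[:b])
        j = seed_len + ext
        s_r = b - ext
        if best is None or j > best[0] or (j == best[0] and s_r < best[1]):
            best = (j, s_r)
    return best


def anchor(
    junction_seq: str, der: DerivativeReference, seed_len: int = DEFAULT_SEED_LEN
) -> AnchorResult:
    """Anchor a junction read to both flanks of a derivative reference.

    Tries the forward read first; orientation is ``"reverse"`` iff only the
    reverse complement carries exact ``seed_len`` matches to both the left
    fragment (via the read prefix) and the right fragment (via the read
    suffix).  Matches are exact and maximal, stopping at the first mismatch
    or ``N``; the left match never extends past the left blunt end, the
    right match never before the right blunt start.
    """
    if seed_len < 8:
        raise ValueError(f"seed_len must be >= 8, got {seed_len}")
    junction_seq = junction_seq.upper()
    for orientation, seq in (
        ("forward", junction_seq),
        ("reverse", revcomp(junction_seq)),
    ):
        left = _best_left_anchor(seq, der.left_fragment, seed_len)
        right = _best_right_anchor(seq, der.right_fragment, seed_len)
        if left is not None and right is not None:
            return AnchorResult(
                orientation=orientation,
                left_start=left[1],
                left_match_len=left[0],
                right_match_start=right[1],
                right_match_len=right[0],
            )
    raise UnalignableJunction(
        f"no {seed_len}-nt exact seed to both reference flanks in either "
        f"orientation"
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_junction(
    junction: Junction,
    der: DerivativeReference,
    seed_len: int = DEFAULT_SEED_LEN,
) -> JunctionAnnotation:
    """Decompose one junction into deletions, microhomology and insertion.

    See the module docstring for the conventions.  Raises
    :class:`UnalignableJunction` if the read cannot be anchored and
    :class:`AnnotationError` if the reconstruction invariant fails (which
    would indicate an internal bug, never bad input).
    """
    anc = anchor(junction.sequence, der, seed_len=seed_len)
    seq = junction.sequence if anc.orientation == "forward" else revcomp(junction.sequence)
    n = len(seq)
    i, a = anc.left_match_len, anc.left_start
    j, s_r = anc.right_match_len, anc.right_match_start
    left_end = len(der.left_fragment)
    e_l = a + i

    m = i + j - n
    terminal_rule_applied = False
    absorbed = ""
    if m >= 0:
        mh_len, mh_seq = m, seq[n - j : i]
        insertion_seq = ""
    else:
        mh_len, mh_seq = 0, ""
        gap = seq[i : n - j]
        v = der.right.variable_terminal_bases
        term = der.right_fragment[:1]
        if v > 0 and len(gap) <= v and term != "" and set(gap) == set(term):
            # variable cleavage retaining extra copies of the terminal base:
            # absorbed into end bookkeeping, not scored as an insertion
            insertion_seq = ""
            absorbed = gap
            terminal_rule_applied = True
        else:
            insertion_seq = gap

    del_left = left_end - e_l
    del_right = s_r
    if insertion_seq:
        junction_class = "insertion"
    elif del_left + del_right == 0:
        junction_class = "perfect"
    else:
        junction_class = "simple_deletion"

    ann = JunctionAnnotation(
        junction_id=junction.id,
        genotype=junction.genotype,
        derivative=der.name,
        del_left=del_left,
        del_right=del_right,
        mh_len=mh_len,
        mh_seq=mh_seq,
        insertion_seq=insertion_seq,
        junction_class=junction_class,
        terminal_rule_applied=terminal_rule_applied,
        orientation=anc.orientation,
        left_start=a,
        left_match_end=e_l,
        right_match_start=s_r,
        right_match_len=j,
        absorbed_seq=absorbed,
    )
    if ann.reconstruct(der) != seq:
        raise AnnotationError(
            f"junction {junction.id!r}: reconstruction does not reproduce the "
            f"input sequence (internal error)"
        )
    return ann


# ---------------------------------------------------------------------------
# insertion derivation
# ---------------------------------------------------------------------------


def _search_region(locus_seq: str, nicks: tuple[int, int], window: int | None) -> tuple[str, int]:
    if window is None:
        return locus_seq, 0
    lo = max(0, min(nicks) - window)
    hi = min(len(locus_seq), max(nicks) + window)
    return locus_seq[lo:hi], lo


def derive_insertion(
    ann: JunctionAnnotation,
    der: DerivativeReference,
    min_len: int = DEFAULT_MIN_DERIVATION_LEN,
    window: int | None = None,
) -> InsertionDerivation:
    """Locate the template of an inserted segment in the parental loci.

    Both strands of both parental loci are searched (optionally restricted
    to ``window`` nt around each cut) for an exact full-length match of the
    insert.  Ties are broken by left locus before right, forward before
    inverted, then smallest start.  ``flanking_mh`` measures templated-
    insertion-style microhomology: the longest exact repeat between each
    insert edge and the retained parental sequence adjacent to it at the
    junction (left edge vs. the end of the retained left fragment, right
    edge vs. the start of the retained right fragment), summed over both
    edges.
    """
    insert = ann.insertion_seq
    if len(insert) < min_len:
        raise ValueError(
            f"insertion_len {len(insert)} < min_len {min_len} for junction "
            f"{ann.junction_id!r}"
        )

    hit = None
    for locus, source in ((der.left, "left_locus"), (der.right, "right_locus")):
        region, offset = _search_region(
            locus.sequence, (locus.nick_top, locus.nick_bottom), window
        )
        for query, inverted in ((insert, False), (revcomp(insert), True)):
            pos = region.find(query)
            if pos != -1 and "N" not in query:
                hit = (source, offset + pos, offset + pos + len(insert), inverted)
                break
        if hit:
            break

    lfrag, rfrag = der.left_fragment, der.right_fragment
    e_l, s_r = ann.left_match_end, ann.right_match_start
    k_left = 0
    for k in range(min(len(insert), e_l), 0, -1):
        if insert[:k] == lfrag[e_l - k : e_l] and "N" not in insert[:k]:
            k_left = k
            break
    k_right = 0
    for k in range(min(len(insert), len(rfrag) - s_r), 0, -1):
        if insert[-k:] == rfrag[s_r : s_r + k] and "N" not in insert[-k:]:
            k_right = k
            break

    if hit is None:
        return InsertionDerivation(
            junction_id=ann.junction_id,
            source="unknown",
            source_start=None,
            source_end=None,
            inverted=False,
            flanking_mh=k_left + k_right,
            flanking_mh_left=k_left,
            flanking_mh_right=k_right,
        )
    source, start, end, inverted = hit
    return InsertionDerivation(
        junction_id=ann.junction_id,
        source=source,
        source_start=start,
        source_end=end,
        inverted=inverted,
        flanking_mh=k_left + k_right,
        flanking_mh_left=k_left,
        flanking_mh_right=k_right,
    )


# ---------------------------------------------------------------------------
# per-genotype summaries
# ---------------------------------------------------------------------------


def summarize_genotype(
    annotations: Sequence[JunctionAnnotation],
    long_insert_threshold: int = DEFAULT_LONG_INSERT_THRESHOLD,
) -> GenotypeSummary:
    """Aggregate junction annotations for a single genotype.

    ``pct_without_mh`` and ``pct_with_insertions`` are percentages of *all*
    junctions; the microhomology length distribution and the median combined
    deletion are computed over simple-deletion junctions only (insertion
    junctions carry no scoreable junctional microhomology, and perfect joins
    have no deletion); the median insertion length is over insertion-bearing
    junctions.  ``pct_long_insertions`` counts inserts strictly longer than
    ``long_insert_threshold`` as a percentage of all junctions.
    """
    if not annotations:
        raise ValueError("cannot summarize an empty annotation collection")
    genotypes = {ann.genotype for ann in annotations}
    if len(genotypes) != 1:
        raise ValueError(f"expected a single genotype, got {sorted(genotypes)}")
    (genotype,) = genotypes

    n = len(annotations)
    simple = [a for a in annotations if a.junction_class == "simple_deletion"]
    inserts = [a for a in annotations if a.insertion_len > 0]

    mh_dist: dict[int, int] = {}
    for a in simple:
        mh_dist[a.mh_len] = mh_dist.get(a.mh_len, 0) + 1

    return GenotypeSummary(
        genotype=genotype,
        n=n,
        pct_without_mh=100.0 * sum(a.mh_len == 0 for a in annotations) / n,
        pct_with_insertions=100.0 * len(inserts) / n,
        pct_long_insertions=100.0
        * sum(a.insertion_len > long_insert_threshold for a in annotations)
        / n,
        mh_distribution=dict(sorted(mh_dist.items())),
        n_simple_deletion=len(simple),
        median_del_total=(
            statistics.median(a.del_total for a in simple) if simple else None
        ),
        n_with_insertion=len(inserts),
        median_insertion_len=(
            statistics.median(a.insertion_len for a in inserts) if inserts else None
        ),
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_junctions_fasta(
    path: str | Path, derivative: str = "der", genotype_sep: str = "|"
) -> list[Junction]:
    """Read junctions from FASTA; record ids encode genotype as 'genotype|id'."""
    from .references import load_fasta

    out = []
    for rec_id, seq in load_fasta(path).items():
        if genotype_sep in rec_id:
            genotype, jid = rec_id.split(genotype_sep, 1)
        else:
            genotype, jid = "unknown", rec_id
        out.append(Junction(id=jid, genotype=genotype, derivative=derivative, sequence=seq))
    return out


def read_junctions_tsv(path: str | Path) -> list[Junction]:
    """Read junctions from TSV with columns id, genotype, derivative, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "genotype", "derivative", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV column(s) {sorted(missing)}")
    return [
        Junction(
            id=row.id, genotype=row.genotype, derivative=row.derivative,
            sequence=row.sequence,
        )
        for row in df.itertuples(index=False)
    ]


def annotations_to_frame(annotations: Iterable[JunctionAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "junction_id": a.junction_id,
            "genotype": a.genotype,
            "derivative": a.derivative,
            "orientation": a.orientation,
            "del_left": a.del_left,
            "del_right": a.del_right,
            "del_total": a.del_total,
            "mh_len": a.mh_len,
            "mh_seq": a.mh_seq,
            "insertion_len": a.insertion_len,
            "insertion_seq": a.insertion_seq,
            "junction_class": a.junction_class,
            "terminal_rule_applied": a.terminal_rule_applied,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Iterable[GenotypeSummary]) -> pd.DataFrame:
    rows = [
        {
            "genotype": s.genotype,
            "n": s.n,
            "pct_without_mh": round(s.pct_without_mh, 2),
            "pct_with_insertions": round(s.pct_with_insertions, 2),
            "pct_long_insertions": round(s.pct_long_insertions, 2),
            "n_simple_deletion": s.n_simple_deletion,
            "median_del_total": s.median_del_total,
            "n_with_insertion": s.n_with_insertion,
            "median_insertion_len": s.median_insertion_len,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
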