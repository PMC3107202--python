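"""Independent oracles used by the test suite.

The decomposition oracle enumerates every anchor position exhaustively with
character-by-character matching and no seeding — deliberately sharing no
code with the package's annotator — and applies the same canonical
tie-breaks: maximal total matched length, then maximal left match, then
smallest right start.
"""

from __future__ import annotations

from altej.references import DerivativeReference


def _match(a: str, b: str) -> bool:
    return a == b and a != "N" and b != "N"


def oracle_decompose(seq: str, der: DerivativeReference) -> dict:
    """Exhaustive (eL, sR, m) decomposition of a forward-oriented junction.

    Prefix matches are enumerated over every start ``a`` in the left
    fragment, suffix matches over every end ``q`` in the right fragment;
    for a fixed anchor the match set is downward closed, so the maximal
    extension covers all sub-matches.
    """
    left = der.left_fragment
    right = der.right_fragment
    n = len(seq)

    best_i, best_a = -1, 0
    for a in range(len(left) + 1):
        i = 0
        while i < n and a + i < len(left) and _match(seq[i], left[a + i]):
            i += 1
        if i > best_i:
            best_i, best_a = i, a

    best_j, best_sr = -1, 0
    for q in range(len(right) + 1):
        j = 0
        while j < n and q - j > 0 and _match(seq[n - j - 1], right[q - j - 1]):
            j += 1
        s_r = q - j
        if j > best_j or (j == best_j and s_r < best_sr):
            best_j, best_sr = j, s_r

    i, a, j, s_r = best_i, best_a, best_j, best_sr
    m = i + j - n
    terminal_rule = False
    if m >= 0:
        mh_len = m
        mh_seq = seq[n - j : i]
        insertion = ""
    else:
        mh_len, mh_seq = 0, ""
        gap = seq[i : n - j]
        v = der.right.variable_terminal_bases
        term = right[:1]
        if v > 0 and 0 < len(gap) <= v and set(gap) == set(term):
            insertion = ""
            terminal_rule = True
        else:
            insertion = gap

    del_left = len(left) - (a + i)
    del_right = s_r
    if insertion:
        klass = "insertion"
    elif del_left + del_right == 0:
        klass = "perfect"
    else:
        klass = "simple_deletion"
    return {
        "del_left": del_left,
        "del_right": del_right,
        "mh_len": mh_len,
        "mh_seq": mh_seq,
        "insertion_seq": insertion,
        "junction_class": klass,
        "terminal_rule_applied": terminal_rule,
    }


def annotation_as_dict(ann) -> dict:
    return {
        "del_left": ann.del_left,
        "del_right": ann.del_right,
        "mh_len": ann.mh_len,
        "mh_seq": ann.mh_seq,
        "insertion_seq": ann.insertion_seq,
        "junction_class": ann.junction_class,
        "terminal_rule_applied": ann.terminal_rule_applied,
    }


def random_junction_case(rng, der, insert_modes=("none", "untemplated", "templated")):
    """Build one junction sequence from a derivative with random end loss.

    Keeps at least 20 intact bases on each flank so seeding can anchor.
    Returns the constructed sequence (the intended decomposition is not
    returned: the oracle defines the canonical truth).
    """
    left = der.left_fragment
    right = der.right_fragment
    max_dl = len(left) - 20
    max_dr = len(right) - 20
    e = len(left) - int(rng.integers(0, max_dl + 1))
    s = int(rng.integers(0, max_dr + 1))
    mode = insert_modes[int(rng.integers(0, len(insert_modes)))]
    if mode == "none":
        insert = ""
    elif mode == "untemplated":
        length = 1 + int(rng.integers(0, 12))
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    else:
        src = der.left.sequence if rng.random() < 0.5 else der.right.sequence
        length = 1 + int(rng.integers(0, 15))
        start = int(rng.integers(0, len(src) - length + 1))
        insert = src[start : start + length]
        if rng.random() < 0.5:
            from altej.references import revcomp

            insert = revcomp(insert)
    return left[:e] + insert + right[s:]
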