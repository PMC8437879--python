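"""Independent brute-force oracle for flank extraction.

Enumerates every (flank5 offset, flank3 offset, strand) triple with explicit
character-by-character Hamming counting — no shared code with the package's
scanner beyond the tie-break definition it checks.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def _scan(seq, design):
    """Return (progress, status, insert, mm5, mm3) for one strand."""
    len5, len3 = len(design.flank5), len(design.flank3)
    lo = design.n_length - design.length_tolerance
    hi = design.n_length + design.length_tolerance
    hits5 = [
        (o, _hamming(seq[o:o + len5], design.flank5))
        for o in range(len(seq) - len5 + 1)
    ]
    hits5 = [(o, m) for o, m in hits5 if m <= design.max_mismatch]
    if not hits5:
        return (0, "NO_FLANK5", None, 0, 0)
    hits3 = [
        (o, _hamming(seq[o:o + len3], design.flank3))
        for o in range(len(seq) - len3 + 1)
    ]
    hits3 = [(o, m) for o, m in hits3 if m <= design.max_mismatch]
    layouts = []
    any_downstream = False
    for o5, m5 in hits5:
        for o3, m3 in hits3:
            if o3 >= o5 + len5:
                any_downstream = True
                insert_len = o3 - (o5 + len5)
                if lo <= insert_len <= hi:
                    layouts.append((m5 + m3, abs(insert_len - design.n_length),
                                    o5, o3, m5, m3))
    if not any_downstream:
        return (1, "NO_FLANK3", None, 0, 0)
    if not layouts:
        return (2, "LENGTH_FAIL", None, 0, 0)
    _, _, o5, o3, m5, m3 = min(layouts)
    insert = seq[o5 + len5:o3]
    if set(insert) - set("ACGT"):
        return (3, "AMBIGUOUS_BASE", None, 0, 0)
    return (4, "PASS", insert, m5, m3)


def brute_force_find_flanks(bases, design):
    """Oracle verdict: (status, insert, orientation)."""
    bases = bases.upper()
    fwd = _scan(bases, design)
    rev = _scan(rc(bases), design)
    if fwd[1] == "PASS":
        return ("PASS", fwd[2], "forward")
    if rev[1] == "PASS":
        return ("PASS", rev[2], "reverse")
    winner = fwd if fwd[0] >= rev[0] else rev
    return (winner[1], None, None)
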