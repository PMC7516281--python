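"""Independent oracles shared by the unit and acceptance tests."""


def allen_oracle(s1: int, e1: int, s2: int, e2: int) -> str:
    """Brute-force interval relation classifier, written against the
    *set* semantics of discrete inclusive intervals — independent of the
    endpoint-arithmetic implementation it checks."""
    a = set(range(s1, e1 + 1))
    b = set(range(s2, e2 + 1))
    if a == b:
        return "equals"
    if not (a & b):
        if max(a) < min(b):
            return "meets" if max(a) + 1 == min(b) else "strictlyPrecedes"
        return "metBy" if max(b) + 1 == min(a) else "precededBy"
    if a < b:
        if min(a) == min(b):
            return "starts"
        if max(a) == max(b):
            return "finishes"
        return "strictlyContainedBy"
    if b < a:
        if min(a) == min(b) or max(a) == max(b):
            return "contains"
        return "strictlyContains"
    return "overlaps" if min(a) < min(b) else "overlappedBy"


def all_range_pairs(lo: int = 1, hi: int = 8):
    """Every ordered pair of well-formed inclusive ranges with endpoints
    in [lo, hi]."""
    ranges = [(s, e) for s in range(lo, hi + 1) for e in range(s, hi + 1)]
    for r1 in ranges:
        for r2 in ranges:
            yield r1, r2
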