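"""Independent brute-force oracles shared by the test modules."""


def oracle_classify(c, k):
    """Independent enumeration of the written taxonomy rules."""
    c, k = tuple(c), tuple(k)
    if not any(c + k):
        return None  # inadmissible
    if not any(c):
        return "kd_specific_open"
    if all(c):
        return "permanently_open" if all(k) else "kd_specific_closed"
    steps = lambda p: [i for i in range(1, len(p)) if p[i] != p[i - 1]]
    if len(steps(c)) > 1 or len(steps(k)) > 1:
        return "complex"
    if c == k:
        return "stable_other"
    opening = c[0] == 0
    target = 1 if opening else 0
    # settling index: last position not yet in the target state, plus one
    def settle(p):
        idx = [i for i in range(len(p)) if p[i] != target]
        return (idx[-1] + 1) if idx else 0
    kc, kk = settle(c), settle(k)
    word = "opening" if opening else "closing"
    if kk < kc:
        return f"accelerated_{word}"
    if kk > kc:
        return f"decelerated_{word}"
    return "stable_other"
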