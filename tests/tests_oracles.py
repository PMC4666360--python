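"""Independent oracles shared by the acceptance tests.

These deliberately re-derive expected values with naive algorithms that do
not share code with the production implementations they check.
"""

from alukit.breakpoint import ThreeWayAlignment


def oracle_breakpoints(labels):
    """Exhaustive cumulative-score argmax, evaluated at every column."""
    inc_l = {"1": 1, "*": 1, "N": -1, "2": -3}
    inc_r = {"2": 1, "*": 1, "N": -1, "1": -3}
    n = len(labels)
    left_scores = [
        sum(inc_l[lab] for lab in labels[: i + 1]) for i in range(n)
    ]
    best = max(left_scores)
    left_col = max(i for i in range(n) if left_scores[i] == best)
    right_scores = [
        sum(inc_r[lab] for lab in labels[i:]) for i in range(n)
    ]
    best = max(right_scores)
    right_col = min(i for i in range(n) if right_scores[i] == best)
    return left_col, right_col


def threeway_from_labels(labels):
    """A gapless three-way alignment realizing a given label string."""
    ref, left, right = [], [], []
    for lab in labels:
        if lab == "*":
            ref.append("A"); left.append("A"); right.append("A")
        elif lab == "1":
            ref.append("C"); left.append("C"); right.append("G")
        elif lab == "2":
            ref.append("G"); left.append("T"); right.append("G")
        else:
            ref.append("T"); left.append("A"); right.append("C")
    return ThreeWayAlignment(
        "".join(ref), "".join(left), "".join(right), labels,
        list(range(len(labels))),
    )


def gotoh_score_oracle(q, r, match=5, mismatch=-4, gap_open=16, gap_extend=4):
    """Plain-python affine-gap global alignment score."""
    NEG = -(10**9)
    n, m = len(q), len(r)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    IX = [[NEG] * (m + 1) for _ in range(n + 1)]
    IY = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for j in range(1, m + 1):
        IX[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        IY[i][0] = -gap_open - gap_extend * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == r[j - 1] and q[i - 1] != "N") else mismatch
            M[i][j] = max(
                M[i - 1][j - 1], IX[i - 1][j - 1], IY[i - 1][j - 1]
            ) + s
            IY[i][j] = max(
                M[i - 1][j] - gap_open,
                IX[i - 1][j] - gap_open,
                IY[i - 1][j] - gap_extend,
            )
            IX[i][j] = max(
                M[i][j - 1] - gap_open,
                IY[i][j - 1] - gap_open,
                IX[i][j - 1] - gap_extend,
            )
    return max(M[n][m], IX[n][m], IY[n][m])
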