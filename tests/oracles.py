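"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results with the most literal possible
implementations (dict-based DP, per-position loops) and share no code with
the package.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def sw_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Literal affine-gap Smith-Waterman with full three-state matrices.

    Tie-breaks mirror the documented contract: best end cell = first maximum
    in (row, col) order; traceback prefers diagonal, then vertical gap
    (subject gap), then horizontal; gap closure preferred over extension.
    Returns (score, identity, coverage_subject, qaln, saln).
    """
    n, m = len(a), len(b)
    oe = gap_open + gap_extend
    H = {}
    E = {}
    F = {}
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 or j == 0:
                H[i, j], E[i, j], F[i, j] = 0.0, NEG, NEG
                continue
            E[i, j] = max(H[i - 1, j] - oe, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - oe, F[i, j - 1] - gap_extend)
            s = _B62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    best, bi, bj = 0.0, 0, 0
    for i in range(n + 1):
        for j in range(m + 1):
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    if best <= 0.0:
        return 0.0, 0.0, 0.0, "", ""
    i, j, state = bi, bj, "H"
    qa, sa = [], []
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + _B62[a[i - 1], b[j - 1]]:
                qa.append(a[i - 1]); sa.append(b[j - 1]); i -= 1; j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append(a[i - 1]); sa.append("-")
            state = "H" if E[i, j] == H[i - 1, j] - oe else "E"
            i -= 1
        else:
            qa.append("-"); sa.append(b[j - 1])
            state = "H" if F[i, j] == H[i, j - 1] - oe else "F"
            j -= 1
    qa.reverse(); sa.reverse()
    cols = len(qa)
    matches = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
    identity = matches / cols if cols else 0.0
    coverage = (bj - j) / m
    return best, identity, coverage, "".join(qa), "".join(sa)


def nw_global_identity(a, b, gap_open=11.0, gap_extend=1.0):
    """Global (Needleman-Wunsch, affine) identity over aligned columns."""
    n, m = len(a), len(b)
    oe = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - oe, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - oe, Y[i][j - 1] - gap_extend)
    # traceback counting matches only
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    matches = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            matches += a[i - 1] == b[j - 1]
            prev = max(("M", "X", "Y"),
                       key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1][j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            state = "M" if X[i][j] == M[i - 1][j] - oe else "X"
            i -= 1
        else:
            state = "M" if Y[i][j] == M[i][j - 1] - oe else "Y"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return matches / cols


def pwm_score_oracle(log_odds, background, seq, offset):
    """Per-position summation of the profile placed at one offset."""
    total = 0.0
    for p, row in enumerate(log_odds):
        k = offset + p
        if k >= len(seq):
            break
        base = "ACGT".find(seq[k].upper())
        if base >= 0:
            total += row[base]
    return total


def best_placement_oracle(log_odds, background, seq):
    """Exhaustive max over all placements (ties -> smallest offset)."""
    L = len(log_odds)
    if not seq:
        return 0.0, 0
    n_off = max(1, len(seq) - L + 1)
    best, best_off = None, 0
    for off in range(n_off):
        s = pwm_score_oracle(log_odds, background, seq, off)
        if best is None or s > best:
            best, best_off = s, off
    return best, best_off
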