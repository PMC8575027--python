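"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written in plain Python with the most
literal formulation available (cell-by-cell dynamic programming,
exhaustive set arithmetic, full re-counting), sharing no code with the
package beyond the published scoring conventions.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_oracle(a: str, b: str, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Cell-by-cell affine global alignment with explicit tie-break order.

    Returns (score, identity, coverage_a, coverage_b) under the same
    conventions as the implementation: a gap of length L costs
    open + (L-1)*extend; identity counts matched columns over all
    columns; coverage is residues inside the first..last substitution
    column; traceback prefers substitution, then gap-in-b, then gap-in-a.
    """
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0
    for i in range(1, m + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
            )
    score = max(M[m][n], X[m][n], Y[m][n])
    # traceback with the documented preference order M, X, Y
    i, j = m, n
    state = "M" if M[i][j] == score else ("X" if X[i][j] == score else "Y")
    cols = []
    while i > 0 or j > 0:
        cols.append(state)
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            opts = [("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])]
        elif state == "X":
            target = X[i][j]
            i -= 1
            opts = [
                ("M", M[i][j] + gap_open),
                ("X", X[i][j] + gap_extend),
                ("Y", Y[i][j] + gap_open),
            ]
        else:
            target = Y[i][j]
            j -= 1
            opts = [
                ("M", M[i][j] + gap_open),
                ("X", X[i][j] + gap_open),
                ("Y", Y[i][j] + gap_extend),
            ]
        for st, val in opts:
            if val == target:
                state = st
                break
    cols.reverse()
    matches = 0
    ia = ib = 0
    subs = []
    for ci, c in enumerate(cols):
        if c == "M":
            if a[ia] == b[ib]:
                matches += 1
            subs.append(ci)
            ia += 1
            ib += 1
        elif c == "X":
            ia += 1
        else:
            ib += 1
    identity = matches / len(cols) if cols else 0.0
    if not subs:
        return score, identity, 0.0, 0.0
    lo, hi = subs[0], subs[-1]
    ca = sum(1 for ci, c in enumerate(cols) if lo <= ci <= hi and c in "MX") / len(a)
    cb = sum(1 for ci, c in enumerate(cols) if lo <= ci <= hi and c in "MY") / len(b)
    return score, identity, ca, cb


def greedy_cluster_oracle(records, identity_fn, min_id=0.9, min_cov=0.8):
    """The greedy rule evaluated from a full all-pairs identity matrix.

    ``identity_fn(seq_a, seq_b) -> (identity, cov_a, cov_b)``.  Returns
    the partition as a list of frozensets of record ids.
    """
    ordered = sorted(records, key=lambda r: (-len(r.protein_seq), r.id))
    table = {}
    for q in ordered:
        for r in ordered:
            table[(q.id, r.id)] = identity_fn(q.protein_seq, r.protein_seq)
    clusters: list[list] = []
    for rec in ordered:
        for members in clusters:
            rep = members[0]
            ident, cq, cr = table[(rec.id, rep.id)]
            if ident >= min_id and cq >= min_cov and cr >= min_cov:
                members.append(rec)
                break
        else:
            clusters.append([rec])
    return [frozenset(r.id for r in members) for members in clusters]


def canonical_kmer_set(sequences, k):
    """Exhaustive canonical k-mer set via string reverse complement."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            rc = km.translate(comp)[::-1]
            out.add(min(km, rc))
    return out
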