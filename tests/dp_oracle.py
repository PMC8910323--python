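"""Independent brute-force affine-gap alignment oracle for tests.

A plain three-state Gotoh dynamic program, written without reference to the
package's aligner: match +2, mismatch -2, a gap of length k costs 6 + k, and
gaps in the read at either end are free (the read may cover only part of the
reference).  Quadratic and slow on purpose -- it exists only to check scores
on small instances.
"""

NEG = float("-inf")

MATCH = 2.0
MISMATCH = -2.0
OPEN = 7.0  # first gap position
EXTEND = 1.0  # each further position


def oracle_score(ref: str, read: str) -> float:
    """Best global alignment score of read vs ref with free read end gaps."""
    m, n = len(ref), len(read)
    # M: ref[i-1] ~ read[j-1]; D: gap in read (ref base unmatched);
    # I: gap in ref (read base unmatched)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        D[i][0] = 0.0  # leading read gap is free
    for j in range(1, n + 1):
        I[0][j] = -(OPEN + (j - 1) * EXTEND)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if ref[i - 1] == read[j - 1] else MISMATCH
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            if j == n:  # trailing read gap is free
                D[i][j] = max(M[i - 1][j], D[i - 1][j], I[i - 1][j])
            else:
                D[i][j] = max(
                    M[i - 1][j] - OPEN, D[i - 1][j] - EXTEND, I[i - 1][j] - OPEN
                )
            I[i][j] = max(M[i][j - 1] - OPEN, I[i][j - 1] - EXTEND, D[i][j - 1] - OPEN)
    return max(M[m][n], D[m][n], I[m][n])
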