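"""Global protein alignment with affine gaps (Gotoh) and a fixed,
deterministic traceback.

Scoring is match +1, mismatch -1, gap open -5, gap extend -1 (a gap of
length k costs -5 - (k - 1)).  At score ties the traceback prefers
diagonal over up (gap in the second sequence) over left (gap in the
first), which makes rendered reports byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Alignment", "global_align"]

NEG = float("-inf")


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        """Fraction of aligned columns that are identical residues."""
        n = len(self.aligned_a)
        if n == 0:
            return 1.0
        matches = sum(a == b for a, b in zip(self.aligned_a, self.aligned_b))
        return matches / n


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Alignment:
    n, m = len(a), len(b)
    # M: a[i-1] aligned to b[j-1]; X: gap in b (consume a); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    # choose final state with the stated preference at ties
    score = max(M[n][m], X[n][m], Y[n][m])
    if M[n][m] == score:
        state = "M"
    elif X[n][m] == score:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i][j] - s
            if i - 1 == 0 and j - 1 == 0:
                state = "M"
            elif M[i - 1][j - 1] == target:
                state = "M"
            elif X[i - 1][j - 1] == target:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if M[i - 1][j] + gap_open == X[i][j]:
                state = "M"
            elif X[i - 1][j] + gap_extend == X[i][j]:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            if M[i][j - 1] + gap_open == Y[i][j]:
                state = "M"
            elif Y[i][j - 1] + gap_extend == Y[i][j]:
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j == 0:
            break
    return Alignment(aligned_a="".join(reversed(out_a)),
                     aligned_b="".join(reversed(out_b)), score=score)
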