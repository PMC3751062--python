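"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: the alignment oracle is
a plain three-matrix dynamic program, the N-statistic oracle works in exact
rational arithmetic, and the ORF oracle enumerates stop-delimited runs via
regular expressions on translated frames.
"""

from __future__ import annotations

import re
from fractions import Fraction

_CODONS = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def translate_frame(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        out.append(_CODONS.get(codon, "X") if "N" not in codon else "X")
    return "".join(out)


def sw_affine_score(a: str, b: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Optimal local alignment score, affine gaps in the BLAST convention
    (a gap of length g costs gap_open + g * gap_extend)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - gap_open - gap_extend,
                          e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open - gap_extend,
                          f[i - 1][j] - gap_extend)
            diag = h[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return best


def n_statistic_oracle(lengths, x) -> int:
    """Exhaustive Nx in exact rational arithmetic."""
    total = sum(lengths)
    target = Fraction(x, 100) * total
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if cum >= target:
            return L
    raise AssertionError("unreachable")


def orf_oracle(seq: str, min_nt: int = 150):
    """All six-frame stop-to-stop runs with nucleotide span strictly greater
    than min_nt.  Returns a set of (strand, frame, nt_start, nt_end, peptide)
    with 1-based inclusive forward coordinates."""
    min_nt -= min_nt % 3
    L = len(seq)
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for off in range(3):
            pep = translate_frame(s[off:])
            for m in re.finditer(r"[^*]+", pep):
                span = 3 * (m.end() - m.start())
                if span <= min_nt:
                    continue
                a = off + 3 * m.start()          # 0-based on strand s
                b = a + span                     # exclusive
                if strand == "+":
                    coords = (a + 1, b)
                else:
                    coords = (L - b + 1, L - a)
                out.add((strand, off + 1, coords[0], coords[1], m.group()))
    return out
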