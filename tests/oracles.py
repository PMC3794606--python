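"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a pipeline quantity by the most literal method
available — pure-Python window enumeration, exact rational arithmetic,
dense grid search — deliberately sharing no code with the implementation
it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "W": {"A", "T"}, "S": {"C", "G"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def naive_mismatches(window, pattern):
    mm = 0
    for b, s in zip(window, pattern):
        if b == "N":
            mm += s != "N"
        elif b not in IUPAC_SETS[s]:
            mm += 1
    return mm


def naive_scan(sequence, pattern="RRRCWWGYYY", max_mm=0):
    """All (start, strand, decamer, mismatches) windows, both strands."""
    k = len(pattern)
    out = []
    for start in range(len(sequence) - k + 1):
        w = sequence[start:start + k]
        mm = naive_mismatches(w, pattern)
        if mm <= max_mm:
            out.append((start, "+", w, mm))
        wrc = naive_revcomp(w)
        mm = naive_mismatches(wrc, pattern)
        if mm <= max_mm:
            out.append((start, "-", wrc, mm))
    return sorted(out)


def fisher_enum(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration over the support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)

    def pmf(x):
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = pmf(x)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def hill_grid_rss(conc, resp, n_ec50=80, n_h=40):
    """Best RSS over a dense (EC50, h) grid, (f0, fmax) solved linearly.

    For fixed EC50 and h the Hill model is linear in (f0, fmax):
    f = f0 * (1 - s) + fmax * s with s = c^h / (EC50^h + c^h), so each grid
    point costs one 2-parameter least-squares solve.
    """
    conc = np.asarray(conc, float)
    resp = np.asarray(resp, float)
    pos = conc[conc > 0]
    ec50s = np.logspace(np.log10(pos.min() / 10), np.log10(conc.max() * 10), n_ec50)
    hs = np.linspace(0.2, 5.0, n_h)
    best = np.inf
    for ec in ec50s:
        for h in hs:
            with np.errstate(over="ignore"):
                s = np.where(conc > 0, conc ** h / (ec ** h + conc ** h), 0.0)
            A = np.column_stack([1.0 - s, s])
            coef, *_ = np.linalg.lstsq(A, resp, rcond=None)
            rss = float(np.sum((A @ coef - resp) ** 2))
            if rss < best:
                best = rss
    return best
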