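"""The RY/WW transactivation code of 20-mer response elements.

Positions are numbered 1-20 on the spacer-removed full site (two decamers
concatenated).  Two dinucleotide features carry the code:

* **RY signature** — ``GG`` immediately 5' of each core C (positions 2-3
  and 12-13) and/or ``CC`` immediately 3' of each core G (positions 8-9 and
  18-19).  An RE carries 0-4 RY signatures.  The p73 change-of-spectrum
  mutant S139F (and its p53/p63 counterparts S121F/S150F) transactivates
  REs lacking any RY signature *less* than wild type, and REs with one or
  more *more*, scaling with the count.
* **WW motif** — the central dinucleotide of each ``CWWG`` core (positions
  5-6 and 15-16), one of AT/TA/AA/TT when both bases are A/T, else
  ``other``.  AT is the most active core for the wild-type protein and TA
  the least; S139F enhancement is favoured when at least one half-site
  core is AA or TT.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RY_SLOTS",
    "SignatureProfile",
    "ResponsePrediction",
    "ry_profile",
    "ww_rank",
    "s139f_predict",
    "s260n_expectation",
]

#: RY signature slots on the 1-based 20-mer: (slot name, 0-based slice, dinucleotide)
RY_SLOTS: tuple[tuple[str, slice, str], ...] = (
    ("RR1", slice(1, 3), "GG"),    # positions 2-3
    ("YY1", slice(7, 9), "CC"),    # positions 8-9
    ("RR2", slice(11, 13), "GG"),  # positions 12-13
    ("YY2", slice(17, 19), "CC"),  # positions 18-19
)

_WW_SLICES = (slice(4, 6), slice(14, 16))     # positions 5-6, 15-16
_CORE_SLICES = (slice(3, 7), slice(13, 17))   # positions 4-7, 14-17

_WW_LABELS = frozenset({"AT", "TA", "AA", "TT"})
_WW_RANK = {"AT": 1, "AA": 2, "TT": 2, "TA": 3, "other": 4}


@dataclass(frozen=True)
class SignatureProfile:
    """Per-RE signature bookkeeping on the spacer-removed 20-mer.

    ``ry_flags`` follow slot order RR1 (2-3), YY1 (8-9), RR2 (12-13),
    YY2 (18-19).  ``inner_only`` is true when the RE has exactly one RY
    signature and it sits in one of the two inner slots (YY1 or RR2, i.e.
    within the second or third monomer-binding quarter) — the position bias
    observed among single-RY enhanced REs.
    """

    re20: str
    ry_flags: tuple[bool, bool, bool, bool]
    ry_count: int
    ww_motifs: tuple[str, str]
    cores: tuple[str, str]
    inner_only: bool


@dataclass(frozen=True)
class ResponsePrediction:
    """Predicted S139F-vs-WT transactivation class with a monotone score."""

    predicted_class: str  # 'enhanced', 'reduced' or 'indeterminate'
    score: float


def ry_profile(re20: str) -> SignatureProfile:
    """Extract RY flags, WW motifs and cores from a 20-mer RE.

    Raises ``ValueError`` for sequences that are not 20 nt over ACGT.
    """
    re20 = re20.upper()
    if len(re20) != 20:
        raise ValueError(f"RE must be a 20-mer, got length {len(re20)}")
    bad = set(re20) - set("ACGT")
    if bad:
        raise ValueError(f"RE must be over ACGT, found {sorted(bad)}")

    flags = tuple(re20[sl] == dinuc for _, sl, dinuc in RY_SLOTS)
    count = sum(flags)
    ww = tuple(
        re20[sl] if re20[sl] in _WW_LABELS else "other" for sl in _WW_SLICES
    )
    cores = tuple(re20[sl] for sl in _CORE_SLICES)
    inner_only = count == 1 and (flags[1] or flags[2])
    return SignatureProfile(re20, flags, count, ww, cores, inner_only)


def ww_rank(label: str) -> int:
    """Ordinal rank of expected wild-type activity by core WW motif.

    AT is the most active core (rank 1), AA/TT intermediate (rank 2), TA
    the weakest A/T core (rank 3); non-W cores rank last (4).
    """
    try:
        return _WW_RANK[label]
    except KeyError:
        raise ValueError(f"unknown WW label {label!r}") from None


def s139f_predict(profile: SignatureProfile) -> ResponsePrediction:
    """Predict the S139F/WT transactivation class of an RE from its profile.

    The class is categorical: ``reduced`` iff the RE has no RY signature,
    ``enhanced`` otherwise.  The score is a package convention —
    ``ry_count + 0.5`` if at least one half-site core is AA or TT, else
    ``ry_count`` — whose only contract is monotonicity: it increases
    strictly with the RY count, with the non-AT W core as a secondary
    additive bonus (never a veto: a 4/4-RY RE with AT cores still scores
    above any 3/4-RY RE).
    """
    bonus = 0.5 if any(w in ("AA", "TT") for w in profile.ww_motifs) else 0.0
    score = profile.ry_count + bonus
    klass = "reduced" if profile.ry_count == 0 else "enhanced"
    return ResponsePrediction(klass, score)


def s260n_expectation() -> str:
    """Expected phenotype annotation for the super-transactivating allele.

    p73 S260N (L3 loop) increases transactivation across nearly all REs
    independently of the RY/WW code, so records for that allele are simply
    annotated as expected super-transactivating; no sequence-based
    prediction is made.
    """
    return "expected_super_trans"
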