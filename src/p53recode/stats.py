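"""Transactivation-change classification and signature association tests.

Per-RE reporter activities (yeast luciferase readings, normalized to
soluble protein or OD600 and expressed as fold induction over the empty
vector background) are compared between alleles as a mutant/WT ratio and
classified as enhanced (ratio > 1.5), reduced (ratio < 0.67) or similar
(in between, boundaries inclusive).  Association between sequence features
and classes is tested at half-site resolution with a two-sided Fisher's
exact test, and the RY-count dose dependence of the ratio with a Spearman
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signature import SignatureProfile

__all__ = [
    "ENHANCED_THRESHOLD",
    "REDUCED_THRESHOLD",
    "TransactivationRecord",
    "RatioClassification",
    "ContingencyTable2x2",
    "AssociationReport",
    "fold_induction",
    "classify_ratio",
    "fisher_exact_two_sided",
    "signature_association",
    "profiles_to_frame",
]

ENHANCED_THRESHOLD = 1.5
REDUCED_THRESHOLD = 0.67

#: Relative tolerance guarding floating-point ties in the two-sided
#: point-probability summation.
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class TransactivationRecord:
    """Replicate reporter readings for one RE under one allele.

    ``activities`` are raw light units per replicate; ``normalizers`` the
    matching per-replicate soluble protein (ug) or OD600; ``background``
    the empty-vector reading with its own normalizer.
    """

    re_name: str
    allele: str
    activities: tuple[float, ...]
    normalizers: tuple[float, ...]
    background: float
    background_normalizer: float = 1.0

    def __post_init__(self) -> None:
        if len(self.activities) < 1:
            raise ValueError("need at least one replicate")
        if len(self.activities) != len(self.normalizers):
            raise ValueError("one normalizer per replicate required")
        if any(a <= 0 for a in self.activities):
            raise ValueError("activities must be positive")
        if any(m <= 0 for m in self.normalizers):
            raise ValueError("normalizers must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


@dataclass(frozen=True)
class RatioClassification:
    ratio: float
    klass: str  # 'enhanced' | 'reduced' | 'similar'
    thresholds: tuple[float, float] = (ENHANCED_THRESHOLD, REDUCED_THRESHOLD)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("feature", "no_feature")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class AssociationReport:
    table: ContingencyTable2x2
    fisher_p: float
    trend_rho: float
    trend_p: float


def fold_induction(record: TransactivationRecord) -> float:
    """Fold induction: mean normalized reading over normalized background."""
    bg = record.background / record.background_normalizer
    if bg <= 0:
        raise ValueError("normalized background must be positive")
    mean_norm = float(
        np.mean([a / m for a, m in zip(record.activities, record.normalizers)])
    )
    return mean_norm / bg


def classify_ratio(
    mut_fold: float,
    wt_fold: float,
    upper: float = ENHANCED_THRESHOLD,
    lower: float = REDUCED_THRESHOLD,
) -> RatioClassification:
    """Classify mutant/WT fold-induction ratio.

    Strict inequalities define the outer classes (>1.5 enhanced, <0.67
    reduced); the boundary values themselves fall in 'similar', so every
    positive ratio lands in exactly one class.
    """
    if mut_fold <= 0 or wt_fold <= 0:
        raise ValueError("fold inductions must be positive")
    if not upper > lower > 0:
        raise ValueError("thresholds must satisfy upper > lower > 0")
    ratio = mut_fold / wt_fold
    if ratio > upper:
        klass = "enhanced"
    elif ratio < lower:
        klass = "reduced"
    else:
        klass = "similar"
    return RatioClassification(ratio, klass, (upper, lower))


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p by point-probability summation.

    With fixed margins the table count ``a`` follows a hypergeometric
    distribution; the two-sided p-value is the sum of point probabilities
    not exceeding that of the observed table (within relative tolerance
    1e-7 to absorb floating-point ties).  Exact enumeration over the full
    support — no large-sample approximation.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum())
    return min(p, 1.0)


def signature_association(
    classified: pd.DataFrame,
    groups: tuple[str, str] = ("enhanced", "reduced"),
    feature: str = "ww",
    feature_labels: frozenset[str] | set[str] = frozenset({"TT", "AA"}),
) -> AssociationReport:
    """Test whether a half-site sequence feature separates two ratio classes.

    ``classified`` needs columns ``ratio``, ``klass``, ``ry_count``,
    ``ww1``, ``ww2`` (and ``ry_half1``/``ry_half2`` booleans for the RY
    feature).  The 2x2 table is built at half-site resolution (two
    half-sites per RE, so a group of 22 REs contributes 44 half-sites):
    rows are the two classes in ``groups``, columns count half-sites that
    carry the feature — with ``feature='ww'``, a WW motif in
    ``feature_labels``; with ``feature='ry'``, at least one of the
    half-site's two RY slots satisfied.  Alongside the Fisher test, the RY
    dose dependence is summarized as the Spearman rank correlation of
    ratio vs ry_count across *all* REs in the input (all classes).

    Raises ``ValueError`` naming any empty group.
    """
    required = {"ratio", "klass", "ry_count", "ww1", "ww2"}
    if feature == "ry":
        required |= {"ry_half1", "ry_half2"}
    elif feature != "ww":
        raise ValueError(f"unknown feature {feature!r}; use 'ww' or 'ry'")
    missing = required - set(classified.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    cells = []
    for g in groups:
        sub = classified[classified["klass"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} contains no REs")
        if feature == "ww":
            half_feature = pd.concat([sub["ww1"], sub["ww2"]]).isin(list(feature_labels))
        else:
            half_feature = pd.concat([sub["ry_half1"], sub["ry_half2"]]).astype(bool)
        with_f = int(half_feature.sum())
        cells.append((with_f, len(half_feature) - with_f))
    feature_name = (
        "WW in " + "/".join(sorted(feature_labels)) if feature == "ww"
        else "half-site with RY signature"
    )
    table = ContingencyTable2x2(
        cells[0][0], cells[0][1], cells[1][0], cells[1][1],
        row_labels=groups,
        col_labels=(feature_name, "without"),
    )
    fisher_p = fisher_exact_two_sided(table)

    if classified["ry_count"].nunique() > 1 and classified["ratio"].nunique() > 1:
        rho, trend_p = sps.spearmanr(classified["ratio"], classified["ry_count"])
    else:  # degenerate: no variation to correlate
        rho, trend_p = float("nan"), float("nan")
    return AssociationReport(table, fisher_p, float(rho), float(trend_p))


def profiles_to_frame(
    ratios: dict[str, float],
    profiles: dict[str, SignatureProfile],
    upper: float = ENHANCED_THRESHOLD,
    lower: float = REDUCED_THRESHOLD,
) -> pd.DataFrame:
    """Join per-RE ratios with signature profiles into the classified table."""
    rows = []
    for name, ratio in ratios.items():
        prof = profiles[name]
        klass = classify_ratio(ratio, 1.0, upper, lower).klass
        rows.append(
            {
                "name": name,
                "ratio": ratio,
                "klass": klass,
                "ry_count": prof.ry_count,
                "ww1": prof.ww_motifs[0],
                "ww2": prof.ww_motifs[1],
                "ry_half1": prof.ry_flags[0] or prof.ry_flags[1],
                "ry_half2": prof.ry_flags[2] or prof.ry_flags[3],
            }
        )
    return pd.DataFrame(rows)
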