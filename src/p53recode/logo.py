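"""Paired-dinucleotide logos for aligned 20-mer response elements.

A conventional sequence logo treats positions independently, which hides
the dinucleotide structure of the RE code (GG/CC flanking the cores, the
WW core itself).  This module computes, for six labelled position pairs —
RR1 (2-3), WW1 (5-6), YY1 (8-9), RR2 (12-13), WW2 (15-16), YY2 (18-19) —
the empirical frequency of every dinucleotide across a set of aligned
20-mers (spacer removed), alongside the per-position mononucleotide
frequency matrix as the conventional baseline, and renders the paired
frequencies as an SVG logo whose glyph heights are proportional to
frequency (no entropy scaling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SLOTS", "SLOT_CLASS", "DinucleotideLogo",
           "dinucleotide_frequencies", "logo_table", "render_logo"]

#: Slot name -> 0-based [start, end) on the 20-mer.
SLOTS: dict[str, tuple[int, int]] = {
    "RR1": (1, 3),
    "WW1": (4, 6),
    "YY1": (7, 9),
    "RR2": (11, 13),
    "WW2": (14, 16),
    "YY2": (17, 19),
}

#: Consensus base class of each slot (both positions share the class).
SLOT_CLASS: dict[str, str] = {
    "RR1": "AG", "WW1": "AT", "YY1": "CT",
    "RR2": "AG", "WW2": "AT", "YY2": "CT",
}

_BASES = "ACGT"
_BASE_COLOR = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}
_GREY = "#9e9e9e"


@dataclass(frozen=True)
class DinucleotideLogo:
    """Empirical slot-wise dinucleotide frequencies over n aligned 20-mers."""

    slot_counts: Mapping[str, Mapping[str, int]]
    slot_freqs: Mapping[str, Mapping[str, float]]
    n: int
    mono: np.ndarray  # (20, 4) per-position base frequencies, columns ACGT


def dinucleotide_frequencies(res: Sequence[str]) -> DinucleotideLogo:
    """Count dinucleotides per slot over a non-empty set of 20-mers.

    Frequencies are exact counts over n; the mononucleotide matrix is
    computed on the same set.  Raises ``ValueError`` on an empty list or
    any sequence not 20 nt over ACGT.
    """
    if not res:
        raise ValueError("need at least one RE")
    seqs = [s.upper() for s in res]
    for s in seqs:
        if len(s) != 20:
            raise ValueError(f"all REs must be 20-mers, got length {len(s)}")
        if set(s) - set(_BASES):
            raise ValueError(f"non-ACGT base in {s!r}")

    n = len(seqs)
    counts: dict[str, dict[str, int]] = {}
    freqs: dict[str, dict[str, float]] = {}
    for slot, (a, b) in SLOTS.items():
        c = Counter(s[a:b] for s in seqs)
        counts[slot] = dict(sorted(c.items()))
        freqs[slot] = {d: k / n for d, k in counts[slot].items()}

    mono = np.zeros((20, 4))
    for s in seqs:
        for i, base in enumerate(s):
            mono[i, _BASES.index(base)] += 1
    mono /= n
    return DinucleotideLogo(counts, freqs, n, mono)


def logo_table(logo: DinucleotideLogo) -> pd.DataFrame:
    """Tidy export: one row per (slot, dinucleotide) with count and fraction."""
    rows = [
        {"slot": slot, "dinucleotide": d, "count": k, "fraction": k / logo.n}
        for slot, cs in logo.slot_counts.items()
        for d, k in cs.items()
    ]
    return pd.DataFrame(rows, columns=["slot", "dinucleotide", "count", "fraction"])


def _is_consensus(slot: str, dinuc: str) -> bool:
    allowed = SLOT_CLASS[slot]
    return all(b in allowed for b in dinuc)


def render_logo(
    logo: DinucleotideLogo,
    consensus_only: bool = False,
    min_freq: float = 0.05,
) -> str:
    """Render the paired-dinucleotide logo as an SVG document string.

    One column per slot; within a column, dinucleotide glyphs are stacked
    by descending frequency with heights strictly proportional to
    frequency.  Dinucleotides below ``min_freq`` are omitted.  With
    ``consensus_only`` only consensus-compatible dinucleotides (both bases
    in the slot's R/W/Y class) are drawn; otherwise non-consensus
    dinucleotides are drawn greyed.  Output is a pure function of the
    inputs (no timestamps), so identical logos render byte-identically.
    """
    if not 0.0 <= min_freq <= 1.0:
        raise ValueError("min_freq must lie in [0, 1]")

    col_w, stack_h, pad, label_h = 64.0, 240.0, 12.0, 24.0
    width = pad * 2 + col_w * len(SLOTS)
    height = pad * 2 + stack_h + label_h

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        f'<!-- paired-dinucleotide logo, n={logo.n} -->',
    ]
    for col, slot in enumerate(SLOTS):
        x0 = pad + col * col_w
        items = sorted(
            logo.slot_freqs[slot].items(), key=lambda kv: (-kv[1], kv[0])
        )
        y = pad + stack_h  # stack grows upward from the baseline
        for dinuc, freq in items:
            if freq < min_freq:
                continue
            consensus = _is_consensus(slot, dinuc)
            if consensus_only and not consensus:
                continue
            h = freq * stack_h
            y -= h
            for k, base in enumerate(dinuc):
                color = _BASE_COLOR[base] if consensus else _GREY
                # glyph box col_w/2 wide, h tall; font scaled into the box
                parts.append(
                    f'<text x="0" y="0" font-family="monospace" '
                    f'font-weight="bold" fill="{color}" '
                    f'data-slot="{slot}" data-dinuc="{dinuc}" '
                    f'data-freq="{freq:.6f}" '
                    f'transform="translate({x0 + k * col_w / 2:.2f},'
                    f'{y + h:.2f}) scale({col_w / 2 / 10:.4f},{h / 12:.4f})" '
                    f'font-size="12">{base}</text>'
                )
        parts.append(
            f'<text x="{x0 + col_w / 2:.2f}" y="{pad + stack_h + label_h:.2f}" '
            f'font-family="sans-serif" font-size="12" '
            f'text-anchor="middle">{slot}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
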