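"""Degenerate-consensus scanning for p53-family response elements.

The canonical response element (RE) bound by p53/p63/p73 tetramers is two
decameric half-sites matching the degenerate pattern ``RRRCWWGYYY``
(R = purine, Y = pyrimidine, W = A/T) separated by a spacer of 0-13 nt.
Functional sites in vivo frequently depart from the canonical architecture:
besides full sites, half-sites (one decamer) and three-quarter sites (a
decamer plus one adjacent conforming pentamer, ``RRRCW`` or ``WGYYY``) are
bound and transactivated to varying degrees.

This module locates all three architectures in arbitrary DNA by exhaustive
window scanning on both strands.  Coordinates are 0-based half-open
internally; report writers convert to the 1-based inclusive numbering used
for the 20-mer RE (positions 1-20, spacer removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "IUPAC",
    "ConsensusModel",
    "HalfSiteMatch",
    "QuarterMatch",
    "SiteMatch",
    "ResponseElement",
    "mismatch_count",
    "reverse_complement",
    "scan_half_sites",
    "assemble_sites",
    "scan_sequence",
    "dedupe_sites",
]

#: IUPAC nucleotide classes.  ``N`` in a *pattern* matches anything; ``N`` in a
#: *scanned sequence* never satisfies a non-N pattern symbol (it counts as a
#: mismatch), because an unknown base cannot be asserted to conform.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

HALF_SITE_LEN = 10
#: Quarter-site patterns: the 5' and 3' halves of the decameric half-site.
QUARTER_HEAD = "RRRCW"
QUARTER_TAIL = "WGYYY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> integer code; 4 is reserved for N
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class ConsensusModel:
    """What counts as a site: half-site pattern, spacer range, mismatch budget.

    Parameters
    ----------
    half_site_pattern
        Decameric IUPAC pattern, default ``RRRCWWGYYY``.
    max_spacer
        Largest spacer (nt) allowed between the two half-sites of a full
        site; 0-13.
    max_mismatches_per_half
        Mismatch allowance per decamer window during scanning.  The default
        of 0 scans for consensus-conforming windows only; signature scoring
        downstream accepts any 20-mer regardless.
    """

    half_site_pattern: str = "RRRCWWGYYY"
    max_spacer: int = 13
    max_mismatches_per_half: int = 0

    def __post_init__(self) -> None:
        if len(self.half_site_pattern) != HALF_SITE_LEN:
            raise ValueError(
                f"half-site pattern must have length {HALF_SITE_LEN}, "
                f"got {len(self.half_site_pattern)}"
            )
        bad = set(self.half_site_pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {sorted(bad)}")
        if not 0 <= self.max_spacer <= 13:
            raise ValueError("max_spacer must be in [0, 13]")
        if self.max_mismatches_per_half < 0:
            raise ValueError("max_mismatches_per_half must be >= 0")


@dataclass(frozen=True)
class HalfSiteMatch:
    """One decamer window matching the half-site pattern.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    (scanned) sequence regardless of strand; ``decamer`` is the matching
    10-mer read 5'->3' on ``strand``.
    """

    start: int
    end: int
    strand: str
    decamer: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start != HALF_SITE_LEN:
            raise ValueError("half-site interval must span 10 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class QuarterMatch:
    """A conforming pentamer flanking a half-site (part of a 3/4-site)."""

    start: int
    end: int
    strand: str
    side: str  # 'five_prime' or 'three_prime' relative to the half-site reading
    pentamer: str


@dataclass(frozen=True)
class SiteMatch:
    """A located site: full (two half-sites), three_quarter, or half.

    ``re20`` is the spacer-removed site sequence read 5'->3' on the site's
    strand: 20-mer for full sites, 15-mer for 3/4-sites, 10-mer for
    half-sites.
    """

    architecture: str
    half_sites: tuple[HalfSiteMatch, ...]
    spacer: int
    re20: str
    strand: str
    start: int
    end: int
    quarter: Optional[QuarterMatch] = None

    def __post_init__(self) -> None:
        if self.architecture not in ("full", "three_quarter", "half"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "full" and (
            len(self.half_sites) != 2 or len(self.re20) != 20
        ):
            raise ValueError("full site requires two half-sites and a 20-mer")
        if self.architecture != "full" and len(self.half_sites) != 1:
            raise ValueError("non-full site carries exactly one half-site")
        if self.architecture == "full" and len({h.strand for h in self.half_sites}) != 1:
            raise ValueError("full-site half-sites must share a strand")

    @property
    def mismatches(self) -> int:
        return sum(h.mismatches for h in self.half_sites)


@dataclass(frozen=True)
class ResponseElement:
    """A named RE as tabulated: 20-mer, spacer, and provenance.

    ``provenance`` distinguishes physiological REs (P-REs, taken from
    promoters of p53-family target genes) from synthetic ones (S-REs,
    designed permutations of the consensus).
    """

    name: str
    re20: str
    spacer: int = 0
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if set(self.re20) - set("ACGT"):
            raise ValueError(f"RE {self.name!r}: sequence must be over ACGT")
        if self.provenance not in ("physiological", "synthetic"):
            raise ValueError("provenance must be 'physiological' or 'synthetic'")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a sequence over ``ACGTN``."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot complement symbols: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def mismatch_count(decamer: str, pattern: str) -> int:
    """Number of positions where ``decamer`` departs from an IUPAC pattern.

    ``N`` in the decamer counts as a mismatch against any non-N pattern
    symbol (an unknown base is not evidence of conformance).  0 means full
    conformance.

    Raises
    ------
    ValueError
        If lengths differ, the decamer holds a symbol outside ``ACGTN``, or
        the pattern holds a non-IUPAC symbol.
    """
    decamer = decamer.upper()
    if len(decamer) != len(pattern):
        raise ValueError(
            f"sequence length {len(decamer)} != pattern length {len(pattern)}"
        )
    mm = 0
    for base, sym in zip(decamer, pattern):
        try:
            allowed = IUPAC[sym]
        except KeyError:
            raise ValueError(f"non-IUPAC pattern symbol {sym!r}") from None
        if base not in "ACGTN":
            raise ValueError(f"non-nucleotide symbol {base!r} in sequence")
        if base == "N":
            if sym != "N":
                mm += 1
        elif base not in allowed:
            mm += 1
    return mm


def _pattern_masks(pattern: str) -> np.ndarray:
    """Boolean (len, 5) table: does base-code j satisfy pattern position i?"""
    masks = np.zeros((len(pattern), 5), dtype=bool)
    for i, sym in enumerate(pattern):
        try:
            allowed = IUPAC[sym]
        except KeyError:
            raise ValueError(f"non-IUPAC pattern symbol {sym!r}") from None
        for base in allowed:
            masks[i, "ACGTN".index(base)] = True
        # N in the scanned sequence conforms only to pattern N
        masks[i, 4] = sym == "N"
    return masks


def _encode(seq: str) -> np.ndarray:
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"non-nucleotide symbol {seq[pos]!r} at offset {pos}")
    return codes


def _window_mismatches(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of every window of len(pattern) along ``seq``."""
    k = len(pattern)
    if len(seq) < k:
        return np.zeros(0, dtype=np.int64)
    codes = _encode(seq)
    masks = _pattern_masks(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = masks[np.arange(k)[None, :], windows]
    return (~ok).sum(axis=1)


def scan_half_sites(sequence: str, model: ConsensusModel | None = None) -> list[HalfSiteMatch]:
    """Exhaustively locate half-site matches on both strands.

    Every decamer window, forward and reverse-complement, with at most
    ``model.max_mismatches_per_half`` mismatches is reported.  Matches are
    sorted by forward-strand offset, '+' before '-' at equal offset.
    Sequences shorter than 10 nt yield an empty list.
    """
    model = model or ConsensusModel()
    sequence = sequence.upper()
    n = len(sequence)
    out: list[HalfSiteMatch] = []
    if n < HALF_SITE_LEN:
        return out

    fwd_mm = _window_mismatches(sequence, model.half_site_pattern)
    rc = reverse_complement(sequence)
    rev_mm = _window_mismatches(rc, model.half_site_pattern)

    for off in np.flatnonzero(fwd_mm <= model.max_mismatches_per_half):
        off = int(off)
        out.append(
            HalfSiteMatch(off, off + HALF_SITE_LEN, "+",
                          sequence[off:off + HALF_SITE_LEN], int(fwd_mm[off]))
        )
    for roff in np.flatnonzero(rev_mm <= model.max_mismatches_per_half):
        roff = int(roff)
        start = n - HALF_SITE_LEN - roff
        out.append(
            HalfSiteMatch(start, start + HALF_SITE_LEN, "-",
                          rc[roff:roff + HALF_SITE_LEN], int(rev_mm[roff]))
        )
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def _quarter_at(sequence: str, start: int, end: int, strand: str,
                side: str) -> Optional[QuarterMatch]:
    """Conforming pentamer in forward interval [start, end), or None."""
    if start < 0 or end > len(sequence):
        return None
    pent = sequence[start:end]
    if set(pent) - set("ACGTN"):
        return None
    oriented = pent if strand == "+" else reverse_complement(pent)
    # 'head' = RRRCW expected 3' of the half-site, 'tail' = WGYYY expected 5'
    pattern = QUARTER_HEAD if side == "head" else QUARTER_TAIL
    if mismatch_count(oriented, pattern) == 0:
        label = "three_prime" if side == "head" else "five_prime"
        return QuarterMatch(start, end, strand, label, oriented)
    return None


def assemble_sites(
    half_matches: Sequence[HalfSiteMatch],
    sequence: str,
    model: ConsensusModel | None = None,
) -> list[SiteMatch]:
    """Pair half-sites into full sites; classify the rest as 3/4- or half-sites.

    Every same-strand pair of half-sites whose spacer lies within the model
    range becomes a full site (all overlapping assemblies are reported, no
    greedy selection).  A half-site in no such pair but with one adjacent
    spacer-0 conforming quarter (``RRRCW`` 3' of it, or ``WGYYY`` 5' of it,
    in its own reading frame) is a three_quarter site; otherwise it stands
    as a half site.  Output is ordered by start, then spacer, then strand.
    """
    model = model or ConsensusModel()
    sequence = sequence.upper()
    sites: list[SiteMatch] = []
    paired: set[int] = set()

    by_strand: dict[str, list[tuple[int, HalfSiteMatch]]] = {"+": [], "-": []}
    for idx, h in enumerate(half_matches):
        by_strand[h.strand].append((idx, h))

    for strand, items in by_strand.items():
        items.sort(key=lambda t: t[1].start)
        for a_pos, (ia, ha) in enumerate(items):
            for ib, hb in (t for t in items[a_pos + 1:]):
                spacer = hb.start - ha.end
                if spacer < 0:
                    continue
                if spacer > model.max_spacer:
                    break
                # reading order on the strand: '+' left-to-right, '-' right-to-left
                first, second = (ha, hb) if strand == "+" else (hb, ha)
                sites.append(
                    SiteMatch(
                        architecture="full",
                        half_sites=(first, second),
                        spacer=spacer,
                        re20=first.decamer + second.decamer,
                        strand=strand,
                        start=ha.start,
                        end=hb.end,
                    )
                )
                paired.update((ia, ib))

    for idx, h in enumerate(half_matches):
        if idx in paired:
            continue
        if h.strand == "+":
            head = _quarter_at(sequence, h.end, h.end + 5, "+", "head")
            tail = _quarter_at(sequence, h.start - 5, h.start, "+", "tail")
        else:
            head = _quarter_at(sequence, h.start - 5, h.start, "-", "head")
            tail = _quarter_at(sequence, h.end, h.end + 5, "-", "tail")
        quarter = head or tail  # prefer the 3' quarter when both conform
        if quarter is not None:
            if quarter.side == "three_prime":
                re15 = h.decamer + quarter.pentamer
            else:
                re15 = quarter.pentamer + h.decamer
            sites.append(
                SiteMatch(
                    architecture="three_quarter",
                    half_sites=(h,),
                    spacer=0,
                    re20=re15,
                    strand=h.strand,
                    start=min(h.start, quarter.start),
                    end=max(h.end, quarter.end),
                    quarter=quarter,
                )
            )
        else:
            sites.append(
                SiteMatch(
                    architecture="half",
                    half_sites=(h,),
                    spacer=0,
                    re20=h.decamer,
                    strand=h.strand,
                    start=h.start,
                    end=h.end,
                )
            )

    sites.sort(key=lambda s: (s.start, s.spacer, s.strand))
    return sites


def dedupe_sites(sites: Iterable[SiteMatch]) -> list[SiteMatch]:
    """Collapse palindromic strand duplicates onto the forward strand.

    A '-' strand site with the same interval, architecture and oriented
    sequence as a '+' strand site is redundant (the window is its own
    reverse complement) and is dropped.
    """
    kept: list[SiteMatch] = []
    plus = {
        (s.start, s.end, s.architecture, s.re20)
        for s in sites if s.strand == "+"
    }
    for s in sites:
        if s.strand == "-" and (s.start, s.end, s.architecture, s.re20) in plus:
            continue
        kept.append(s)
    return kept


def scan_sequence(
    sequence: str,
    model: ConsensusModel | None = None,
    dedupe: bool = False,
) -> list[SiteMatch]:
    """Scan one sequence end to end: half-site windows, then site assembly."""
    model = model or ConsensusModel()
    halves = scan_half_sites(sequence, model)
    sites = assemble_sites(halves, sequence, model)
    return dedupe_sites(sites) if dedupe else sites
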