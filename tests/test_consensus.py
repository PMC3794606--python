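"""Consensus scanning: window matching, strand handling, site assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import GAACA_FULL, GGGCA_FULL, random_dna
from p53recode import (ConsensusModel, mismatch_count, reverse_complement,
                       scan_half_sites, scan_sequence)
from p53recode.consensus import assemble_sites, dedupe_sites

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


@pytest.mark.parametrize(
    "decamer, pattern, expected",
    [
        ("GGGCATGCCC", "RRRCWWGYYY", 0),
        ("GAGCATGTCC", "RRRCWWGYYY", 0),
        ("CCCCATGCCC", "RRRCWWGYYY", 3),
        ("NNGCATGCCC", "RRRCWWGYYY", 2),  # N conforms to nothing but N
        ("ACGT", "NNNN", 0),
    ],
)
def test_mismatch_count(decamer, pattern, expected):
    assert mismatch_count(decamer, pattern) == expected


def test_mismatch_count_rejects_bad_input():
    with pytest.raises(ValueError):
        mismatch_count("ACGT", "RRRCWWGYYY")
    with pytest.raises(ValueError):
        mismatch_count("GGGCATGCCX", "RRRCWWGYYY")


@pytest.mark.parametrize(
    "seq, expected",
    [("GGGCATGCCC", "GGGCATGCCC"), ("GAACA", "TGTTC"), ("", "")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


@given(dna)
@settings(max_examples=100, deadline=None)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_model_validation():
    with pytest.raises(ValueError):
        ConsensusModel(half_site_pattern="RRRC")
    with pytest.raises(ValueError):
        ConsensusModel(half_site_pattern="RRRCWWGYYZ")
    with pytest.raises(ValueError):
        ConsensusModel(max_spacer=14)


def test_scan_palindromic_full_site(default_model):
    matches = scan_half_sites(GGGCA_FULL, default_model)
    assert [(m.start, m.strand) for m in matches] == [
        (0, "+"), (0, "-"), (10, "+"), (10, "-")
    ]


def test_scan_nonmatching_and_short(default_model):
    assert scan_half_sites("AAAAAAAAAA", default_model) == []
    assert scan_half_sites("ACGTACGT", default_model) == []


@pytest.mark.parametrize("max_mm", [0, 1, 2])
def test_scan_matches_naive_oracle(rng, default_model, max_mm):
    """Exhaustiveness: vectorized scan equals window-by-window enumeration."""
    model = ConsensusModel(max_mismatches_per_half=max_mm)
    for _ in range(5):
        seq = random_dna(rng, 500)
        got = sorted(
            (m.start, m.strand, m.decamer, m.mismatches)
            for m in scan_half_sites(seq, model)
        )
        assert got == oracles.naive_scan(seq, max_mm=max_mm)


def test_strand_symmetry(rng):
    """Scanning the reverse complement mirrors offsets and swaps strands."""
    model = ConsensusModel(max_mismatches_per_half=1)
    seq = random_dna(rng, 300)
    fwd = scan_half_sites(seq, model)
    rev = scan_half_sites(reverse_complement(seq), model)
    n = len(seq)
    mirrored = sorted(
        (n - m.end, "-" if m.strand == "+" else "+", m.decamer, m.mismatches)
        for m in fwd
    )
    assert mirrored == sorted(
        (m.start, m.strand, m.decamer, m.mismatches) for m in rev
    )


def test_full_site_counts_monotone(rng):
    """More spacer or mismatch allowance never loses full sites."""
    seq = random_dna(rng, 400)
    counts = []
    for mm in (0, 1, 2):
        for spacer in (0, 5, 13):
            model = ConsensusModel(max_spacer=spacer, max_mismatches_per_half=mm)
            sites = scan_sequence(seq, model)
            counts.append((mm, spacer,
                           sum(s.architecture == "full" for s in sites)))
    by_key = {(mm, sp): n for mm, sp, n in counts}
    assert by_key[(0, 0)] <= by_key[(0, 5)] <= by_key[(0, 13)]
    assert by_key[(0, 13)] <= by_key[(1, 13)] <= by_key[(2, 13)]


def test_assemble_full_site(default_model):
    halves = scan_half_sites(GAACA_FULL, default_model)
    sites = assemble_sites(halves, GAACA_FULL, default_model)
    full = [s for s in sites if s.architecture == "full"]
    assert {s.strand for s in full} == {"+", "-"}
    for s in full:
        assert s.spacer == 0
        assert s.re20 == GAACA_FULL  # palindromic: same 20-mer on both strands


def test_assemble_spacer_bookkeeping(default_model):
    seq = "GGGCATGCCC" + "ACGTA" + "GGGCATGCCC"
    sites = [s for s in scan_sequence(seq, default_model)
             if s.architecture == "full" and s.strand == "+"]
    assert len(sites) == 1
    assert sites[0].spacer == 5
    assert sites[0].re20 == GGGCA_FULL  # spacer removed from the site 20-mer


def test_assemble_unpaired_half(default_model):
    seq = "TTTTT" + "GGGCATGCCC" + "TTTTT"
    sites = scan_sequence(seq, default_model, dedupe=True)
    assert [s.architecture for s in sites] == ["half"]


def test_assemble_three_quarter_site(default_model):
    """A half-site plus an adjacent conforming RRRCW quarter is a 3/4-site."""
    seq = "GGGCATGCCCGGGCA"
    sites = [s for s in scan_sequence(seq, default_model) if s.strand == "+"]
    assert [s.architecture for s in sites] == ["three_quarter"]
    assert sites[0].re20 == seq
    assert sites[0].quarter.pentamer == "GGGCA"
    # hand enumeration: the only conforming pentamer flank is GGGCA at 10..15
    assert (sites[0].quarter.start, sites[0].quarter.end) == (10, 15)


def test_full_site_re20_conforms(rng):
    """Every full-site 20-mer fits the doubled pattern within 2x the budget."""
    model = ConsensusModel(max_mismatches_per_half=2)
    doubled = model.half_site_pattern * 2
    seq = random_dna(rng, 600)
    for s in scan_sequence(seq, model):
        if s.architecture == "full":
            assert mismatch_count(s.re20, doubled) <= 4


def test_dedupe_collapses_palindromes(default_model):
    sites = scan_sequence(GGGCA_FULL, default_model)
    deduped = dedupe_sites(sites)
    assert all(s.strand == "+" for s in deduped)
    assert {s.re20 for s in deduped} == {s.re20 for s in sites}
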