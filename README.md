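# p53recode

Tools for the **sequence code of p53-family response elements (REs)** — the
DNA features that determine how strongly p53, p63 and p73 (and their
altered-specificity mutants) transactivate a target site.

The canonical RE is two decameric half-sites separated by a short spacer,

```
RRRCWWGYYY -(n=0..13)- RRRCWWGYYY      (R = A/G, W = A/T, Y = C/T)
```

Within the spacer-removed 20-mer, two dinucleotide features carry a
transactivation code for the p73 change-of-spectrum mutant S139F (and its
p53 S121F / p63 S150F counterparts):

* the **RY signature** — `GG` at positions 2–3 and/or 12–13, `CC` at 8–9
  and/or 18–19 (count 0–4 per full site). REs with no RY signature are
  transactivated *less* by S139F than by wild type; REs with one or more
  are transactivated *more*, scaling with the count;
* the **WW core motif** — the central dinucleotide of each `CWWG` core
  (positions 5–6 and 15–16), with AT the most active core for the
  wild-type protein and AA/TT favouring S139F enhancement.

The package provides, as a library plus a `p53recode` command line:

| module | what it does |
| --- | --- |
| `consensus` | exhaustive both-strand scanning for full, ¾- and ½-sites against the degenerate consensus, with spacer and mismatch bookkeeping |
| `signature` | RY/WW signature profiles and the S139F response prediction |
| `stats` | fold induction, enhanced/reduced/similar ratio classification (thresholds 1.5 / 0.67), exact two-sided Fisher association at half-site resolution, Spearman RY-dose trend |
| `logo` | paired-dinucleotide logos (frequency-proportional, SVG) over aligned RE sets, with the per-position mononucleotide matrix as baseline |
| `binding` | fraction bound from fluorescence polarization and cooperative Hill fits (EC50 ≡ K_d, Hill coefficient h, censoring for unsaturated curves) |
| `simulate` | seeded generators for RE panels, reporter activities and titration curves with exact truth labels |
| `io` / `cli` | FASTA/TSV/BED6/JSON/SVG readers and writers and the umbrella CLI |

## Worked example

```python
from p53recode import ry_profile, s139f_predict, fisher_exact_two_sided

for name, seq in [("GGGCA full site", "GGGCATGCCCGGGCATGCCC"),
                  ("GAACA full site", "GAACATGTTCGAACATGTTC"),
                  ("ConP",            "GGGCATGTCCGAGCATGTCC")]:
    prof = ry_profile(seq)
    pred = s139f_predict(prof)
    print(f"{name:16s} RY {prof.ry_count}/4  WW {prof.ww_motifs}"
          f"  -> {pred.predicted_class} (score {pred.score})")
print("Fisher p (28/44 vs 5/18):",
      round(fisher_exact_two_sided([[28, 16], [5, 13]]), 3))
```

prints

```
GGGCA full site  RY 4/4  WW ('AT', 'AT')  -> enhanced (score 4.0)
GAACA full site  RY 0/4  WW ('AT', 'AT')  -> reduced (score 0.0)
ConP             RY 1/4  WW ('AT', 'AT')  -> enhanced (score 1.0)
Fisher p (28/44 vs 5/18): 0.013
```

The GGGCA full site carries all four RY signatures and is predicted
enhanced under S139F; the GAACA full site carries none and is predicted
reduced; ConP — the ConE consensus permutation (two repeats of
`GAGCATGTCC`) with a single A→G change at position 2 — gains one RY
signature and flips to enhanced. The Fisher line tests whether AA/TT core
motifs are enriched among the half-sites of enhanced REs (28 of 44) versus
reduced REs (5 of 18).

Binding curves work the same way end to end: simulate (or load) an
18-point titration, fit, and compare affinities:

```python
from p53recode import fit_hill, affinity_ratio
from p53recode.simulate import generate_binding_curve

tight = fit_hill(generate_binding_curve(230, 1.9, noise_sd=0.02, replicates=3, seed=1))
weak  = fit_hill(generate_binding_curve(4480, 1.7, noise_sd=0.02, replicates=3, seed=2))
print(f"tight: Kd {tight.ec50:.0f} nM, h {tight.hill:.2f}; "
      f"weak: Kd {weak.ec50:.0f} nM, h {weak.hill:.2f}")
print(f"affinity ratio: {affinity_ratio(tight, weak).value:.1f}")
```

```
tight: Kd 228 nM, h 2.02; weak: Kd 4450 nM, h 1.72
affinity ratio: 19.5
```

The same operations are available from the shell, e.g.

```sh
p53recode scan --fasta promoters.fa --max-spacer 13 --dedupe
p53recode score --table re_panel.tsv
p53recode simulate activities --seed 7 --out sim/
p53recode classify --table sim/activities.tsv
p53recode assoc --classified sim/truth.tsv --feature ry
p53recode fitbind --curve titration.tsv
```

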