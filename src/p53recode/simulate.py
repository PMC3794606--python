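"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators emulate the study's measurements without any downloads:

* :func:`generate_re_set` — response-element sets with controlled RY-count
  and WW-motif composition (the composition of an RE panel like the
  48-RE yeast panel), each with an exact truth record;
* :func:`generate_transactivation` — noisy WT and mutant reporter
  activities whose log mutant/WT ratio depends linearly on the RY count
  and on the presence of an AA/TT core, the directionality observed for
  the change-of-spectrum allele;
* :func:`generate_binding_curve` — fluorescence-polarization-style
  titrations on an 18-point grid from 0 to 20 000 nM.

Every generator is a pure function of its configuration, including the
seed: identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import BindingCurve, hill_fraction
from .signature import RY_SLOTS, ry_profile, s139f_predict
from .stats import classify_ratio

__all__ = [
    "SyntheticConfig",
    "generate_re_set",
    "generate_transactivation",
    "generate_binding_curve",
    "default_titration_grid",
]

_R, _Y, _W = "AG", "CT", "AT"
#: Consensus base class per 0-based position of the 20-mer.
_POSITION_CLASS = (_R, _R, _R, "C", _W, _W, "G", _Y, _Y, _Y) * 2

#: 0-based positions that are neither an RY slot, a WW position nor the
#: invariant C/G of a core; mismatches are confined here so that truth
#: labels stay exact.
_FREE_POSITIONS = (0, 9, 10, 19)

_RY_SLOT_POS = {1: "R", 2: "R", 7: "Y", 8: "Y", 11: "R", 12: "R", 17: "Y", 18: "Y"}
_WW_POS = {4, 5, 14, 15}

# pairs drawn for a slot forced OFF: consensus-conforming but not the signature
_RR_OFF = ("AA", "AG", "GA")
_YY_OFF = ("TT", "TC", "CT")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study.

    The effect model for the change-of-spectrum allele is
    ``log ratio = beta0 + beta_ry * ry_count + beta_ww * [any WW in {AA,TT}]
    + Normal(0, noise_sd)``; the defaults (beta0 = log 0.5, beta_ry =
    log 1.6, beta_ww = log 1.3) place the expected class at 'reduced' for
    0/4-RY REs and 'enhanced' from 3/4 RY (2/4 with the AA/TT bonus),
    reproducing the qualitative dose dependence of the code.  WT fold
    inductions are lognormal around ~12-fold, the scale of a responsive
    reporter over the empty-vector background.
    """

    seed: int = 0
    n_res: int = 50
    ry_mix: tuple[float, float, float, float, float] = (0.25, 0.20, 0.20, 0.20, 0.15)
    ww_mix: Mapping[str, float] = field(
        default_factory=lambda: {"AT": 0.25, "TA": 0.25, "AA": 0.25, "TT": 0.25}
    )
    spacer_mix: tuple[float, ...] = (1.0,)  # point mass at spacer 0
    mismatch_rate: float = 0.1
    beta0: float = math.log(0.5)
    beta_ry: float = math.log(1.6)
    beta_ww: float = math.log(1.3)
    noise_sd: float = 0.2
    wt_log_mean: float = math.log(12.0)
    wt_log_sd: float = 0.5
    replicates: int = 4
    background: float = 100.0

    def __post_init__(self) -> None:
        for name, dist in (("ry_mix", self.ry_mix),
                           ("ww_mix", tuple(self.ww_mix.values())),
                           ("spacer_mix", self.spacer_mix)):
            if any(p < 0 for p in dist):
                raise ValueError(f"{name} has negative mass")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.ww_mix) - {"AT", "TA", "AA", "TT"}:
            raise ValueError("ww_mix labels must be AT/TA/AA/TT")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must lie in [0, 1]")
        if len(self.spacer_mix) > 14:
            raise ValueError("spacer_mix supports spacers 0-13 only")
        if self.n_res < 1 or self.replicates < 1:
            raise ValueError("n_res and replicates must be positive")


def _sample_re20(rng: np.random.Generator, ry_count: int,
                 ww: tuple[str, str], mismatch_rate: float) -> str:
    """One 20-mer with exactly ``ry_count`` RY signatures and given WW cores."""
    bases = [rng.choice(list(cls)) for cls in _POSITION_CLASS]
    on = rng.choice(4, size=ry_count, replace=False) if 0 < ry_count < 4 else (
        np.arange(4) if ry_count == 4 else np.array([], dtype=int)
    )
    on_set = set(int(i) for i in on)
    for slot_idx, (_, sl, dinuc) in enumerate(RY_SLOTS):
        if slot_idx in on_set:
            pair = dinuc
        else:
            pool = _RR_OFF if dinuc == "GG" else _YY_OFF
            pair = pool[rng.integers(len(pool))]
        bases[sl.start], bases[sl.start + 1] = pair[0], pair[1]
    for half, sl in enumerate((slice(4, 6), slice(14, 16))):
        bases[sl.start], bases[sl.start + 1] = ww[half][0], ww[half][1]
    for pos in _FREE_POSITIONS:
        if rng.random() < mismatch_rate:
            off_class = [b for b in "ACGT" if b not in _POSITION_CLASS[pos]]
            bases[pos] = off_class[rng.integers(len(off_class))]
    return "".join(bases)


def generate_re_set(config: SyntheticConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Sample a panel of REs; return (name -> sequence, truth table).

    Sequences carry the sampled spacer (random bases inserted between the
    half-sites); the truth table records the spacer-removed 20-mer, the
    forced RY count and WW labels, and the class the effect model implies
    at zero noise.  Recomputing :func:`~p53recode.signature.ry_profile` on
    any generated 20-mer reproduces its truth row exactly, because
    mismatches never touch signature or core positions.
    """
    rng = np.random.default_rng(config.seed)
    ww_labels = sorted(config.ww_mix)
    ww_probs = [config.ww_mix[l] for l in ww_labels]

    seqs: dict[str, str] = {}
    rows = []
    for i in range(config.n_res):
        ry_count = int(rng.choice(5, p=config.ry_mix))
        ww = tuple(str(rng.choice(ww_labels, p=ww_probs)) for _ in range(2))
        re20 = _sample_re20(rng, ry_count, ww, config.mismatch_rate)
        spacer = int(rng.choice(len(config.spacer_mix), p=config.spacer_mix))
        spacer_seq = "".join(rng.choice(list("ACGT")) for _ in range(spacer))
        name = f"sre{i:04d}"
        seqs[name] = re20[:10] + spacer_seq + re20[10:]

        any_ww = any(w in ("AA", "TT") for w in ww)
        det_ratio = math.exp(
            config.beta0 + config.beta_ry * ry_count + config.beta_ww * any_ww
        )
        flags = ry_profile(re20).ry_flags
        rows.append(
            {
                "name": name,
                "re20": re20,
                "spacer": spacer,
                "ry_count": ry_count,
                "ww1": ww[0],
                "ww2": ww[1],
                "ry_half1": flags[0] or flags[1],
                "ry_half2": flags[2] or flags[3],
                "any_ww_aatt": any_ww,
                "true_class": classify_ratio(det_ratio, 1.0).klass,
            }
        )
    return seqs, pd.DataFrame(rows)


def generate_transactivation(
    truth: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate WT and mutant reporter activities for a generated panel.

    Returns ``(activities, truth_out)``: a long-format activities table
    (re_name, allele, replicate, activity, normalizer, background) and the
    truth table augmented with the drawn fold inductions, realized ratio
    and realized class.  WT fold induction is lognormal; the mutant/WT
    log ratio follows the linear RY/WW effect model with Gaussian noise.
    Replicate readings are the fold induction times the background (a
    measurement-noise-free rendering: all stochasticity lives in the
    fold-induction draw, see the effect model).
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng((config.seed * 2654435761 + 1) % 2**31)
    truth_out = truth.copy()
    wt = np.exp(rng.normal(config.wt_log_mean, config.wt_log_sd, len(truth)))
    log_ratio = (
        config.beta0
        + config.beta_ry * truth["ry_count"].to_numpy()
        + config.beta_ww * truth["any_ww_aatt"].to_numpy().astype(float)
        + rng.normal(0.0, config.noise_sd, len(truth))
    )
    mut = wt * np.exp(log_ratio)
    truth_out["wt_fold"] = wt
    truth_out["mut_fold"] = mut
    truth_out["ratio"] = mut / wt
    truth_out["klass"] = [classify_ratio(m, w).klass for m, w in zip(mut, wt)]

    records = []
    for name, wt_f, mut_f in zip(truth["name"], wt, mut):
        for allele, fold in (("WT", wt_f), ("S139F", mut_f)):
            for rep in range(config.replicates):
                records.append(
                    {
                        "re_name": name,
                        "allele": allele,
                        "replicate": rep + 1,
                        "activity": fold * config.background,
                        "normalizer": 1.0,
                        "background": config.background,
                    }
                )
    return pd.DataFrame(records), truth_out


def default_titration_grid(top: float = 20000.0, n: int = 18) -> np.ndarray:
    """Zero anchor plus (n-1) log-spaced concentrations from 1 nM to ``top``."""
    return np.concatenate([[0.0], np.logspace(0.0, math.log10(top), n - 1)])


def generate_binding_curve(
    ec50: float,
    hill: float,
    f0: float = 0.0,
    fmax: float = 1.0,
    grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    dna_conc: float = 50.0,
    stoichiometry: str = "tetramer_per_fullsite",
) -> BindingCurve:
    """Hill-curve titration with i.i.d. Gaussian noise per replicate.

    The default grid is the 18-point design: a zero anchor plus 17
    log-spaced points from 1 to 20 000 nM.  With ``noise_sd = 0`` the
    response equals :func:`~p53recode.binding.hill_fraction` exactly.
    """
    conc = np.asarray(default_titration_grid() if grid is None else grid, dtype=float)
    rng = np.random.default_rng(seed)
    clean = hill_fraction(conc, ec50, hill, f0, fmax)
    noisy = clean[:, None] + rng.normal(0.0, noise_sd, (conc.size, replicates))
    noisy = np.clip(noisy, -0.1, 1.1)
    return BindingCurve(
        concentrations=tuple(float(c) for c in conc),
        response=tuple(tuple(float(v) for v in row) for row in noisy),
        dna_conc=dna_conc,
        stoichiometry=stoichiometry,
    )
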