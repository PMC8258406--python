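"""Primer-level quantitative metrics.

GC content with degeneracy weighting, nearest-neighbor melting temperature
under explicit ionic conditions, linguistic complexity, and a 3'-anchored
self-dimer screen.

Melting temperatures use the unified SantaLucia (1998) nearest-neighbor
parameters. Divalent cations are folded into an effective monovalent
concentration (von Ahsen: Mon + 120*sqrt([Mg2+])) applied as an entropic
salt correction. Degenerate positions are handled analytically in two ways:

* each nearest-neighbor stack containing ambiguity codes contributes the
  arithmetic mean of dH and dS over its expansions (the exact average over
  the pool, at O(L) cost instead of enumerating 4^d variants);
* a degenerate primer is a *mixture*, so the concentration of variants able
  to anneal at any one site is far below the nominal primer concentration.
  We charge half the ideal mixing entropy: effective CT = CT / sqrt(D),
  where D is the pool degeneracy (4^d for d fully degenerate bases). The
  full penalty (CT/D) would assume only the exact complement anneals; no
  penalty would assume the whole pool does. Near-matching variants anneal
  partially, so the operative concentration lies between those limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .seqcore import (
    IUPAC_EXPAND,
    DegenerateSequenceError,
    reverse_complement,
    validate_dna,
    validate_plain_dna,
)

R_GAS = 1.987  # cal / (mol K)

# SantaLucia PNAS 1998 unified parameters: (dH kcal/mol, dS cal/mol/K)
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
NN_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}

#: expected G+C fraction contributed by each IUPAC code
GC_WEIGHT = {
    "G": 1.0, "C": 1.0, "S": 1.0,
    "A": 0.0, "T": 0.0, "W": 0.0,
    "N": 0.5, "R": 0.5, "Y": 0.5, "K": 0.5, "M": 0.5,
    "B": 2 / 3, "V": 2 / 3, "D": 1 / 3, "H": 1 / 3,
}


@dataclass(frozen=True)
class ThermoConditions:
    """Ionic/primer conditions under which a melting temperature is computed."""

    monovalent_mM: float = 50.0
    divalent_mM: float = 2.0
    primer_uM: float = 0.5

    def __post_init__(self) -> None:
        if min(self.monovalent_mM, self.divalent_mM, self.primer_uM) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def effective_monovalent_M(self) -> float:
        """Monovalent-equivalent salt (M), divalent folded in via 120*sqrt(Mg)."""
        return (self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)) / 1000.0


#: conditions used for walking-primer cores: 50 mM K+/NH4+, 2 mM Mg2+, 0.5 uM primer
PST_CONDITIONS = ThermoConditions(50.0, 2.0, 0.5)
#: conditions used for sequence-specific primers: 50 mM monovalent, no divalent, 0.25 uM
SSP_CONDITIONS = ThermoConditions(50.0, 0.0, 0.25)


@dataclass(frozen=True)
class PrimerMetrics:
    tm_C: float
    gc_percent: float
    lc_percent: int | None
    self_dimer_flag: bool
    self_dimer_len: int

    def __post_init__(self) -> None:
        if not 0 <= self.gc_percent <= 100:
            raise ValueError("gc_percent out of [0, 100]")


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(seq: str) -> float:
    """Percent G+C, ambiguity codes weighted by expected GC fraction.

    Each base contributes its expected G/C content (N and the half-GC codes
    count 0.5, B/V count 2/3, D/H 1/3); the percentage is rounded half-up to
    one decimal so that e.g. a 10xN + GACGTC core gives 9/16 = 56.3.
    """
    validate_dna(seq)
    total = sum(GC_WEIGHT[b] for b in seq.upper())
    return _round_half_up(100.0 * total / len(seq), 1)


def degeneracy(seq: str) -> int:
    """Number of distinct plain sequences the IUPAC string stands for."""
    validate_dna(seq)
    d = 1
    for b in seq.upper():
        d *= len(IUPAC_EXPAND[b])
    return d


def _mean_params(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    n = len(pairs)
    return sum(p[0] for p in pairs) / n, sum(p[1] for p in pairs) / n


def melting_temperature(
    seq: str,
    cond: ThermoConditions = PST_CONDITIONS,
    *,
    mixing_entropy_fraction: float = 0.5,
) -> float:
    """Nearest-neighbor Tm (degrees C) of ``seq`` under ``cond``.

    Degenerate stacks are averaged analytically over their expansions;
    ``mixing_entropy_fraction`` sets how much of the pool's ideal mixing
    entropy is charged as an effective-concentration penalty (see module
    docstring). Sequences shorter than 8 nt are rejected: the two-state NN
    model is not meaningful for very short duplexes.
    """
    validate_dna(seq)
    s = seq.upper()
    if len(s) < 8:
        raise ValueError(f"sequence too short for NN Tm: {len(s)} < 8 nt")

    dH = 0.0  # kcal/mol
    dS = 0.0  # cal/mol/K
    for terminal in (s[0], s[-1]):
        h, sv = _mean_params([NN_INIT[b] for b in IUPAC_EXPAND[terminal]])
        dH += h
        dS += sv
    for i in range(len(s) - 1):
        stacks = [
            NN_PARAMS[a + b]
            for a in IUPAC_EXPAND[s[i]]
            for b in IUPAC_EXPAND[s[i + 1]]
        ]
        h, sv = _mean_params(stacks)
        dH += h
        dS += sv

    plain = degeneracy(s) == 1
    if plain and s == reverse_complement(s):
        dS += -1.4  # self-complementary symmetry correction

    dS += 0.368 * (len(s) - 1) * math.log(cond.effective_monovalent_M)

    ct = cond.primer_uM * 1e-6
    if ct <= 0:
        raise ValueError("primer concentration must be positive")
    ct_eff = ct * degeneracy(s) ** (-mixing_entropy_fraction)
    return dH * 1000.0 / (dS + R_GAS * math.log(ct_eff)) - 273.15


def linguistic_complexity(seq: str) -> int:
    """Substring-vocabulary richness as a percent, rounded to integer.

    100 x (distinct substrings over all lengths 1..L) / max possible for a
    length-L DNA string, where the maximum is sum_k min(4^k, L-k+1).
    Saturated sequences (every substring distinct up to the 4^k bound)
    score 100; a homopolymer of length 6 scores 6/19 = 32.
    """
    validate_plain_dna(seq)
    s = seq.upper()
    L = len(s)
    observed = sum(
        len({s[i : i + k] for i in range(L - k + 1)}) for k in range(1, L + 1)
    )
    maximum = sum(min(4**k, L - k + 1) for k in range(1, L + 1))
    return int(_round_half_up(100.0 * observed / maximum, 0))


def self_dimer_check(primer: str, threshold: int = 5) -> tuple[bool, int]:
    """3'-anchored self-dimer screen.

    Flags a primer whose 3'-terminal k-mer (k >= ``threshold``) is
    reverse-complementary to any window of the same primer, i.e. the 3' end
    can prime on a second copy of itself. Returns ``(flagged, worst_k)``
    where ``worst_k`` is the longest such 3'-anchored duplex (0 if none).
    Note a palindromic 3' terminus always self-pairs, which is why this
    screen is meant for sequence-specific primers, not walking primers.
    """
    validate_dna(primer)
    p = primer.upper()
    if len(p) < 8:
        raise ValueError(f"primer too short for dimer screen: {len(p)} < 8 nt")
    worst = 0
    for k in range(threshold, len(p) + 1):
        if reverse_complement(p[-k:]) in p:
            worst = k
    return worst >= threshold, worst


def primer_metrics(
    core: str,
    cond: ThermoConditions = PST_CONDITIONS,
    dimer_threshold: int = 5,
) -> PrimerMetrics:
    """All metrics for one primer core (LC only where the core is defined)."""
    try:
        lc: int | None = linguistic_complexity(core)
    except DegenerateSequenceError:
        lc = None
    flagged, worst = self_dimer_check(core, threshold=dimer_threshold)
    return PrimerMetrics(
        tm_C=_round_half_up(melting_temperature(core, cond), 1),
        gc_percent=gc_content(core),
        lc_percent=lc,
        self_dimer_flag=flagged,
        self_dimer_len=worst,
    )


def metrics_table(
    primers: Iterable[tuple[str, str, str]],
    cond: ThermoConditions = PST_CONDITIONS,
) -> pd.DataFrame:
    """Tabulate metrics for ``(id, core_sequence, site_label)`` triples.

    Columns mirror the shipped primer catalog: id, sequence, site, tm_C,
    gc_percent, lc_percent.
    """
    rows = []
    for pid, core, site in primers:
        m = primer_metrics(core, cond)
        rows.append(
            {
                "id": pid,
                "sequence": core,
                "site": site,
                "tm_C": m.tm_C,
                "gc_percent": m.gc_percent,
                "lc_percent": m.lc_percent,
            }
        )
    return pd.DataFrame(rows)
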