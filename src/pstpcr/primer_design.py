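"""Construction and validation of the two primer classes.

A walking (PST) primer is adaptor + fully degenerate run + 3' palindrome;
its "core" (degenerate run + palindrome) is the only part expected to pair
with template. A sequence-specific primer (SSP) is the same adaptor + a
defined hybridizing sequence targeting a known sequence tag. Both carry the
identical 5' adaptor so a single universal tail primer can reamplify every
first-round product.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import seqcore, thermo
from .seqcore import GenomicInterval, validate_dna, validate_plain_dna
from .thermo import (
    PST_CONDITIONS,
    SSP_CONDITIONS,
    PrimerMetrics,
    ThermoConditions,
    melting_temperature,
    primer_metrics,
)

#: the invariable 19-nt adaptor shared by every shipped primer
DEFAULT_ADAPTOR = "GTTGCGGCAGGTCCTCACC"

MIN_DEGENERATE_LEN = 6
MAX_DEGENERATE_LEN = 12


class DesignError(ValueError):
    """A primer violates a structural design constraint."""


@dataclass(frozen=True)
class PSTPrimer:
    """Walking primer: adaptor + N-run + self-reverse-complementary 3' end."""

    id: str
    palindrome: str
    degenerate_len: int = 10
    adaptor: str = DEFAULT_ADAPTOR
    restriction_site_name: str | None = None
    metrics: PrimerMetrics | None = None

    @property
    def core(self) -> str:
        return "N" * self.degenerate_len + self.palindrome.upper()

    @property
    def sequence(self) -> str:
        return self.adaptor.upper() + "n" * self.degenerate_len + self.palindrome.upper()


@dataclass(frozen=True)
class SSPrimer:
    """Tailed sequence-specific primer; hybridizing part is plain ACGT."""

    id: str
    hybridizing: str
    adaptor: str = DEFAULT_ADAPTOR
    target_name: str | None = None
    target_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        validate_plain_dna(self.hybridizing, name="hybridizing sequence")
        validate_dna(self.adaptor, name="adaptor")

    @property
    def sequence(self) -> str:
        """Full primer with the table case convention (adaptor upper, target lower)."""
        return self.adaptor.upper() + self.hybridizing.lower()


def make_pst_primer(
    palindrome: str,
    degenerate_len: int = 10,
    adaptor: str = DEFAULT_ADAPTOR,
    id: str | None = None,
    restriction_site_name: str | None = None,
    cond: ThermoConditions = PST_CONDITIONS,
) -> PSTPrimer:
    """Assemble a walking primer and compute its core metrics.

    The 3' end must be self-reverse-complementary (6 or 8 nt) and the
    degenerate run 6-12 nt; every shipped primer uses 10.
    """
    validate_plain_dna(palindrome, name="palindrome")
    if len(palindrome) not in (6, 8):
        raise DesignError(
            f"palindrome must be 6 or 8 nt, got {len(palindrome)}"
        )
    if not seqcore.is_palindrome(palindrome):
        raise DesignError(
            f"{palindrome!r} is not self-reverse-complementary"
        )
    if not MIN_DEGENERATE_LEN <= degenerate_len <= MAX_DEGENERATE_LEN:
        raise DesignError(
            f"degenerate_len must be in [{MIN_DEGENERATE_LEN}, "
            f"{MAX_DEGENERATE_LEN}], got {degenerate_len}"
        )
    validate_dna(adaptor, name="adaptor")
    primer = PSTPrimer(
        id=id or f"pst_{palindrome.upper()}",
        palindrome=palindrome.upper(),
        degenerate_len=degenerate_len,
        adaptor=adaptor.upper(),
        restriction_site_name=restriction_site_name,
    )
    core = primer.core
    return PSTPrimer(
        id=primer.id,
        palindrome=primer.palindrome,
        degenerate_len=degenerate_len,
        adaptor=primer.adaptor,
        restriction_site_name=restriction_site_name,
        metrics=primer_metrics(core, cond),
    )


def ssp_from_table_sequence(
    seq: str,
    id: str,
    target_name: str | None = None,
) -> SSPrimer:
    """Split a cased full-length table entry into adaptor + hybridizing part.

    Uppercase prefix = adaptor, lowercase suffix = target-hybridizing
    region, per the shipped table convention.
    """
    m = re.fullmatch(r"([A-Z]+)([a-z]+)", seq)
    if not m:
        raise DesignError(
            "SSP table sequence must be UPPERCASE adaptor followed by "
            f"lowercase hybridizing part, got {seq!r}"
        )
    return SSPrimer(
        id=id, adaptor=m.group(1), hybridizing=m.group(2).upper(),
        target_name=target_name,
    )


# ---------------------------------------------------------------------------
# SSP design rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignRules:
    """Quantitative SSP selection rules.

    Defaults follow the published screening protocol (25-35 nt, 40-60% GC,
    Tm >= 65 C); :data:`RELAXED_RULES` carries the alternative operating
    band (26-32 nt, 40-65% GC). The two 12-mer sub-rules (3' 12-mer Tm
    should stay below, 5' 12-mer Tm above, 42 C) are preferences and
    reported as warnings unless ``strict`` validation is requested.
    """

    ssp_len_range: tuple[int, int] = (25, 35)
    ssp_gc_range: tuple[float, float] = (40.0, 60.0)
    ssp_tm_min: float = 65.0
    three_prime_12mer_tm_max: float = 42.0
    five_prime_12mer_tm_min: float = 42.0
    pst_core_gc_range: tuple[float, float] = (67.0, 100.0)
    dimer_threshold: int = 5

    def __post_init__(self) -> None:
        for lo, hi in (self.ssp_len_range, self.ssp_gc_range, self.pst_core_gc_range):
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi})")


#: the alternative recommended operating band for SSPs
RELAXED_RULES = DesignRules(ssp_len_range=(26, 32), ssp_gc_range=(40.0, 65.0))


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    value: float | int | bool
    requirement: str
    passed: bool
    advisory: bool = False


@dataclass(frozen=True)
class SSPReport:
    primer_id: str
    checks: tuple[RuleCheck, ...]
    strict: bool = False

    @property
    def verdict(self) -> bool:
        return all(
            c.passed for c in self.checks if self.strict or not c.advisory
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "primer_id": self.primer_id,
                    "rule": c.rule,
                    "value": c.value,
                    "requirement": c.requirement,
                    "passed": c.passed,
                    "advisory": c.advisory,
                }
                for c in self.checks
            ]
        )


def validate_ssp(
    primer: SSPrimer,
    rules: DesignRules | None = None,
    cond: ThermoConditions = SSP_CONDITIONS,
    strict: bool = False,
) -> SSPReport:
    """Per-rule report for one SSP; reports rather than raises on failure."""
    rules = rules or DesignRules()
    hyb = primer.hybridizing.upper()
    checks: list[RuleCheck] = []

    n = len(hyb)
    lo, hi = rules.ssp_len_range
    checks.append(RuleCheck("length", n, f"{lo}-{hi} nt", lo <= n <= hi))

    gc = thermo.gc_content(hyb)
    glo, ghi = rules.ssp_gc_range
    checks.append(RuleCheck("gc", gc, f"{glo}-{ghi} %", glo <= gc <= ghi))

    tm = thermo._round_half_up(melting_temperature(hyb, cond), 1)
    checks.append(RuleCheck("tm", tm, f">= {rules.ssp_tm_min} C", tm >= rules.ssp_tm_min))

    if n >= 12:
        tm3 = thermo._round_half_up(melting_temperature(hyb[-12:], cond), 1)
        checks.append(
            RuleCheck(
                "three_prime_12mer_tm", tm3,
                f"<= {rules.three_prime_12mer_tm_max} C",
                tm3 <= rules.three_prime_12mer_tm_max, advisory=True,
            )
        )
        tm5 = thermo._round_half_up(melting_temperature(hyb[:12], cond), 1)
        checks.append(
            RuleCheck(
                "five_prime_12mer_tm", tm5,
                f">= {rules.five_prime_12mer_tm_min} C",
                tm5 >= rules.five_prime_12mer_tm_min, advisory=True,
            )
        )

    flagged, worst = thermo.self_dimer_check(hyb, threshold=rules.dimer_threshold)
    checks.append(
        RuleCheck(
            "self_dimer", worst,
            f"no 3'-anchored duplex >= {rules.dimer_threshold} nt", not flagged,
        )
    )
    return SSPReport(primer_id=primer.id, checks=tuple(checks), strict=strict)


class UnderScreeningWarning(UserWarning):
    """Fewer walking primers supplied than the recommended screening breadth."""


RECOMMENDED_MIN_PST = 4


def screen_plan(
    ssps: list[SSPrimer], pst_primers: list[PSTPrimer]
) -> pd.DataFrame:
    """Full SSP x PST cross-product as a plate plan (one reaction per pair)."""
    if not ssps or not pst_primers:
        raise ValueError("screen_plan requires at least one SSP and one PST primer")
    if len(pst_primers) < RECOMMENDED_MIN_PST:
        warnings.warn(
            f"only {len(pst_primers)} PST primer(s) supplied; screening at "
            f"least {RECOMMENDED_MIN_PST} is recommended",
            UnderScreeningWarning,
            stacklevel=2,
        )
    rows = []
    for i, ssp in enumerate(ssps):
        for j, pst in enumerate(pst_primers):
            k = i * len(pst_primers) + j
            rows.append(
                {
                    "pair_id": f"{ssp.id}x{pst.id}",
                    "well": f"{chr(ord('A') + k // 12 % 8)}{k % 12 + 1}",
                    "ssp_id": ssp.id,
                    "pst_id": pst.id,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shipped primer catalog
# ---------------------------------------------------------------------------

def load_primer_catalog(which: str = "pst") -> pd.DataFrame:
    """Raw shipped primer table (``'pst'`` incl. tail row, or ``'ssp'``)."""
    fname = {"pst": "pst_primers.tsv", "ssp": "ssp_primers.tsv"}[which]
    with resources.as_file(resources.files("pstpcr.data") / fname) as path:
        return seqcore.read_primer_table(path)


def load_pst_primers(cond: ThermoConditions = PST_CONDITIONS) -> list[PSTPrimer]:
    """The 25 shipped walking primers as constructed objects."""
    df = load_primer_catalog("pst")
    primers = []
    for _, row in df[df["kind"] == "PST"].iterrows():
        m = re.fullmatch(r"([A-Z]+)(n+)([A-Z]+)", row["sequence"])
        if not m:
            raise DesignError(f"malformed PST table sequence: {row['sequence']!r}")
        primers.append(
            make_pst_primer(
                palindrome=m.group(3),
                degenerate_len=len(m.group(2)),
                adaptor=m.group(1),
                id=str(row["id"]),
                restriction_site_name=row["annotation"],
                cond=cond,
            )
        )
    return primers


def load_ssp_primers() -> list[SSPrimer]:
    """The 3 shipped Ac-targeting SSPs."""
    df = load_primer_catalog("ssp")
    return [
        ssp_from_table_sequence(
            row["sequence"], id=str(row["id"]), target_name=row["annotation"]
        )
        for _, row in df.iterrows()
    ]


def load_tail_primer() -> str:
    """The universal second-round (adaptor) primer sequence."""
    df = load_primer_catalog("pst")
    tail = df[df["kind"] == "TAIL"]
    return str(tail.iloc[0]["sequence"])
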