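"""Two-round PST-PCR simulation: predicted amplicons with class and yield.

Round 1 begins with a linear phase at high annealing temperature in which
only the sequence-specific primer extends, accumulating single-stranded
copies; lowering the temperature then lets the walking primer join for a
few exponential cycles. Products are classed as

* ``SPECIFIC``   - one SSP end, one walking-primer (palindrome) end;
* ``IRAP_LIKE``  - two inverted SSP target copies facing each other;
* ``RAPD_LIKE``  - two palindrome sites facing each other; these only
  arise when the exponential phase runs past the ~20-cycle threshold.

Round 2 reamplifies, with a single universal tail primer, every product
that carries the adaptor on both ends.

The yield model (logistic annealing efficiency, multiplicative cycles) is
deliberately simple: it orders products and expresses phase semantics but
never changes product membership.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .primer_design import PSTPrimer, SSPrimer
from .seqcore import GenomicInterval, reverse_complement, write_bed, write_fasta
from .site_scan import LEFT, RIGHT, AnnealingSite, find_pst_sites, find_ssp_sites
from .thermo import PST_CONDITIONS, ThermoConditions, melting_temperature

logger = logging.getLogger(__name__)

SPECIFIC = "SPECIFIC"
RAPD_LIKE = "RAPD_LIKE"
IRAP_LIKE = "IRAP_LIKE"


class ProtocolWarning(UserWarning):
    """A cycling parameter is outside the recommended operating envelope."""


@dataclass(frozen=True)
class ThermalProfile:
    """Cycling profile for the two-round process.

    Defaults reproduce the published protocol: 20 linear cycles annealing
    at 72 C, 3 exponential cycles at 60 C (recommended range 1-3, at most
    5), then 28 single-primer cycles at 72 C. ``rapd_cycle_threshold`` is
    the exponential-cycle count past which palindrome-palindrome
    (RAPD-like) side products become possible.
    """

    round1_linear_cycles: int = 20
    round1_linear_anneal_C: float = 72.0
    round1_exp_cycles: int = 3
    round1_exp_anneal_C: float = 60.0
    round2_cycles: int = 28
    round2_anneal_C: float = 72.0
    rapd_cycle_threshold: int = 20

    def __post_init__(self) -> None:
        if min(self.round1_linear_cycles, self.round1_exp_cycles, self.round2_cycles) < 0:
            raise ValueError("cycle counts must be non-negative")
        if self.round1_linear_anneal_C <= self.round1_exp_anneal_C:
            raise ValueError(
                "linear-phase annealing must be hotter than exponential-phase "
                "annealing (specificity first)"
            )
        if self.round1_exp_cycles > 5:
            warnings.warn(
                f"{self.round1_exp_cycles} exponential cycles exceeds the "
                "recommended maximum of 5; RAPD-like side products become "
                "likely past ~20",
                ProtocolWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class AmplifyConfig:
    max_product_len: int = 3000  #: amplifiable window, genomic span + degenerate flank
    efficiency_scale_C: float = 2.0  #: logistic width of annealing efficiency
    min_yield_report: float = 0.0
    conditions: ThermoConditions = PST_CONDITIONS
    proofreading: bool = False  #: 3'->5' exonuclease destroys walking-primer ends

    def __post_init__(self) -> None:
        if self.max_product_len <= 0:
            raise ValueError("max_product_len must be positive")


@dataclass(frozen=True)
class PCRProduct:
    """A predicted amplicon.

    ``genomic_span`` covers every template base that ends up in the product
    (including bases paired by the degenerate run); ``total_length`` adds
    the two adaptor tails.
    """

    template_id: str
    genomic_span: GenomicInterval
    left_primer_id: str
    right_primer_id: str
    product_class: str
    total_length: int
    relative_yield: float
    left_adaptor: str
    right_adaptor: str
    sequence: str | None = None


def anneal_efficiency(t_anneal_C: float, tm_C: float, scale_C: float = 2.0) -> float:
    """Logistic per-cycle annealing efficiency; 0.5 at Tm, ->1 well below it."""
    return 1.0 / (1.0 + math.exp((t_anneal_C - tm_C) / scale_C))


def _primer_tms(
    ssp: SSPrimer | None,
    pst: PSTPrimer | None,
    cond: ThermoConditions,
) -> dict[str, float]:
    tms = {}
    if ssp is not None:
        tms["ssp"] = melting_temperature(ssp.hybridizing, cond)
    if pst is not None:
        tms["pst"] = melting_temperature(pst.core, cond)
    return tms


def estimate_yield(
    product_class: str,
    tms: dict[str, float],
    profile: ThermalProfile,
    config: AmplifyConfig,
) -> float:
    """Relative round-1 copy number for one product.

    Linear phase: ``cycles x e(driver)`` single strands at the hot anneal
    temperature (driver = SSP where one participates, else the walking
    primer, whose core is essentially unable to anneal that hot). The
    exponential phase multiplies by ``1 + min(e_left, e_right)`` per cycle
    at the low anneal temperature: the weaker-annealing end limits doubling.
    """
    scale = config.efficiency_scale_C
    if product_class == SPECIFIC:
        driver, ends = tms["ssp"], (tms["ssp"], tms["pst"])
    elif product_class == IRAP_LIKE:
        driver, ends = tms["ssp"], (tms["ssp"], tms["ssp"])
    elif product_class == RAPD_LIKE:
        driver, ends = tms["pst"], (tms["pst"], tms["pst"])
    else:
        raise ValueError(f"unknown product class {product_class!r}")
    linear = profile.round1_linear_cycles * anneal_efficiency(
        profile.round1_linear_anneal_C, driver, scale
    )
    e_exp = min(
        anneal_efficiency(profile.round1_exp_anneal_C, tm, scale) for tm in ends
    )
    return linear * (1.0 + e_exp) ** profile.round1_exp_cycles


def _product_sequence(
    template: str, span: GenomicInterval, left_adaptor: str, right_adaptor: str
) -> str:
    """Top-strand product: 5' adaptor, template segment, reverse-complemented
    adaptor of the right primer (extension copies template bases, so the
    degenerate run appears as whatever it paired with)."""
    return (
        left_adaptor.upper()
        + template[span.start : span.end].upper()
        + reverse_complement(right_adaptor.upper())
    )


def simulate_round1(
    template: str,
    ssp: SSPrimer | None = None,
    pst: PSTPrimer | None = None,
    profile: ThermalProfile | None = None,
    config: AmplifyConfig | None = None,
    template_id: str = "template",
    with_sequences: bool = False,
) -> list[PCRProduct]:
    """Predict first-round products for one template and one primer pair.

    Either primer may be omitted to model the single-primer control
    reactions; an absent or site-less SSP is a logged notice, not an error.
    """
    profile = profile or ThermalProfile()
    config = config or AmplifyConfig()
    tms = _primer_tms(ssp, pst, config.conditions)

    ssp_sites = find_ssp_sites(template, ssp, template_id=template_id) if ssp else []
    pst_sites: list[AnnealingSite] = []
    if pst is not None and not config.proofreading:
        pst_sites = find_pst_sites(template, pst, template_id=template_id)
    if ssp is not None and not ssp_sites:
        logger.info("no SSP sites for %s on %s", ssp.id, template_id)

    d = pst.degenerate_len if pst is not None else 0
    products: list[PCRProduct] = []

    def emit(start, end, left_id, right_id, cls, left_ad, right_ad):
        if end - start > config.max_product_len:
            return
        span = GenomicInterval(template_id, start, end)
        y = estimate_yield(cls, tms, profile, config)
        if y < config.min_yield_report:
            return
        seq = (
            _product_sequence(template, span, left_ad, right_ad)
            if with_sequences
            else None
        )
        products.append(
            PCRProduct(
                template_id, span, left_id, right_id, cls,
                total_length=(end - start) + len(left_ad) + len(right_ad),
                relative_yield=y, left_adaptor=left_ad, right_adaptor=right_ad,
                sequence=seq,
            )
        )

    # SPECIFIC: SSP paired with a facing palindrome site within the window
    for s_site in ssp_sites:
        for p_site in pst_sites:
            pal = p_site.interval
            if s_site.extension_direction == RIGHT and p_site.extension_direction == LEFT:
                if pal.start >= s_site.interval.end:
                    emit(
                        s_site.interval.start, pal.end + d,
                        ssp.id, pst.id, SPECIFIC, ssp.adaptor, pst.adaptor,
                    )
            elif s_site.extension_direction == LEFT and p_site.extension_direction == RIGHT:
                if pal.end <= s_site.interval.start:
                    emit(
                        pal.start - d, s_site.interval.end,
                        pst.id, ssp.id, SPECIFIC, pst.adaptor, ssp.adaptor,
                    )

    # IRAP_LIKE: inverted SSP target copies facing each other
    for a in ssp_sites:
        for b in ssp_sites:
            if (
                a.extension_direction == RIGHT
                and b.extension_direction == LEFT
                and b.interval.start >= a.interval.end
            ):
                emit(
                    a.interval.start, b.interval.end,
                    ssp.id, ssp.id, IRAP_LIKE, ssp.adaptor, ssp.adaptor,
                )

    # RAPD_LIKE: palindrome-palindrome pairs, only past the cycle threshold
    if pst is not None and profile.round1_exp_cycles > profile.rapd_cycle_threshold:
        for a in pst_sites:
            for b in pst_sites:
                if (
                    a.extension_direction == RIGHT
                    and b.extension_direction == LEFT
                    and b.interval.start >= a.interval.end
                ):
                    emit(
                        a.interval.start - d, b.interval.end + d,
                        pst.id, pst.id, RAPD_LIKE, pst.adaptor, pst.adaptor,
                    )
    return products


def simulate_round2(
    products: Sequence[PCRProduct],
    tail_primer: str,
    profile: ThermalProfile | None = None,
    config: AmplifyConfig | None = None,
) -> list[PCRProduct]:
    """Single-primer reamplification of adaptor-flanked round-1 products.

    Products whose two ends both carry the tail sequence are multiplied by
    ``(1 + e_tail)^cycles``; anything else is silently dropped (logged).
    Output is sorted by total length, descending (gel order, largest first).
    """
    profile = profile or ThermalProfile()
    config = config or AmplifyConfig()
    tail = tail_primer.upper()
    tail_tm = melting_temperature(tail, config.conditions)
    e_tail = anneal_efficiency(
        profile.round2_anneal_C, tail_tm, config.efficiency_scale_C
    )
    mult = (1.0 + e_tail) ** profile.round2_cycles
    final = []
    for p in products:
        if p.left_adaptor.upper() == tail and p.right_adaptor.upper() == tail:
            final.append(replace(p, relative_yield=p.relative_yield * mult))
        else:
            logger.info(
                "product %s-%s lacks the tail adaptor on both ends; not amplified",
                p.left_primer_id, p.right_primer_id,
            )
    final.sort(
        key=lambda p: (-p.total_length, p.genomic_span.start, p.product_class)
    )
    return final


def pst_pcr_v2(
    template: str,
    ssp: SSPrimer | None = None,
    pst: PSTPrimer | None = None,
    profile: ThermalProfile | None = None,
    config: AmplifyConfig | None = None,
    tail_primer: str | None = None,
    template_id: str = "template",
    with_sequences: bool = False,
) -> list[PCRProduct]:
    """The full two-round process; deterministic for fixed inputs.

    ``tail_primer`` defaults to the shared adaptor of the supplied primers.
    """
    if tail_primer is None:
        if ssp is not None:
            tail_primer = ssp.adaptor
        elif pst is not None:
            tail_primer = pst.adaptor
        else:
            raise ValueError("no primers supplied")
    round1 = simulate_round1(
        template, ssp, pst, profile, config,
        template_id=template_id, with_sequences=with_sequences,
    )
    return simulate_round2(round1, tail_primer, profile, config)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def products_to_frame(products: Sequence[PCRProduct]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "template_id": p.template_id,
                "start": p.genomic_span.start,
                "end": p.genomic_span.end,
                "left_primer": p.left_primer_id,
                "right_primer": p.right_primer_id,
                "class": p.product_class,
                "total_length": p.total_length,
                "relative_yield": p.relative_yield,
            }
            for p in products
        ],
        columns=[
            "template_id", "start", "end", "left_primer", "right_primer",
            "class", "total_length", "relative_yield",
        ],
    )


def products_to_tsv(products: Sequence[PCRProduct], path: str | Path) -> None:
    products_to_frame(products).to_csv(path, sep="\t", index=False)


def products_to_bed(products: Sequence[PCRProduct], path: str | Path) -> None:
    write_bed(
        [p.genomic_span for p in products],
        path,
        names=[f"{p.left_primer_id}|{p.right_primer_id}|{p.product_class}" for p in products],
        scores=[min(1000, int(p.relative_yield)) for p in products],
    )


def products_to_fasta(products: Sequence[PCRProduct], path: str | Path) -> None:
    records = [
        (
            f"{p.template_id}:{p.genomic_span.start}-{p.genomic_span.end}"
            f"|{p.product_class}|{p.total_length}nt",
            p.sequence,
        )
        for p in products
        if p.sequence
    ]
    write_fasta(records, path)
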