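"""Locate primer annealing sites on both strands of a template.

A walking-primer site is an occurrence of the primer's 3' palindrome. The
palindrome is self-reverse-complementary, so each genomic occurrence can be
primed in either orientation and yields up to two sites, one per extension
direction; a site survives only if the degenerate run of the core also fits
on the template (on the side opposite the extension direction).

SSP sites are near-exact matches of the hybridizing sequence: the
3'-terminal block (default 12 nt) must match exactly (extension starts
there), a small number of mismatches are tolerated elsewhere. Template
ambiguity codes never match a primer base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .primer_design import PSTPrimer, SSPrimer
from .seqcore import GenomicInterval, reverse_complement, validate_dna, write_bed

RIGHT = "right"
LEFT = "left"


@dataclass(frozen=True)
class AnnealingSite:
    """A located primer-binding event on a template.

    ``interval`` covers the template bases paired by the primer's *defined*
    sequence (palindrome for walking primers, hybridizing part for SSPs).
    ``extension_direction`` is the direction of synthesis in template
    coordinates: a primer whose 3' end points to increasing coordinates has
    direction ``right``.
    """

    interval: GenomicInterval
    primer_id: str
    site_kind: str  # "PST" | "SSP"
    extension_direction: str  # "right" | "left"
    mismatches: int = 0


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (overlapping) exact occurrence positions of needle in haystack."""
    hits, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return hits
        hits.append(idx)
        start = idx + 1


def find_pst_sites(
    template: str, pst: PSTPrimer, template_id: str = "template"
) -> list[AnnealingSite]:
    """Every palindrome occurrence, once per viable extension direction.

    Extension ``right`` needs the degenerate flank on the left of the
    palindrome (the core's N-run pairs there); extension ``left`` needs it
    on the right. Occurrences too close to a template edge for the flank
    are dropped. Overlapping occurrences are all reported.
    """
    validate_dna(template)
    t = template.upper()
    pal = pst.palindrome.upper()
    d = pst.degenerate_len
    sites = []
    for s in _occurrences(t, pal):
        interval_kw = dict(sequence_id=template_id, start=s, end=s + len(pal))
        if s - d >= 0:
            sites.append(
                AnnealingSite(
                    GenomicInterval(strand="+", **interval_kw),
                    pst.id, "PST", RIGHT,
                )
            )
        if s + len(pal) + d <= len(t):
            sites.append(
                AnnealingSite(
                    GenomicInterval(strand="-", **interval_kw),
                    pst.id, "PST", LEFT,
                )
            )
    return sites


@dataclass(frozen=True)
class SSPMatchCriteria:
    """Protected 3' block must match exactly; limited mismatches elsewhere."""

    protected_len: int = 12
    max_mismatches: int = 2


def _count_mismatches(window: str, query: str, limit: int) -> int:
    """Mismatches between equal-length strings; ambiguity in the template
    counts as a mismatch. Returns limit+1 early once exceeded."""
    mm = 0
    for a, b in zip(window, query):
        if a != b:
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_ssp_sites(
    template: str,
    ssp: SSPrimer,
    criteria: SSPMatchCriteria | None = None,
    template_id: str = "template",
) -> list[AnnealingSite]:
    """All sites on both strands matching the hybridizing sequence.

    Candidates are anchored on the exact protected 3' block, then the
    remainder is checked against the mismatch budget. Forward-strand
    matches extend right; reverse-strand matches extend left.
    """
    validate_dna(template)
    criteria = criteria or SSPMatchCriteria()
    t = template.upper()
    hyb = ssp.hybridizing.upper()
    h = len(hyb)
    if h > len(t):
        return []
    k = min(criteria.protected_len, h)
    sites = []

    # forward strand: 3' block is the last k bases of the match window
    for idx in _occurrences(t, hyb[-k:]):
        start = idx - (h - k)
        if start < 0:
            continue
        mm = _count_mismatches(
            t[start : start + h - k], hyb[: h - k], criteria.max_mismatches
        )
        if mm <= criteria.max_mismatches:
            sites.append(
                AnnealingSite(
                    GenomicInterval(template_id, start, start + h, "+"),
                    ssp.id, "SSP", RIGHT, mm,
                )
            )

    # reverse strand: the primer's 3' block maps to the lowest coordinates
    rc = reverse_complement(hyb)
    for idx in _occurrences(t, rc[:k]):
        if idx + h > len(t):
            continue
        mm = _count_mismatches(
            t[idx + k : idx + h], rc[k:], criteria.max_mismatches
        )
        if mm <= criteria.max_mismatches:
            sites.append(
                AnnealingSite(
                    GenomicInterval(template_id, idx, idx + h, "-"),
                    ssp.id, "SSP", LEFT, mm,
                )
            )
    sites.sort(key=lambda s: (s.interval.start, s.extension_direction))
    return sites


def sites_to_bed(sites: Sequence[AnnealingSite], path: str | Path) -> None:
    """Export as BED6; strand encodes extension direction, score mismatches."""
    write_bed(
        [s.interval for s in sites],
        path,
        names=[s.primer_id for s in sites],
        scores=[s.mismatches for s in sites],
    )
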