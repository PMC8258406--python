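"""Synthetic genomes with implanted DNA-transposon insertions.

Generates maize-like test material end to end: an i.i.d. random host
genome, an Ac-like element (4.6 kb, 11-bp terminal inverted repeats,
SSP-targetable tag regions within 200 bp of each terminus), insertions
that create 8-bp target-site duplications, and a cohort of inbred lines
plus F1 hybrids with a machine-readable truth table.

All inbred lines share one ancestral host sequence and differ only in
which insertions they carry; an F1 is simply the two parental haplotypes
side by side. Insertion positions are rejection-sampled so that every
insertion is guaranteed recoverable by the configured walking primer:
exactly one palindrome occurrence inside the amplifiable window downstream
of the element, and pairwise well-separated band lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .primer_design import DEFAULT_ADAPTOR, PSTPrimer, SSPrimer, make_pst_primer
from .seqcore import GenomicInterval, reverse_complement, write_bed, write_fasta

TIR_LEN = 11
TSD_LEN = 8
AC_ELEMENT_LEN = 4600
TAG_MARGIN = 200  # tag regions sit within this many bases of each terminus

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_host(length: int, gc_fraction: float = 0.45, seed=0) -> str:
    """Reproducible i.i.d. host genome with the requested GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = _rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    return "".join(rng.choice(_BASES, size=length, p=[at, gc, gc, at]))


@dataclass(frozen=True)
class TransposonModel:
    """An Ac-like element: TIRs at both ends, tag regions near both termini."""

    element_sequence: str
    tir_len: int = TIR_LEN
    tsd_len: int = TSD_LEN
    tag_regions: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        L = len(self.element_sequence)
        s = self.element_sequence.upper()
        if s[: self.tir_len] != reverse_complement(s[-self.tir_len :]):
            raise ValueError("element termini are not inverted repeats")
        if L < 2 * self.tir_len + sum(len(t) for t in self.tag_regions):
            raise ValueError("element too short for its TIRs and tag regions")


def make_element(
    length: int = AC_ELEMENT_LEN,
    seed=0,
    gc_fraction: float = 0.5,
    exclude_motifs: Sequence[str] = (),
    tag_len: int = 30,
) -> TransposonModel:
    """Random element with enforced 11-bp TIRs and terminal tag regions.

    ``exclude_motifs`` lets the caller keep chosen palindromes out of the
    terminal tag-to-terminus stretches so a walking primer never lands
    inside the element between the SSP target and the element end.
    """
    if length < 2 * TAG_MARGIN:
        raise ValueError(f"element length must be >= {2 * TAG_MARGIN}")
    rng = _rng(seed)
    tags = (
        GenomicInterval("element", TAG_MARGIN - tag_len - 20, TAG_MARGIN - 20),
        GenomicInterval("element", length - TAG_MARGIN + 20, length - TAG_MARGIN + 20 + tag_len),
    )
    for _ in range(200):
        body = generate_host(length, gc_fraction, rng)
        seq = body[: length - TIR_LEN] + reverse_complement(body[:TIR_LEN])
        # terminal stretches that end up inside amplified flank products
        critical = seq[: TAG_MARGIN] + "|" + seq[length - TAG_MARGIN :]
        if any(m.upper() in critical.upper() for m in exclude_motifs):
            continue
        return TransposonModel(seq, TIR_LEN, TSD_LEN, tags)
    raise RuntimeError("could not generate an element avoiding the excluded motifs")


def ssp_for_element(
    element: TransposonModel,
    end: str = "3prime",
    adaptor: str = DEFAULT_ADAPTOR,
    id: str | None = None,
) -> SSPrimer:
    """An SSP annealing in a tag region and extending outward across the
    element terminus into flanking host DNA."""
    seq = element.element_sequence.upper()
    if end == "3prime":
        tag = element.tag_regions[1]
        hyb = seq[tag.start : tag.end]
    elif end == "5prime":
        tag = element.tag_regions[0]
        hyb = reverse_complement(seq[tag.start : tag.end])
    else:
        raise ValueError("end must be '5prime' or '3prime'")
    return SSPrimer(
        id=id or f"ssp_{end}", hybridizing=hyb, adaptor=adaptor,
        target_name=f"element:{tag.start}-{tag.end}({end})",
    )


@dataclass(frozen=True)
class InsertionRecord:
    """One implanted element in one haplotype (ancestral host coordinates)."""

    insertion_id: str
    host_position: int  # pre-insertion coordinate of the cut
    orientation: str  # '+' | '-'
    final_position: int  # element start in the assembled haplotype


def implant(
    genome: str,
    element_sequence: str,
    positions: Sequence[int],
    orientations: Sequence[str] | None = None,
    tsd_len: int = TSD_LEN,
    ids: Sequence[str] | None = None,
) -> tuple[str, list[InsertionRecord]]:
    """Insert the element at host positions, duplicating the 8-bp target site.

    The ``tsd_len`` bases immediately left of each cut are duplicated to
    the element's right flank, so both element flanks carry an identical
    copy and the genome grows by ``len(element) + tsd_len`` per insertion.
    """
    orientations = list(orientations or ["+"] * len(positions))
    ids = list(ids or [f"ins{i+1}" for i in range(len(positions))])
    if not (len(positions) == len(orientations) == len(ids)):
        raise ValueError("positions, orientations and ids must align")
    order = np.argsort(positions)
    sorted_pos = [positions[i] for i in order]
    for a, b in zip(sorted_pos, sorted_pos[1:]):
        if b - a < tsd_len:
            raise ValueError(
                f"insertions at {a} and {b} overlap within one target site"
            )
    if sorted_pos and (sorted_pos[0] < tsd_len or sorted_pos[-1] > len(genome)):
        raise ValueError("insertion position outside the host genome")

    grow = len(element_sequence) + tsd_len
    records = []
    out = genome
    # insert right-to-left so earlier coordinates stay valid
    for rank, i in enumerate(reversed(order)):
        p, orient = positions[i], orientations[i]
        elem = element_sequence if orient == "+" else reverse_complement(element_sequence)
        tsd = out[p - tsd_len : p]
        out = out[:p] + elem + tsd + out[p:]
        n_before = len(positions) - 1 - rank  # insertions left of this one
        records.append(
            InsertionRecord(ids[i], p, orient, p + n_before * grow)
        )
    records.sort(key=lambda r: r.host_position)
    return out, records


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPlan:
    """Which insertions each inbred line carries, and how hybrids pair lines."""

    lines: Mapping[str, tuple[str, ...]]
    hybrids: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for hybrid, parents in self.hybrids.items():
            unknown = [p for p in parents if p not in self.lines]
            if unknown:
                raise ValueError(f"hybrid {hybrid!r} references unknown parent(s) {unknown}")

    @property
    def insertion_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for members in self.lines.values():
            for i in members:
                seen[i] = None
        return tuple(seen)


def default_plan() -> CohortPlan:
    """Four inbred lines and two F1s, echoing a classic maize panel: one
    insertion fixed in all lines, five line-unique insertions."""
    return CohortPlan(
        lines={
            "A619": ("i1", "i2"),
            "A632": ("i1", "i3"),
            "B73": ("i1", "i4", "i5"),
            "Mo17": ("i1", "i6"),
        },
        hybrids={"A619xA632": ("A619", "A632"), "B73xMo17": ("B73", "Mo17")},
    )


@dataclass(frozen=True)
class Cohort:
    samples: dict[str, list[tuple[str, str]]]  # sample -> [(haplotype, seq)]
    truth: pd.DataFrame
    manifest: pd.DataFrame
    element: TransposonModel
    ssp: SSPrimer
    pst: PSTPrimer
    host: str


def make_cohort(
    plan: CohortPlan | None = None,
    seed: int = 0,
    host_length: int = 60_000,
    gc_fraction: float = 0.45,
    element_length: int = AC_ELEMENT_LEN,
    pst: PSTPrimer | None = None,
    max_window: int = 3000,
    min_separation: int = 3500,
    band_tolerance: float = 0.02,
) -> Cohort:
    """Build a parents-and-hybrids cohort with a guaranteed-recoverable truth.

    Every insertion position is rejection-sampled until the assembled
    junction (element tail + target-site duplication + downstream host)
    contains exactly one occurrence of the walking primer's palindrome
    within the amplifiable window, and until all expected band lengths are
    separated by more than the band-matching tolerance.
    """
    plan = plan or default_plan()
    pst = pst or make_pst_primer("GACGTC", id="5601", restriction_site_name="AatII")
    rng = np.random.default_rng(seed)

    host = generate_host(host_length, gc_fraction, rng)
    element = make_element(
        element_length, rng, exclude_motifs=[pst.palindrome]
    )
    ssp = ssp_for_element(element, "3prime")

    eseq = element.element_sequence
    tag = element.tag_regions[1]
    tail_len = len(eseq) - tag.start  # SSP target start .. element end
    pal, d = pst.palindrome, pst.degenerate_len
    # farthest palindrome start (within the junction context) still in window
    ctx_limit = max_window - len(pal) - d

    positions: dict[str, int] = {}
    lengths: dict[str, int] = {}
    for ins_id in plan.insertion_ids:
        for _ in range(10_000):
            p = int(rng.integers(TSD_LEN + 100, host_length - max_window))
            if any(abs(p - q) < min_separation for q in positions.values()):
                continue
            ctx = eseq[tag.start :] + host[p - TSD_LEN : p] + host[p : p + ctx_limit]
            hits = [
                i for i in range(len(ctx) - len(pal) + 1)
                if ctx[i : i + len(pal)].upper() == pal
                and i <= ctx_limit
            ]
            if len(hits) != 1 or hits[0] < tail_len + TSD_LEN:
                continue
            band = hits[0] + len(pal) + d + len(ssp.adaptor) + len(pst.adaptor)
            if any(
                abs(band - other) <= 2 * band_tolerance * max(band, other)
                for other in lengths.values()
            ):
                continue
            positions[ins_id] = p
            lengths[ins_id] = band
            break
        else:
            raise RuntimeError(f"could not place insertion {ins_id!r}")

    samples: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for line, members in plan.lines.items():
        pos = [positions[i] for i in members]
        genome, records = implant(host, eseq, pos, ids=list(members))
        samples[line] = [(line, genome)]
        for rec in records:
            truth_rows.append(
                {
                    "sample_id": line,
                    "insertion_id": rec.insertion_id,
                    "host_position": rec.host_position,
                    "final_position": rec.final_position,
                    "orientation": rec.orientation,
                    "pst_id": pst.id,
                    "palindrome_distance": lengths[rec.insertion_id]
                    - len(pal) - d - len(ssp.adaptor) - len(pst.adaptor)
                    - (tail_len + TSD_LEN),
                    "expected_band_length": lengths[rec.insertion_id],
                }
            )
    for hybrid, (pa, pb) in plan.hybrids.items():
        samples[hybrid] = [
            (f"{hybrid}|{pa}", samples[pa][0][1]),
            (f"{hybrid}|{pb}", samples[pb][0][1]),
        ]

    manifest = pd.DataFrame(
        [{"sample_id": s, "parents": ""} for s in plan.lines]
        + [
            {"sample_id": h, "parents": f"{pa},{pb}"}
            for h, (pa, pb) in plan.hybrids.items()
        ]
    )
    truth = pd.DataFrame(truth_rows)
    return Cohort(samples, truth, manifest, element, ssp, pst, host)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Per-sample FASTA, truth TSV + BED, and the cohort manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, haplotypes in cohort.samples.items():
        write_fasta(haplotypes, outdir / f"{sample}.fasta")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    elem_len = len(cohort.element.element_sequence)
    intervals, names = [], []
    for _, row in cohort.truth.iterrows():
        intervals.append(
            GenomicInterval(
                row["sample_id"],
                int(row["final_position"]),
                int(row["final_position"]) + elem_len,
                row["orientation"],
            )
        )
        names.append(str(row["insertion_id"]))
    write_bed(intervals, outdir / "truth.bed", names=names)
    cohort.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
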