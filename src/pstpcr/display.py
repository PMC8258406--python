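"""Virtual transposon display: band patterns and cross-sample comparison.

Product lengths become gel "bands"; two bands match when their sizes agree
within a relative tolerance (default 2%, roughly agarose sizing error).
Cross-sample band classes are built by single-linkage clustering, scored
into a 0/1 presence matrix, and summarized as monomorphic (present in all
samples) versus polymorphic bands. Parent/hybrid inheritance is checked
directly: every band in a parental line must reappear in the F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .amplify import AmplifyConfig, PCRProduct, ThermalProfile, pst_pcr_v2

DEFAULT_TOLERANCE = 0.02

#: GeneRuler DNA Ladder Mix sizes, 100-10,000 bp
GENERULER_MIX = (
    100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
    1200, 1500, 2000, 2500, 3000, 3500, 4000, 5000, 6000, 8000, 10000,
)


def bands_match(a: float, b: float, tolerance: float = DEFAULT_TOLERANCE) -> bool:
    return abs(a - b) <= tolerance * max(a, b)


@dataclass(frozen=True)
class BandPattern:
    sample_id: str
    band_lengths: tuple[int, ...]
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.band_lengths):
            raise ValueError("band lengths must be positive")
        if list(self.band_lengths) != sorted(self.band_lengths):
            raise ValueError("band lengths must be sorted ascending")


def _cluster_lengths(
    lengths: Sequence[float], tolerance: float
) -> list[list[float]]:
    """Single-linkage clusters of sizes; adjacent sizes within tolerance link."""
    clusters: list[list[float]] = []
    for x in sorted(lengths):
        if clusters and bands_match(clusters[-1][-1], x, tolerance):
            clusters[-1].append(x)
        else:
            clusters.append([x])
    return clusters


def band_pattern(
    products: Sequence[PCRProduct],
    sample_id: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> BandPattern:
    """Collapse a product set into a deduplicated, sorted band list.

    Lengths within tolerance of each other merge; the smallest member of a
    cluster is kept as its representative. An empty product set is a valid
    empty pattern (an empty lane).
    """
    clusters = _cluster_lengths([p.total_length for p in products], tolerance)
    return BandPattern(
        sample_id, tuple(int(min(c)) for c in clusters), tolerance
    )


@dataclass(frozen=True)
class ConsistencyReport:
    fraction: float
    violations: tuple[tuple[str, int], ...]  # (parent sample, missing band)
    passed: bool


def hybrid_consistency(
    parent_a: BandPattern,
    parent_b: BandPattern,
    hybrid: BandPattern,
    min_fraction: float = 1.0,
) -> ConsistencyReport:
    """Check that every parental band reappears in the hybrid.

    An F1 carries both parental haplotypes, so in the absence of new
    transposition every parental band must be present. Returns the matched
    fraction, the list of violations, and a verdict against
    ``min_fraction`` (default: all bands must match).
    """
    if not (parent_a.tolerance == parent_b.tolerance == hybrid.tolerance):
        raise ValueError("patterns must share one band-matching tolerance")
    tol = hybrid.tolerance
    expected = [(parent_a.sample_id, b) for b in parent_a.band_lengths] + [
        (parent_b.sample_id, b) for b in parent_b.band_lengths
    ]
    violations = [
        (sample, band)
        for sample, band in expected
        if not any(bands_match(band, hb, tol) for hb in hybrid.band_lengths)
    ]
    fraction = 1.0 if not expected else 1.0 - len(violations) / len(expected)
    return ConsistencyReport(fraction, tuple(violations), fraction >= min_fraction)


def presence_matrix(patterns: Sequence[BandPattern]) -> pd.DataFrame:
    """0/1 matrix of band classes (rows) x samples (columns).

    Band classes are single-linkage clusters of all observed band sizes
    across samples; each row is labelled by its smallest member.
    """
    if len(patterns) < 2:
        raise ValueError("presence matrix needs at least 2 samples")
    tols = {p.tolerance for p in patterns}
    if len(tols) > 1:
        raise ValueError("patterns must share one band-matching tolerance")
    tol = tols.pop()
    pairs = [
        (b, p.sample_id) for p in patterns for b in p.band_lengths
    ]
    clusters = _cluster_lengths([b for b, _ in pairs], tol)
    samples = [p.sample_id for p in patterns]
    rows = {}
    for cluster in clusters:
        members = set(cluster)
        present = {s for b, s in pairs if b in members}
        rows[int(min(cluster))] = [int(s in present) for s in samples]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "band"
    return df.sort_index()


def polymorphism_summary(matrix: pd.DataFrame) -> dict[str, int]:
    """Counts of bands present in every sample vs only a subset."""
    mono = int((matrix.sum(axis=1) == matrix.shape[1]).sum())
    return {
        "n_bands": int(matrix.shape[0]),
        "monomorphic": mono,
        "polymorphic": int(matrix.shape[0]) - mono,
    }


# ---------------------------------------------------------------------------
# gel rendering
# ---------------------------------------------------------------------------

def render_gel_text(
    patterns: Sequence[BandPattern],
    ladder: Sequence[int] = GENERULER_MIX,
    height: int = 28,
    lane_width: int = 9,
) -> str:
    """Lane-per-sample schematic; migration distance grows with -log(size)."""
    if not patterns:
        raise ValueError("no patterns to render")
    import math

    all_sizes = [s for p in patterns for s in p.band_lengths] + list(ladder)
    lo, hi = math.log(min(all_sizes)), math.log(max(all_sizes))

    def row_of(size: int) -> int:
        if hi == lo:
            return 0
        return round((hi - math.log(size)) / (hi - lo) * (height - 1))

    lanes = [("M", ladder)] + [(p.sample_id, p.band_lengths) for p in patterns]
    canvas = [
        ["".center(lane_width) for _ in lanes] for _ in range(height)
    ]
    for j, (_, sizes) in enumerate(lanes):
        for size in sizes:
            canvas[row_of(size)][j] = f"={size}=".center(lane_width)
    header = "".join(name[:lane_width].center(lane_width) for name, _ in lanes)
    body = "\n".join("".join(r) for r in canvas)
    return header + "\n" + body + "\n"


def render_gel_image(
    patterns: Sequence[BandPattern],
    path: str | Path,
    ladder: Sequence[int] = GENERULER_MIX,
) -> None:
    """Optional matplotlib rendering of the same schematic."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lanes = [("M", ladder)] + [(p.sample_id, p.band_lengths) for p in patterns]
    fig, ax = plt.subplots(figsize=(1 + len(lanes), 5))
    for j, (name, sizes) in enumerate(lanes):
        for size in sizes:
            ax.hlines(math.log10(size), j + 0.15, j + 0.85, lw=2.5, color="k")
    ax.set_xticks([j + 0.5 for j in range(len(lanes))])
    ax.set_xticklabels([name for name, _ in lanes], rotation=45, ha="right")
    ax.set_ylabel("log10 size (nt)")
    ax.set_xlim(0, len(lanes))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_transposon_display(
    samples: Mapping[str, Sequence[tuple[str, str]]],
    ssp,
    pst,
    profile: ThermalProfile | None = None,
    config: AmplifyConfig | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[str, BandPattern]:
    """Amplify every haplotype of every sample and collapse to band patterns.

    ``samples`` maps sample id to ``[(haplotype_name, sequence), ...]``; a
    hybrid's two haplotypes are amplified independently and their bands
    pooled, mirroring an F1 of two inbred lines.
    """
    patterns = {}
    for sample_id, haplotypes in samples.items():
        products: list[PCRProduct] = []
        for hap_name, seq in haplotypes:
            products.extend(
                pst_pcr_v2(
                    seq, ssp, pst, profile, config, template_id=hap_name
                )
            )
        patterns[sample_id] = band_pattern(products, sample_id, tolerance)
    return patterns
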