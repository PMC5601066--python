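"""Allele-frequency-difference scanning and QTL calling.

The association statistic is the allele frequency difference (AFD): the
reference allele frequency of the high-phenotype pool minus that of the low
pool, computed directly from read counts, with range [-1, 1].  Markers whose
|AFD| exceeds a threshold (default 0.75) are clustered into QTL by
single-linkage chaining with a region-dependent gap: two passing markers
stay in one QTL when separated by less than 400 Mbp where the separating
span crosses the centromere, or 10 Mbp elsewhere.  The threshold's implied
significance is quantified by a Pearson chi-squared test on the line-count
table of two fully homozygous pools at the threshold frequency difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .validation import chisq_homogeneity
from .variants import PooledVariant

log = logging.getLogger(__name__)

#: clustering gap (bp) where the separating span crosses a centromere
DEFAULT_GAP_CENTROMERIC = 400_000_000
#: clustering gap (bp) elsewhere
DEFAULT_GAP_OTHER = 10_000_000


@dataclass(frozen=True)
class AFDRecord:
    """A variant with per-pool reference allele frequencies and their difference."""

    variant: PooledVariant
    raf_high: float
    raf_low: float
    afd: float


@dataclass(frozen=True)
class QTLCall:
    """A clustered associated region.

    ``interval`` spans the member marker positions (1-based, closed;
    degenerate for single-marker QTL), ``peak_position`` is the member with
    the largest |AFD| (ties broken by smallest position) and ``max_afd`` is
    the signed AFD at the peak.
    """

    name: str
    contrast: str
    chromosome: str
    interval: tuple[int, int]
    n_markers: int
    peak_position: int
    max_afd: float

    def __post_init__(self) -> None:
        s, e = self.interval
        if not (s <= self.peak_position <= e):
            raise ValueError("peak must lie inside the interval")
        if self.n_markers < 1:
            raise ValueError("a QTL needs at least one supporting marker")


CentromereMap = Mapping[str, tuple[int, int]]


def load_centromeres(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a per-chromosome centromere interval TSV (chromosome, start, end)."""
    df = pd.read_table(path)
    cols = list(df.columns[:3])
    return {
        str(r[cols[0]]): (int(r[cols[1]]), int(r[cols[2]])) for _, r in df.iterrows()
    }


def compute_afd(variants: Iterable[PooledVariant]) -> list[AFDRecord]:
    """Reference allele frequencies per pool and their difference.

    Every pool must have at least one allele-informative read (the depth
    filter guarantees this); a zero-depth pool raises.
    """
    out = []
    for v in variants:
        rh, rl = v.raf("high"), v.raf("low")
        if rh is None or rl is None:
            raise ValueError(
                f"zero-depth pool at {v.chromosome}:{v.position}; "
                "apply the depth filter before computing AFD"
            )
        out.append(AFDRecord(variant=v, raf_high=rh, raf_low=rl, afd=rh - rl))
    return out


def _gap_for_span(
    chromosome: str,
    span: tuple[int, int],
    centromeres: CentromereMap | None,
    gap_centromeric: float,
    gap_other: float,
    warned: set[str],
) -> float:
    if centromeres is None or chromosome not in centromeres:
        if centromeres is not None and chromosome not in warned:
            log.warning(
                "chromosome %s absent from centromere map; treated as non-centromeric",
                chromosome,
            )
            warned.add(chromosome)
        return gap_other
    cs, ce = centromeres[chromosome]
    lo, hi = span
    return gap_centromeric if (lo <= ce and hi >= cs) else gap_other


def call_qtl(
    records: Sequence[AFDRecord],
    threshold: float = 0.75,
    centromeres: CentromereMap | None = None,
    gap_centromeric: float = DEFAULT_GAP_CENTROMERIC,
    gap_other: float = DEFAULT_GAP_OTHER,
    contrast: str = "contrast",
    name_prefix: str = "QTL",
    sign_mode: str = "absolute",
) -> list[QTLCall]:
    """Threshold on |AFD| and cluster passing markers into independent QTL.

    Passing markers (|AFD| strictly greater than ``threshold``) are scanned
    in position order within each chromosome; two consecutive passing
    markers join the same QTL when their separation is below the applicable
    gap — ``gap_centromeric`` when the span between them intersects the
    chromosome's centromere interval, ``gap_other`` otherwise.  Markers
    separated by at least the gap, with no passing marker between them,
    start independent QTL.  ``sign_mode='strict'`` additionally splits
    between passing markers of opposite AFD sign; the default clusters on
    |AFD| alone.  The result is invariant to input order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if sign_mode not in ("absolute", "strict"):
        raise ValueError("sign_mode must be 'absolute' or 'strict'")
    passing = [r for r in records if abs(r.afd) > threshold]
    passing.sort(key=lambda r: (r.variant.chromosome, r.variant.position))
    warned: set[str] = set()

    clusters: list[list[AFDRecord]] = []
    for r in passing:
        if clusters:
            prev = clusters[-1][-1]
            same_chrom = prev.variant.chromosome == r.variant.chromosome
            if same_chrom:
                span = (prev.variant.position, r.variant.position)
                gap = _gap_for_span(
                    r.variant.chromosome, span, centromeres, gap_centromeric, gap_other, warned
                )
                joined = (r.variant.position - prev.variant.position) < gap
                if sign_mode == "strict" and np.sign(prev.afd) != np.sign(r.afd):
                    joined = False
                if joined:
                    clusters[-1].append(r)
                    continue
        clusters.append([r])

    calls: list[QTLCall] = []
    for i, members in enumerate(clusters, start=1):
        positions = [m.variant.position for m in members]
        peak = max(members, key=lambda m: (abs(m.afd), -m.variant.position))
        calls.append(
            QTLCall(
                name=f"{name_prefix}-{i}",
                contrast=contrast,
                chromosome=members[0].variant.chromosome,
                interval=(min(positions), max(positions)),
                n_markers=len(members),
                peak_position=peak.variant.position,
                max_afd=peak.afd,
            )
        )
    return calls


def contrast_table(threshold: float = 0.75, pool_size: int = 12) -> np.ndarray:
    """Line-count table implied by a frequency difference of ``threshold``.

    Two pools of ``pool_size`` fully homozygous lines: one fixed for the
    reference allele, the other at reference frequency ``1 - threshold``.
    For threshold 0.75 and pools of 12 this is [[12, 0], [3, 9]].
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    r = (1 - threshold) * pool_size
    r_int = int(round(r))
    if abs(r - r_int) > 0.5:
        raise ValueError("threshold * pool_size must be within one of an integer")
    if abs(r - r_int) > 1e-9:
        log.warning(
            "threshold %.3g with pool size %d implies a non-integer line count; rounding",
            threshold,
            pool_size,
        )
    return np.array([[pool_size, 0], [r_int, pool_size - r_int]])


def threshold_significance(threshold: float = 0.75, pool_size: int = 12) -> float:
    """-log10 p implied by an AFD threshold under perfect frequency estimates.

    Pearson chi-squared (1 df, no continuity correction) on the
    :func:`contrast_table` line counts, two-sided p from the chi-squared
    distribution.  For threshold 0.75 and pools of 12 the statistic is 14.4
    and the result is ~3.8.
    """
    res = chisq_homogeneity(contrast_table(threshold, pool_size))
    return res.neglog10p


# ---------------------------------------------------------------------------
# tabular output


def afd_table(records: Sequence[AFDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [r.variant.chromosome for r in records],
            "position": [r.variant.position for r in records],
            "ref": [r.variant.ref_allele for r in records],
            "alt": [r.variant.alt_allele for r in records],
            "raf_high": [r.raf_high for r in records],
            "raf_low": [r.raf_low for r in records],
            "afd": [r.afd for r in records],
        }
    )


def qtl_table(calls: Sequence[QTLCall]) -> pd.DataFrame:
    """QTL calls as a table (name, contrast, chromosome, interval, markers, peak, max AFD)."""
    return pd.DataFrame(
        {
            "name": [c.name for c in calls],
            "contrast": [c.contrast for c in calls],
            "chromosome": [c.chromosome for c in calls],
            "interval_start": [c.interval[0] for c in calls],
            "interval_end": [c.interval[1] for c in calls],
            "n_markers": [c.n_markers for c in calls],
            "peak_position": [c.peak_position for c in calls],
            "max_afd": [c.max_afd for c in calls],
        }
    )


def write_qtl_bed(calls: Sequence[QTLCall], path: str | Path) -> None:
    """QTL spans as BED (0-based half-open, converted from 1-based closed)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chromosome}\t{c.interval[0] - 1}\t{c.interval[1]}\t{c.name}\n")
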