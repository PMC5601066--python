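"""Pooled variant records, VCF input/output, and the post-calling filter cascade.

A :class:`PooledVariant` is one biallelic SNP with per-pool reference/alternate
read depths, as emitted by a pooled-sample variant caller (FreeBayes-style
``RO``/``AO`` FORMAT fields, ``AD`` accepted as a fallback).  The filter
cascade reproduces the three post-calling rules used in pooled contrast-set
mapping: minimum phred-scaled call quality, exclusion of variants fixed for
the same non-reference allele in both pools, and a minimum per-pool
allele-informative read depth.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNP with read depths for a high and a low phenotype pool.

    ``depth_high``/``depth_low`` are ``(ref_reads, alt_reads)`` pairs of
    allele-informative read counts.  ``qual`` is the phred-scaled call
    quality.  ``flag`` carries record-level annotations (e.g. an empty pool
    in simulation, or a missing depth field on input).
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float
    depth_high: tuple[int, int]
    depth_low: tuple[int, int]
    flag: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        for ref_n, alt_n in (self.depth_high, self.depth_low):
            if ref_n < 0 or alt_n < 0:
                raise ValueError("read counts must be >= 0")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-base (SNP) alleles are allowed")

    def raf(self, pool: str) -> float | None:
        """Reference allele frequency in ``pool`` ('high' or 'low').

        Returns None when the pool has zero allele-informative reads.
        """
        ref_n, alt_n = self.depth_high if pool == "high" else self.depth_low
        total = ref_n + alt_n
        return None if total == 0 else ref_n / total


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three-rule filter cascade.

    min_qual
        Keep a variant iff its phred quality is >= this value (default 50;
        "less than 50" excluded).
    fixed_raf
        A pool counts as fixed for the non-reference allele when its
        reference allele frequency is below this value (default 0.01).
    min_reads
        Keep a variant iff both pools have at least this many
        allele-informative (ref + alt) reads (default 100).
    fixed_mode
        "both" (default): exclude only when the RAF is below ``fixed_raf`` in
        both pools — i.e. the variant is a fixed difference of both pools
        against the reference genome and carries no contrast information.
        "either": the stricter reading that excludes when either pool is
        below the threshold.
    """

    min_qual: float = 50.0
    fixed_raf: float = 0.01
    min_reads: int = 100
    fixed_mode: str = "both"

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if not (0 <= self.fixed_raf < 0.5):
            raise ValueError("fixed_raf must be in [0, 0.5)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.fixed_mode not in ("both", "either"):
            raise ValueError("fixed_mode must be 'both' or 'either'")


# ---------------------------------------------------------------------------
# filter cascade


def _passes_qual(v: PooledVariant, cfg: FilterConfig) -> bool:
    return v.qual >= cfg.min_qual


def _passes_fixed(v: PooledVariant, cfg: FilterConfig) -> bool:
    # A pool with zero depth has no defined RAF; the fixed rule never fires
    # on it (the depth rule is responsible for such records).
    rafs = [v.raf("high"), v.raf("low")]
    fixed = [r is not None and r < cfg.fixed_raf for r in rafs]
    if cfg.fixed_mode == "both":
        return not all(fixed)
    return not any(fixed)


def _passes_depth(v: PooledVariant, cfg: FilterConfig) -> bool:
    return (sum(v.depth_high) >= cfg.min_reads) and (sum(v.depth_low) >= cfg.min_reads)


RULES = (("qual", _passes_qual), ("fixed", _passes_fixed), ("depth", _passes_depth))


def filter_variants(
    variants: Iterable[PooledVariant], config: FilterConfig = FilterConfig()
) -> tuple[list[PooledVariant], dict[str, int]]:
    """Apply the quality -> fixed-allele -> depth cascade.

    Returns the kept records and a per-rule exclusion tally attributing each
    excluded record to the first rule it fails, so that
    ``kept + sum(tally.values()) == input count``.  Each rule is a pure
    predicate, so the kept set does not depend on rule order; only the
    attribution does.
    """
    kept: list[PooledVariant] = []
    tally: dict[str, int] = {name: 0 for name, _ in RULES}
    for v in variants:
        for name, rule in RULES:
            if not rule(v, config):
                tally[name] += 1
                break
        else:
            kept.append(v)
    return kept, tally


# ---------------------------------------------------------------------------
# VCF input


def read_pooled_vcf(
    path: str | Path, high_pool_name: str, low_pool_name: str
) -> tuple[list[PooledVariant], dict[str, int]]:
    """Read biallelic SNP records with per-pool RO/AO (or AD) depths.

    Multiallelic lines, indels and MNPs are skipped and counted, mirroring a
    caller run with complex/MNP/indel emission disabled.  Missing depth
    fields become zero counts with the record flagged.  Returns the records
    and a counter of skipped line classes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (high_pool_name, low_pool_name):
        if name not in samples:
            raise ValueError(
                f"pool sample {name!r} absent from VCF header (samples: {samples})"
            )
    i_high = samples.index(high_pool_name)
    i_low = samples.index(low_pool_name)

    records: list[PooledVariant] = []
    skipped: Counter[str] = Counter()
    for var in vcf:
        if len(var.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped["indel_or_mnp"] += 1
            continue
        def _fmt(tag):
            try:
                return var.format(tag)
            except KeyError:
                return None

        try:
            ro, ao = _fmt("RO"), _fmt("AO")
            if ro is not None and ao is not None:
                depths = [(int(ro[i][0]), int(ao[i][0])) for i in (i_high, i_low)]
            else:
                ad = _fmt("AD")
                if ad is None:
                    raise ValueError("no RO/AO or AD FORMAT field")
                depths = [(int(ad[i][0]), int(ad[i][1])) for i in (i_high, i_low)]
        except (ValueError, TypeError, IndexError) as exc:
            log.warning("skipping malformed depth at %s:%s (%s)", var.CHROM, var.POS, exc)
            skipped["malformed"] += 1
            continue
        flag = ""
        clean: list[tuple[int, int]] = []
        for ref_n, alt_n in depths:
            if ref_n < 0 or alt_n < 0:  # cyvcf2 missing-value sentinel
                flag = "missing_depth"
            clean.append((max(0, ref_n), max(0, alt_n)))
        depths = clean
        records.append(
            PooledVariant(
                chromosome=var.CHROM,
                position=var.POS,
                ref_allele=ref,
                alt_allele=alt,
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                depth_high=depths[0],  # type: ignore[arg-type]
                depth_low=depths[1],  # type: ignore[arg-type]
                flag=flag,
            )
        )
    if skipped:
        log.info("read_pooled_vcf skipped lines: %s", dict(skipped))
    return records, dict(skipped)


# ---------------------------------------------------------------------------
# VCF output


def write_pooled_vcf(
    variants: Sequence[PooledVariant],
    path: str | Path,
    high_pool_name: str = "HIGH",
    low_pool_name: str = "LOW",
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write records as VCF 4.2 with RO/AO FORMAT fields, one sample per pool."""
    if contigs is None:
        seen: dict[str, int] = {}
        for v in variants:
            seen[v.chromosome] = max(seen.get(v.chromosome, 0), v.position)
        contigs = list(seen.items())
    lines = ["##fileformat=VCFv4.2", "##source=poolscan"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + f"{high_pool_name}\t{low_pool_name}",
    ]
    for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
        qual = f"{v.qual:g}"
        hi = f"{v.depth_high[0]}:{v.depth_high[1]}"
        lo = f"{v.depth_low[0]}:{v.depth_low[1]}"
        lines.append(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
            f"{qual}\t.\t.\tRO:AO\t{hi}\t{lo}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
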