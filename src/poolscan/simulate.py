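"""Synthetic inbred-panel, trait and pooled read-count generation.

Emulates the data a pooled extreme-phenotype mapping experiment consumes:
a panel of fully inbred varieties genotyped at biallelic markers, a
quantitative trait built from additive effects at planted causal markers
plus Gaussian noise, and pooled sequencing read counts for a high/low
contrasting-set pair, drawn binomially from the true pool allele frequency
with an optional per-read base error.

The genotype model is deliberately simple: marker genotypes are independent
draws from per-marker founder allele frequencies (no linkage
disequilibrium), homozygous only, with missingness inserted at random.
Coverage per pool per variant is independent across markers
(Poisson by default, negative binomial optionally).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .variants import PooledVariant, write_pooled_vcf

if TYPE_CHECKING:  # pragma: no cover
    from .selection import ContrastSets

#: seven 600-Mbp chromosomes with a 100-Mbp pericentromeric block, a coarse
#: stand-in for a 7-chromosome inbred cereal genome
DEFAULT_CHROMOSOMES: tuple[tuple[str, int, int, int], ...] = tuple(
    (f"{i}H", 600_000_000, 250_000_000, 350_000_000) for i in range(1, 8)
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel and pooled-sequencing experiment.

    chromosomes
        ``(name, length_bp, centromere_start_bp, centromere_end_bp)`` tuples.
    founder_allele_freq_law
        ``("uniform", lo, hi)`` — per-marker reference allele frequency law.
    qtl_effects
        Additive effect sizes, in trait units per reference-homozygous
        genotype at the causal marker; must have length ``n_qtl``.
    qtl_freq_range
        Optional ``(lo, hi)``: founder frequencies of causal markers are
        redrawn uniformly in this range (keeps planted QTL segregating).
    coverage_law
        ``"poisson"`` or ``"negative_binomial(<dispersion>)"`` with variance
        ``mu + mu^2 / dispersion``.
    base_error
        Per-read probability of reading the opposite allele, in [0, 0.5).
    qual_law
        ``("constant", q)`` or ``("uniform", lo, hi)`` for the phred call
        quality attached to simulated variant records.
    """

    n_varieties: int = 400
    chromosomes: tuple[tuple[str, int, int, int], ...] = DEFAULT_CHROMOSOMES
    n_markers: int = 1000
    founder_allele_freq_law: tuple = ("uniform", 0.05, 0.95)
    n_qtl: int = 0
    qtl_effects: tuple[float, ...] = ()
    qtl_freq_range: tuple[float, float] | None = None
    noise_sd: float = 10.0
    pool_size: int = 12
    mean_coverage: float = 275.0
    coverage_law: str = "poisson"
    base_error: float = 0.001
    missing_genotype_rate: float = 0.01
    qual_law: tuple = ("constant", 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ConfigError("pool_size must be >= 2")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be > 0")
        if self.n_qtl != len(self.qtl_effects):
            raise ConfigError("qtl_effects must have length n_qtl")
        if self.n_qtl > self.n_markers:
            raise ConfigError("n_qtl cannot exceed n_markers")
        if not all(np.isfinite(self.qtl_effects)):
            raise ConfigError("all QTL effects must be finite")
        if not (0 <= self.base_error < 0.5):
            raise ConfigError("base_error must be in [0, 0.5)")
        if not (0 <= self.missing_genotype_rate < 1):
            raise ConfigError("missing_genotype_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name, length, cs, ce in self.chromosomes:
            if not (1 <= cs <= ce <= length):
                raise ConfigError(f"centromere interval outside chromosome {name}")
        self._parse_coverage_law()

    def _parse_coverage_law(self) -> tuple[str, float | None]:
        law = self.coverage_law
        if law == "poisson":
            return "poisson", None
        m = re.fullmatch(r"negative_binomial\(([-0-9.eE+]+)\)", law)
        if m:
            disp = float(m.group(1))
            if disp <= 0:
                raise ConfigError("negative binomial dispersion must be > 0")
            return "negative_binomial", disp
        raise ConfigError(f"unknown coverage_law {law!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("chromosomes",):
            if key in raw:
                raw[key] = tuple(tuple(c) for c in raw[key])
        for key in ("qtl_effects", "founder_allele_freq_law", "qual_law", "qtl_freq_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class VarietyPanel:
    """An inbred panel: trait means, genotypes and marker positions.

    ``genotypes`` is variety x marker int8 with codes 2 (reference
    homozygote), 0 (alternate homozygote) and -1 (missing).  ``markers`` has
    columns marker_id, chromosome, position, ref, alt, founder_freq;
    positions are strictly increasing within each chromosome.  ``causal``
    lists planted causal markers and their additive effects.
    """

    variety_ids: list[str]
    trait: np.ndarray
    genotypes: np.ndarray
    markers: pd.DataFrame
    causal: pd.DataFrame

    def members_index(self, members: Sequence[str]) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variety_ids)}
        missing = [m for m in members if m not in index]
        if missing:
            raise KeyError(f"varieties not in panel: {missing}")
        return np.array([index[m] for m in members], dtype=int)


def _draw_founder_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    law = config.founder_allele_freq_law
    if law[0] != "uniform":
        raise ConfigError(f"unsupported founder allele frequency law {law[0]!r}")
    return rng.uniform(law[1], law[2], size=config.n_markers)


def simulate_panel(config: SimConfig) -> VarietyPanel:
    """Draw an inbred variety panel with planted additive QTL.

    Genotypes at each marker are reference homozygotes with the marker's
    founder frequency, independently across markers and varieties.  The
    trait is the sum of the planted effects over causal reference-homozygous
    genotypes plus Normal(0, noise_sd^2) noise.  Missing genotype codes are
    inserted after the trait is computed, so the trait reflects the true
    underlying genotypes.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_varieties, config.n_markers

    # markers spread over chromosomes proportionally to length, sorted positions
    lengths = np.array([c[1] for c in config.chromosomes], dtype=float)
    counts = np.floor(m * lengths / lengths.sum()).astype(int)
    while counts.sum() < m:
        counts[int(np.argmin(counts / np.maximum(lengths, 1)))] += 1
    rows = []
    for (name, length, _cs, _ce), k in zip(config.chromosomes, counts):
        pos = np.unique(rng.integers(1, length + 1, size=k))
        while pos.size < k:  # redraw collisions; k << length so this is rare
            extra = rng.integers(1, length + 1, size=k - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        for p in pos:
            rows.append((name, int(p)))
    markers = pd.DataFrame(rows, columns=["chromosome", "position"])
    markers["marker_id"] = [
        f"M{c}_{p}" for c, p in zip(markers.chromosome, markers.position)
    ]
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    markers["ref"] = bases[ref_idx]
    markers["alt"] = bases[alt_idx]

    freqs = _draw_founder_freqs(config, rng)
    causal_cols = rng.choice(m, size=config.n_qtl, replace=False)
    if config.qtl_freq_range is not None and config.n_qtl:
        lo, hi = config.qtl_freq_range
        freqs[causal_cols] = rng.uniform(lo, hi, size=config.n_qtl)
    markers["founder_freq"] = freqs

    geno = np.where(rng.random((n, m)) < freqs[None, :], 2, 0).astype(np.int8)
    trait = rng.normal(0.0, config.noise_sd, size=n)
    for col, eff in zip(causal_cols, config.qtl_effects):
        trait = trait + eff * (geno[:, col] == 2)

    if config.missing_genotype_rate > 0:
        miss = rng.random((n, m)) < config.missing_genotype_rate
        geno = geno.copy()
        geno[miss] = -1

    causal = pd.DataFrame(
        {
            "marker_id": markers.marker_id.values[causal_cols],
            "chromosome": markers.chromosome.values[causal_cols],
            "position": markers.position.values[causal_cols],
            "effect": list(config.qtl_effects),
        }
    ).sort_values(["chromosome", "position"], ignore_index=True)

    ids = [f"V{i:04d}" for i in range(n)]
    return VarietyPanel(
        variety_ids=ids,
        trait=trait,
        genotypes=geno,
        markers=markers[["marker_id", "chromosome", "position", "ref", "alt", "founder_freq"]],
        causal=causal,
    )


def _draw_coverage(config: SimConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    law, disp = config._parse_coverage_law()
    mu = config.mean_coverage
    if law == "poisson":
        return rng.poisson(mu, size=size)
    # NB with mean mu, variance mu + mu^2/disp (gamma-Poisson mixture)
    return rng.negative_binomial(disp, disp / (disp + mu), size=size)


def _draw_qual(config: SimConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    law = config.qual_law
    if law[0] == "constant":
        return np.full(size, float(law[1]))
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    raise ConfigError(f"unknown qual_law {law[0]!r}")


def true_pool_rafs(panel: VarietyPanel, members: Sequence[str]) -> np.ndarray:
    """Per-marker reference allele frequency of a pool, missing calls dropped.

    NaN where every member is missing at a marker.
    """
    idx = panel.members_index(members)
    g = panel.genotypes[idx].astype(float)
    g[g < 0] = np.nan
    ref = np.nansum(g / 2.0, axis=0)
    n = np.isfinite(g).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ref / n
    out[n == 0] = np.nan
    return out


def simulate_pooled_reads(
    panel: VarietyPanel, sets: "ContrastSets", config: SimConfig
) -> list[PooledVariant]:
    """Draw pooled read counts for one high/low contrast.

    For each marker and pool, the true pool reference allele frequency is
    the reference-homozygote fraction among non-missing members; total reads
    are drawn from the coverage law and reference reads from
    ``Binomial(total, raf * (1 - e) + (1 - raf) * e)`` with base error
    ``e``.  A marker where a pool has no non-missing member is emitted with
    zero depth and flagged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1337]))
    m = len(panel.markers)
    rafs = {
        "high": true_pool_rafs(panel, sets.high_members),
        "low": true_pool_rafs(panel, sets.low_members),
    }
    totals = {p: _draw_coverage(config, m, rng) for p in ("high", "low")}
    quals = _draw_qual(config, m, rng)
    e = config.base_error

    depths: dict[str, np.ndarray] = {}
    for p in ("high", "low"):
        raf = rafs[p]
        ok = np.isfinite(raf)
        prob = np.where(ok, raf * (1 - e) + (1 - raf) * e, 0.0)
        tot = np.where(ok, totals[p], 0)
        ref = rng.binomial(tot, np.clip(prob, 0, 1))
        depths[p] = np.stack([ref, tot - ref], axis=1)

    records: list[PooledVariant] = []
    mk = panel.markers
    for j in range(m):
        flag = ""
        if not np.isfinite(rafs["high"][j]) or not np.isfinite(rafs["low"][j]):
            flag = "empty_pool"
        records.append(
            PooledVariant(
                chromosome=mk.chromosome.iat[j],
                position=int(mk.position.iat[j]),
                ref_allele=mk.ref.iat[j],
                alt_allele=mk.alt.iat[j],
                qual=float(quals[j]),
                depth_high=(int(depths["high"][j, 0]), int(depths["high"][j, 1])),
                depth_low=(int(depths["low"][j, 0]), int(depths["low"][j, 1])),
                flag=flag,
            )
        )
    return records


# ---------------------------------------------------------------------------
# fixture writers


def write_panel(panel: VarietyPanel, out_dir: str | Path, habit: str = "spring") -> None:
    """Write phenotype CSV, genotype CSV (0/2/NA), marker TSV and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"variety_id": panel.variety_ids, "habit": habit, "trait": panel.trait}
    ).to_csv(out / "pheno.csv", index=False, float_format="%.6g")
    geno = pd.DataFrame(
        panel.genotypes, index=panel.variety_ids, columns=panel.markers.marker_id
    ).astype(object)
    geno[geno == -1] = "NA"
    geno.to_csv(out / "geno.csv", index_label="variety_id")
    panel.markers.to_csv(out / "markers.tsv", sep="\t", index=False, float_format="%.6g")
    panel.causal.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")


def load_panel(
    pheno_csv: str | Path, geno_csv: str | Path, markers_tsv: str | Path | None = None
) -> VarietyPanel:
    """Rebuild a :class:`VarietyPanel` from phenotype/genotype (and marker) files."""
    pheno = pd.read_csv(pheno_csv)
    geno = pd.read_csv(geno_csv, index_col=0, na_values=["NA"])
    geno = geno.reindex(pheno.variety_id)
    genotypes = geno.to_numpy(dtype=float)
    genotypes[~np.isfinite(genotypes)] = -1
    if markers_tsv is not None:
        markers = pd.read_table(markers_tsv)
    else:
        markers = pd.DataFrame({"marker_id": geno.columns})
    return VarietyPanel(
        variety_ids=list(pheno.variety_id),
        trait=pheno.trait.to_numpy(dtype=float),
        genotypes=genotypes.astype(np.int8),
        markers=markers,
        causal=pd.DataFrame(columns=["marker_id", "chromosome", "position", "effect"]),
    )


def simulate_experiment(
    config: SimConfig,
    out_dir: str | Path | None = None,
    set_size: int | None = None,
    min_distance: float = 0.0,
) -> tuple[VarietyPanel, "ContrastSets", list[PooledVariant]]:
    """Panel -> contrasting sets -> pooled reads, optionally written to disk.

    ``min_distance`` defaults to 0 (pure phenotypic extremes): the simulated
    panel has no pedigree structure, so the diversity constraint is inert
    unless requested.
    """
    from .selection import build_contrast_sets

    panel = simulate_panel(config)
    sets = build_contrast_sets(
        panel, set_size=set_size or config.pool_size, min_distance=min_distance
    )
    reads = simulate_pooled_reads(panel, sets, config)
    if out_dir is not None:
        out = Path(out_dir)
        write_panel(panel, out)
        contigs = [(c[0], c[1]) for c in config.chromosomes]
        write_pooled_vcf(reads, out / "pooled.vcf", contigs=contigs)
        import json

        (out / "sets.json").write_text(
            json.dumps(
                {
                    "high_members": sets.high_members,
                    "low_members": sets.low_members,
                    "set_size": sets.set_size,
                    "min_distance": sets.min_distance,
                    "forced_members": sets.forced_members,
                    "skip_log": sets.skip_log,
                },
                indent=2,
            )
            + "\n"
        )
    return panel, sets, reads
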