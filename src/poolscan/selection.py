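"""Selection of phenotypically contrasting variety sets and structure checks.

Extreme-phenotype pools are built by ranking varieties on their trait mean
and greedily admitting them from the most extreme value inward, skipping any
candidate whose Euclidean genotype distance to an already admitted variety
falls below a threshold.  The admitted sets are then screened for
population-structure confounding with per-marker chi-squared homogeneity
tests whose sorted p-values are compared against a null QQ envelope.

Distances use 0/1 allele coding (homozygous inbred material) with
pairwise-complete handling of missing genotypes: the squared distance over
the markers complete for a pair is rescaled by ``n_markers / n_complete``,
matching the conventional treatment in R's ``dist``.  Under this coding a
distance of 20 corresponds to 400 differing markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import VarietyPanel

log = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """Raised when a contrasting set cannot be filled."""


@dataclass
class ContrastSets:
    """High/low contrasting-set membership with selection provenance."""

    high_members: list[str]
    low_members: list[str]
    set_size: int
    min_distance: float
    forced_members: list[str] = field(default_factory=list)
    skip_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.high_members) & set(self.low_members):
            raise ValueError("high and low sets must be disjoint")
        if len(self.high_members) != self.set_size or len(self.low_members) != self.set_size:
            raise ValueError("both sets must contain exactly set_size members")


@dataclass
class StructureCheck:
    """Per-marker homogeneity p-values with a QQ null envelope.

    ``per_marker_p`` is in input marker order; ``sorted_p`` pairs with
    ``expected_quantiles`` and the pointwise 95% band
    ``envelope_low``/``envelope_high``.  ``degenerate`` flags markers that
    were monomorphic within the selected lines (p fixed at 1).
    """

    per_marker_p: np.ndarray
    sorted_p: np.ndarray
    expected_quantiles: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    degenerate: np.ndarray

    def fraction_inside(self) -> float:
        """Fraction of sorted p-values inside the 95% envelope."""
        return float(
            ((self.sorted_p >= self.envelope_low) & (self.sorted_p <= self.envelope_high)).mean()
        )


# ---------------------------------------------------------------------------
# genotype coding and distances


def _allele_codes(genotypes: np.ndarray) -> np.ndarray:
    """Recode a genotype matrix to float 0/1 with NaN for missing.

    Accepts {0, 2} or {0, 1} homozygote codes with -1 or NaN as missing.
    """
    x = np.asarray(genotypes, dtype=float).copy()
    x[x < 0] = np.nan
    finite = x[np.isfinite(x)]
    if finite.size and np.nanmax(finite) > 1:
        x = x / 2.0
    if np.nanmax(x[np.isfinite(x)], initial=0.0) > 1 or np.nanmin(
        x[np.isfinite(x)], initial=0.0
    ) < 0:
        raise ValueError("genotype codes must be {0,2} or {0,1} with -1/NaN missing")
    return x


def euclidean_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distances between variety genotype rows.

    For each pair the squared distance over mutually non-missing markers is
    rescaled by ``n_markers / n_complete`` before the square root.  A pair
    with no complete marker gets NaN and a warning.
    """
    x = _allele_codes(genotypes)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least two varieties")
    mask = np.isfinite(x).astype(float)
    xf = np.nan_to_num(x)
    sq = xf**2
    # sum over complete markers of (xi - xj)^2, via masked cross terms
    raw = sq @ mask.T + mask @ sq.T - 2.0 * (xf @ xf.T)
    n_complete = mask @ mask.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = raw * (m / n_complete)
    d2[n_complete == 0] = np.nan
    np.fill_diagonal(d2, 0.0)
    if np.isnan(d2).any():
        warnings.warn(
            "some variety pairs share no complete markers; their distance is undefined (NaN)",
            RuntimeWarning,
        )
    d2 = np.clip(d2, 0.0, None)
    return np.sqrt(d2)


# ---------------------------------------------------------------------------
# greedy extreme-set selection


def select_contrasting_sets(
    panel: "VarietyPanel",
    tail: str,
    set_size: int = 12,
    min_distance: float = 20.0,
    forced: Sequence[str] = (),
    distance_matrix: np.ndarray | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedily select one phenotypic extreme set under a distance constraint.

    Candidates are scanned in trait order starting from the most extreme
    value (descending for ``tail='high'``, ascending for ``'low'``; ties
    broken by input order).  A candidate is admitted iff its distance to
    every already admitted member is at least ``min_distance``.  ``forced``
    members are admitted first, exempt from the distance rule.

    Returns the admitted variety ids and an ordered skip log of
    ``(variety, reason)`` pairs.
    """
    if tail not in ("high", "low"):
        raise ValueError("tail must be 'high' or 'low'")
    ids = list(panel.variety_ids)
    index = {v: i for i, v in enumerate(ids)}
    for f in forced:
        if f not in index:
            raise ValueError(f"forced member {f!r} not in panel")
    if distance_matrix is None:
        distance_matrix = euclidean_distance_matrix(panel.genotypes)

    trait = np.asarray(panel.trait, dtype=float)
    usable = np.isfinite(trait)
    order = np.argsort(-trait if tail == "high" else trait, kind="stable")
    order = [i for i in order if usable[i] and ids[i] not in set(forced)]

    selected: list[int] = [index[f] for f in forced]
    skip_log: list[tuple[str, str]] = []
    for i in order:
        if len(selected) >= set_size:
            break
        d = distance_matrix[i, selected] if selected else np.array([])
        if np.isnan(d).any():
            skip_log.append((ids[i], "undefined distance to a selected line"))
            continue
        if d.size and d.min() < min_distance:
            j = selected[int(np.argmin(d))]
            skip_log.append((ids[i], f"distance {d.min():.3g} to {ids[j]} < {min_distance:g}"))
            continue
        selected.append(i)
    if len(selected) < set_size:
        raise SelectionError(
            f"candidates exhausted: {len(selected)} of {set_size} {tail}-set members "
            f"admitted at min_distance={min_distance:g}"
        )
    return [ids[i] for i in selected[:set_size]], skip_log


def build_contrast_sets(
    panel: "VarietyPanel",
    set_size: int = 12,
    min_distance: float = 20.0,
    forced_high: Sequence[str] = (),
    forced_low: Sequence[str] = (),
) -> ContrastSets:
    """Select both extremes of the trait distribution as a :class:`ContrastSets`."""
    dmat = euclidean_distance_matrix(panel.genotypes)
    high, skip_h = select_contrasting_sets(
        panel, "high", set_size, min_distance, forced_high, distance_matrix=dmat
    )
    low, skip_l = select_contrasting_sets(
        panel, "low", set_size, min_distance, forced_low, distance_matrix=dmat
    )
    return ContrastSets(
        high_members=high,
        low_members=low,
        set_size=set_size,
        min_distance=min_distance,
        forced_members=list(forced_high) + list(forced_low),
        skip_log=skip_h + skip_l,
    )


# ---------------------------------------------------------------------------
# population-structure check


def _chi2_2x2_vectorised(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Pearson chi-squared (1 df, no continuity correction) for stacked 2x2 tables."""
    n = a + b + c + d
    num = n * (a * d - b * c).astype(float) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi = np.zeros_like(num, dtype=float)
    ok = den > 0
    chi[ok] = num[ok] / den[ok]
    return chi, ~ok


def structure_check(
    genotypes: np.ndarray,
    membership: Sequence[str] | np.ndarray,
    envelope: str = "beta",
    n_null: int = 200,
    seed: int | None = 0,
) -> StructureCheck:
    """Test the selected lines for allele/set-membership association.

    For each marker a 2x2 count table of allele (ref/alt, one call per
    inbred line, missing dropped) against set membership is tested with a
    Pearson chi-squared (1 df, no continuity correction).  Monomorphic
    markers within the selected lines get p = 1 and are flagged.

    The sorted p-values are paired with expected quantiles and a pointwise
    95% envelope.  ``envelope='beta'`` uses the uniform order-statistic
    band Beta(i, m - i + 1); this is exact for continuous p-values but
    anti-conservative for the discrete p-values produced by small 2x2
    tables.  ``envelope='permutation'`` draws the band from ``n_null``
    random relabelings of set membership, which respects that discreteness.
    """
    lab = np.asarray(membership)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("membership must contain exactly two groups")
    x = _allele_codes(genotypes)
    in_a = lab == groups[0]

    def _pvalues(in_first: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ga, gb = x[in_first], x[~in_first]
        a = np.nansum(ga, axis=0)  # ref calls in group A
        b = np.sum(np.isfinite(ga), axis=0) - a
        c = np.nansum(gb, axis=0)
        d = np.sum(np.isfinite(gb), axis=0) - c
        chi, degen = _chi2_2x2_vectorised(a, b, c, d)
        p = stats.chi2.sf(chi, df=1)
        p[degen] = 1.0
        return p, degen

    p, degen = _pvalues(in_a)
    m = p.size
    i = np.arange(1, m + 1)
    sorted_p = np.sort(p)

    if envelope == "beta":
        expected = i / (m + 1)
        lo = stats.beta.ppf(0.025, i, m - i + 1)
        hi = stats.beta.ppf(0.975, i, m - i + 1)
    elif envelope == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty((n_null, m))
        base = in_a.copy()
        for k in range(n_null):
            null[k] = np.sort(_pvalues(rng.permutation(base))[0])
        expected = null.mean(axis=0)
        lo = np.percentile(null, 2.5, axis=0)
        hi = np.percentile(null, 97.5, axis=0)
    else:
        raise ValueError("envelope must be 'beta' or 'permutation'")

    if degen.any():
        log.info("structure_check: %d monomorphic markers set to p=1", int(degen.sum()))
    return StructureCheck(
        per_marker_p=p,
        sorted_p=sorted_p,
        expected_quantiles=expected,
        envelope_low=lo,
        envelope_high=hi,
        degenerate=degen,
    )
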