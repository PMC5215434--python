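"""Poisson-corrected distance estimators and meta-combination tests.

The substitution proportion ``p`` between human positions and their
orthologous residues in one reference organism is binomial, so
``var(p) = p(1-p)/n``.  The Poisson correction ``d = -ln(1-p)`` accounts for
multiple substitutions at a position and is linear in divergence time under a
per-residue Poisson substitution process; its variance follows by the delta
method, ``var(d) = var(p)/(1-p)^2``.

Sites and their flanking background are contrasted per organism with a
two-sample z statistic and across organisms with a chi-square combination of
the squared z scores (df = number of organisms).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats as sps

from .types import GAP, SiteObservation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionCount:
    """Pooled counts of differing vs compared residues for one group/organism."""

    n_diff: int
    n_total: int
    group_id: str = ""
    organism: str = ""
    region: str = "sites"

    def __post_init__(self) -> None:
        if not 0 <= self.n_diff <= self.n_total:
            raise ValueError(
                f"need 0 <= n_diff <= n_total, got ({self.n_diff}, {self.n_total})"
            )


@dataclass(frozen=True)
class PoissonEstimate:
    """Difference proportion and Poisson-corrected distance with variances."""

    p: float
    var_p: float
    d: float
    var_d: float
    n_total: int
    n_diff: int = 0
    group_id: str = ""
    organism: str = ""
    region: str = "sites"

    @property
    def se_d(self) -> float:
        return math.sqrt(self.var_d)


@dataclass(frozen=True)
class TwoSampleZ:
    """z contrast of two distance (or ratio) estimates for one organism."""

    z: float
    p_value: float
    organism: str = ""


@dataclass(frozen=True)
class ChiSquareCombined:
    """Sum of squared z across organisms ~ chi-square with df = n organisms."""

    statistic: float
    df: int
    p_value: float
    mean_z: float


def count_substitutions(
    observations: Iterable[SiteObservation],
    *,
    gap_as_diff: bool = True,
    group_id: str = "",
    organism: str = "",
    region: str = "",
) -> SubstitutionCount:
    """Pool observations of one group/organism into (n_diff, n_total).

    A residue counts as different when it is not identical to the human
    residue at that position.  Gaps in the ortholog count as different when
    ``gap_as_diff`` (a deleted site cannot carry the modification) and are
    excluded from the comparison otherwise.  MISSING orthologs (None) never
    contribute.  Pooling is across all positions of the group, not a per-site
    average.
    """
    n_diff = 0
    n_total = 0
    reg = region
    for obs in observations:
        r = obs.ortholog_residue
        if r is None:
            continue
        if not reg:
            reg = obs.region
        if r == GAP:
            if gap_as_diff:
                n_diff += 1
                n_total += 1
            continue
        n_total += 1
        if r != obs.human_residue:
            n_diff += 1
    if n_total == 0:
        raise ValueError(f"empty group: no comparable residues ({group_id!r})")
    return SubstitutionCount(
        n_diff=n_diff, n_total=n_total, group_id=group_id,
        organism=organism, region=reg or "sites",
    )


def poisson_estimate(
    count: SubstitutionCount, *, clamp_p1: bool = True
) -> PoissonEstimate:
    """Poisson-corrected distance for pooled substitution counts.

    p = n_diff / n_total, var(p) = p(1-p)/n, d = -ln(1-p),
    var(d) = var(p)/(1-p)^2.  A saturated group (p = 1) yields an infinite
    distance; it is clamped to (n-0.5)/n with a warning by default so tiny
    pooled groups do not abort a pipeline run (set ``clamp_p1=False`` for a
    hard error).
    """
    n = count.n_total
    if n < 1:
        raise ValueError("n_total must be >= 1")
    p = count.n_diff / n
    if p >= 1.0:
        if not clamp_p1:
            raise ValueError(
                f"saturated group ({count.group_id!r}/{count.organism!r}): "
                "all residues differ; Poisson distance undefined"
            )
        p = (n - 0.5) / n
        logger.warning(
            "clamped saturated proportion to %.6g for group %r organism %r",
            p, count.group_id, count.organism,
        )
    var_p = p * (1.0 - p) / n
    d = -math.log1p(-p)
    var_d = var_p / (1.0 - p) ** 2
    return PoissonEstimate(
        p=p, var_p=var_p, d=d, var_d=var_d, n_total=n, n_diff=count.n_diff,
        group_id=count.group_id, organism=count.organism, region=count.region,
    )


def two_sample_z(
    a_value: float, a_var: float, b_value: float, b_var: float,
    organism: str = "",
) -> TwoSampleZ:
    """z = (a - b)/sqrt(var_a + var_b) with a two-sided normal p-value."""
    denom = a_var + b_var
    if denom <= 0:
        raise ValueError("both variances are zero; z undefined")
    z = (a_value - b_value) / math.sqrt(denom)
    p = 2.0 * sps.norm.sf(abs(z))
    return TwoSampleZ(z=z, p_value=min(p, 1.0), organism=organism)


def z_site_vs_flank(
    sites: PoissonEstimate, flanks: PoissonEstimate
) -> TwoSampleZ:
    """Contrast site vs flanking-background distance in one organism.

    Negative z: sites are more conserved (evolve slower) than their flanks.
    """
    if not (math.isfinite(sites.d) and math.isfinite(flanks.d)):
        raise ValueError("non-finite distance estimate")
    return two_sample_z(
        sites.d, sites.var_d, flanks.d, flanks.var_d,
        organism=sites.organism or flanks.organism,
    )


def combine_chi_square(z_list: Sequence[TwoSampleZ]) -> ChiSquareCombined:
    """Combine per-organism z scores: sum of z^2 ~ chi-square, df = len."""
    zs = [t.z for t in z_list if math.isfinite(t.z)]
    if not zs:
        raise ValueError("no finite z scores to combine")
    stat = sum(z * z for z in zs)
    df = len(zs)
    p = float(sps.chi2.sf(stat, df))
    return ChiSquareCombined(
        statistic=stat, df=df, p_value=p, mean_z=sum(zs) / df
    )


def significance_stars(p_value: Optional[float]) -> str:
    """Render the conventional tiers: * <0.05, ** <0.01, *** <0.001."""
    if p_value is None or not math.isfinite(p_value):
        return ""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""
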