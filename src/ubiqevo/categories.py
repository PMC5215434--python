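"""Group-level constraints: relative distances, tissue specificity, hubs.

Relative Poisson distance normalizes the site distance of a protein group by
the distance of the flanking background of the same group, removing
group-level conservation differences (a globally conserved group has slowly
evolving flanks too).  Its variance follows from the delta method for a ratio
of independent estimates.

Tissue-specificity (TSPS) is the relative entropy, in bits, between a
protein's fractional expression across tissues and the uniform distribution:
0 for uniform expression ("facilitator" when < 1), log2(n_tissues) for
single-tissue expression ("specifier" when >= 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .stats import PoissonEstimate, TwoSampleZ, two_sample_z

logger = logging.getLogger(__name__)

#: Proteins with more than this many distinct interaction partners are hubs.
HUB_MIN_DEGREE_EXCLUSIVE = 20

#: TSPS below this threshold -> facilitator, at/above -> specifier.
TSPS_THRESHOLD = 1.0


@dataclass(frozen=True)
class RelativeEstimate:
    """Ratio of site to flank Poisson distance with delta-method variance."""

    r: float
    var_r: float
    group_id: str = ""
    organism: str = ""


@dataclass(frozen=True)
class TSPSResult:
    protein_id: str
    tsps: float
    tsps_class: str  # "facilitator" | "specifier"


@dataclass(frozen=True)
class DegreeRecord:
    protein_id: str
    degree: int
    is_hub: bool


def relative_distance(
    sites: PoissonEstimate, flanks: PoissonEstimate
) -> RelativeEstimate:
    """r = d_sites / d_flanks; var(r) = var_d/d'^2 + d^2 var_d'/d'^4."""
    d, dp = sites.d, flanks.d
    if dp <= 0:
        raise ValueError(
            f"degenerate background: flank distance is zero "
            f"({sites.group_id!r}/{sites.organism!r})"
        )
    r = d / dp
    var_r = sites.var_d / dp**2 + d**2 * flanks.var_d / dp**4
    return RelativeEstimate(
        r=r, var_r=var_r,
        group_id=sites.group_id or flanks.group_id,
        organism=sites.organism or flanks.organism,
    )


def compare_groups(
    r_i: RelativeEstimate, r_j: RelativeEstimate
) -> TwoSampleZ:
    """z contrast of the relative distances of two protein groups.

    Positive z: group i's sites evolve faster (relative to their own flanks)
    than group j's.
    """
    if not (math.isfinite(r_i.r) and math.isfinite(r_j.r)):
        raise ValueError("non-finite relative estimate")
    return two_sample_z(
        r_i.r, r_i.var_r, r_j.r, r_j.var_r,
        organism=r_i.organism or r_j.organism,
    )


def tsps(expression: Sequence[float], protein_id: str = "") -> TSPSResult:
    """Tissue-specificity score of one nonnegative expression vector.

    TSPS = sum_j p_j * log2(p_j / q_j) with p the fractional expression,
    q uniform over tissues, and the convention 0*log(0) = 0.
    """
    e = np.asarray(expression, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("expression must be a vector over >= 2 tissues")
    if np.any(e < 0):
        raise ValueError(f"negative expression value for {protein_id!r}")
    total = e.sum()
    if total <= 0:
        raise ValueError(f"all-zero expression vector for {protein_id!r}")
    p = e / total
    nz = p > 0
    score = float(np.sum(p[nz] * np.log2(p[nz] * e.size)))
    score = max(score, 0.0)  # guard tiny negative rounding
    cls = "facilitator" if score < TSPS_THRESHOLD else "specifier"
    return TSPSResult(protein_id=protein_id, tsps=score, tsps_class=cls)


def tsps_table(expression_df) -> List[TSPSResult]:
    """TSPS per protein from a proteins x tissues DataFrame.

    All-zero proteins are excluded with a warning rather than aborting.
    """
    out: List[TSPSResult] = []
    for pid, row in expression_df.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.sum() <= 0:
            logger.warning("excluding protein %r: all-zero expression", pid)
            continue
        out.append(tsps(vals, protein_id=str(pid)))
    return out


def degree_and_hubs(
    edges: Iterable[Tuple[str, str]],
    proteins: Iterable[str] = (),
    *,
    min_degree_exclusive: int = HUB_MIN_DEGREE_EXCLUSIVE,
) -> List[DegreeRecord]:
    """Distinct-partner degree per protein; hub iff degree > threshold.

    Self-loops are dropped; duplicate and reversed edges collapse to one
    undirected edge.  ``proteins`` seeds zero-degree records for isolated
    proteins not present in the edge list.
    """
    partners: Dict[str, set] = {p: set() for p in proteins}
    for a, b in edges:
        if a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return [
        DegreeRecord(
            protein_id=p,
            degree=len(ps),
            is_hub=len(ps) > min_degree_exclusive,
        )
        for p, ps in sorted(partners.items())
    ]
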