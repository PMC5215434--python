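"""Gain-epoch inference along the divergence order and category enrichment.

A human ubiquitination lysine is timed by the most distant reference organism
still carrying a lysine at the orthologous position: the site is inferred to
have emerged at the boundary just beyond that organism.  Organisms without an
ortholog (MISSING) are uninformative and skipped.  In strict mode a lysine is
additionally required in every informative organism closer than the inferred
boundary; a profile with an interior loss is reported as unresolved instead
of guessed.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from scipy.stats import hypergeom

from .types import EnrichmentResult, GainEvent, OrganismOrder, SiteRecord


def infer_gain_epoch(
    site: SiteRecord,
    profile: Sequence[Optional[str]],
    order: OrganismOrder,
    *,
    mode: str = "first_appearance",
) -> Optional[GainEvent]:
    """Infer the emergence boundary of a site from its residue ladder.

    Returns None when the profile is unresolved (strict mode with an
    interior non-lysine).  The event is flagged ``low_coverage`` when every
    organism beyond the most distant lysine is MISSING, so the boundary is
    only the youngest epoch consistent with the data.
    """
    if site.residue != "K":
        raise ValueError(
            f"{site.protein_id}@{site.position}: human residue is "
            f"{site.residue!r}, expected 'K'"
        )
    if mode not in ("first_appearance", "strict"):
        raise ValueError(f"unknown gain inference mode {mode!r}")
    if len(profile) != len(order):
        raise ValueError(
            f"profile length {len(profile)} != organism count {len(order)}"
        )

    deepest_k = -1
    for idx, res in enumerate(profile):
        if res == "K":
            deepest_k = idx
    boundary = deepest_k + 1

    if mode == "strict":
        for idx in range(deepest_k):
            if profile[idx] is not None and profile[idx] != "K":
                return None  # interior loss: unresolved

    low_coverage = boundary < len(order) and all(
        profile[idx] is None for idx in range(boundary, len(order))
    )
    return GainEvent(
        site=site,
        boundary=boundary,
        epoch=order.label(boundary),
        residues=tuple(profile),
        low_coverage=low_coverage,
    )


def count_gains_per_epoch(
    events: Iterable[GainEvent], order: OrganismOrder
) -> Dict[str, int]:
    """Site counts per boundary label, youngest first; zeros included."""
    counts = Counter(e.boundary for e in events)
    return {
        order.label(b): counts.get(b, 0) for b in range(len(order) + 1)
    }


def enrichment(
    gained_proteins: Set[str],
    background: Set[str],
    categories: Mapping[str, Set[str]],
    *,
    epoch: str = "",
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment/depletion of categories among gained proteins.

    For a category with K of the N background proteins and k of the n gained
    proteins, the enrichment p-value is P[X >= k] and the depletion p-value
    P[X <= k] for X ~ Hypergeom(N, K, n); the reported direction is the
    smaller tail.  The expectation n*K/N is the "random expectation".
    Bonferroni correction is across the categories tested at one epoch.
    """
    if not background:
        raise ValueError("background protein set is empty")
    extra = gained_proteins - background
    if extra:
        raise ValueError(
            f"gained proteins not in background: {sorted(extra)[:5]}"
        )
    N = len(background)
    n = len(gained_proteins)
    tested = {
        name: members & background for name, members in categories.items()
    }
    m = len(tested)
    results: List[EnrichmentResult] = []
    for name in sorted(tested):
        members = tested[name]
        K = len(members)
        k = len(gained_proteins & members)
        expected = n * K / N
        p_upper = float(hypergeom.sf(k - 1, N, K, n))
        p_lower = float(hypergeom.cdf(k, N, K, n))
        if p_upper <= p_lower:
            p, direction = p_upper, "enriched"
        else:
            p, direction = p_lower, "depleted"
        results.append(
            EnrichmentResult(
                epoch=epoch,
                category=name,
                observed=k,
                expected=expected,
                p_value=p,
                corrected_p=min(1.0, p * m),
                direction=direction,
            )
        )
    return results
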