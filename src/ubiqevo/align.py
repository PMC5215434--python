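"""Human-anchored pairwise alignment and site/flank mapping.

The aligner is a global Needleman-Wunsch with affine gap penalties (Gotoh's
three-state recursion).  Default scoring is BLOSUM62 with gap open 10 and gap
extend 1; a gap of length L costs ``open + (L-1) * extend``.  Downstream
analysis uses residue identity only, so any fixed, documented alignment
convention suffices; ties are broken by preferring a match/mismatch step over
a gap in the second sequence over a gap in the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from Bio.Align import substitution_matrices

from .types import (
    AMINO_ACIDS,
    GAP,
    MISSING,
    AlignedOrthologPair,
    OrganismOrder,
    SiteObservation,
    SiteRecord,
)

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix name plus affine gap penalties (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def substitution(self) -> dict:
        mat = substitution_matrices.load(self.matrix)
        return {
            (a, b): float(mat[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }


DEFAULT_SCORING = AlignmentScoring()


def global_align(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    *,
    human_id: str = "",
    organism: str = "",
    ortholog_id: str = "",
) -> AlignedOrthologPair:
    """Optimal global alignment of two protein sequences (affine gaps).

    States: M (a[i] aligned to b[j]), X (gap in ``seq_b``, consuming a[i]),
    Y (gap in ``seq_a``, consuming b[j]).  Returns the maximal-score alignment
    with deterministic tie-breaking M > X > Y.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{name} contains illegal characters: {sorted(bad)}")

    sub = scoring.substitution()
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(seq_a), len(seq_b)

    # Score and traceback matrices per state; traceback stores the
    # predecessor state (0=M, 1=X, 2=Y).
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    tb_m = [[0] * (m + 1) for _ in range(n + 1)]
    tb_x = [[0] * (m + 1) for _ in range(n + 1)]
    tb_y = [[0] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -go - (i - 1) * ge
        tb_x[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = -go - (j - 1) * ge
        tb_y[0][j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, seq_b[j - 1])]
            # M: diagonal step from any state (tie-break M > X > Y).
            best, state = prev_m[j - 1], 0
            if prev_x[j - 1] > best:
                best, state = prev_x[j - 1], 1
            if prev_y[j - 1] > best:
                best, state = prev_y[j - 1], 2
            row_m[j] = best + s
            tb_m[i][j] = state
            # X: consume a[i], gap in b. Open from M or Y, extend from X.
            best, state = prev_m[j] - go, 0
            if prev_x[j] - ge > best:
                best, state = prev_x[j] - ge, 1
            if prev_y[j] - go > best:
                best, state = prev_y[j] - go, 2
            row_x[j] = best
            tb_x[i][j] = state
            # Y: consume b[j], gap in a. Open from M or X, extend from Y.
            best, state = row_m[j - 1] - go, 0
            if row_x[j - 1] - go > best:
                best, state = row_x[j - 1] - go, 1
            if row_y[j - 1] - ge > best:
                best, state = row_y[j - 1] - ge, 2
            row_y[j] = best
            tb_y[i][j] = state

    # Final state with tie-break M > X > Y.
    end_scores = (M[n][m], X[n][m], Y[n][m])
    state = max(range(3), key=lambda k: (end_scores[k], -k))
    score = end_scores[state]

    out_a: List[str] = []
    out_b: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i][j]
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            prev = tb_x[i][j]
            out_a.append(seq_a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            prev = tb_y[i][j]
            out_a.append(GAP)
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev

    return AlignedOrthologPair(
        human_id=human_id,
        organism=organism,
        aligned_human="".join(reversed(out_a)),
        aligned_ortholog="".join(reversed(out_b)),
        ortholog_id=ortholog_id,
        score=score,
    )


def map_site(
    pair: AlignedOrthologPair, position: int, *, region: str = "sites"
) -> SiteObservation:
    """Residue of the ortholog in the alignment column of a human position."""
    cols = pair.column_of_human_position
    if position not in cols:
        raise ValueError(
            f"{pair.human_id}: position {position} outside protein "
            f"(length {len(cols)})"
        )
    col = cols[position]
    return SiteObservation(
        protein_id=pair.human_id,
        position=position,
        human_residue=pair.aligned_human[col],
        organism=pair.organism,
        ortholog_residue=pair.aligned_ortholog[col],
        region=region,
    )


def flank_positions(
    protein_length: int, site_position: int, half_width: int = 5
) -> List[int]:
    """The flanking background: up to ``half_width`` residues on each side of
    the site, site itself excluded, truncated at the protein termini."""
    if not 1 <= site_position <= protein_length:
        raise ValueError(
            f"site position {site_position} outside protein of length "
            f"{protein_length}"
        )
    lo = max(1, site_position - half_width)
    hi = min(protein_length, site_position + half_width)
    return [p for p in range(lo, hi + 1) if p != site_position]


def build_species_ladder_profile(
    site: SiteRecord,
    pairs: Dict[str, AlignedOrthologPair],
    order: OrganismOrder,
) -> List[Optional[str]]:
    """Per-organism residue vector at a site, ordered nearest-first.

    Entries are one-letter residues, '-' for an alignment gap, or None
    (MISSING) where the organism has no ortholog of the protein.
    """
    profile: List[Optional[str]] = []
    for organism in order.names:
        pair = pairs.get(organism)
        if pair is None:
            profile.append(MISSING)
            continue
        if pair.human_id != site.protein_id:
            raise ValueError(
                f"pair for {organism} references {pair.human_id}, "
                f"expected {site.protein_id}"
            )
        profile.append(map_site(pair, site.position).ortholog_residue)
    return profile
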