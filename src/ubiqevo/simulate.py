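"""Synthetic datasets with known ground truth.

The generator emulates the statistical structure of the pipeline's inputs: a
set of human proteins carrying ubiquitination lysines, orthologs in an
ordered ladder of reference organisms at increasing divergence, functional
category labels with optional rate effects, Dirichlet expression profiles
spanning near-uniform to single-tissue, a degree-heterogeneous interaction
network, and optionally planted gain epochs along the ladder.

Substitution model: each residue accumulates Poisson(depth x multiplier)
substitution events; every event replaces the residue with one of the 19
other amino acids uniformly.  This matches the assumptions of the
Poisson-corrected distance estimator and keeps back-substitution analytically
tractable: the probability that a residue differs from human after rate
``lam`` is (19/20) * (1 - exp(-20*lam/19)).

All randomness flows from one seeded generator, so the full bundle is a pure
function of the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    AMINO_ACIDS,
    AlignedOrthologPair,
    OrganismOrder,
    SiteRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_K_INDEX = AMINO_ACIDS.index("K")

#: Default 14-organism ladder, nearest to human first, with synthetic
#: divergence depths (expected substitutions per background residue).
DEFAULT_ORGANISMS: Tuple[Tuple[str, float], ...] = (
    ("G. gorilla", 0.05),
    ("M. mulatta", 0.08),
    ("R. norvegicus", 0.15),
    ("M. musculus", 0.18),
    ("G. gallus", 0.30),
    ("X. tropicalis", 0.40),
    ("D. rerio", 0.55),
    ("D. melanogaster", 0.90),
    ("A. gambiae", 1.10),
    ("C. elegans", 1.40),
    ("K. lactis", 1.90),
    ("S. cerevisiae", 2.10),
    ("N. crassa", 2.40),
    ("S. pombe", 2.80),
)

#: Named divergence boundaries on the default ladder (cut-point indices).
DEFAULT_EPOCHS: Dict[str, int] = {
    "primate": 2,
    "mammalian": 4,
    "vertebrate": 7,
    "animal": 10,
    "eukaryote": 14,
}


def expected_difference_proportion(lam: float) -> float:
    """P(residue differs from human) under the uniform 20-state jump model."""
    return (19.0 / 20.0) * (1.0 - np.exp(-lam * 20.0 / 19.0))


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 200
    protein_length_range: Tuple[int, int] = (200, 400)
    sites_per_protein: int = 3
    organisms: Tuple[Tuple[str, float], ...] = DEFAULT_ORGANISMS
    epochs: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EPOCHS))
    background_rate_multiplier: float = 1.0
    site_rate_multiplier: float = 1.0
    flank_rate_multiplier: float = 1.0
    flank_half_width: int = 5
    indel_rate: float = 0.0
    #: (label, site-rate multiplier) pairs; each protein gets one label.
    category_labels: Tuple[Tuple[str, float], ...] = (
        ("metabolism", 1.0),
        ("signaling", 1.0),
    )
    category_namespace: str = "kegg"
    n_tissues: int = 32
    #: Dirichlet concentration per expression class.
    expression_concentration: Dict[str, float] = field(
        default_factory=lambda: {"facilitator": 5.0, "specifier": 0.05}
    )
    facilitator_fraction: float = 0.5
    hub_fraction: float = 0.1
    hub_degree_range: Tuple[int, int] = (25, 60)
    degree_exponent: float = 2.5
    #: epoch name -> number of sites planted with that gain epoch.
    planted_gain_epochs: Dict[str, int] = field(default_factory=dict)
    #: fraction of planted sites given one detectable (interior) loss.
    gain_loss_rate: float = 0.0
    missing_ortholog_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if lo < 25 or hi < lo:
            raise ValidationError(
                "protein_length_range: min must be >= 25 and <= max"
            )
        if self.sites_per_protein < 1:
            raise ValidationError("sites_per_protein must be >= 1")
        if not self.organisms:
            raise ValidationError("organisms must be nonempty")
        depths = [d for _, d in self.organisms]
        if any(d < 0 for d in depths):
            raise ValidationError("organisms: divergence depths must be >= 0")
        if any(b > a for a, b in zip(depths[1:], depths)):
            raise ValidationError(
                "organisms must be ordered by nondecreasing divergence depth"
            )
        for name, mult in (
            ("background_rate_multiplier", self.background_rate_multiplier),
            ("site_rate_multiplier", self.site_rate_multiplier),
            ("flank_rate_multiplier", self.flank_rate_multiplier),
            ("indel_rate", self.indel_rate),
            ("gain_loss_rate", self.gain_loss_rate),
            ("missing_ortholog_rate", self.missing_ortholog_rate),
        ):
            if mult < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2")
        if not 0 <= self.facilitator_fraction <= 1:
            raise ValidationError("facilitator_fraction must be in [0, 1]")
        if not 0 <= self.hub_fraction <= 1:
            raise ValidationError("hub_fraction must be in [0, 1]")
        names = [n for n, _ in self.organisms]
        for epoch, b in self.epochs.items():
            if not 0 <= b <= len(names):
                raise ValidationError(
                    f"epochs[{epoch!r}]: boundary {b} outside [0, {len(names)}]"
                )
        n_sites = self.n_proteins * self.sites_per_protein
        planted = sum(self.planted_gain_epochs.values())
        if planted > n_sites:
            raise ValidationError(
                f"planted_gain_epochs: {planted} sites requested but only "
                f"{n_sites} generated"
            )
        for epoch in self.planted_gain_epochs:
            if epoch not in self.epochs:
                raise ValidationError(
                    f"planted_gain_epochs: unknown epoch {epoch!r}"
                )

    def organism_order(self) -> OrganismOrder:
        return OrganismOrder(
            names=tuple(n for n, _ in self.organisms), epochs=dict(self.epochs)
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    protein_category: Dict[str, str]
    expression_class: Dict[str, str]
    degree: Dict[str, int]
    site_rate_multiplier: Dict[Tuple[str, int], float]
    gain_epoch: Dict[Tuple[str, int], Optional[str]]
    gain_boundary: Dict[Tuple[str, int], Optional[int]]
    loss_organism: Dict[Tuple[str, int], Optional[str]]


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated inputs plus ground truth."""

    config: SimulationConfig
    organism_order: OrganismOrder
    sequences: Dict[str, str]
    sites: List[SiteRecord]
    ortholog_map: List[Tuple[str, str, str]]  # (human_id, organism, ortholog_id)
    aligned_pairs: Dict[str, Dict[str, AlignedOrthologPair]]
    annotations: Dict[str, Dict[str, set]]  # pid -> namespace -> categories
    expression: pd.DataFrame  # proteins x tissues
    edges: List[Tuple[str, str]]
    truth: GroundTruth


def _sample_site_positions(
    rng: np.random.Generator, length: int, k: int, min_sep: int
) -> List[int]:
    """Distinct 1-based positions, greedily spaced >= min_sep when feasible."""
    chosen: List[int] = []
    for pos in rng.permutation(length) + 1:
        if all(abs(pos - c) >= min_sep for c in chosen):
            chosen.append(int(pos))
            if len(chosen) == k:
                return sorted(chosen)
    for pos in rng.permutation(length) + 1:  # relax spacing if needed
        if pos not in chosen:
            chosen.append(int(pos))
            if len(chosen) == k:
                break
    return sorted(chosen)


def _evolve(
    rng: np.random.Generator, residues: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Apply Poisson substitution events with per-residue rates."""
    events = rng.poisson(rates)
    out = residues.copy()
    remaining = events
    while remaining.max(initial=0) > 0:
        mask = remaining > 0
        draws = rng.integers(0, 19, size=int(mask.sum()))
        cur = out[mask]
        out[mask] = draws + (draws >= cur)
        remaining = remaining - mask
    return out


def _indel_alignment(
    rng: np.random.Generator,
    human: np.ndarray,
    ortholog: np.ndarray,
    n_events: int,
    protected: set,
    max_len: int = 5,
) -> Tuple[str, str]:
    """Apply insertion/deletion events, returning aligned strings.

    Columns holding planted gain sites are protected from deletion so planted
    ladders stay observable; other positions may be deleted freely.
    """
    a = [AMINO_ACIDS[i] for i in human]
    b = [AMINO_ACIDS[i] for i in ortholog]
    # Track original human position per column (None for inserted columns).
    origin: List[Optional[int]] = list(range(1, len(a) + 1))
    for _ in range(n_events):
        length = min(int(rng.geometric(0.5)), max_len)
        if rng.random() < 0.5 and len(a) > length:
            # deletion in the ortholog
            for _try in range(10):
                start = int(rng.integers(0, len(a) - length + 1))
                window = range(start, start + length)
                if not any(origin[c] in protected for c in window):
                    for c in window:
                        b[c] = "-"
                    break
        else:
            # insertion in the ortholog
            at = int(rng.integers(0, len(a) + 1))
            ins = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
            a[at:at] = ["-"] * length
            b[at:at] = ins
            origin[at:at] = [None] * length
    keep = [c for c in range(len(a)) if not (a[c] == "-" and b[c] == "-")]
    return "".join(a[c] for c in keep), "".join(b[c] for c in keep)


def _organism_code(name: str) -> str:
    return name.replace(". ", "").replace(" ", "_").replace(".", "")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete dataset bundle with recorded ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    order = config.organism_order()
    n = config.n_proteins
    pids = [f"P{i:05d}" for i in range(1, n + 1)]

    # --- human proteins and sites -------------------------------------------
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    sequences: Dict[str, np.ndarray] = {}
    sites: List[SiteRecord] = []
    site_positions: Dict[str, List[int]] = {}
    min_sep = 2 * config.flank_half_width + 1
    for pid, L in zip(pids, lengths):
        seq = rng.integers(0, 20, size=int(L))
        positions = _sample_site_positions(
            rng, int(L), config.sites_per_protein, min_sep
        )
        seq[[p - 1 for p in positions]] = _K_INDEX
        sequences[pid] = seq
        site_positions[pid] = positions
        sites.extend(SiteRecord(pid, p, "K") for p in positions)

    # --- categories ----------------------------------------------------------
    labels = [lbl for lbl, _ in config.category_labels]
    mults = {lbl: m for lbl, m in config.category_labels}
    cat_of = {
        pid: labels[int(i)]
        for pid, i in zip(pids, rng.integers(0, len(labels), size=n))
    }
    annotations = {
        pid: {config.category_namespace: {cat_of[pid]}} for pid in pids
    }

    # --- expression ----------------------------------------------------------
    classes = np.where(
        rng.random(n) < config.facilitator_fraction, "facilitator", "specifier"
    )
    tissue_names = [f"tissue_{j:02d}" for j in range(1, config.n_tissues + 1)]
    rows = []
    for cls in classes:
        alpha = config.expression_concentration[str(cls)]
        profile = rng.dirichlet(np.full(config.n_tissues, alpha))
        rows.append(profile * rng.uniform(50.0, 500.0))
    expression = pd.DataFrame(rows, index=pids, columns=tissue_names)
    expression_class = dict(zip(pids, (str(c) for c in classes)))

    # --- interaction network --------------------------------------------------
    n_hubs = int(round(config.hub_fraction * n))
    hub_ids = set(rng.choice(n, size=n_hubs, replace=False).tolist())
    ks = np.arange(1, 21, dtype=float)
    weights = ks ** -config.degree_exponent
    weights /= weights.sum()
    target = np.empty(n)
    for i in range(n):
        if i in hub_ids:
            target[i] = rng.integers(
                config.hub_degree_range[0], config.hub_degree_range[1] + 1
            )
        else:
            target[i] = rng.choice(ks, p=weights)
    graph_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.expected_degree_graph(target, seed=graph_seed, selfloops=False)
    edges = sorted(
        (pids[min(u, v)], pids[max(u, v)]) for u, v in g.edges()
    )
    degree = {pid: 0 for pid in pids}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1

    # --- per-residue substitution rates --------------------------------------
    site_mult_of: Dict[Tuple[str, int], float] = {}
    rate_mult: Dict[str, np.ndarray] = {}
    for pid in pids:
        L = len(sequences[pid])
        mult = np.full(L, config.background_rate_multiplier)
        for p in site_positions[pid]:
            for q in range(
                max(1, p - config.flank_half_width),
                min(L, p + config.flank_half_width) + 1,
            ):
                if q not in site_positions[pid]:
                    mult[q - 1] = config.flank_rate_multiplier
        for p in site_positions[pid]:
            m = config.site_rate_multiplier * mults[cat_of[pid]]
            mult[p - 1] = m
            site_mult_of[(pid, p)] = m
        rate_mult[pid] = mult

    # --- planted gain patterns ------------------------------------------------
    all_sites = [(s.protein_id, s.position) for s in sites]
    planted: Dict[Tuple[str, int], str] = {}
    loss_at: Dict[Tuple[str, int], int] = {}
    n_planted = sum(config.planted_gain_epochs.values())
    if n_planted:
        picked = rng.choice(len(all_sites), size=n_planted, replace=False)
        it = iter(picked.tolist())
        for epoch, count in sorted(config.planted_gain_epochs.items()):
            for _ in range(count):
                key = all_sites[next(it)]
                planted[key] = epoch
                b = config.epochs[epoch]
                # Detectable (interior) losses only: a loss at the deepest
                # lysine-bearing organism is indistinguishable from a
                # younger gain.
                if config.gain_loss_rate > 0 and b >= 2:
                    if rng.random() < config.gain_loss_rate:
                        loss_at[key] = int(rng.integers(0, b - 1))

    # --- orthologs ------------------------------------------------------------
    ortholog_map: List[Tuple[str, str, str]] = []
    aligned_pairs: Dict[str, Dict[str, AlignedOrthologPair]] = {
        pid: {} for pid in pids
    }
    protected_sites = {
        pid: {p for (q, p) in planted if q == pid} for pid in pids
    }
    for org_idx, (organism, depth) in enumerate(config.organisms):
        code = _organism_code(organism)
        for pid in pids:
            if (
                config.missing_ortholog_rate > 0
                and rng.random() < config.missing_ortholog_rate
            ):
                continue
            human = sequences[pid]
            orth = _evolve(rng, human, depth * rate_mult[pid])
            # overwrite planted-gain site residues
            for p in site_positions[pid]:
                key = (pid, p)
                if key not in planted:
                    continue
                b = config.epochs[planted[key]]
                if org_idx < b:
                    orth[p - 1] = _K_INDEX
                    if loss_at.get(key) == org_idx:
                        d = int(rng.integers(0, 19))
                        orth[p - 1] = d + (d >= _K_INDEX)
                else:
                    if orth[p - 1] == _K_INDEX:
                        d = int(rng.integers(0, 19))
                        orth[p - 1] = d + (d >= _K_INDEX)
            oid = f"{code}_{pid}"
            if config.indel_rate > 0:
                n_events = int(
                    rng.poisson(config.indel_rate * depth * len(human))
                )
                ah, ao = _indel_alignment(
                    rng, human, orth, n_events, protected_sites[pid]
                )
            else:
                ah = "".join(AMINO_ACIDS[i] for i in human)
                ao = "".join(AMINO_ACIDS[i] for i in orth)
            aligned_pairs[pid][organism] = AlignedOrthologPair(
                human_id=pid,
                organism=organism,
                aligned_human=ah,
                aligned_ortholog=ao,
                ortholog_id=oid,
            )
            ortholog_map.append((pid, organism, oid))

    truth = GroundTruth(
        protein_category=cat_of,
        expression_class=expression_class,
        degree=degree,
        site_rate_multiplier=site_mult_of,
        gain_epoch={
            key: planted.get(key) for key in all_sites
        },
        gain_boundary={
            key: (config.epochs[planted[key]] if key in planted else None)
            for key in all_sites
        },
        loss_organism={
            key: (order.names[loss_at[key]] if key in loss_at else None)
            for key in all_sites
        },
    )
    return SyntheticDataset(
        config=config,
        organism_order=order,
        sequences={
            pid: "".join(AMINO_ACIDS[i] for i in seq)
            for pid, seq in sequences.items()
        },
        sites=sites,
        ortholog_map=ortholog_map,
        aligned_pairs=aligned_pairs,
        annotations=annotations,
        expression=expression,
        edges=edges,
        truth=truth,
    )


def plant_gain_pattern(
    site: SiteRecord,
    epoch: str,
    order: OrganismOrder,
    rng: Optional[np.random.Generator] = None,
) -> List[str]:
    """Per-organism residue vector for a site gained at a named epoch.

    Lysine in every organism diverging after the epoch (closer to human),
    a random non-lysine residue in every organism diverging before it.
    """
    boundary = order.boundary_of(epoch)
    rng = rng or np.random.default_rng(0)
    out: List[str] = []
    non_k = [a for a in AMINO_ACIDS if a != "K"]
    for idx in range(len(order)):
        if idx < boundary:
            out.append("K")
        else:
            out.append(non_k[int(rng.integers(0, 19))])
    return out
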