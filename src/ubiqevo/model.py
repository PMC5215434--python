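"""Model/Results objects tying the estimators to a dataset.

``ConservationModel`` is built from a table of site/flank observations (one
row per human position x organism) and, once fitted, yields a
``ConservationResults`` carrying Poisson-distance estimates with standard
errors, per-organism site-vs-flank z contrasts, the chi-square combination
across organisms, relative distances per protein group, and group-vs-group
comparisons.  ``GainTimingModel`` infers gain epochs from species-ladder
residue profiles and tests category enrichment of the gaining proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import stats as cstats
from .align import flank_positions
from .categories import RelativeEstimate, compare_groups, relative_distance
from .gains import count_gains_per_epoch, enrichment, infer_gain_epoch
from .stats import (
    ChiSquareCombined,
    PoissonEstimate,
    SubstitutionCount,
    TwoSampleZ,
    combine_chi_square,
    poisson_estimate,
    significance_stars,
    two_sample_z,
)
from .types import GAP, GainEvent, OrganismOrder, SiteRecord

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = [
    "protein_id", "position", "organism", "region",
    "human_residue", "ortholog_residue",
]


def build_observations(
    bundle,
    *,
    half_width: int = 5,
    exclude_flank_lysines: bool = False,
) -> pd.DataFrame:
    """One row per (site or flank position) x organism with an ortholog.

    Overlapping flanks of nearby sites are pooled with repetition: each site
    contributes its full flank.  Organisms without an ortholog of a protein
    contribute no rows (MISSING).
    """
    seq_len = {pid: len(seq) for pid, seq in bundle.sequences.items()}
    rows: List[tuple] = []
    pairs_of: Dict[str, dict] = bundle.aligned_pairs
    for site in bundle.sites:
        pid = site.protein_id
        length = seq_len[pid]
        flanks = flank_positions(length, site.position, half_width)
        for organism, pair in pairs_of.get(pid, {}).items():
            cols = pair.column_of_human_position
            col = cols[site.position]
            rows.append((
                pid, site.position, organism, "sites",
                pair.aligned_human[col], pair.aligned_ortholog[col],
            ))
            for fp in flanks:
                fcol = cols[fp]
                hres = pair.aligned_human[fcol]
                if exclude_flank_lysines and hres == "K":
                    continue
                rows.append((
                    pid, fp, organism, "flanks",
                    hres, pair.aligned_ortholog[fcol],
                ))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def vs_rest_groups(
    partition: Mapping[str, Set[str]], proteins: Set[str]
) -> Dict[str, Set[str]]:
    """Each category plus its complement (proteins not annotated to it)."""
    groups: Dict[str, Set[str]] = {}
    for name, members in partition.items():
        members = set(members) & proteins
        groups[name] = members
        groups[f"not:{name}"] = proteins - members
    return groups


class ConservationModel:
    """Site-vs-flank conservation contrasts over an organism ladder.

    Parameters
    ----------
    observations : DataFrame with OBSERVATION_COLUMNS
    organism_order : ordered reference organisms
    groups : optional mapping group_id -> set of protein ids (may overlap);
        default puts every protein in one group ``"all"``.
    gap_as_diff : count an alignment gap at a compared position as a
        difference (default) or exclude it from the comparison.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        organism_order: OrganismOrder,
        groups: Optional[Mapping[str, Set[str]]] = None,
        *,
        gap_as_diff: bool = True,
    ) -> None:
        missing_cols = set(OBSERVATION_COLUMNS) - set(observations.columns)
        if missing_cols:
            raise ValueError(f"observations missing {sorted(missing_cols)}")
        self.observations = observations
        self.organism_order = organism_order
        if groups is None:
            groups = {"all": set(observations["protein_id"].unique())}
        self.groups = {g: set(m) for g, m in groups.items()}
        self.gap_as_diff = gap_as_diff

    @classmethod
    def from_dataset(
        cls,
        bundle,
        groups: Optional[Mapping[str, Set[str]]] = None,
        *,
        half_width: int = 5,
        exclude_flank_lysines: bool = False,
        gap_as_diff: bool = True,
    ) -> "ConservationModel":
        obs = build_observations(
            bundle,
            half_width=half_width,
            exclude_flank_lysines=exclude_flank_lysines,
        )
        return cls(
            obs, bundle.organism_order, groups, gap_as_diff=gap_as_diff
        )

    def _counts(self) -> pd.DataFrame:
        obs = self.observations.dropna(subset=["ortholog_residue"]).copy()
        is_gap = obs["ortholog_residue"] == GAP
        if self.gap_as_diff:
            obs["compared"] = True
            obs["diff"] = obs["ortholog_residue"] != obs["human_residue"]
        else:
            obs["compared"] = ~is_gap
            obs["diff"] = (
                ~is_gap & (obs["ortholog_residue"] != obs["human_residue"])
            )
        return obs

    def fit(self) -> "ConservationResults":
        obs = self._counts()
        estimates: Dict[Tuple[str, str, str], PoissonEstimate] = {}
        contrasts: Dict[Tuple[str, str], TwoSampleZ] = {}
        relative: Dict[Tuple[str, str], RelativeEstimate] = {}
        combined: Dict[str, ChiSquareCombined] = {}
        for group_id, members in self.groups.items():
            sub = obs[obs["protein_id"].isin(members)]
            if sub.empty:
                logger.warning("group %r is empty; skipped", group_id)
                continue
            agg = sub.groupby(["organism", "region"])[
                ["diff", "compared"]
            ].sum()
            z_list: List[TwoSampleZ] = []
            for organism in self.organism_order.names:
                ests = {}
                for region in ("sites", "flanks"):
                    key = (organism, region)
                    if key not in agg.index:
                        continue
                    n_diff = int(agg.loc[key, "diff"])
                    n_total = int(agg.loc[key, "compared"])
                    if n_total == 0:
                        continue
                    est = poisson_estimate(SubstitutionCount(
                        n_diff=n_diff, n_total=n_total, group_id=group_id,
                        organism=organism, region=region,
                    ))
                    ests[region] = est
                    estimates[(group_id, organism, region)] = est
                if "sites" in ests and "flanks" in ests:
                    try:
                        tz = cstats.z_site_vs_flank(
                            ests["sites"], ests["flanks"]
                        )
                    except ValueError:
                        continue
                    contrasts[(group_id, organism)] = tz
                    z_list.append(tz)
                    if ests["flanks"].d > 0:
                        relative[(group_id, organism)] = relative_distance(
                            ests["sites"], ests["flanks"]
                        )
            if z_list:
                combined[group_id] = combine_chi_square(z_list)
        return ConservationResults(
            model=self,
            estimates=estimates,
            contrasts=contrasts,
            relative=relative,
            combined=combined,
        )


@dataclass
class ConservationResults:
    """Fitted conservation contrasts with uncertainties and summaries."""

    model: ConservationModel
    estimates: Dict[Tuple[str, str, str], PoissonEstimate]
    contrasts: Dict[Tuple[str, str], TwoSampleZ]
    relative: Dict[Tuple[str, str], RelativeEstimate]
    combined: Dict[str, ChiSquareCombined]

    @property
    def organism_order(self) -> OrganismOrder:
        return self.model.organism_order

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (group, organism, region) estimate plus
        the contrast columns, and one combined row per group."""
        rows = []
        groups = sorted({g for g, _, _ in self.estimates})
        for g in groups:
            for organism in self.organism_order.names:
                for region in ("sites", "flanks"):
                    est = self.estimates.get((g, organism, region))
                    if est is None:
                        continue
                    tz = self.contrasts.get((g, organism))
                    rel = self.relative.get((g, organism))
                    rows.append({
                        "group": g, "organism": organism, "region": region,
                        "n_diff": est.n_diff, "n_total": est.n_total,
                        "p": est.p, "d": est.d, "var_d": est.var_d,
                        "se_d": est.se_d,
                        "z": tz.z if (tz and region == "sites") else np.nan,
                        "p_value": tz.p_value
                        if (tz and region == "sites") else np.nan,
                        "stars": significance_stars(tz.p_value)
                        if (tz and region == "sites") else "",
                        "r": rel.r if (rel and region == "sites") else np.nan,
                        "var_r": rel.var_r
                        if (rel and region == "sites") else np.nan,
                    })
            comb = self.combined.get(g)
            if comb is not None:
                rows.append({
                    "group": g, "organism": "COMBINED", "region": "",
                    "n_diff": np.nan, "n_total": np.nan, "p": np.nan,
                    "d": np.nan, "var_d": np.nan, "se_d": np.nan,
                    "z": comb.mean_z, "p_value": comb.p_value,
                    "stars": significance_stars(comb.p_value),
                    "r": np.nan, "var_r": np.nan,
                })
        return pd.DataFrame(rows)

    def compare(
        self, group_i: str, group_j: str
    ) -> Tuple[List[TwoSampleZ], ChiSquareCombined]:
        """Contrast relative distances of two groups per organism and
        combined across organisms (positive z: group_i evolves faster)."""
        z_list: List[TwoSampleZ] = []
        for organism in self.organism_order.names:
            ri = self.relative.get((group_i, organism))
            rj = self.relative.get((group_j, organism))
            if ri is None or rj is None:
                continue
            z_list.append(compare_groups(ri, rj))
        if not z_list:
            raise ValueError(
                f"no organism with estimates for both {group_i!r} "
                f"and {group_j!r}"
            )
        return z_list, combine_chi_square(z_list)

    def compare_table(
        self, pairs: Iterable[Tuple[str, str]]
    ) -> pd.DataFrame:
        rows = []
        for gi, gj in pairs:
            try:
                z_list, comb = self.compare(gi, gj)
            except ValueError as exc:
                logger.warning("skipping contrast %s vs %s: %s", gi, gj, exc)
                continue
            for tz in z_list:
                rows.append({
                    "group_i": gi, "group_j": gj, "organism": tz.organism,
                    "z": tz.z, "p_value": tz.p_value,
                    "stars": significance_stars(tz.p_value),
                })
            rows.append({
                "group_i": gi, "group_j": gj, "organism": "COMBINED",
                "z": comb.mean_z, "p_value": comb.p_value,
                "stars": significance_stars(comb.p_value),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Ubiquitination-site conservation: Poisson distance of sites vs"
            " flanking background",
            f"organisms (nearest first): {', '.join(self.organism_order.names)}",
            f"gap counted as difference: {self.model.gap_as_diff}",
            "",
            f"{'group':<16}{'organism':<18}{'d_sites':>9}{'d_flanks':>9}"
            f"{'z':>8}{'p':>11}  sig",
        ]
        for g in sorted(self.combined):
            for organism in self.organism_order.names:
                es = self.estimates.get((g, organism, "sites"))
                ef = self.estimates.get((g, organism, "flanks"))
                tz = self.contrasts.get((g, organism))
                if es is None or ef is None or tz is None:
                    continue
                lines.append(
                    f"{g:<16}{organism:<18}{es.d:>9.4f}{ef.d:>9.4f}"
                    f"{tz.z:>8.2f}{tz.p_value:>11.3g}  "
                    f"{significance_stars(tz.p_value)}"
                )
            comb = self.combined[g]
            lines.append(
                f"{g:<16}{'COMBINED':<18}{'':>9}{'':>9}"
                f"{comb.mean_z:>8.2f}{comb.p_value:>11.3g}  "
                f"{significance_stars(comb.p_value)} "
                f"(chi2={comb.statistic:.2f}, df={comb.df})"
            )
        return "\n".join(lines)

    def plot_distances(self, group: str = "all", ax=None):
        """Bar chart of Poisson distance +/- s.e. for sites vs flanks per
        organism, nearest organism first."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        names = [
            o for o in self.organism_order.names
            if (group, o, "sites") in self.estimates
            and (group, o, "flanks") in self.estimates
        ]
        x = np.arange(len(names))
        for off, region, color in (
            (-0.2, "sites", "#d62728"), (0.2, "flanks", "#7f7f7f")
        ):
            ests = [self.estimates[(group, o, region)] for o in names]
            ax.bar(
                x + off, [e.d for e in ests], width=0.4,
                yerr=[e.se_d for e in ests], label=region, color=color,
            )
        ax.set_xticks(x)
        ax.set_xticklabels(names, rotation=60, ha="right")
        ax.set_ylabel("Poisson distance")
        ax.set_title(f"group: {group}")
        ax.legend()
        return ax


def partition_and_compare(
    bundle,
    partition: Mapping[str, Set[str]],
    *,
    vs_rest: bool = True,
    half_width: int = 5,
    gap_as_diff: bool = True,
) -> Tuple[ConservationResults, pd.DataFrame]:
    """Fit per-partition conservation and emit group contrasts.

    With ``vs_rest`` each category is contrasted against its complement
    (proteins not annotated to it); otherwise all unordered category pairs
    are contrasted.  Returns the fitted results and the contrast table.
    """
    proteins = {s.protein_id for s in bundle.sites}
    cats = {name: set(m) & proteins for name, m in partition.items()}
    cats = {name: m for name, m in cats.items() if m}
    if vs_rest:
        groups = vs_rest_groups(cats, proteins)
        pairs = [
            (name, f"not:{name}") for name in sorted(cats)
            if groups.get(f"not:{name}")
        ]
    else:
        groups = dict(cats)
        names = sorted(cats)
        pairs = [
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        ]
    model = ConservationModel.from_dataset(
        bundle, groups, half_width=half_width, gap_as_diff=gap_as_diff
    )
    results = model.fit()
    if len(groups) < 2:
        return results, pd.DataFrame(
            columns=["group_i", "group_j", "organism", "z", "p_value", "stars"]
        )
    return results, results.compare_table(pairs)


class GainTimingModel:
    """Infer gain epochs for every site and test category enrichment."""

    def __init__(
        self,
        sites: List[SiteRecord],
        aligned_pairs: Dict[str, Dict],
        organism_order: OrganismOrder,
        *,
        mode: str = "first_appearance",
    ) -> None:
        self.sites = sites
        self.aligned_pairs = aligned_pairs
        self.organism_order = organism_order
        self.mode = mode

    @classmethod
    def from_dataset(cls, bundle, *, mode: str = "first_appearance"):
        return cls(
            bundle.sites, bundle.aligned_pairs, bundle.organism_order,
            mode=mode,
        )

    def fit(self) -> "GainTimingResults":
        from .align import build_species_ladder_profile

        events: List[GainEvent] = []
        unresolved: List[SiteRecord] = []
        for site in self.sites:
            profile = build_species_ladder_profile(
                site, self.aligned_pairs.get(site.protein_id, {}),
                self.organism_order,
            )
            event = infer_gain_epoch(
                site, profile, self.organism_order, mode=self.mode
            )
            if event is None:
                unresolved.append(site)
            else:
                events.append(event)
        return GainTimingResults(
            model=self, events=events, unresolved=unresolved
        )


@dataclass
class GainTimingResults:
    model: GainTimingModel
    events: List[GainEvent]
    unresolved: List[SiteRecord] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        return count_gains_per_epoch(self.events, self.model.organism_order)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": e.site.protein_id,
                "position_1based": e.site.position,
                "boundary": e.boundary,
                "epoch": e.epoch,
                "low_coverage": e.low_coverage,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["protein_id", "position_1based", "boundary",
                           "epoch", "low_coverage"],
        )

    def enrichment_table(
        self,
        categories: Mapping[str, Set[str]],
        *,
        background: Optional[Set[str]] = None,
        epochs: Optional[Iterable[str]] = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Hypergeometric enrichment of categories among proteins gaining a
        site at each named epoch.  Background defaults to all ubiquitinated
        proteins in the dataset."""
        if background is None:
            background = {s.protein_id for s in self.model.sites}
        order = self.model.organism_order
        if epochs is None:
            epochs = sorted(order.epochs, key=order.epochs.get)
        rows = []
        for epoch in epochs:
            boundary = order.boundary_of(epoch)
            gained = {
                e.site.protein_id for e in self.events
                if e.boundary == boundary
            } & background
            if not gained:
                logger.warning("no gains at epoch %r; skipped", epoch)
                continue
            for res in enrichment(
                gained, set(background), categories, epoch=epoch, alpha=alpha
            ):
                rows.append({
                    "epoch": res.epoch, "category": res.category,
                    "observed": res.observed, "expected": res.expected,
                    "p_value": res.p_value, "corrected_p": res.corrected_p,
                    "direction": res.direction,
                    "significant": res.corrected_p < alpha,
                })
        return pd.DataFrame(
            rows, columns=["epoch", "category", "observed", "expected",
                           "p_value", "corrected_p", "direction",
                           "significant"],
        )

    def summary(self) -> str:
        counts = self.counts()
        lines = [
            f"Gain timing ({self.model.mode} mode): "
            f"{len(self.events)} resolved, {len(self.unresolved)} unresolved",
            "sites gained per boundary (youngest first):",
        ]
        lines += [f"  {label:<24}{n:>6}" for label, n in counts.items()]
        return "\n".join(lines)
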