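"""End-to-end orchestration: simulate/load -> conserve -> categories ->
tsps/hubs -> gains -> enrich -> report.

A run is a pure function of its configuration: synthetic mode derives every
input from the seed, provided-data mode reads a serialized bundle directory.
Stage outputs are plain TSV written with a fixed float format so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import io as uio
from .categories import degree_and_hubs, tsps_table
from .model import (
    ConservationModel,
    GainTimingModel,
    partition_and_compare,
)
from .simulate import SimulationConfig, simulate_dataset
from .types import ValidationError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "provided"
    out_dir: str = "ubiq_evo_run"
    data_dir: Optional[str] = None  # required in provided mode
    seed: int = 0
    simulation: Dict = field(default_factory=dict)  # SimulationConfig overrides
    flank_half_width: int = 5
    exclude_flank_lysines: bool = False
    gap_as_diff: bool = True
    gains_mode: str = "first_appearance"
    enrichment_alpha: float = 0.05
    namespaces: Optional[list] = None  # annotation namespaces to analyse

    def validate(self) -> None:
        if self.mode not in ("synthetic", "provided"):
            raise ValidationError(f"mode: unknown run mode {self.mode!r}")
        if self.mode == "provided":
            if not self.data_dir:
                raise ValidationError("data_dir: required in provided mode")
            src = Path(self.data_dir)
            for name in ("human_proteins.fasta", "sites.tsv",
                         "organisms.yaml"):
                if not (src / name).exists():
                    raise ValidationError(
                        f"data_dir: missing input file {src / name}"
                    )
        if self.gains_mode not in ("first_appearance", "strict"):
            raise ValidationError(f"gains_mode: unknown {self.gains_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    On stage failure the output directory receives a ``failed`` marker naming
    the stage, partial outputs are retained, and the error is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- data ----------------------------------------------------------
        stage = "data"
        if config.mode == "synthetic":
            sim = SimulationConfig(
                **{**config.simulation, "seed": config.seed}
            )
            bundle = simulate_dataset(sim)
            uio.write_bundle(bundle, out / "data")
            logger.info(
                "simulated %d proteins / %d sites / %d organisms",
                len(bundle.sequences), len(bundle.sites),
                len(bundle.organism_order),
            )
        else:
            bundle = uio.read_bundle(config.data_dir)
            logger.info(
                "loaded %d proteins / %d sites from %s",
                len(bundle.sequences), len(bundle.sites), config.data_dir,
            )
        summaries = []

        # --- conservation ----------------------------------------------------
        stage = "conserve"
        model = ConservationModel.from_dataset(
            bundle,
            half_width=config.flank_half_width,
            exclude_flank_lysines=config.exclude_flank_lysines,
            gap_as_diff=config.gap_as_diff,
        )
        results = model.fit()
        _write_tsv(results.to_frame(), out / "conservation.tsv")
        summaries.append(results.summary())
        logger.info("conservation: %d observation rows",
                    len(model.observations))

        # --- functional categories --------------------------------------------
        stage = "categories"
        namespaces = config.namespaces
        if namespaces is None:
            namespaces = sorted({
                ns for by_ns in bundle.annotations.values() for ns in by_ns
            })
        for ns in namespaces:
            partition: Dict[str, set] = {}
            for pid, by_ns in bundle.annotations.items():
                for cat in by_ns.get(ns, ()):
                    partition.setdefault(cat, set()).add(pid)
            if not partition:
                logger.warning("namespace %r: no annotations; skipped", ns)
                continue
            _, table = partition_and_compare(
                bundle, partition,
                half_width=config.flank_half_width,
                gap_as_diff=config.gap_as_diff,
            )
            _write_tsv(table, out / f"categories_{ns}.tsv")

        # --- tissue specificity ------------------------------------------------
        stage = "tsps"
        if bundle.expression is not None:
            scored = tsps_table(bundle.expression)
            tsps_df = pd.DataFrame(
                [(t.protein_id, t.tsps, t.tsps_class) for t in scored],
                columns=["protein_id", "tsps", "class"],
            )
            _write_tsv(tsps_df, out / "tsps.tsv")
            split = {
                "facilitator": {
                    t.protein_id for t in scored
                    if t.tsps_class == "facilitator"
                },
                "specifier": {
                    t.protein_id for t in scored
                    if t.tsps_class == "specifier"
                },
            }
            _, table = partition_and_compare(
                bundle, split, vs_rest=False,
                half_width=config.flank_half_width,
                gap_as_diff=config.gap_as_diff,
            )
            _write_tsv(table, out / "tsps_compare.tsv")

        # --- network connectivity ----------------------------------------------
        stage = "hubs"
        if bundle.edges:
            records = degree_and_hubs(
                bundle.edges, proteins=bundle.sequences.keys()
            )
            _write_tsv(
                pd.DataFrame(
                    [(r.protein_id, r.degree, r.is_hub) for r in records],
                    columns=["protein_id", "degree", "is_hub"],
                ),
                out / "hubs.tsv",
            )
            split = {
                "hub": {r.protein_id for r in records if r.is_hub},
                "non-hub": {r.protein_id for r in records if not r.is_hub},
            }
            _, table = partition_and_compare(
                bundle, split, vs_rest=False,
                half_width=config.flank_half_width,
                gap_as_diff=config.gap_as_diff,
            )
            _write_tsv(table, out / "hubs_compare.tsv")

        # --- gains and enrichment -----------------------------------------------
        stage = "gains"
        gains = GainTimingModel.from_dataset(
            bundle, mode=config.gains_mode
        ).fit()
        _write_tsv(gains.to_frame(), out / "gains.tsv")
        counts = gains.counts()
        _write_tsv(
            pd.DataFrame(
                list(counts.items()), columns=["epoch", "n_sites"]
            ),
            out / "gain_counts.tsv",
        )
        summaries.append(gains.summary())

        stage = "enrich"
        for ns in namespaces:
            categories = {}
            for pid, by_ns in bundle.annotations.items():
                for cat in by_ns.get(ns, ()):
                    categories.setdefault(cat, set()).add(pid)
            if not categories:
                continue
            table = gains.enrichment_table(
                categories, alpha=config.enrichment_alpha
            )
            _write_tsv(table, out / f"enrichment_{ns}.tsv")

        # --- report --------------------------------------------------------------
        stage = "report"
        report = "\n\n".join(summaries)
        # analytic parameters only: paths are run-local, not provenance
        params = {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("out_dir", "data_dir")
        }
        provenance = yaml.safe_dump(params, sort_keys=True)
        (out / "summary.txt").write_text(
            report + "\n\n# configuration\n" + provenance
        )
    except Exception as exc:
        (out / "failed").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
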