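"""Readers and writers for every file the pipeline touches.

One strict dialect everywhere: tables are UTF-8 TSV with a header row and
'#' comment lines; sequences are FASTA; pairwise alignments are two-record
aligned FASTA with '-' gaps.  Readers validate type invariants and reject
bad records with positional error messages.  All protein coordinates are
1-based in serialized form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AlignedOrthologPair,
    OrganismOrder,
    SiteRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class DataBundle:
    """All analysis inputs as one object graph (no ground truth)."""

    organism_order: OrganismOrder
    sequences: Dict[str, str]
    sites: List[SiteRecord]
    ortholog_map: List[Tuple[str, str, str]]
    aligned_pairs: Dict[str, Dict[str, AlignedOrthologPair]]
    annotations: Dict[str, Dict[str, set]] = field(default_factory=dict)
    expression: Optional[pd.DataFrame] = None
    edges: List[Tuple[str, str]] = field(default_factory=list)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate identifier {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Site table

def read_site_table(path, sequences: Dict[str, str]) -> List[SiteRecord]:
    df = _read_tsv(path)
    required = {"protein_id", "position_1based", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records: List[SiteRecord] = []
    seen = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.protein_id
        pos = int(row.position_1based)
        residue = row.residue
        if pid not in sequences:
            raise ValidationError(
                f"{path}:{row_no}: unknown protein {pid!r}"
            )
        seq = sequences[pid]
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"{path}:{row_no}: {pid} position {pos} outside protein "
                f"(length {len(seq)})"
            )
        if seq[pos - 1] != residue:
            raise ValidationError(
                f"{path}:{row_no}: {pid} position {pos} holds "
                f"{seq[pos - 1]!r}, site table claims {residue!r}"
            )
        if (pid, pos) in seen:
            raise ValidationError(
                f"{path}:{row_no}: duplicate site {pid}@{pos}"
            )
        seen.add((pid, pos))
        mod = getattr(row, "modification", "ubiquitination")
        records.append(
            SiteRecord(pid, pos, residue, mod if isinstance(mod, str) else
                       "ubiquitination")
        )
    return records


def write_site_table(sites: List[SiteRecord], path) -> None:
    df = pd.DataFrame(
        [
            (s.protein_id, s.position, s.residue, s.modification)
            for s in sorted(sites, key=lambda s: (s.protein_id, s.position))
        ],
        columns=["protein_id", "position_1based", "residue", "modification"],
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Ortholog map

def read_ortholog_map(path) -> List[Tuple[str, str, str]]:
    """(human_id, organism, ortholog_id) triples; first pairing wins on
    duplicates (co-ortholog emissions), with a warning."""
    df = _read_tsv(path)
    required = {"human_id", "organism", "ortholog_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: List[Tuple[str, str, str]] = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.human_id, row.organism)
        if key in seen:
            logger.warning(
                "duplicate ortholog pairing for %s/%s; keeping the first",
                row.human_id, row.organism,
            )
            continue
        seen.add(key)
        out.append((row.human_id, row.organism, row.ortholog_id))
    return out


def write_ortholog_map(pairings: List[Tuple[str, str, str]], path) -> None:
    df = pd.DataFrame(
        sorted(pairings), columns=["human_id", "organism", "ortholog_id"]
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Aligned pairs

def read_aligned_pair(path) -> AlignedOrthologPair:
    """Two-record aligned FASTA: human first, ortholog second with an
    ``organism=<name>`` tag in its description."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValidationError(
            f"{path}: expected exactly 2 records, found {len(records)}"
        )
    human, orth = records
    if len(human.seq) != len(orth.seq):
        raise ValidationError(f"{path}: aligned lengths differ")
    organism = ""
    marker = "organism="
    if marker in orth.description:
        organism = orth.description.split(marker, 1)[1].strip()
    if not organism:
        raise ValidationError(f"{path}: ortholog record lacks organism= tag")
    return AlignedOrthologPair(
        human_id=human.id,
        organism=organism,
        aligned_human=str(human.seq),
        aligned_ortholog=str(orth.seq),
        ortholog_id=orth.id,
    )


def write_aligned_pair(pair: AlignedOrthologPair, path) -> None:
    records = [
        SeqRecord(Seq(pair.aligned_human), id=pair.human_id, description=""),
        SeqRecord(
            Seq(pair.aligned_ortholog),
            id=pair.ortholog_id or f"{pair.human_id}_ortholog",
            description=f"organism={pair.organism}",
        ),
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Annotations

def read_annotations(path) -> Dict[str, Dict[str, set]]:
    """protein_id -> namespace -> set of category labels.

    An empty file (header only) yields an empty mapping.
    """
    df = _read_tsv(path)
    required = {"protein_id", "namespace", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[str, Dict[str, set]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, {}).setdefault(
            row.namespace, set()
        ).add(row.category)
    return out


def write_annotations(annotations: Dict[str, Dict[str, set]], path) -> None:
    rows = sorted(
        (pid, ns, cat)
        for pid, by_ns in annotations.items()
        for ns, cats in by_ns.items()
        for cat in cats
    )
    pd.DataFrame(rows, columns=["protein_id", "namespace", "category"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Expression matrix

def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        bad = df.index[(values < 0).any(axis=1)][0]
        raise ValidationError(
            f"{path}: negative expression value for protein {bad!r}"
        )
    return df


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.sort_index().to_csv(
        path, sep="\t", index_label="protein_id", float_format="%.6g"
    )


# --------------------------------------------------------------------------
# Edge list

def read_edges(path) -> List[Tuple[str, str]]:
    """Undirected edges, deduplicated, self-loops dropped."""
    df = _read_tsv(path)
    required = {"protein_a", "protein_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    seen = set()
    out: List[Tuple[str, str]] = []
    for row in df.itertuples(index=False):
        if row.protein_a == row.protein_b:
            continue
        edge = (min(row.protein_a, row.protein_b),
                max(row.protein_a, row.protein_b))
        if edge in seen:
            continue
        seen.add(edge)
        out.append(edge)
    return out


def write_edges(edges: List[Tuple[str, str]], path) -> None:
    rows = sorted({(min(a, b), max(a, b)) for a, b in edges if a != b})
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Organism order (YAML config section)

def read_organism_order(source) -> OrganismOrder:
    """From a YAML file path or an already-parsed mapping with keys
    ``organisms`` (ordered list of names or {name, depth} entries) and
    ``epochs`` (name -> boundary index)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    organisms = data.get("organisms")
    if not organisms:
        raise ValidationError("organism order: missing 'organisms' list")
    names = [
        o["name"] if isinstance(o, dict) else str(o) for o in organisms
    ]
    epochs = {str(k): int(v) for k, v in (data.get("epochs") or {}).items()}
    return OrganismOrder(names=tuple(names), epochs=epochs)


def write_organism_order(order: OrganismOrder, path) -> None:
    data = {
        "organisms": [{"name": n} for n in order.names],
        "epochs": {k: int(v) for k, v in sorted(order.epochs.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Whole bundles

def _pair_filename(pair: AlignedOrthologPair) -> str:
    org = pair.organism.replace(". ", "").replace(" ", "_").replace(".", "")
    return f"{pair.human_id}__{org}.afa"


def write_bundle(dataset, out_dir) -> None:
    """Serialize a dataset bundle (synthetic or assembled) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.sequences, out / "human_proteins.fasta")
    write_site_table(dataset.sites, out / "sites.tsv")
    write_ortholog_map(dataset.ortholog_map, out / "orthologs.tsv")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for pid in sorted(dataset.aligned_pairs):
        for organism in sorted(dataset.aligned_pairs[pid]):
            pair = dataset.aligned_pairs[pid][organism]
            write_aligned_pair(pair, aln_dir / _pair_filename(pair))
    write_annotations(dataset.annotations, out / "annotations.tsv")
    if dataset.expression is not None:
        write_expression(dataset.expression, out / "expression.tsv")
    write_edges(dataset.edges, out / "edges.tsv")
    write_organism_order(dataset.organism_order, out / "organisms.yaml")
    truth = getattr(dataset, "truth", None)
    if truth is not None:
        _write_truth(truth, out / "ground_truth")


def _write_truth(truth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(
            (pid, truth.protein_category[pid],
             truth.expression_class[pid], truth.degree[pid])
            for pid in truth.protein_category
        ),
        columns=["protein_id", "category", "expression_class", "degree"],
    ).to_csv(out / "proteins.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(
            (pid, pos,
             truth.site_rate_multiplier[(pid, pos)],
             truth.gain_epoch.get((pid, pos)) or "",
             "" if truth.gain_boundary.get((pid, pos)) is None
             else truth.gain_boundary[(pid, pos)],
             truth.loss_organism.get((pid, pos)) or "")
            for (pid, pos) in truth.site_rate_multiplier
        ),
        columns=["protein_id", "position_1based", "rate_multiplier",
                 "gain_epoch", "gain_boundary", "loss_organism"],
    ).to_csv(out / "sites.tsv", sep="\t", index=False)


def read_bundle(in_dir) -> DataBundle:
    """Load a serialized bundle back into the in-memory object graph."""
    src = Path(in_dir)
    order = read_organism_order(src / "organisms.yaml")
    sequences = read_fasta(src / "human_proteins.fasta")
    sites = read_site_table(src / "sites.tsv", sequences)
    ortholog_map = read_ortholog_map(src / "orthologs.tsv")
    aligned_pairs: Dict[str, Dict[str, AlignedOrthologPair]] = {}
    aln_dir = src / "alignments"
    if aln_dir.is_dir():
        for path in sorted(aln_dir.glob("*.afa")):
            pair = read_aligned_pair(path)
            aligned_pairs.setdefault(pair.human_id, {})[pair.organism] = pair
    annotations = {}
    if (src / "annotations.tsv").exists():
        annotations = read_annotations(src / "annotations.tsv")
    expression = None
    if (src / "expression.tsv").exists():
        expression = read_expression(src / "expression.tsv")
    edges = []
    if (src / "edges.tsv").exists():
        edges = read_edges(src / "edges.tsv")
    return DataBundle(
        organism_order=order,
        sequences=sequences,
        sites=sites,
        ortholog_map=ortholog_map,
        aligned_pairs=aligned_pairs,
        annotations=annotations,
        expression=expression,
        edges=edges,
    )
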