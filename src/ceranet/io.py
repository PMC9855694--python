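"""Readers and writers for the pipeline's on-disk formats.

Counts and design tables are TSV, sequences FASTA (via Biopython),
annotation GMT, networks TSV plus SIF for graph viewers, configuration
YAML. Malformed inputs raise ``ValueError`` naming the offending line or
cell.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ceranet.core import ExpressionMatrix, SegmentDesign
from ceranet.network import CeRNANetwork, CorrEdge, edges_to_frame
from ceranet.targets import TargetSite


def read_counts_tsv(path, rna_class: str) -> ExpressionMatrix:
    """Counts TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric count at gene {df.index[bad[0]]!r}, sample {col!r}"
            )
        if vals.isna().any():
            r = np.nonzero(vals.isna().to_numpy())[0][0]
            raise ValueError(f"{path}: missing count at gene {df.index[r]!r}, sample {col!r}")
        neg = np.nonzero((vals < 0).to_numpy())[0]
        if len(neg):
            raise ValueError(
                f"{path}: negative count at gene {df.index[neg[0]]!r}, sample {col!r}"
            )
        df[col] = vals
    return ExpressionMatrix(df, rna_class)


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")


def read_design_tsv(path) -> SegmentDesign:
    return SegmentDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_design_tsv(design: SegmentDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA to an id -> sequence dict; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> member ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: expected >= 3 tab-separated fields")
            name = fields[0]
            if not name:
                raise ValueError(f"{path}: line {ln}: empty set name")
            if name in sets:
                raise ValueError(f"{path}: line {ln}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}: line {ln}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def read_ppi_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def sites_to_frame(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "score": s.score,
                "seed_match": s.seed_match,
            }
            for s in sites
        ],
        columns=["mirna_id", "transcript_id", "start", "end", "score", "seed_match"],
    )


def frame_to_sites(df: pd.DataFrame) -> list[TargetSite]:
    return [
        TargetSite(
            str(r.mirna_id), str(r.transcript_id), int(r.start), int(r.end),
            float(r.score), bool(r.seed_match),
        )
        for r in df.itertuples(index=False)
    ]


def write_sites_tsv(sites: list[TargetSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[TargetSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t"))


def write_edges_tsv(edges: list[CorrEdge], path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sif(network: CeRNANetwork, path) -> None:
    """Simple-interaction-format export: node_a <tab> edge_type <tab> node_b."""
    with open(path, "w") as fh:
        for a, b, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{d['edge_type']}\t{b}\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: YAML config must be a mapping")
    return data


def save_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
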