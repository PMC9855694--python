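"""End-to-end orchestration: counts -> DE -> patterns -> targets -> network.

``run_pipeline`` chains the stages over the three RNA classes and the three
segment contrasts, writes every stage's table under the output directory,
and returns (and writes) a machine-readable run summary. Identical inputs,
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

from ceranet.core import RNA_CLASSES
from ceranet import io as cio
from ceranet.diffexpr import CONTRASTS, de_test, size_factors
from ceranet.enrichment import GeneSetCollection, ora
from ceranet.network import (
    assemble_network,
    build_edges,
    correlation_target_sets,
    filter_ppi,
    triplets_to_frame,
)
from ceranet.patterns import call_patterns, calls_to_frame, segment_means, split_gene_sets
from ceranet.targets import AlignParams, predict_targets


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[{name}] {exc}") from exc


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Threshold defaults follow the study's stated cutoffs: DE at raw
    p < 0.05, Spearman filters at |rho| >= 0.7 with p < 0.05, enrichment at
    p < 0.05, protein-interaction combined score strictly > 0.4.
    """

    counts_mrna: str
    counts_lncrna: str
    counts_mirna: str
    design: str
    mirna_fasta: str
    transcript_fasta: str
    outdir: str
    gmt: str | None = None
    ppi: str | None = None
    truth_triplets: str | None = None

    alpha_de: float = 0.05
    rel_tol: float = 0.05
    abs_floor: float = 1.0
    score_threshold: float = 140.0
    require_seed: bool = True
    rho_neg: float = -0.7
    rho_pos: float = 0.7
    alpha_corr: float = 0.05
    rho_min_targets: float = 0.7
    alpha_enrich: float = 0.05
    ppi_min_score: float = 0.4
    mirna_target_corr_mode: str = "absolute"
    network_gene_sets: str = "growth"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_corr", "alpha_enrich"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if not 0 < self.rho_pos <= 1 or not 0 < self.rho_min_targets <= 1:
            raise ValueError("positive rho thresholds must be in (0, 1]")
        if not -1 <= self.rho_neg < 0:
            raise ValueError(f"rho_neg must be in [-1, 0), got {self.rho_neg!r}")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError(f"ppi_min_score must be in [0, 1], got {self.ppi_min_score!r}")
        if self.network_gene_sets not in ("growth", "formation"):
            raise ValueError(
                f"network_gene_sets must be growth or formation, got {self.network_gene_sets!r}"
            )
        if self.mirna_target_corr_mode not in ("positive", "negative", "absolute"):
            raise ValueError(
                f"mirna_target_corr_mode must be positive/negative/absolute, "
                f"got {self.mirna_target_corr_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**cio.load_yaml(path))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run summary dict.

    Writes, under ``config.outdir``: per-contrast DE tables, pattern calls
    and gene sets, predicted target sites, the correlation-filtered edge
    list, triplets, labeled components, a SIF export, enrichment tables
    (when a GMT is supplied), the filtered protein-interaction table (when
    supplied), and ``summary.json``.
    """
    out = cio.ensure_dir(config.outdir)
    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}

    with _stage("io"):
        matrices = {
            "mRNA": cio.read_counts_tsv(config.counts_mrna, "mRNA"),
            "lncRNA": cio.read_counts_tsv(config.counts_lncrna, "lncRNA"),
            "miRNA": cio.read_counts_tsv(config.counts_mirna, "miRNA"),
        }
        design = cio.read_design_tsv(config.design)
        mirna_seqs = cio.read_fasta(config.mirna_fasta)
        transcript_seqs = cio.read_fasta(config.transcript_fasta)

    with _stage("diffexpr"):
        factors = {cls: size_factors(m) for cls, m in matrices.items()}
        de_union: dict[str, set[str]] = {cls: set() for cls in RNA_CLASSES}
        summary["de_counts"] = {}
        for cls in RNA_CLASSES:
            for contrast in CONTRASTS:
                res = de_test(
                    matrices[cls], design, contrast, config.alpha_de, factors[cls]
                )
                tag = f"{contrast[0]}_vs_{contrast[1]}"
                res.to_csv(out / f"de_{cls}_{tag}.tsv", sep="\t", index=False,
                           float_format="%.6g")
                de_genes = set(res.loc[res["de_flag"], "gene"])
                de_union[cls] |= de_genes
                summary["de_counts"][f"{cls}_{tag}"] = len(de_genes)

    with _stage("patterns"):
        norm = {cls: matrices[cls].normalized(factors[cls]) for cls in RNA_CLASSES}
        calls_all = []
        sets_sizes = {}
        for cls in RNA_CLASSES:
            means = segment_means(norm[cls], design)
            calls = call_patterns(
                means, cls, genes=sorted(de_union[cls]),
                rel_tol=config.rel_tol, abs_floor=config.abs_floor,
            )
            calls_to_frame(calls).to_csv(out / f"patterns_{cls}.tsv", sep="\t",
                                         index=False, float_format="%.6g")
            calls_all.extend(calls)
        gene_sets = split_gene_sets(calls_all)
        for (kind, direction, cls), members in sorted(gene_sets.items()):
            sets_sizes[f"{kind}_{direction}_{cls}"] = len(members)
        summary["pattern_set_sizes"] = sets_sizes

    with _stage("target_prediction"):
        kind = config.network_gene_sets
        selected = {
            cls: sorted(
                gene_sets.get((kind, "up", cls), set())
                | gene_sets.get((kind, "down", cls), set())
            )
            for cls in RNA_CLASSES
        }
        scan_mirnas = {g: mirna_seqs[g] for g in selected["miRNA"] if g in mirna_seqs}
        scan_tx = {
            g: transcript_seqs[g]
            for g in selected["mRNA"] + selected["lncRNA"]
            if g in transcript_seqs
        }
        if scan_mirnas and scan_tx:
            sites = predict_targets(
                scan_mirnas, scan_tx,
                score_threshold=config.score_threshold,
                require_seed=config.require_seed,
                params=AlignParams(),
            )
        else:
            sites = []
        cio.write_sites_tsv(sites, out / "target_sites.tsv")
        summary["n_target_sites"] = len(sites)

    with _stage("cerna_network"):
        exprs_sel = {cls: norm[cls].subset_genes(selected[cls]) for cls in RNA_CLASSES}
        edges = build_edges(
            exprs_sel, sites,
            rho_neg=config.rho_neg, rho_pos=config.rho_pos, alpha=config.alpha_corr,
        )
        net = assemble_network(edges, calls_all)
        cio.write_edges_tsv(edges, out / "corr_edges.tsv")
        triplets_to_frame(net.triplets).to_csv(
            out / "triplets.tsv", sep="\t", index=False, float_format="%.6g"
        )
        comp_rows = []
        for i, (comp, label, hubs) in enumerate(
            zip(net.components, net.component_labels, net.hubs)
        ):
            comp_rows.append(
                f"{i}\t{label}\t{','.join(sorted(comp))}\t{','.join(hubs)}"
            )
        (out / "components.tsv").write_text(
            "component\tlabel\tnodes\thubs\n" + "".join(r + "\n" for r in comp_rows)
        )
        cio.write_sif(net, out / "network.sif")
        net_edges = [
            e for e in edges
            if net.graph.has_edge(e.node_a, e.node_b)
        ]
        summary["network"] = {
            "nodes": net.node_counts(),
            "n_edges": len(net_edges),
            "n_triplets": len(net.triplets),
            "n_components": len(net.components),
            "component_labels": sorted(net.component_labels),
        }

    if config.gmt:
        with _stage("enrichment"):
            anno = cio.read_gmt(config.gmt)
            universe = set(matrices["mRNA"].genes)
            collection = GeneSetCollection(sets=anno, universe=universe)
            frames = []
            for direction in ("up", "down"):
                members = gene_sets.get((kind, direction, "mRNA"), set())
                if members & universe:
                    res = ora(members, collection, alpha=config.alpha_enrich)
                    res.insert(0, "query", f"{kind}_{direction}_mRNA")
                    frames.append(res)
            corr_sets = correlation_target_sets(
                exprs_sel, sites,
                rho_min=config.rho_min_targets, alpha=config.alpha_corr,
                mirna_mode=config.mirna_target_corr_mode,
            )
            for cls in ("miRNA", "lncRNA"):
                for gid in sorted(corr_sets[cls]):
                    members = corr_sets[cls][gid] & universe
                    if members:
                        res = ora(members, collection, alpha=config.alpha_enrich)
                        res.insert(0, "query", f"{cls}:{gid}")
                        frames.append(res)
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
                )
            summary["n_enrichment_queries"] = len(frames)

    if config.ppi:
        with _stage("ppi_filter"):
            ppi = cio.read_ppi_tsv(config.ppi)
            network_mrnas = {
                v for v, d in net.graph.nodes(data=True) if d["rna_class"] == "mRNA"
            }
            kept = filter_ppi(ppi, min_score=config.ppi_min_score, genes=network_mrnas)
            kept.to_csv(out / "ppi_filtered.tsv", sep="\t", index=False)
            summary["n_ppi_edges"] = len(kept)

    if config.truth_triplets:
        with _stage("truth_eval"):
            import pandas as pd

            truth_df = pd.read_csv(config.truth_triplets, sep="\t")
            truth = {
                (str(r.mRNA), str(r.miRNA), str(r.lncRNA))
                for r in truth_df.itertuples(index=False)
            }
            found = {(t.mrna, t.mirna, t.lncrna) for t in net.triplets}
            summary["triplet_recovery"] = {
                "n_planted": len(truth),
                "n_reported": len(found),
                "recall": (len(truth & found) / len(truth)) if truth else None,
                "precision": (len(truth & found) / len(found)) if found else None,
            }

    with _stage("summary"):
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
    return summary
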