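"""Expression-pattern classification along the three body segments.

Genes differentially expressed in at least one pairwise segment contrast
are classified from their per-segment mean normalized expression:
monotone profiles (S1 < S2 < S3 or S1 > S2 > S3) are "growth"-associated,
profiles peaking or dipping in the middle segment are
"formation"-associated, anything within tolerance of flat is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ceranet.core import ExpressionMatrix, SegmentDesign, SEGMENTS

LABELS = ("growth_up", "growth_down", "formation_up", "formation_down", "other")


@dataclass(frozen=True)
class PatternCall:
    gene: str
    rna_class: str
    means: tuple[float, float, float]  # S1, S2, S3
    label: str

    @property
    def direction(self) -> str | None:
        """up/down regulation direction, defined for growth labels."""
        if self.label.endswith("_up"):
            return "up"
        if self.label.endswith("_down"):
            return "down"
        return None


def segment_means(matrix: ExpressionMatrix, design: SegmentDesign) -> pd.DataFrame:
    """Arithmetic mean of (already normalized) expression per segment.

    Columns are S1, S2, S3 in order; missing segments are an error.
    """
    missing = [s for s in SEGMENTS if s not in design.present_segments()]
    if missing:
        raise ValueError(f"design lacks segment(s) {missing}")
    cols = {}
    for seg in SEGMENTS:
        samples = [s for s in matrix.samples if design.segment_of(s) == seg]
        if not samples:
            raise ValueError(f"matrix has no samples for segment {seg}")
        cols[seg] = matrix.values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.values.index)


def classify_pattern(
    means, rel_tol: float = 0.05, abs_floor: float = 1.0
) -> str:
    """Label one 3-segment mean profile.

    Consecutive differences are compared to a tolerance
    ``eps = rel_tol * max(max(means), abs_floor)``: both above +eps is
    growth_up, both below -eps growth_down, an S2 peak formation_up, an S2
    dip formation_down, anything else (flat, or sub-tolerance wiggles)
    other. The floor keeps noise-level profiles near zero from being
    classified on tiny absolute differences.
    """
    m1, m2, m3 = (float(v) for v in means)
    if min(m1, m2, m3) < 0:
        raise ValueError(f"negative segment mean in {means!r}")
    eps = rel_tol * max(m1, m2, m3, abs_floor)
    d1, d2 = m2 - m1, m3 - m2
    if d1 > eps and d2 > eps:
        return "growth_up"
    if d1 < -eps and d2 < -eps:
        return "growth_down"
    if d1 > eps and d2 < -eps:
        return "formation_up"
    if d1 < -eps and d2 > eps:
        return "formation_down"
    return "other"


def call_patterns(
    means: pd.DataFrame,
    rna_class: str,
    genes=None,
    rel_tol: float = 0.05,
    abs_floor: float = 1.0,
) -> list[PatternCall]:
    """Classify every row of a segment-means table (optionally restricted
    to ``genes``, typically the DE union across contrasts)."""
    if genes is not None:
        keep = set(genes)
        means = means.loc[[g for g in means.index if g in keep]]
    calls = []
    for gene, row in means.iterrows():
        profile = (float(row["S1"]), float(row["S2"]), float(row["S3"]))
        calls.append(
            PatternCall(
                gene=str(gene),
                rna_class=rna_class,
                means=profile,
                label=classify_pattern(profile, rel_tol=rel_tol, abs_floor=abs_floor),
            )
        )
    return calls


def split_gene_sets(calls: list[PatternCall]) -> dict[tuple[str, str, str], set[str]]:
    """Disjoint id sets keyed by (type, direction, RNA class).

    ``type`` is growth or formation; genes labeled ``other`` are excluded.
    Duplicate gene ids (within an RNA class) are an error.
    """
    seen: set[tuple[str, str]] = set()
    out: dict[tuple[str, str, str], set[str]] = {}
    for call in calls:
        key_id = (call.rna_class, call.gene)
        if key_id in seen:
            raise ValueError(f"duplicate gene id {call.gene!r} ({call.rna_class})")
        seen.add(key_id)
        if call.label == "other":
            continue
        kind, direction = call.label.split("_")
        out.setdefault((kind, direction, call.rna_class), set()).add(call.gene)
    return out


def calls_to_frame(calls: list[PatternCall]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene,
            "class": c.rna_class,
            "m_S1": c.means[0],
            "m_S2": c.means[1],
            "m_S3": c.means[2],
            "label": c.label,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["gene", "class", "m_S1", "m_S2", "m_S3", "label"])
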