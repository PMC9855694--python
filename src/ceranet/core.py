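"""Core containers: the sample design and typed expression matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical segment order along the body axis (no IBs -> forming -> formed).
SEGMENTS = ("S1", "S2", "S3")

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")


@dataclass(frozen=True)
class SegmentDesign:
    """Assignment of samples to developmental segments.

    Parameters
    ----------
    samples :
        Sample identifiers, in matrix column order.
    segments :
        Segment label per sample; each must be one of ``SEGMENTS``.
    replicates :
        Replicate index per sample (1-based within segment).
    """

    samples: tuple[str, ...]
    segments: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.segments) == len(self.replicates)):
            raise ValueError("samples, segments and replicates must have equal length")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in design")
        bad = sorted(set(self.segments) - set(SEGMENTS))
        if bad:
            raise ValueError(f"unknown segment labels: {bad}; expected {SEGMENTS}")

    @classmethod
    def canonical(cls, n_replicates: int = 3) -> "SegmentDesign":
        """The study's 3-segment x n-replicate design, samples ``S1_r1 .. S3_rn``."""
        samples, segs, reps = [], [], []
        for seg in SEGMENTS:
            for r in range(1, n_replicates + 1):
                samples.append(f"{seg}_r{r}")
                segs.append(seg)
                reps.append(r)
        return cls(tuple(samples), tuple(segs), tuple(reps))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentDesign":
        for col in ("sample", "segment", "replicate"):
            if col not in df.columns:
                raise ValueError(f"design table missing column {col!r}")
        return cls(
            tuple(df["sample"].astype(str)),
            tuple(df["segment"].astype(str)),
            tuple(int(r) for r in df["replicate"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "segment": self.segments, "replicate": self.replicates}
        )

    def samples_in(self, segment: str) -> list[str]:
        return [s for s, g in zip(self.samples, self.segments) if g == segment]

    def segment_of(self, sample: str) -> str:
        try:
            return self.segments[self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"sample {sample!r} not in design") from None

    def present_segments(self) -> list[str]:
        return [s for s in SEGMENTS if s in self.segments]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes-x-samples expression values for one RNA class.

    ``values`` is a pandas DataFrame indexed by gene id with sample columns.
    Raw simulator / sequencing output holds integer counts; normalized
    matrices hold nonnegative reals.
    """

    values: pd.DataFrame
    rna_class: str
    design: SegmentDesign | None = field(default=None)

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in {self.rna_class} matrix")
        arr = self.values.to_numpy()
        if arr.size and (np.asarray(arr) < 0).any():
            r, c = np.argwhere(np.asarray(arr) < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.design is not None:
            missing = set(self.values.columns) - set(self.design.samples)
            if missing:
                raise ValueError(f"samples {sorted(missing)} not in design")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(gene_ids)]
        return ExpressionMatrix(self.values.loc[keep], self.rna_class, self.design)

    def normalized(self, factors: pd.Series) -> "ExpressionMatrix":
        """Divide each sample column by its size factor."""
        factors = factors.reindex(self.values.columns)
        if factors.isna().any():
            raise ValueError("size factors missing for some samples")
        return ExpressionMatrix(self.values / factors, self.rna_class, self.design)
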