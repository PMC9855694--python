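"""Seeded synthetic multi-omic data with planted ground truth.

Emulates the three-segment (S1: no intermuscular bones, S2: forming,
S3: formed) x three-replicate design: negative-binomial counts for the
three RNA classes, planted monotone ("growth") and middle-segment-extremum
("formation") trends, planted ceRNA triplets in which the miRNA trend
opposes the mRNA/lncRNA trend, and sequences carrying exact complementary
binding sites for the planted miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ceranet.core import ExpressionMatrix, SegmentDesign, RNA_CLASSES
from ceranet.targets import TargetSite, AlignParams, perfect_complement_score

_RNA_BASES = "ACGU"
_DNA_BASES = "ACGT"
# miRNA base -> complementary transcript (DNA) base
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}

MIRNA_LENGTH = 22


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``dispersion`` is the negative-binomial alpha with variance
    ``mu + alpha * mu**2``; ``fold_step`` is the multiplicative change per
    segment for planted trends, so a planted monotone-up gene has segment
    means ``(m, m*f, m*f**2)``.
    """

    n_mrna: int
    n_lncrna: int
    n_mirna: int
    n_replicates: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    fold_step: float = 4.0
    n_planted_triplets: int = 0
    n_planted_formation: int = 0
    site_length: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_planted_triplets",
                     "n_planted_formation"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates!r}")
        if not self.baseline_mean > 0:
            raise ValueError(f"baseline_mean must be > 0, got {self.baseline_mean!r}")
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion!r}")
        if not self.fold_step > 1:
            raise ValueError(f"fold_step must be > 1, got {self.fold_step!r}")
        if self.n_planted_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError(
                "n_planted_triplets exceeds the smallest class size "
                f"({self.n_planted_triplets} > "
                f"{min(self.n_mrna, self.n_lncrna, self.n_mirna)})"
            )
        if self.n_planted_triplets + self.n_planted_formation > self.n_mrna:
            raise ValueError("n_planted_formation leaves no room in the mRNA class")
        if not 6 <= self.site_length <= 8:
            raise ValueError(f"site_length must be in [6, 8], got {self.site_length!r}")

    def gene_ids(self, rna_class: str) -> list[str]:
        n = {"mRNA": self.n_mrna, "lncRNA": self.n_lncrna, "miRNA": self.n_mirna}[rna_class]
        prefix = {"mRNA": "mRNA", "lncRNA": "lnc", "miRNA": "miR"}[rna_class]
        return [f"{prefix}_{i + 1:04d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Planted signal of one simulated dataset."""

    pattern_by_gene: dict[str, str]
    planted_triplets: list[tuple[str, str, str]]  # (mRNA, miRNA, lncRNA)
    planted_sites: list[TargetSite] = field(default_factory=list)
    size_factors_true: dict[str, float] = field(default_factory=dict)


def _pattern_means(label: str, m: float, f: float) -> tuple[float, float, float]:
    if label == "growth_up":
        return (m, m * f, m * f * f)
    if label == "growth_down":
        return (m * f * f, m * f, m)
    if label == "formation_up":
        return (m, m * f, m)
    if label == "formation_down":
        return (m, m / f, m)
    return (m, m, m)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + np.asarray(mu, dtype=float))
    return rng.negative_binomial(r, p)


def generate_counts(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Draw the three count matrices and their ground truth.

    Planted triplets occupy the leading ids of each class; each triplet's
    mRNA and lncRNA share a monotone trend and its miRNA takes the opposite
    trend, with the up/down orientation flipped per triplet by the RNG.
    Per-sample library-size factors are drawn log-uniform in [0.7, 1.4] and
    scale every gene's mean in that sample. Sub-seeds are derived per gene,
    so draws do not depend on iteration order.
    """
    design = SegmentDesign.canonical(config.n_replicates)
    top = np.random.default_rng([config.rng_seed, 0])

    sizes = np.exp(top.uniform(np.log(0.7), np.log(1.4), size=len(design.samples)))
    size_by_sample = dict(zip(design.samples, sizes))

    # planted assignment
    pattern_by_gene: dict[str, str] = {}
    triplets: list[tuple[str, str, str]] = []
    mrna_ids = config.gene_ids("mRNA")
    lnc_ids = config.gene_ids("lncRNA")
    mir_ids = config.gene_ids("miRNA")
    for t in range(config.n_planted_triplets):
        up = bool(top.integers(0, 2))
        host, guest = ("growth_up", "growth_down") if up else ("growth_down", "growth_up")
        pattern_by_gene[mrna_ids[t]] = host
        pattern_by_gene[lnc_ids[t]] = host
        pattern_by_gene[mir_ids[t]] = guest
        triplets.append((mrna_ids[t], mir_ids[t], lnc_ids[t]))
    for i in range(config.n_planted_formation):
        gid = mrna_ids[config.n_planted_triplets + i]
        pattern_by_gene[gid] = "formation_up" if i % 2 == 0 else "formation_down"

    seg_index = np.array([("S1", "S2", "S3").index(s) for s in design.segments])
    matrices: dict[str, ExpressionMatrix] = {}
    for ci, rna_class in enumerate(RNA_CLASSES):
        ids = config.gene_ids(rna_class)
        counts = np.empty((len(ids), len(design.samples)), dtype=np.int64)
        for gi, gid in enumerate(ids):
            label = pattern_by_gene.get(gid, "flat")
            seg_means = _pattern_means(label, config.baseline_mean, config.fold_step)
            mu = np.array([seg_means[k] for k in seg_index]) * sizes
            grng = np.random.default_rng([config.rng_seed, 1 + ci, gi])
            counts[gi] = _nb_draw(grng, mu, config.dispersion)
        matrices[rna_class] = ExpressionMatrix(
            pd.DataFrame(counts, index=ids, columns=list(design.samples)),
            rna_class,
            design,
        )

    truth = GroundTruth(
        pattern_by_gene=pattern_by_gene,
        planted_triplets=triplets,
        size_factors_true=size_by_sample,
    )
    return matrices, truth


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def reverse_complement_site(mirna: str) -> str:
    """DNA reverse complement of an (RNA-alphabet) miRNA, 5'->3'."""
    return "".join(_COMPLEMENT[b] for b in reversed(mirna.upper().replace("T", "U")))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Random Eulerian walk on the dinucleotide multigraph (same first and
    last base as the input); used to build negative-control transcripts
    that keep local composition but destroy planted binding sites.
    """
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            edges[a] = list(rng.permutation(edges[a]))
        walk = [seq[0]]
        cur = seq[0]
        while edges.get(cur):
            cur = edges[cur].pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def generate_sequences(
    truth: GroundTruth, config: SimConfig
) -> tuple[dict[str, str], dict[str, str]]:
    """Emit miRNA and transcript sequences; plant binding sites for triplets.

    Returns ``(mirnas, transcripts)`` as id -> sequence dicts (miRNAs in the
    RNA alphabet, transcripts in DNA). For every planted triplet the mRNA and
    lncRNA transcript each receive one exact full-length reverse complement
    of the 22-nt miRNA, which necessarily contains the exact complement of
    the miRNA seed (positions 2 .. 1+site_length). The planted sites are
    appended to ``truth.planted_sites`` with 0-based half-open sense-strand
    coordinates. Non-target transcripts are uniform random sequences with no
    planted site.
    """
    mrna_ids = config.gene_ids("mRNA")
    lnc_ids = config.gene_ids("lncRNA")
    mir_ids = config.gene_ids("miRNA")
    known = set(mrna_ids) | set(lnc_ids) | set(mir_ids)
    referenced = set(truth.pattern_by_gene) | {g for t in truth.planted_triplets for g in t}
    unknown = referenced - known
    if unknown:
        raise ValueError(
            f"ground truth references ids absent from config: {sorted(unknown)[:5]}"
        )

    mirnas = {
        gid: _random_seq(np.random.default_rng([config.rng_seed, 4, gi]),
                         MIRNA_LENGTH, _RNA_BASES)
        for gi, gid in enumerate(mir_ids)
    }

    # transcript id -> list of miRNAs with a site to plant
    plant: dict[str, list[str]] = {}
    for m_id, mi_id, l_id in truth.planted_triplets:
        plant.setdefault(m_id, []).append(mi_id)
        plant.setdefault(l_id, []).append(mi_id)

    params = AlignParams()
    transcripts: dict[str, str] = {}
    truth.planted_sites = []
    for ci, ids in ((5, mrna_ids), (6, lnc_ids)):
        for gi, gid in enumerate(ids):
            rng = np.random.default_rng([config.rng_seed, ci, gi])
            length = int(rng.integers(200, 1001))
            seq = list(_random_seq(rng, length, _DNA_BASES))
            for mi_id in plant.get(gid, []):
                site = reverse_complement_site(mirnas[mi_id])
                start = int(rng.integers(0, length - len(site) + 1))
                seq[start:start + len(site)] = site
                truth.planted_sites.append(
                    TargetSite(
                        mirna_id=mi_id,
                        transcript_id=gid,
                        start=start,
                        end=start + len(site),
                        score=perfect_complement_score(MIRNA_LENGTH, params),
                        seed_match=True,
                    )
                )
            transcripts[gid] = "".join(seq)
    return mirnas, transcripts
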