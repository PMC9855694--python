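import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ceranet as cn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded dataset with planted triplets and formation genes."""
    cfg = cn.SimConfig(
        n_mrna=60,
        n_lncrna=25,
        n_mirna=12,
        n_planted_triplets=8,
        n_planted_formation=6,
        rng_seed=101,
    )
    mats, truth = cn.generate_counts(cfg)
    mirnas, transcripts = cn.generate_sequences(truth, cfg)
    return cfg, mats, truth, mirnas, transcripts


def write_dataset(outdir, cfg):
    """Materialize a simulated dataset plus a pipeline config on disk."""
    from ceranet import io as cio
    import pandas as pd

    out = cio.ensure_dir(outdir)
    mats, truth = cn.generate_counts(cfg)
    mirnas, transcripts = cn.generate_sequences(truth, cfg)
    for cls, m in mats.items():
        cio.write_counts_tsv(m, out / f"counts_{cls}.tsv")
    cio.write_design_tsv(mats["mRNA"].design, out / "design.tsv")
    cio.write_fasta(mirnas, out / "mirna.fa")
    cio.write_fasta(transcripts, out / "transcripts.fa")
    pd.DataFrame(truth.planted_triplets, columns=["mRNA", "miRNA", "lncRNA"]).to_csv(
        out / "truth_triplets.tsv", sep="\t", index=False
    )
    config = cn.PipelineConfig(
        counts_mrna=str(out / "counts_mRNA.tsv"),
        counts_lncrna=str(out / "counts_lncRNA.tsv"),
        counts_mirna=str(out / "counts_miRNA.tsv"),
        design=str(out / "design.tsv"),
        mirna_fasta=str(out / "mirna.fa"),
        transcript_fasta=str(out / "transcripts.fa"),
        truth_triplets=str(out / "truth_triplets.tsv"),
        outdir=str(out / "results"),
        rng_seed=cfg.rng_seed,
    )
    return config, truth


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the default study-scale simulation."""
    cfg = cn.SimConfig(
        n_mrna=150,
        n_lncrna=50,
        n_mirna=25,
        n_planted_triplets=20,
        n_planted_formation=10,
        rng_seed=11,
    )
    config, truth = write_dataset(tmp_path_factory.mktemp("demo"), cfg)
    summary = cn.run_pipeline(config)
    return config, truth, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
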