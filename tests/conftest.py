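import warnings
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import duplexscan as ds
from duplexscan.pipeline import run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def matrix():
    return ds.default_matrix()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    ds.make_fixture(seed=1, out_dir=out)
    return out


@pytest.fixture(scope="session")
def fixture_bundle(fixture_dir):
    return ds.make_fixture(seed=1)


def pipeline_config(fixture_dir: Path, mode: str, **extra):
    cfg = dict(
        mode=mode,
        lnc_fasta=fixture_dir / "lnc.fa",
        target_fasta=fixture_dir / "targets.fa",
        annotation=fixture_dir / "annotation.gtf",
        genome_fasta=fixture_dir / "genome.fa",
        clip_bed=fixture_dir / "clip.bed",
        mirna_clip_bed=fixture_dir / "mirna_clip.bed",
        mirna_predicted_bed=fixture_dir / "mirna_predicted.bed",
        alu_bed=fixture_dir / "alu.bed",
        editing_bed=fixture_dir / "editing.bed",
        mappings_tsv=fixture_dir / "mappings.tsv",
        threshold=107 if mode == "mRNA" else 108,
    )
    cfg.update(extra)
    return cfg


@pytest.fixture(scope="session")
def mrna_results(fixture_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(pipeline_config(fixture_dir, "mRNA"))


@pytest.fixture(scope="session")
def premrna_results(fixture_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(pipeline_config(fixture_dir, "pre-mRNA"))


def random_record(name, length, rng, gc=0.5):
    from duplexscan.scoring import random_sequence

    return ds.SequenceRecord(name, random_sequence(length, rng, gc))


def plant_complement(rng, flank_len, n_gc, n_at, guard=0):
    """A (lnc, target) pair with one perfect planted complement.

    Returns (lnc_record, target_record, planted_score, lnc_iv, target_iv).
    """
    from duplexscan.scoring import random_sequence

    seg = "".join(rng.choice(list("GC"), size=n_gc)) + "".join(
        rng.choice(list("AT"), size=n_at)
    )
    seg = "".join(rng.permutation(list(seg)))
    pad = "A" * guard
    tgt = random_sequence(flank_len, rng) + pad + seg + pad + random_sequence(flank_len, rng)
    lnc = random_sequence(flank_len, rng) + pad + ds.revcomp(seg) + pad + random_sequence(flank_len, rng)
    score = 4 * n_gc + 2 * n_at
    L = n_gc + n_at
    lnc_iv = (flank_len + guard, flank_len + guard + L)
    tgt_iv = (flank_len + guard, flank_len + guard + L)
    return (
        ds.SequenceRecord("lnc", lnc),
        ds.SequenceRecord("tgt", tgt),
        score,
        lnc_iv,
        tgt_iv,
    )
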