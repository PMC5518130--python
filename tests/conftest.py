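"""Shared fixtures: the seeded synthetic study and an end-to-end pipeline run."""

from __future__ import annotations

import pandas as pd
import pytest

from lncseek import SimulationConfig, run_pipeline, simulate_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Default synthetic study (seed fixed) with its truth tables loaded."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SimulationConfig(seed=STUDY_SEED)
    paths = simulate_study(cfg, outdir)
    truth = pd.read_csv(paths["truth.tsv"], sep="\t")
    return {
        "cfg": cfg,
        "paths": paths,
        "truth": truth,
        "truth_motifs": pd.read_csv(paths["truth_motifs.tsv"], sep="\t"),
        "truth_seeds": pd.read_csv(paths["truth_seeds.tsv"], sep="\t"),
    }


def pipeline_config(paths, outdir) -> dict:
    return {
        "inputs": {
            "genome": str(paths["genome.fa"]),
            "annotation": str(paths["annotation.gtf"]),
            "candidates": str(paths["candidates.gtf"]),
            "expression": str(paths["expression.tsv"]),
            "smallrna": str(paths["smallrna.bed"]),
            "pwm": str(paths["pwm.txt"]),
            "mirnas": str(paths["mirnas.tsv"]),
            "pathways": str(paths["pathways.gmt"]),
        },
        "outdir": str(outdir),
    }


@pytest.fixture(scope="session")
def pipeline_result(study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(pipeline_config(study["paths"], outdir))
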