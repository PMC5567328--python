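import numpy as np
import pandas as pd
import pytest

from occbias import synth
from occbias.ingest import read_backbone, read_occurrences_frame
from occbias.synth import ClassSpec, SynthConfig


@pytest.fixture
def small_config() -> SynthConfig:
    return SynthConfig(
        seed=42,
        n_records=6000,
        classes=[
            ClassSpec(
                "Avesia",
                n_species=60,
                weight=3.0,
                precision_rate=0.95,
                origin_mix=(0.15, 0.75, 0.10),
                missing_time_rate=0.05,
                missing_space_rate=0.10,
                geo_issue_rate=0.02,
            ),
            ClassSpec(
                "Insectia",
                n_species=300,
                weight=1.5,
                precision_rate=0.70,
                origin_mix=(0.60, 0.30, 0.10),
                missing_time_rate=0.30,
                missing_space_rate=0.40,
            ),
            ClassSpec(
                "Moluscia",
                n_species=80,
                weight=0.5,
                precision_rate=0.80,
                origin_mix=(0.70, 0.10, 0.20),
                missing_time_rate=0.50,
                missing_space_rate=0.50,
            ),
        ],
        synonym_fraction=0.1,
    )


@pytest.fixture
def dataset(small_config, tmp_path):
    """Synthetic dataset round-tripped through the on-disk dialects."""
    backbone = synth.gen_backbone(small_config)
    occ, bookkeeping = synth.gen_occurrences(small_config, backbone)
    synth.write_backbone(backbone, tmp_path / "backbone.tsv")
    synth.write_occurrences(occ, tmp_path / "occurrences.tsv")
    records, tally = read_occurrences_frame(tmp_path / "occurrences.tsv")
    entries = read_backbone(tmp_path / "backbone.tsv")
    return {
        "config": small_config,
        "backbone": entries,
        "records": records,
        "bookkeeping": bookkeeping,
        "tally": tally,
        "paths": {
            "backbone": tmp_path / "backbone.tsv",
            "occurrences": tmp_path / "occurrences.tsv",
        },
    }


@pytest.fixture
def coupled_covariates():
    cfg = SynthConfig(
        seed=7,
        classes=[ClassSpec("Avesia", n_species=1000, weight=1.0)],
        glm_truth=synth.GlmTruth(b0=1.0, b1=0.8, b2=0.0, b3=0.0, k=1.0),
    )
    backbone = synth.gen_backbone(cfg)
    table, truth = synth.gen_covariates(cfg, backbone, mode="coupled")
    return table, truth
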