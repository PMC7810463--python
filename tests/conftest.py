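"""Shared fixtures: one default synthetic dataset and one full pipeline run
per session, so the heavier integration checks reuse the same artefacts."""

import pytest

from bifate.pipeline import PipelineConfig, run_pipeline
from bifate.synthetic import SimulationConfig, simulate_dataset, write_dataset

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """(dataset, config, summary, outdir) for a full default run."""
    root = tmp_path_factory.mktemp("pipeline")
    paths = write_dataset(dataset, root / "data")
    cfg = PipelineConfig(
        genes=paths["genes"],
        chrom_sizes=paths["chrom_sizes"],
        expr_counts=paths["expr_counts"],
        expr_meta=paths["expr_meta"],
        replicate_beds=[v for k, v in paths.items() if k.startswith("bed:")],
        atac_counts=paths["atac_counts"],
        atac_tissues=paths["atac_tissues"],
        peak_coords=paths["peak_coords"],
        blacklist=paths["blacklist"],
        tracks_manifest=paths["tracks_manifest"],
        sequences=paths["sequences"],
        motifs_table=paths["motifs"],
        outdir=str(root / "out"),
        seed=DEFAULT_SEED,
    )
    summary = run_pipeline(cfg)
    return dataset, cfg, summary, root / "out"
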