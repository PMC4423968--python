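"""Shared fixtures: a small seeded simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit.io import CollapsedReadSet, clip_and_filter
from pirnakit.mapping import ExactMatchIndex, assign_weights, map_perfect
from pirnakit.simulate import SimulationConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # scaled-down study: same structure as the default conditions, smaller
    # genome and depth so the whole suite stays fast
    return SimulationConfig(seed=11, depth=30_000, chrom_len=600_000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    artifacts = make_genome(small_config)
    reads, truth = simulate_reads(artifacts)
    return artifacts, reads, truth


@pytest.fixture(scope="session")
def small_collapsed(small_sim, small_config) -> CollapsedReadSet:
    _, reads, _ = small_sim
    return clip_and_filter(reads, adapter3=small_config.adapter3)


@pytest.fixture(scope="session")
def small_hits(small_sim, small_collapsed):
    artifacts, _, _ = small_sim
    index = ExactMatchIndex(artifacts.genome)
    return assign_weights(map_perfect(small_collapsed, index))


@pytest.fixture(scope="session")
def pipeline_run(small_sim, small_config, tmp_path_factory):
    """One full pipeline execution over the shared small simulation."""
    from pirnakit.pipeline import PipelineConfig, run_pipeline
    from pirnakit.simulate import write_artifacts

    artifacts, reads, truth = small_sim
    indir = tmp_path_factory.mktemp("sim_inputs")
    outdir = tmp_path_factory.mktemp("pipeline_out")
    paths = write_artifacts(artifacts, reads, truth, indir)
    cfg = PipelineConfig(
        reads_fasta=str(paths["reads"]),
        genome_fasta=str(paths["genome"]),
        outdir=str(outdir),
        ncrna_fastas={k.split("_", 1)[1]: str(v) for k, v in paths.items() if k.startswith("ncrna_")},
        repeats_out=str(paths["repeats"]),
        genes_gtf=str(paths["genes"]),
        adapter3=small_config.adapter3,
        seed=small_config.seed,
    )
    result = run_pipeline(cfg)
    return cfg, result, paths


def naive_scan(reads: CollapsedReadSet, references: dict[str, str], orientation="both"):
    """Brute-force all-positions exact-match oracle (independent of the index)."""
    from pirnakit.io import reverse_complement

    hits = []
    for i, seq in enumerate(reads.sequences):
        rc = reverse_complement(seq)
        for ref_name, ref in references.items():
            L = len(seq)
            for start in range(len(ref) - L + 1):
                window = ref[start : start + L]
                if window == seq:
                    hits.append((i, ref_name, "+", start))
                if orientation == "both" and window == rc and rc != seq:
                    hits.append((i, ref_name, "-", start))
    return sorted(hits)
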