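import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import phage_profiler as pp


@pytest.fixture(scope="session")
def small_community():
    """Three 20-kb clusters of three genomes plus one singleton, disjoint
    domain pools, 2% within-cluster divergence."""
    spec = pp.CommunitySpec(
        clusters=[
            pp.ClusterSpec(3, 20000, 0.50, 0.02, 18, 10),
            pp.ClusterSpec(3, 22000, 0.60, 0.02, 18, 10),
            pp.ClusterSpec(3, 24000, 0.70, 0.02, 18, 10),
        ],
        n_singletons=1,
        shared_domain_fraction=0.0,
        seed=42,
        singleton_length=21000,
        singleton_gc=0.65,
        singleton_domains_per_genome=10,
    )
    return pp.plant_community(spec)


@pytest.fixture(scope="session")
def small_pipeline_config():
    """A reduced-size pipeline configuration (fast enough for repeated runs)."""

    def make(outdir, seed=7):
        spec = pp.CommunitySpec(
            clusters=[
                pp.ClusterSpec(2, 16000, 0.55, 0.02, 15, 9),
                pp.ClusterSpec(2, 18000, 0.65, 0.02, 15, 9),
            ],
            n_singletons=1,
            shared_domain_fraction=0.0,
            seed=seed,
            singleton_length=17000,
            singleton_gc=0.60,
            singleton_domains_per_genome=9,
        )
        return pp.PipelineConfig(
            outdir=outdir, seed=seed, community=spec, target_depth=20.0
        )

    return make


@pytest.fixture(scope="session")
def pipeline_run(small_pipeline_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline") / "bundle"
    config = small_pipeline_config(outdir)
    result = pp.run_pipeline(config)
    return outdir, result
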