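import numpy as np
import pytest

from holopop import simdata
from holopop.formats import GenotypeMatrix, PopulationMap


def make_matrix(calls, depth=None, qual=None, contigs=None, samples=None,
                positions=None, ref=None, alt=None):
    """Small-matrix helper used across test modules."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        contigs=np.array(contigs if contigs is not None else [f"c{l}" for l in range(L)], dtype=object),
        positions=np.array(positions if positions is not None else np.arange(1, L + 1)),
        ref=np.array(ref if ref is not None else ["A"] * L, dtype=object),
        alt=np.array(alt if alt is not None else ["T"] * L, dtype=object),
        calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        site_qual=None if qual is None else np.asarray(qual, dtype=float),
    )


def popmap_for(gm, n_pops=2):
    """Assign samples round-robin-free: contiguous blocks to n_pops pops."""
    labels = {}
    per = max(1, gm.n_samples // n_pops)
    origins = ["VA", "RI", "MA", "CT"]
    for i, s in enumerate(gm.samples):
        j = min(i // per, n_pops - 1)
        labels[s] = (origins[j % len(origins)], "B" if j < len(origins) else "W")
    return PopulationMap.from_records(labels)


@pytest.fixture
def sim_default():
    cfg = simdata.SimConfig(
        seed=11, n_neutral_loci=400, n_outlier_loci=25, missing_rate=0.04
    )
    gm, truth = simdata.simulate_genotypes(cfg)
    pm = simdata._population_map_for(gm, cfg.resolved_labels())
    return cfg, gm, truth, pm


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = simdata.SimConfig(seed=7, n_neutral_loci=300, n_outlier_loci=20,
                            missing_rate=0.03)
    manifest = simdata.write_fixture_bundle(cfg, out)
    return cfg, out, manifest
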