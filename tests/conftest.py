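import warnings

import numpy as np
import pytest

from denovoscape.datasets import ProteinRecord, SequenceSet
from denovoscape.pipeline import RunConfig, run_pipeline
from denovoscape.synthetic_data import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle, generated once per session (seed 1)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SyntheticConfig(seed=1), out)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run over the session bundle."""
    out = tmp_path_factory.mktemp("run")
    config = RunConfig.from_bundle(bundle["fasta"].parent, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(config, out)
    return {"manifest": manifest, "out": out, "bundle": bundle}


def random_protein_set(n, rng, min_len=5, max_len=60, name="random"):
    """Uniform-composition random records, for tally/predicate oracles."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    out = SequenceSet(name=name)
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.add(ProteinRecord(f"r{i:05d}", "".join(rng.choice(aa, size=L))))
    return out
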