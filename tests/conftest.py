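import numpy as np
import pytest

from nmdeff import generate_annotation, parse_transcript_models
from nmdeff.features import annotate_nmd_features


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory):
    """Generated toy locus: bundle, parsed models and feature profiles."""
    out = tmp_path_factory.mktemp("toy_annotation")
    bundle = generate_annotation(
        8, feature_mix={"ejc": 0.5, "uorf": 0.25, "none": 0.25}, seed=11, out_dir=str(out)
    )
    models = parse_transcript_models(bundle.gtf_path, bundle.fasta_path)
    profiles = {
        m.transcript_id: annotate_nmd_features(m, bundle.genome) for m in models
    }
    return bundle, models, profiles


@pytest.fixture()
def rng(request):
    """Per-test deterministic generator (seeded from the test id)."""
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.nodeid.encode()))
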