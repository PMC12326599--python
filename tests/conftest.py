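import pytest

from telokit import simulate_reference
from telokit.formats_io import read_fasta, read_gtf, read_repeatmasker
from telokit.genome_mask import build_mask_set


@pytest.fixture(scope="session")
def toy_ref():
    """Deterministic toy reference: 2 x 100 kb, 20 genes, 200 TEs."""
    return simulate_reference(seed=1)


@pytest.fixture(scope="session")
def ref_dir(toy_ref, tmp_path_factory):
    """The toy reference written to disk, plus parsed-back annotations."""
    d = tmp_path_factory.mktemp("toyref")
    paths = toy_ref.write(d)
    return {
        "dir": d,
        "paths": paths,
        "repeats": read_repeatmasker(paths["rmsk"], te_only=True),
        "genes": read_gtf(paths["gtf"]),
        "genome": read_fasta(paths["fasta"]),
    }


@pytest.fixture(scope="session")
def toy_masks(ref_dir, toy_ref):
    return build_mask_set(ref_dir["repeats"], ref_dir["genes"],
                          toy_ref.sizes)
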