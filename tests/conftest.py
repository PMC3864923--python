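import numpy as np
import pytest

from x3dis.protein_model import AA_ALPHABET, ProteinRecord, one_hot_track


def random_record(rng: np.random.Generator, n: int | None = None,
                  with_disorder: bool = False) -> ProteinRecord:
    """A fully annotated random protein for feature/oracle tests."""
    if n is None:
        n = int(rng.integers(1, 80))
    seq = "".join(rng.choice(list(AA_ALPHABET), n))
    rec = ProteinRecord(id=f"r{rng.integers(1 << 30)}", sequence=seq)
    rec.tracks["sa"] = one_hot_track("sa", "".join(rng.choice(list("BE"), n)))
    rec.tracks["ss3"] = one_hot_track("ss3", "".join(rng.choice(list("HEC"), n)))
    rec.attach_pssm(rng.integers(-10, 14, size=(n, 20)))
    if with_disorder:
        from x3dis.protein_model import label_disorder_from_missing

        rec.disorder = label_disorder_from_missing(rng.random(n) < 0.2)
    return rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded synthetic corpus shared by learner tests."""
    from x3dis.synthetic_data import SyntheticConfig, generate_corpus

    config = SyntheticConfig(
        n_proteins=40, length_log_mean=4.0, length_log_sd=0.3, length_max=100
    )
    records, truth = generate_corpus(config, seed=11)
    return records, truth
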