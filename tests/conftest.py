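import numpy as np
import pytest

from attforge import fixtures


@pytest.fixture(scope="session")
def junction_run():
    """One deterministic junction-sequencing simulation plus its pipeline input."""
    from attforge import integration_mapping as im

    genome = fixtures.make_genome(100_000, 0.41, seed=5)
    attd = fixtures.make_genome(50, 0.5, seed=6)
    donor = fixtures.build_donor(attd, core_offset=24, seed=7)
    sim = fixtures.simulate_junction_reads(
        genome, donor, n_reads=2000, n_sites=20, error_rate=0.001, seed=8)
    config = im.SiteConfig(donor_seq=donor.sequence, primer=donor.primer,
                           attd_interval=donor.attd_interval,
                           core_offset=donor.core_offset)
    return sim, config


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
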