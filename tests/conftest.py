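import numpy as np
import pytest

from metaregulon.motif import Background, SiteAlignment, build_pwm
from metaregulon.simulate import MagSpec, CommunitySpec, generate_genomes


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def small_pwm():
    """A sharp 6-bp PWM from three identical sites plus one variant."""
    align = SiteAlignment("TESTTF", ["ACGTAC", "ACGTAC", "ACGTAC", "ACGTAA"])
    return build_pwm(align, pseudocount=1.0)


def random_pwm(rng: np.random.Generator, width: int, n_sites: int = 8):
    """A random valid PWM for property tests."""
    sites = ["".join(rng.choice(list("ACGT"), size=width)) for _ in range(n_sites)]
    return build_pwm(SiteAlignment("RAND", sites), pseudocount=1.0)


@pytest.fixture(scope="session")
def small_community():
    """A 2-MAG community small enough for fast per-test use."""
    spec = CommunitySpec(
        mags=[
            MagSpec(mag_id="MAG_A", genome_size_bp=120_000, gc_content=0.36,
                    n_genes=70, tf_name="FNR", planted_fraction=0.1,
                    relative_dna=0.3, relative_mrna=0.6),
            MagSpec(mag_id="MAG_B", genome_size_bp=120_000, gc_content=0.64,
                    n_genes=70, tf_name="DNR", planted_fraction=0.1,
                    relative_dna=0.7, relative_mrna=0.4),
        ]
    )
    return generate_genomes(spec, seed=42)
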