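import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from exomesift.core import AnnotatedVariant, ConsequenceClass, Zygosity


def make_variant(**kwargs) -> AnnotatedVariant:
    """A valid variant with every field defaulted; override freely."""
    base = dict(
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="G",
        gene="DNAI1",
        transcript="NM_012144.4",
        cnomen="c.100A>G",
        consequence=ConsequenceClass.MISSENSE,
        splice_distance=0,
        zygosity=Zygosity.HETEROZYGOUS,
        quality=500.0,
        depth=100,
        alt_depth=50,
    )
    base.update(kwargs)
    return AnnotatedVariant(**base)


@pytest.fixture
def variant_factory():
    return make_variant
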