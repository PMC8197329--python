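import itertools

import pytest
from hypothesis import HealthCheck, settings

from pairconcord.model import SampleRole, VariantClass, VariantRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_counter = itertools.count(1)


def make_variant(
    gene="TP53",
    patient_id="P0001",
    sample_id=None,
    sample_role=SampleRole.PRIMARY,
    pos=None,
    ref="C",
    alt="T",
    variant_class=VariantClass.MISSENSE_SNV,
    **kwargs,
):
    """A valid VariantRecord with unique coordinates unless pinned."""
    if pos is None:
        pos = 1000 + next(_counter)
    if sample_id is None:
        suffix = "P" if sample_role is SampleRole.PRIMARY else "M"
        sample_id = f"{patient_id}-{suffix}"
    return VariantRecord(
        patient_id=patient_id,
        sample_id=sample_id,
        sample_role=sample_role,
        gene=gene,
        chrom="chr17",
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        **kwargs,
    )


@pytest.fixture
def variant_factory():
    return make_variant
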