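import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_truthless_patient_warnings():
    # cohort fixtures legitimately contain patients without truth records
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="patient .* has no truth records"
        )
        yield


@pytest.fixture
def small_callset():
    """Five KEEP calls with LODs {2,3,4,5,100}; the fourth carries pop_af 0.3."""
    from lbseq.callset_io import (
        GenomicLocus,
        Judgement,
        SampleCallSet,
        VariantCall,
    )

    lods = [2.0, 3.0, 4.0, 5.0, 100.0]
    pop = [None, None, None, 0.3, None]
    calls = [
        VariantCall(
            locus=GenomicLocus("chr1", 100 + i, "A", "T"),
            t_ref_count=1000 - 10 * (i + 1),
            t_alt_count=10 * (i + 1),
            tumour_f=10 * (i + 1) / 1000,
            t_lod=lod,
            judgement=Judgement.KEEP,
            pop_af=p,
        )
        for i, (lod, p) in enumerate(zip(lods, pop))
    ]
    return SampleCallSet(sample_id="S1", patient_id="P1", calls=calls)
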