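import numpy as np
import pytest
from hypothesis import settings

from epiclone.panel import default_panel, small_panel
from epiclone.signature_fit import packaged_reference_signatures
from epiclone.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return packaged_reference_signatures()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def tiny_panel():
    return small_panel()


@pytest.fixture(scope="session")
def cohort11():
    """The default 11-donor cohort at the published areas and burdens."""
    return generate_cohort(CohortConfig(seed=1))


def make_record(**kw):
    """A valid SBS record with overridable fields, for hand-built tables."""
    from epiclone.core_io import MutationRecord

    base = dict(
        donor_id="D1",
        piece_id="D1_p0",
        sample_id="D1_p0_s00",
        chrom="chr1",
        pos=100,
        ref="C",
        alt="T",
        mut_class="SBS",
        consequence="missense",
        vaf=0.1,
        alt_reads=70,
        depth=700,
        gene="TP53",
        context="T[C>T]G",
        strand_class="unknown",
    )
    base.update(kw)
    if "vaf" not in kw and ("alt_reads" in kw or "depth" in kw):
        base["vaf"] = base["alt_reads"] / base["depth"]
    rec = MutationRecord(**base)
    rec.validate()
    return rec
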