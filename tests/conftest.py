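import numpy as np
import pytest

from sweepkit.regions import Feature, HaplotypeAlignment, RegionAnnotation
from sweepkit.synth import RegionFixtureSpec, generate_region_fixture


def make_alignment(seqs, outgroup=None, region_id="test"):
    return HaplotypeAlignment(
        region_id=region_id,
        sample_ids=[f"h{i}" for i in range(len(seqs))],
        sequences=list(seqs),
        outgroup_id="out" if outgroup else None,
        outgroup_sequence=outgroup,
    )


def coding_annotation(length, cds_start=0, cds_end=None, strand="+"):
    cds_end = cds_end if cds_end is not None else length
    feats = []
    if cds_start > 0:
        feats.append(Feature("flanking", 0, cds_start))
    feats.append(Feature("CDS", cds_start, cds_end, strand=strand, gene="g1"))
    if cds_end < length:
        feats.append(Feature("intergenic", cds_end, length))
    return RegionAnnotation(features=feats)


@pytest.fixture(scope="session")
def small_region():
    """One mixed coding/noncoding synthetic region with outgroup and truth."""
    spec = RegionFixtureSpec(
        region_id="tiny",
        n=10,
        layout=[
            ("flanking", 300),
            ("CDS", 150, "g1"),
            ("intron", 60),
            ("CDS", 90, "g1"),
            ("intergenic", 400),
        ],
        target_silent_pi=0.008,
        target_silent_K=0.08,
        constraint=0.7,
    )
    return generate_region_fixture(spec, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
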