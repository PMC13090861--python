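import numpy as np
import pytest

from tumorhet import CloneCluster, LocusObservation, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_cluster(label, cps, vafs=None):
    """Build a CloneCluster from explicit CP (and optional VAF) values."""
    cps = list(cps)
    if vafs is None:
        vafs = [c / 2 for c in cps]
    return CloneCluster(
        label=str(label),
        members=[
            LocusObservation(
                mutation_id=f"{label}_{i}", cellular_prevalence=float(c), vaf=float(v)
            )
            for i, (c, v) in enumerate(zip(cps, vafs))
        ],
    )


def make_variant(
    sample_id="s1",
    vaf=None,
    depth=100,
    alt_count=20,
    effect_class="nonsilent",
    caller_evidence=None,
    **kwargs,
):
    if caller_evidence is None:
        caller_evidence = {"mutect": "KEEP", "strelka": "PASS"}
    return VariantRecord(
        sample_id=sample_id,
        chrom=kwargs.pop("chrom", "1"),
        pos=kwargs.pop("pos", 12345),
        ref=kwargs.pop("ref", "A"),
        alt=kwargs.pop("alt", "T"),
        effect_class=effect_class,
        caller_evidence=caller_evidence,
        depth=depth,
        alt_count=alt_count,
        vaf=vaf,
        **kwargs,
    )
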