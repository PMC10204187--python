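import numpy as np
import pytest

from orthomut.align import ScoringParams, align_global, map_to_reference
from orthomut.io import SequenceRecord
from orthomut.profile import ReferenceAnnotation, build_profile
from orthomut.simulate import default_annotation, make_benchmark_family


@pytest.fixture(scope="session")
def annotation():
    """Annotation of the synthetic 321-residue reference."""
    return default_annotation()


@pytest.fixture(scope="session")
def toy_annotation():
    """A 2-residue reference ('MK') for hand-enumerable profiles."""
    return ReferenceAnnotation(
        reference=SequenceRecord(id="toy_ref", residues="MK"),
        focal_position=1,
    )


@pytest.fixture(scope="session")
def benchmark(annotation):
    """A small benchmark family with its profile (one seed, n=300)."""
    records, truth = make_benchmark_family(annotation, seed=7, n_sequences=300)
    params = ScoringParams()
    alignments = {
        r.id: align_global(annotation.reference, r, params) for r in records
    }
    maps = [map_to_reference(a) for a in alignments.values()]
    profile = build_profile(annotation, maps)
    return {
        "records": records,
        "truth": truth,
        "alignments": alignments,
        "maps": maps,
        "profile": profile,
    }
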