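import numpy as np
import pytest

from crpmap.core_sequence import load_mature_sequence, tile_sequence
from crpmap.epitope_caller import (
    call_positive_tiles,
    call_subject_epitopes,
    harmonize_cohort,
)
from crpmap.synthetic_data import fixture_cohort


@pytest.fixture(scope="session")
def crp_seq():
    return load_mature_sequence("CRP")


@pytest.fixture(scope="session")
def crp_tiles(crp_seq):
    return tile_sequence(crp_seq)


@pytest.fixture(scope="session")
def fixture_pipeline(crp_seq, crp_tiles):
    """Run the frozen fixture cohort through the whole calling pipeline."""
    samples, records, truth = fixture_cohort()
    calls_by, groups = {}, {}
    for s in samples:
        positives = call_positive_tiles(s)
        calls_by[s.subject_id] = call_subject_epitopes(
            positives, crp_tiles, crp_seq, intensities=s.intensities
        )
        groups[s.subject_id] = s.group
    epitopes, matrix = harmonize_cohort(calls_by, crp_seq, groups)
    return {
        "samples": samples,
        "records": records,
        "truth": truth,
        "calls": calls_by,
        "epitopes": epitopes,
        "matrix": matrix,
    }


def tiles_containing(tiles, span):
    """Indices of tiles whose mature span fully contains ``span``."""
    s, e = span
    return [
        t.index
        for t in tiles
        if t.mature_span and t.mature_span[0] <= s and t.mature_span[1] >= e
    ]


def positives_for(tiles, spans):
    """Boolean positivity vector flagging exactly the tiles containing a span."""
    pos = np.zeros(len(tiles), dtype=bool)
    for span in spans:
        for i in tiles_containing(tiles, span):
            pos[i] = True
    return pos
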