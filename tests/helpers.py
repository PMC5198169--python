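"""Shared builders for hand-constructed segments and assignments."""

import numpy as np

from blsomhgt.composition import Segment
from blsomhgt.pipeline import SegmentAssignment, Territory


def seg(contig="c1", start=0, comp=None):
    comp = np.asarray(comp, dtype=float) if comp is not None else None
    return Segment(contig_id=contig, start=start, end=start + 5000,
                   n_count=0, composition=comp, omitted=False)


def make_assignment(contig, candidate, phylum=None, genus=None, start=0):
    return SegmentAssignment(
        segment=seg(contig, start),
        node=(0, 0),
        territory=Territory.PROKARYOTE if candidate else Territory.HOST,
        is_hgt_candidate=candidate,
        phylum=phylum,
        genus=genus,
    )
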