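"""Small builders shared across test modules."""

import numpy as np

from bivdom import GenomicInterval, RegionSet, TagCollection


def make_tags(positions, strands=None, chrom="chrT"):
    pos = np.asarray(positions, dtype=np.int64)
    strand = np.asarray(strands if strands is not None else ["+"] * len(pos))
    return TagCollection.from_arrays({chrom: (pos, strand)})


def make_regions(triples, label="regions", layout=None):
    return RegionSet([GenomicInterval(c, s, e) for c, s, e in triples],
                     label=label, layout=layout)
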