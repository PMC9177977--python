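"""Hand-constructed annotation/track builders shared across test modules."""

import numpy as np

from acylstall import ribo
from acylstall.ribo import ORF, GenomeAnnotation


def uniform_annotation_and_track(orf_lens_bp, reads_per_pos):
    """Contig with consecutive plus-strand ORFs and a hand-built density track
    where ORF i carries ``reads_per_pos[i]`` counts at every position."""
    spacer = 60
    seq_parts, orfs = [], []
    pos = 0
    for i, length in enumerate(orf_lens_bp):
        seq_parts.append("C" * spacer)
        pos += spacer
        body = "ATG" + "GGC" * (length // 3 - 2) + "TAA"
        seq_parts.append(body)
        orfs.append(ORF(f"o{i}", "chr1", pos, pos + length, "+"))
        pos += length
    seq_parts.append("C" * spacer)
    contig = "".join(seq_parts)
    ann = GenomeAnnotation({"chr1": contig}, orfs)
    counts = np.zeros(len(contig), dtype=np.int64)
    for orf, r in zip(orfs, reads_per_pos):
        counts[orf.start : orf.end] = r
    total = int(counts.sum()) or 1
    track = ribo.DensityTrack(
        {("chr1", "+"): counts, ("chr1", "-"): np.zeros_like(counts)}, total
    )
    return ann, track
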