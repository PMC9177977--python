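"""Codon-resolution ribosome pause statistics from aligned footprints.

The pipeline starts from alignments (SAM/BAM), a genome (FASTA) and an ORF
annotation (GFF3 or BED).  Footprint positions are summarised by their 3' end
— for MNase-generated bacterial footprints the 3' boundary is the
better-defined one — and converted to a reads-per-million density track.  Per
ORF, densities are normalised by the ORF's own mean to give pause scores (PS);
the first 15 and last 7 codons are excluded throughout because initiation- and
termination-proximal densities are systematically biased.  The distance from a
footprint 3' end back to the first nucleotide of the A-site codon (a negative
offset, typically around -11 nt) is calibrated from the stop-codon metagene:
terminating ribosomes hold the stop codon in the A site and leave a density
peak a fixed distance downstream of it.  Mean pause scores (MPS) per codon in
the A, P and E sites then localise stalls: a codon whose cognate
aminoacyl-tRNA has been depleted (e.g. acetylated by a GNAT toxin) shows an
A-site-specific MPS elevation.

Coordinates are 0-based half-open internally; GFF3 input is interpreted as
1-based inclusive, BED as 0-based half-open; human-readable outputs are
1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ORF",
    "GenomeAnnotation",
    "Alignments",
    "DensityTrack",
    "OffsetCalibration",
    "CalibrationError",
    "SITE_SHIFT",
    "load_alignments",
    "density_track",
    "orf_profile",
    "filter_orfs",
    "pause_scores",
    "pause_score_table",
    "calibrate_asite_offset",
    "codon_mps",
    "mps_matrix",
    "amino_acid_mps",
    "bin_profile",
    "mps_contrast",
    "run_pipeline",
]

TRIM5_CODONS = 15
TRIM3_CODONS = 7

#: Transcript-coordinate shift from the A-site codon to the codon occupying
#: each ribosomal site: the P-site codon sits 3 nt upstream of the A-site
#: codon and the E-site codon 6 nt upstream.
SITE_SHIFT = {"A": 0, "P": 3, "E": 6}

STOP_CODONS = {"TAA", "TAG", "TGA"}


class CalibrationError(RuntimeError):
    """A-site offset calibration found no unambiguous stop-codon peak."""


@dataclass(frozen=True)
class ORF:
    """A protein-coding region; ``start``/``end`` are 0-based half-open
    genomic coordinates regardless of strand."""

    orf_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.orf_id}: end must exceed start")
        if (self.end - self.start) % 3:
            raise ValueError(f"{self.orf_id}: length not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, contigs: dict[str, str]) -> str:
        seq = contigs[self.contig][self.start : self.end]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


@dataclass
class GenomeAnnotation:
    """Contig sequences plus the ORF catalogue."""

    contigs: dict[str, str]
    orfs: list[ORF]

    def __post_init__(self) -> None:
        for orf in self.orfs:
            if orf.contig not in self.contigs:
                raise ValueError(f"{orf.orf_id}: unknown contig {orf.contig}")
            if orf.end > len(self.contigs[orf.contig]):
                raise ValueError(f"{orf.orf_id}: extends past contig end")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def validate_orfs(self) -> None:
        """Check every ORF starts with a start codon and ends with a stop."""
        for orf in self.orfs:
            seq = orf.sequence(self.contigs)
            if seq[:3] not in {"ATG", "GTG", "TTG"}:
                raise ValueError(f"{orf.orf_id}: no start codon ({seq[:3]})")
            if seq[-3:] not in STOP_CODONS:
                raise ValueError(f"{orf.orf_id}: no stop codon ({seq[-3:]})")

    @classmethod
    def from_files(cls, fasta, annotation, fmt: str | None = None) -> "GenomeAnnotation":
        """Load from a FASTA plus a GFF3 (CDS features, 1-based inclusive) or
        BED (0-based half-open) annotation; ``fmt`` is inferred from the file
        suffix when omitted."""
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        annotation = Path(annotation)
        if fmt is None:
            fmt = "bed" if annotation.suffix.lower() == ".bed" else "gff3"
        orfs = _read_gff3(annotation) if fmt == "gff3" else _read_bed(annotation)
        return cls(contigs, orfs)


def _read_gff3(path: Path) -> list[ORF]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    orfs = []
    for feat in db.features_of_type("CDS", order_by="start"):
        name = feat.attributes.get("ID", [feat.id or f"cds_{feat.start}"])[0]
        orfs.append(ORF(name, feat.seqid, feat.start - 1, feat.end, feat.strand))
    if not orfs:
        raise ValueError(f"{path}: no CDS features found")
    return orfs


def _read_bed(path: Path) -> list[ORF]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED needs at least 6 columns (strand required)")
    return [
        ORF(str(r[3]), str(r[0]), int(r[1]), int(r[2]), str(r[5]))
        for r in df.itertuples(index=False)
    ]


@dataclass
class Alignments:
    """Filtered footprint alignments in column form.

    ``contig`` holds indices into ``contig_names``; ``is_reverse`` marks minus
    strand reads; ``pos3`` is the 0-based genomic coordinate of the 3' end
    (rightmost aligned base for plus strand, leftmost for minus strand).
    """

    contig_names: list[str]
    contig: np.ndarray
    is_reverse: np.ndarray
    pos3: np.ndarray
    length: np.ndarray

    def __len__(self) -> int:
        return self.pos3.size


def load_alignments(
    path,
    min_len: int = 15,
    max_len: int = 40,
    unique_only: bool = True,
    min_mapq: int = 10,
) -> Alignments:
    """Read SAM/BAM and keep uniquely mapped footprints of 15-40 nt.

    Reads outside ``[min_len, max_len]`` are discarded.  "Unique" means
    primary, non-supplementary, and MAPQ >= ``min_mapq`` — an
    alignment-tool-agnostic proxy for single-hit mapping.
    """
    contigs: list[str] = []
    index: dict[str, int] = {}
    cols: list[tuple[int, bool, int, int]] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), require_index=False) as handle:
            for read in handle.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if unique_only and read.mapping_quality < min_mapq:
                    continue
                rlen = read.query_length or read.infer_query_length() or 0
                if not (min_len <= rlen <= max_len):
                    continue
                name = read.reference_name
                if name not in index:
                    index[name] = len(contigs)
                    contigs.append(name)
                pos3 = read.reference_start if read.is_reverse else read.reference_end - 1
                cols.append((index[name], read.is_reverse, pos3, rlen))
    finally:
        pysam.set_verbosity(save)
    if not cols:
        return Alignments(contigs, np.empty(0, int), np.empty(0, bool),
                          np.empty(0, int), np.empty(0, int))
    arr = np.array(cols, dtype=np.int64)
    return Alignments(
        contigs, arr[:, 0], arr[:, 1].astype(bool), arr[:, 2], arr[:, 3]
    )


@dataclass
class DensityTrack:
    """Per-contig, per-strand 3'-end counts with RPM normalisation."""

    counts: dict[tuple[str, str], np.ndarray]
    total_unique: int

    def rpm(self, contig: str, strand: str) -> np.ndarray:
        return self.counts[(contig, strand)] * (1e6 / self.total_unique)

    @property
    def total_positions(self) -> int:
        return sum(v.size for v in self.counts.values())

    def to_bedgraph(self, strand: str, path) -> None:
        """Write the RPM track of one strand as bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for (contig, s), _ in sorted(self.counts.items()):
                if s != strand:
                    continue
                track = self.rpm(contig, s)
                nz = np.flatnonzero(track)
                for i in nz:
                    fh.write(f"{contig}\t{i}\t{i + 1}\t{track[i]:.6g}\n")


def density_track(
    alignments: Alignments, contig_lengths: dict[str, int]
) -> DensityTrack:
    """Count footprint 3' ends per genomic position and normalise to RPM
    (reads per million uniquely mapped footprints), strand-specifically."""
    if len(alignments) == 0:
        raise ValueError("no alignments to build a density track from")
    counts: dict[tuple[str, str], np.ndarray] = {
        (name, strand): np.zeros(length, dtype=np.int64)
        for name, length in contig_lengths.items()
        for strand in "+-"
    }
    for ci, name in enumerate(alignments.contig_names):
        if name not in contig_lengths:
            raise ValueError(f"alignment contig {name!r} absent from annotation")
        mask_c = alignments.contig == ci
        for strand, rev in (("+", False), ("-", True)):
            pos = alignments.pos3[mask_c & (alignments.is_reverse == rev)]
            if pos.size:
                counts[(name, strand)] += np.bincount(
                    pos, minlength=contig_lengths[name]
                )
    return DensityTrack(counts, total_unique=len(alignments))


def orf_profile(track: DensityTrack, orf: ORF) -> np.ndarray:
    """Per-nucleotide RPM density over the ORF in transcription order."""
    dens = track.rpm(orf.contig, orf.strand)[orf.start : orf.end]
    return dens[::-1].copy() if orf.strand == "-" else dens


def _trim_slice(length: int, trim5: int = TRIM5_CODONS, trim3: int = TRIM3_CODONS):
    return slice(3 * trim5, length - 3 * trim3)


def trimmed_mean_density(
    track: DensityTrack, orf: ORF, trim5: int = TRIM5_CODONS, trim3: int = TRIM3_CODONS
) -> float:
    """Mean per-nucleotide RPM over the trimmed region of the ORF."""
    prof = orf_profile(track, orf)
    region = prof[_trim_slice(orf.length, trim5, trim3)]
    if region.size == 0:
        return 0.0
    return float(region.mean())


def filter_orfs(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    min_len_bp: int = 170,
    min_mean_density_per_codon: float = 1.0,
    trim5: int = TRIM5_CODONS,
    trim3: int = TRIM3_CODONS,
) -> list[ORF]:
    """Retain ORFs of at least ``min_len_bp`` with trimmed-region mean density
    of at least ``min_mean_density_per_codon`` (RPM per codon); an ORF failing
    either criterion is discarded."""
    retained = []
    for orf in annotation.orfs:
        if orf.length < min_len_bp:
            continue
        if orf.length <= 3 * (trim5 + trim3):
            continue
        if 3.0 * trimmed_mean_density(track, orf, trim5, trim3) < min_mean_density_per_codon:
            continue
        retained.append(orf)
    return retained


def pause_scores(
    track: DensityTrack, orf: ORF, trim5: int = TRIM5_CODONS, trim3: int = TRIM3_CODONS
) -> np.ndarray:
    """Per-nucleotide pause score over the ORF (transcription order).

    PS = density / mean density of the ORF's trimmed region; positions inside
    the trimmed-off start/stop margins are NaN.  The trimmed-region mean of
    the returned PS is exactly 1.
    """
    prof = orf_profile(track, orf)
    sl = _trim_slice(orf.length, trim5, trim3)
    mean = prof[sl].mean() if prof[sl].size else 0.0
    if mean <= 0:
        raise ValueError(f"{orf.orf_id}: zero mean density; filter ORFs first")
    ps = np.full(orf.length, np.nan)
    ps[sl] = prof[sl] / mean
    return ps


def pause_score_table(
    annotation: GenomeAnnotation, track: DensityTrack, orfs: list[ORF],
    trim5: int = TRIM5_CODONS, trim3: int = TRIM3_CODONS,
) -> pd.DataFrame:
    """Long-format PS table: ``orf_id, position_1based, codon, PS`` (positions
    are 1-based within the ORF in transcription order; trimmed region only)."""
    rows = []
    for orf in orfs:
        ps = pause_scores(track, orf, trim5, trim3)
        seq = orf.sequence(annotation.contigs)
        for i in np.flatnonzero(~np.isnan(ps)):
            codon = seq[3 * (i // 3) : 3 * (i // 3) + 3]
            rows.append((orf.orf_id, int(i) + 1, codon, ps[i]))
    return pd.DataFrame(rows, columns=["orf_id", "position_1based", "codon", "PS"])


@dataclass
class OffsetCalibration:
    """Calibrated 3'-end -> A-site offset plus diagnostic metagenes.

    ``offset`` is negative: the first nucleotide of the A-site codon lies
    ``-offset`` nt upstream of the footprint 3' end in transcription
    coordinates.
    """

    offset: int
    stop_metagene: pd.DataFrame = field(repr=False)
    start_metagene: pd.DataFrame = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "offset": int(self.offset),
            "stop_metagene": self.stop_metagene.to_dict(orient="list"),
            "start_metagene": self.start_metagene.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _metagene(track, orfs, anchor: str, rel_range: tuple[int, int]) -> pd.DataFrame:
    """Average ORF-mean-normalised 3'-end density around an anchor codon.

    ``rel_range`` is inclusive, in transcription coordinates relative to the
    first nucleotide of the start codon (``anchor="start"``) or of the stop
    codon (``anchor="stop"``).  Positions beyond the contig are skipped.
    """
    lo, hi = rel_range
    xs = np.arange(lo, hi + 1)
    acc = np.zeros(xs.size)
    norm = np.zeros(xs.size)
    for orf in orfs:
        mean = trimmed_mean_density(track, orf)
        if mean <= 0:
            continue
        dens = track.rpm(orf.contig, orf.strand)
        clen = dens.size
        anchor_t = 0 if anchor == "start" else orf.length - 3
        for j, x in enumerate(xs):
            t = anchor_t + x
            if orf.strand == "+":
                g = orf.start + t
            else:
                g = orf.end - 1 - t
            if 0 <= g < clen:
                acc[j] += dens[g] / mean
                norm[j] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(norm > 0, acc / np.maximum(norm, 1), np.nan)
    return pd.DataFrame({"rel_pos": xs, "mean_norm_density": profile})


def calibrate_asite_offset(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    orfs: list[ORF],
    search_range: tuple[int, int] = (-20, -6),
    min_orfs: int = 50,
    min_peak_prominence: float = 2.0,
) -> OffsetCalibration:
    """Infer the 3'-end -> A-site offset from the stop-codon metagene.

    Terminating ribosomes hold the stop codon in the A site, so the stop-
    aligned metagene of (ORF-mean-normalised) 3'-end density shows a peak at
    distance ``-offset`` downstream of the stop codon's first nucleotide.  The
    returned offset is the candidate in ``search_range`` under that peak; the
    peak must exceed ``min_peak_prominence`` times the median of the searched
    window, otherwise :class:`CalibrationError` is raised (pass an explicit
    offset downstream instead).  Ties resolve to the most-3' offset (closest
    to the read 3' end).  The start-aligned metagene is kept as a diagnostic.
    """
    if len(orfs) < min_orfs:
        raise CalibrationError(
            f"only {len(orfs)} retained ORFs (< {min_orfs}); not enough for a metagene"
        )
    lo, hi = search_range
    if not (-30 <= lo < hi <= -1):
        raise ValueError("search_range must be negative offsets, e.g. (-20, -6)")
    stop_meta = _metagene(track, orfs, "stop", (-hi - 6, -lo + 6))
    start_meta = _metagene(track, orfs, "start", (-5, -lo + 15))
    window = stop_meta[
        (stop_meta.rel_pos >= -hi) & (stop_meta.rel_pos <= -lo)
    ].dropna()
    if window.empty:
        raise CalibrationError("stop metagene window is empty")
    values = window.mean_norm_density.to_numpy()
    rel = window.rel_pos.to_numpy()
    peak_idx = int(np.argmax(values))  # first max = smallest rel_pos = most-3' offset
    peak = float(values[peak_idx])
    # Compare against the strongest competitor more than 1 nt away: 3'-end
    # density is 3-nt phased, so the relevant null is "every in-frame column
    # equally high", not a flat profile.
    competitors = values[np.abs(rel - rel[peak_idx]) > 1]
    runner_up = float(competitors.max()) if competitors.size else 0.0
    if peak <= 0 or (runner_up > 0 and peak < min_peak_prominence * runner_up):
        raise CalibrationError(
            "no unambiguous stop-codon-proximal peak in the metagene; "
            "supply the offset manually"
        )
    offset = -int(window.rel_pos.iloc[peak_idx])
    return OffsetCalibration(offset, stop_meta, start_meta)


def _per_orf_site_scores(
    ps: np.ndarray, seq: str, offset: int, site: str,
    trim5: int, trim3: int,
) -> dict[str, tuple[float, int]]:
    """Per-codon-type (sum of PS, n nucleotides) for one ORF at one site.

    For a codon starting at transcript position c, footprints decoding it in
    the queried site have 3' ends at c + shift - offset .. +2 (shift 0/3/6 for
    A/P/E).  Only windows fully inside the trimmed region count.
    """
    shift = SITE_SHIFT[site]
    length = len(seq)
    lo, hi = 3 * trim5, length - 3 * trim3
    out: dict[str, list[float]] = {}
    for c in range(0, length - 3, 3):  # exclude the stop codon
        codon = seq[c : c + 3]
        if codon in STOP_CODONS:
            continue
        w = c + shift - offset
        if w < lo or w + 3 > hi:
            continue
        vals = ps[w : w + 3]
        rec = out.setdefault(codon, [0.0, 0])
        rec[0] += float(np.nansum(vals))
        rec[1] += 3
    return {k: (v[0], v[1]) for k, v in out.items()}


def codon_mps(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    orfs: list[ORF],
    offset: int,
    site: str = "A",
    trim5: int = TRIM5_CODONS,
    trim3: int = TRIM3_CODONS,
) -> pd.DataFrame:
    """Mean pause score per codon at one ribosomal site.

    Per ORF, the PS values of all nucleotides attributed to every in-frame
    occurrence of a codon at the queried site are averaged; these per-ORF
    means are then averaged (unweighted) across all ORFs with at least one
    occurrence.  Returns ``codon, amino_acid, site, mps, n_orfs`` for the 61
    sense codons; codons observed in no ORF carry NaN.
    """
    if site not in SITE_SHIFT:
        raise ValueError(f"site must be one of {sorted(SITE_SHIFT)}, got {site!r}")
    sums: dict[str, list[float]] = {}
    for orf in orfs:
        ps = pause_scores(track, orf, trim5, trim3)
        seq = orf.sequence(annotation.contigs)
        per = _per_orf_site_scores(ps, seq, offset, site, trim5, trim3)
        for codon, (total, n) in per.items():
            rec = sums.setdefault(codon, [0.0, 0])
            rec[0] += total / n
            rec[1] += 1
    rows = []
    for codon in sorted(_sense_codons()):
        aa = str(Seq(codon).translate())
        if codon in sums:
            total, n_orfs = sums[codon]
            rows.append((codon, aa, site, total / n_orfs, n_orfs))
        else:
            rows.append((codon, aa, site, np.nan, 0))
    return pd.DataFrame(rows, columns=["codon", "amino_acid", "site", "mps", "n_orfs"])


def _sense_codons() -> list[str]:
    return [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]


def mps_matrix(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    orfs: list[ORF],
    offset: int,
    **kwargs,
) -> pd.DataFrame:
    """Codon x {A, P, E} MPS matrix (long format concatenation of
    :func:`codon_mps` over the three sites)."""
    return pd.concat(
        [codon_mps(annotation, track, orfs, offset, site, **kwargs) for site in "APE"],
        ignore_index=True,
    )


def amino_acid_mps(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    orfs: list[ORF],
    offset: int,
    site: str = "A",
    trim5: int = TRIM5_CODONS,
    trim3: int = TRIM3_CODONS,
) -> pd.DataFrame:
    """MPS aggregated to amino acids: codons are pooled by translation within
    each ORF before the per-ORF average, then averaged across ORFs."""
    if site not in SITE_SHIFT:
        raise ValueError(f"site must be one of {sorted(SITE_SHIFT)}")
    sums: dict[str, list[float]] = {}
    for orf in orfs:
        ps = pause_scores(track, orf, trim5, trim3)
        seq = orf.sequence(annotation.contigs)
        per = _per_orf_site_scores(ps, seq, offset, site, trim5, trim3)
        by_aa: dict[str, list[float]] = {}
        for codon, (total, n) in per.items():
            aa = str(Seq(codon).translate())
            rec = by_aa.setdefault(aa, [0.0, 0])
            rec[0] += total
            rec[1] += n
        for aa, (total, n) in by_aa.items():
            rec = sums.setdefault(aa, [0.0, 0])
            rec[0] += total / n
            rec[1] += 1
    rows = [
        (aa, site, total / n, n) for aa, (total, n) in sorted(sums.items())
    ]
    return pd.DataFrame(rows, columns=["amino_acid", "site", "mps", "n_orfs"])


def bin_profile(
    annotation: GenomeAnnotation,
    track: DensityTrack,
    orfs: list[ORF],
    n_bins: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Decile occupancy profile: per ORF, codons are split 5'->3' into
    ``n_bins`` contiguous near-equal bins (earlier bins take the remainder),
    footprint counts per bin are converted to fractions (with a per-bin
    pseudocount so the cross-ORF geometric mean is defined for empty bins).

    Returns ``bin (1-based), geo_mean_fraction, n_orfs``.
    """
    from scipy.stats import gmean

    fracs = []
    for orf in orfs:
        n_codons = orf.length // 3
        if n_codons < n_bins:
            raise ValueError(f"{orf.orf_id}: fewer codons than bins")
        prof = orf_profile(track, orf)
        per_codon = prof[: 3 * n_codons].reshape(n_codons, 3).sum(axis=1)
        base, rem = divmod(n_codons, n_bins)
        sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
        edges = np.cumsum([0] + sizes)
        binned = np.add.reduceat(per_codon, edges[:-1]) + pseudocount
        fracs.append(binned / binned.sum())
    mat = np.array(fracs)
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "geo_mean_fraction": gmean(mat, axis=0),
            "n_orfs": len(orfs),
        }
    )


def mps_contrast(toxin: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Join toxin and control MPS tables and add the toxin/control ratio.

    Cells missing (NaN) in either input propagate as missing ratios; the two
    tables must share at least one (codon, site) pair.
    """
    keys = [c for c in ("codon", "amino_acid", "site") if c in toxin.columns and c in control.columns]
    if not keys:
        raise ValueError("tables share no join keys")
    merged = toxin.merge(
        control, on=keys, suffixes=("_toxin", "_control"), how="inner"
    )
    if merged.empty:
        raise ValueError("disjoint codon sets")
    merged["ratio"] = merged["mps_toxin"] / merged["mps_control"]
    merged.loc[~np.isfinite(merged["ratio"]), "ratio"] = np.nan
    return merged


def run_pipeline(
    bam,
    genome_fasta,
    annotation_file,
    out_dir,
    offset: int | str = "auto",
    min_orf_len: int = 170,
    min_density: float = 1.0,
    trim5: int = TRIM5_CODONS,
    trim3: int = TRIM3_CODONS,
    min_len: int = 15,
    max_len: int = 40,
) -> dict:
    """End-to-end run: alignments -> density -> filters -> calibration ->
    PS / MPS / bin profile, with tabular outputs written to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = GenomeAnnotation.from_files(genome_fasta, annotation_file)
    aln = load_alignments(bam, min_len=min_len, max_len=max_len)
    track = density_track(aln, annotation.contig_lengths)
    retained = filter_orfs(
        annotation, track, min_orf_len, min_density, trim5, trim3
    )
    if offset == "auto":
        calibration = calibrate_asite_offset(annotation, track, retained)
        offset_val = calibration.offset
        calibration.to_json(out / "calibration.json")
    else:
        offset_val = int(offset)
    track.to_bedgraph("+", out / "density_plus.bedgraph")
    track.to_bedgraph("-", out / "density_minus.bedgraph")
    ps_table = pause_score_table(annotation, track, retained, trim5, trim3)
    ps_table.to_csv(out / "pause_scores.tsv", sep="\t", index=False)
    mps = mps_matrix(annotation, track, retained, offset_val, trim5=trim5, trim3=trim3)
    mps.to_csv(out / "mps.tsv", sep="\t", index=False)
    bins = bin_profile(annotation, track, retained)
    bins.to_csv(out / "bin_profile.tsv", sep="\t", index=False)
    return {
        "n_alignments": len(aln),
        "n_retained_orfs": len(retained),
        "offset": offset_val,
        "mps": mps,
        "bin_profile": bins,
    }
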