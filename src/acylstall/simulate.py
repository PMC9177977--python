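"""Ground-truthed synthetic inputs for both quantification engines.

Two generators:

* a toy genome + ribosome-footprint library in which per-codon dwell times are
  known exactly — including an elevated dwell ("stall factor") at chosen
  codons whenever they occupy the ribosomal A site, a termination pause at the
  stop codon, and a fixed (or distributed) 3'-end offset — so that the pause
  pipeline's calibration, MPS ranking and null behaviour can be checked
  against the simulated truth;

* LC/MS peak-area tables and extracted-ion chromatograms whose underlying
  acetylated fractions and relative response factors are specified, with
  log-normal multiplicative area noise and EMG peak rendering (including
  co-eluting pairs that exercise the deconvolution path).

All randomness flows from a single integer seed per spec; identical specs
reproduce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .lcms import Chromatogram, EMGPeak, emg_profile
from .ribo import ORF, Alignments, GenomeAnnotation

__all__ = [
    "RiboSimSpec",
    "LCMSSimSpec",
    "gen_genome",
    "simulate_footprints",
    "write_sam",
    "simulate_ribo_files",
    "simulate_lcms",
    "render_coeluting_pair",
    "SENSE_CODONS",
]

_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS: list[str] = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class RiboSimSpec:
    """Study conditions for the footprint simulator.

    ``orf_len_codons`` counts every codon including start and stop.  ``stalls``
    maps sense codons to dwell multipliers applied when the codon is in the A
    site; ``stop_dwell`` models the termination pause that makes the stop-
    codon metagene peak (and hence offset calibration) possible.  ``offset``
    is the signed distance from the first A-site nucleotide to the footprint
    3' end (negative: A site upstream of the 3' end); a dict maps offsets to
    probabilities for a distributed offset.  Expression weights across ORFs
    are log-normal with coefficient of variation ``expression_cv`` so the
    density filter sees realistic depth heterogeneity.
    """

    seed: int
    n_orfs: int = 100
    orf_len_codons: int = 200
    codon_weights: dict[str, float] | None = None
    stalls: dict[str, float] = field(default_factory=dict)
    offset: int | dict[int, float] = -11
    depth: int = 1_000_000
    read_len_range: tuple[int, int] = (24, 32)
    expression_cv: float = 1.0
    stop_dwell: float = 5.0
    frac_minus: float = 0.5
    spacer: int = 60
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for codon, mult in self.stalls.items():
            if codon not in SENSE_CODONS:
                raise ValueError(f"stall codon {codon!r} is not a sense codon")
            if mult < 1:
                raise ValueError("dwell multipliers must be >= 1")
        for off in self._offsets()[0]:
            if not (-20 <= off <= -6):
                raise ValueError(f"offset {off} outside [-20, -6]")
        lo, hi = self.read_len_range
        if not (15 <= lo <= hi <= 40):
            raise ValueError("read lengths must lie within 15-40 nt")

    def _offsets(self) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(self.offset, dict):
            offs = np.array(sorted(self.offset), dtype=int)
            probs = np.array([self.offset[o] for o in offs], dtype=float)
            return offs, probs / probs.sum()
        return np.array([int(self.offset)]), np.array([1.0])


def _codon_probs(spec: RiboSimSpec) -> np.ndarray:
    if spec.codon_weights is None:
        w = np.ones(len(SENSE_CODONS))
    else:
        w = np.array([spec.codon_weights.get(c, 0.0) for c in SENSE_CODONS])
    if w.sum() <= 0:
        raise ValueError("codon usage weights sum to zero")
    return w / w.sum()


def gen_genome(spec: RiboSimSpec) -> tuple[GenomeAnnotation, dict]:
    """Build a single-contig toy genome with non-overlapping ORFs.

    Each ORF is ATG + (len-2) sense codons drawn from the usage weights + TAA,
    placed on either strand with random intergenic spacers; the annotation is
    returned in memory together with a ground-truth record.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    probs = _codon_probs(spec)
    parts: list[str] = []
    orfs: list[ORF] = []
    truth_orfs = {}
    pos = 0
    for i in range(spec.n_orfs):
        spacer = "".join(rng.choice(list("ACGT"), size=spec.spacer))
        parts.append(spacer)
        pos += len(spacer)
        n_body = spec.orf_len_codons - 2
        body = "".join(rng.choice(SENSE_CODONS, size=n_body, p=probs))
        orf_seq = "ATG" + body + "TAA"
        strand = "-" if rng.random() < spec.frac_minus else "+"
        placed = orf_seq if strand == "+" else _revcomp(orf_seq)
        parts.append(placed)
        orf_id = f"orf{i + 1:04d}"
        orfs.append(
            ORF(orf_id, spec.contig_name, pos, pos + len(orf_seq), strand)
        )
        truth_orfs[orf_id] = {"strand": strand, "start": pos, "length": len(orf_seq)}
        pos += len(orf_seq)
    tail = "".join(rng.choice(list("ACGT"), size=spec.spacer))
    parts.append(tail)
    genome = GenomeAnnotation({spec.contig_name: "".join(parts)}, orfs)
    truth = {"spec": _spec_dict(spec), "orfs": truth_orfs}
    return genome, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_footprints(
    genome: GenomeAnnotation, spec: RiboSimSpec
) -> tuple[Alignments, dict]:
    """Sample footprints with known per-codon dwell times.

    A read is placed by drawing an ORF proportionally to its expression
    weight, then a ribosome position along it proportionally to per-codon
    dwell (stall multipliers apply to A-site codons in ``spec.stalls``; the
    stop codon dwell is ``spec.stop_dwell``), then setting the 3' end to
    ``first A-site nucleotide - offset`` with a read length drawn uniformly
    from ``read_len_range``.  Returns in-memory alignments plus the realized
    ground truth (per-ORF read counts and expression weights).
    """
    rng = np.random.default_rng([int(spec.seed), 1])
    orfs = genome.orfs
    sigma = np.sqrt(np.log1p(spec.expression_cv**2))
    expr = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(orfs))
    p_orf = expr / expr.sum()
    per_orf_reads = rng.multinomial(spec.depth, p_orf)

    offs, off_probs = spec._offsets()
    lo_len, hi_len = spec.read_len_range
    contig_len = {k: len(v) for k, v in genome.contigs.items()}

    all_pos3 = []
    all_len = []
    all_rev = []
    all_contig = []
    contig_names = list(genome.contigs)
    contig_idx = {name: i for i, name in enumerate(contig_names)}
    realized = {}
    for orf, n_reads in zip(orfs, per_orf_reads):
        realized[orf.orf_id] = int(n_reads)
        if n_reads == 0:
            continue
        seq = orf.sequence(genome.contigs)
        n_codons = orf.length // 3
        # A-site codon indices 1 .. n_codons-1 (start codon begins in the P site)
        ks = np.arange(1, n_codons)
        dwell = np.ones(ks.size)
        for j, k in enumerate(ks):
            codon = seq[3 * k : 3 * k + 3]
            if codon in _STOPS:
                dwell[j] = spec.stop_dwell
            else:
                dwell[j] = spec.stalls.get(codon, 1.0)
        counts = rng.multinomial(n_reads, dwell / dwell.sum())
        k_arr = np.repeat(ks, counts)
        offsets = offs[rng.choice(offs.size, size=k_arr.size, p=off_probs)]
        p3_t = 3 * k_arr - offsets
        lens = rng.integers(lo_len, hi_len + 1, size=k_arr.size)
        if orf.strand == "+":
            g3 = orf.start + p3_t
            g_start = g3 - lens + 1
            g_end = g3 + 1
        else:
            g3 = orf.end - 1 - p3_t
            g_start = g3
            g_end = g3 + lens
        ok = (g_start >= 0) & (g_end <= contig_len[orf.contig])
        all_pos3.append(g3[ok])
        all_len.append(lens[ok])
        all_rev.append(np.full(ok.sum(), orf.strand == "-"))
        all_contig.append(np.full(ok.sum(), contig_idx[orf.contig]))

    if not all_pos3:
        raise ValueError("no reads generated (depth 0 after placement?)")
    aln = Alignments(
        contig_names,
        np.concatenate(all_contig).astype(np.int64),
        np.concatenate(all_rev).astype(bool),
        np.concatenate(all_pos3).astype(np.int64),
        np.concatenate(all_len).astype(np.int64),
    )
    truth = {
        "spec": _spec_dict(spec),
        "per_orf_reads": realized,
        "expression_weights": {o.orf_id: float(w) for o, w in zip(orfs, expr)},
        "n_reads": int(len(aln)),
    }
    return aln, truth


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
        if isinstance(val, dict):
            d[key] = {str(k): v for k, v in val.items()}
    return d


def write_sam(
    alignments: Alignments, genome: GenomeAnnotation, path, as_bam: bool = False
) -> None:
    """Write alignments as coordinate-sorted SAM (or BAM) with read sequences
    taken from the genome (forward-strand orientation, per SAM convention)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()
        ],
    }
    starts = np.where(
        alignments.is_reverse,
        alignments.pos3,
        alignments.pos3 - alignments.length + 1,
    )
    order = np.lexsort((starts, alignments.contig))
    mode = "wb" if as_bam else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        ref_ids = {name: i for i, name in enumerate(out.header.references)}
        for n, i in enumerate(order):
            a = pysam.AlignedSegment(out.header)
            name = alignments.contig_names[alignments.contig[i]]
            start = int(starts[i])
            length = int(alignments.length[i])
            a.query_name = f"read{n:08d}"
            a.reference_id = ref_ids[name]
            a.reference_start = start
            a.flag = 16 if alignments.is_reverse[i] else 0
            a.mapping_quality = 42
            a.cigarstring = f"{length}M"
            a.query_sequence = genome.contigs[name][start : start + length]
            out.write(a)


def simulate_ribo_files(spec: RiboSimSpec, out_dir) -> dict:
    """Generate FASTA + GFF3 + sorted SAM + ground_truth.json in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth_g = gen_genome(spec)
    aln, truth_r = simulate_footprints(genome, spec)
    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gff = out / "annotation.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in genome.orfs:
            fh.write(
                "\t".join(
                    [
                        orf.contig, "acylstall_sim", "CDS",
                        str(orf.start + 1), str(orf.end), ".", orf.strand, "0",
                        f"ID={orf.orf_id}",
                    ]
                )
                + "\n"
            )
    sam = out / "footprints.sam"
    write_sam(aln, genome, sam)
    truth = {"genome": truth_g, "footprints": truth_r}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {"fasta": fasta, "gff3": gff, "sam": sam, "alignments": aln,
            "genome": genome, "truth": truth}


@dataclass
class LCMSSimSpec:
    """Study conditions for the LC/MS simulator.

    ``fractions`` maps one-letter amino-acid codes to the true acetylated
    fraction f*; ``rrf_true`` gives the true Fmoc/acetyl response ratio (a
    scalar applies to every amino acid).  Areas are drawn as
    molar amount x response x log-normal noise of coefficient of variation
    ``noise_cv``; ``n_replicates`` independent measurements emulate repeated
    experiments.  The RRF calibration is itself simulated from an equimolar
    split sample with the same noise.
    """

    seed: int
    fractions: dict[str, float] = field(default_factory=lambda: {"G": 0.7})
    rrf_true: float | dict[str, float] = 2.0
    molar: float = 1000.0
    noise_cv: float = 0.05
    n_replicates: int = 3
    sigma_min: float = 0.05
    tau_min: float = 0.12
    baseline: tuple[float, float] = (20.0, 0.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        for aa, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {aa} outside [0, 1]")
        rrfs = self._rrf_map().values()
        if any(r <= 0 for r in rrfs):
            raise ValueError("true RRF must be positive")

    def _rrf_map(self) -> dict[str, float]:
        if isinstance(self.rrf_true, dict):
            return {aa: self.rrf_true.get(aa, 1.0) for aa in self.fractions}
        return {aa: float(self.rrf_true) for aa in self.fractions}


def _lognoise(rng, cv, size=None):
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_lcms(spec: LCMSSimSpec) -> dict:
    """Simulate peak-area tables and an RRF calibration with known truth.

    Returns ``areas`` (columns ``sample, species, derivative, area, area_sd``),
    ``rrf_table`` (``amino_acid, rrf, rrf_sd``) and ``truth``.
    """
    rng = np.random.default_rng([int(spec.seed), 2])
    rrf_map = spec._rrf_map()
    resp_ac = 1.0

    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for aa, f in spec.fractions.items():
            resp_fmoc = rrf_map[aa] * resp_ac
            s_ac = f * spec.molar * resp_ac * _lognoise(rng, spec.noise_cv)
            s_fm = (1 - f) * spec.molar * resp_fmoc * _lognoise(rng, spec.noise_cv)
            rows.append((f"rep{rep}", aa, "acetyl", s_ac, spec.noise_cv * s_ac))
            rows.append((f"rep{rep}", aa, "fmoc", s_fm, spec.noise_cv * s_fm))
    areas = pd.DataFrame(
        rows, columns=["sample", "species", "derivative", "area", "area_sd"]
    )

    cal_rows = []
    for aa in spec.fractions:
        resp_fmoc = rrf_map[aa] * resp_ac
        s_fm = 0.5 * spec.molar * resp_fmoc * _lognoise(rng, spec.noise_cv)
        s_ac = 0.5 * spec.molar * resp_ac * _lognoise(rng, spec.noise_cv)
        rrf = s_fm / s_ac
        rrf_sd = rrf * np.sqrt(2) * spec.noise_cv
        cal_rows.append((aa, rrf, rrf_sd))
    rrf_table = pd.DataFrame(cal_rows, columns=["amino_acid", "rrf", "rrf_sd"])

    rrf_true_table = pd.DataFrame(
        [(aa, rrf_map[aa], 0.0) for aa in spec.fractions],
        columns=["amino_acid", "rrf", "rrf_sd"],
    )
    truth = {
        "spec": _spec_dict(spec),
        "fractions": dict(spec.fractions),
        "rrf_true": rrf_map,
    }
    return {
        "areas": areas,
        "rrf_table": rrf_table,
        "rrf_true_table": rrf_true_table,
        "truth": truth,
    }


def render_coeluting_pair(
    area1: float,
    area2: float,
    mu1: float = 10.0,
    delta_mu: float = 0.1,
    sigma: float = 0.05,
    tau: float = 0.12,
    baseline: tuple[float, float] = (20.0, 0.0),
    noise_cv: float = 0.01,
    seed: int = 0,
    t_pad: float = 1.5,
    dt: float = 0.002,
) -> tuple[Chromatogram, list[EMGPeak]]:
    """Render two co-eluting EMG peaks on a shared trace (e.g. the Leu/Ile
    adenosine pair) with a linear baseline and multiplicative Gaussian noise
    of coefficient of variation ``noise_cv`` (detector noise scales with the
    local signal).  Returns the trace and the true peaks."""
    rng = np.random.default_rng([int(seed), 3])
    t = np.arange(mu1 - t_pad, mu1 + delta_mu + 3 * t_pad, dt)
    peaks = [
        EMGPeak(area1, mu1, sigma, tau),
        EMGPeak(area2, mu1 + delta_mu, sigma, tau),
    ]
    signal = baseline[0] + baseline[1] * (t - t[0])
    for pk in peaks:
        signal = signal + emg_profile(pk, t)
    noisy = signal * (1.0 + noise_cv * rng.normal(size=t.size))
    return Chromatogram(t, noisy, "coeluting-pair"), peaks
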