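"""Density tracks, ORF filtering, pause scores, calibration and MPS."""

import numpy as np
import pandas as pd
import pytest

from helpers import uniform_annotation_and_track

from acylstall import ribo
from acylstall.ribo import (
    ORF,
    Alignments,
    CalibrationError,
    GenomeAnnotation,
    bin_profile,
    calibrate_asite_offset,
    codon_mps,
    density_track,
    filter_orfs,
    load_alignments,
    mps_contrast,
    mps_matrix,
    pause_scores,
)
from acylstall.simulate import RiboSimSpec, gen_genome, simulate_footprints

SAM_TEMPLATE = """@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:400
{records}
"""


def _sam_line(name, flag, pos1, length, mapq=42):
    seq = "A" * length
    return f"{name}\t{flag}\t{chr1()}\t{pos1}\t{mapq}\t{length}M\t*\t0\t0\t{seq}\t*"


def chr1():
    return "chr1"


@pytest.fixture()
def tiny_sam(tmp_path):
    records = "\n".join(
        [
            _sam_line("fwd30", 0, 101, 30),       # spans [100,130) -> 3' end 129
            _sam_line("rev30", 16, 101, 30),      # spans [100,130) -> 3' end 100
            _sam_line("short14", 0, 151, 14),     # too short, discarded
            _sam_line("long41", 0, 151, 41),      # too long, discarded
            _sam_line("lowmapq", 0, 201, 30, 3),  # below MAPQ 10, discarded
        ]
    )
    path = tmp_path / "tiny.sam"
    path.write_text(SAM_TEMPLATE.format(records=records))
    return path


class TestLoadAlignments:
    def test_length_and_mapq_filters_and_3prime_coords(self, tiny_sam):
        aln = load_alignments(tiny_sam)
        assert len(aln) == 2
        plus = aln.pos3[~aln.is_reverse]
        minus = aln.pos3[aln.is_reverse]
        assert plus.tolist() == [129]
        assert minus.tolist() == [100]

    def test_length_window_is_inclusive(self, tmp_path):
        records = "\n".join(
            [_sam_line("len15", 0, 11, 15), _sam_line("len40", 0, 11, 40)]
        )
        path = tmp_path / "edges.sam"
        path.write_text(SAM_TEMPLATE.format(records=records))
        assert len(load_alignments(path)) == 2


class TestDensityTrack:
    def test_rpm_definition_and_count_conservation(self):
        aln = Alignments(
            ["chr1"],
            contig=np.zeros(4, int),
            is_reverse=np.zeros(4, bool),
            pos3=np.array([10, 10, 20, 30]),
            length=np.full(4, 30),
        )
        track = density_track(aln, {"chr1": 100})
        assert track.counts[("chr1", "+")].sum() == 4
        assert track.rpm("chr1", "+")[10] == pytest.approx(2e6 / 4)
        assert track.rpm("chr1", "+")[15] == 0.0

    def test_empty_alignments_rejected(self):
        aln = Alignments(["chr1"], np.empty(0, int), np.empty(0, bool),
                         np.empty(0, int), np.empty(0, int))
        with pytest.raises(ValueError):
            density_track(aln, {"chr1": 100})




class TestFilterORFs:
    def test_length_and_coverage_semantics(self):
        # 168 bp ORF (too short), 300 bp with zero reads, 300 bp well covered
        ann, track = uniform_annotation_and_track([168, 300, 300], [5, 0, 5])
        kept = filter_orfs(ann, track, min_len_bp=170, min_mean_density_per_codon=1.0)
        assert [o.orf_id for o in kept] == ["o2"]

    def test_boundary_length_retained(self):
        ann, track = uniform_annotation_and_track([171, 300], [5, 5])
        kept = filter_orfs(ann, track, min_len_bp=170)
        assert {o.orf_id for o in kept} == {"o0", "o1"}


class TestPauseScores:
    def test_uniform_density_gives_unit_scores(self):
        ann, track = uniform_annotation_and_track([300], [4])
        ps = pause_scores(track, ann.orfs[0])
        inside = ps[45:-21]
        assert np.allclose(inside, 1.0)
        assert np.all(np.isnan(ps[:45])) and np.all(np.isnan(ps[-21:]))

    def test_single_spike_closed_form(self):
        ann, track = uniform_annotation_and_track([300], [1])
        counts = track.counts[("chr1", "+")]
        orf = ann.orfs[0]
        spike_pos = orf.start + 60
        counts[spike_pos] = 10  # one position at 10x the others
        n = 300 - 45 - 21
        expected = 10 * n / (n + 9)
        ps = pause_scores(track, orf)
        assert ps[60] == pytest.approx(expected)

    def test_scale_invariance(self):
        ann, track = uniform_annotation_and_track([300], [2])
        ps1 = pause_scores(track, ann.orfs[0])
        track.counts[("chr1", "+")] *= 5
        ps2 = pause_scores(track, ann.orfs[0])
        assert np.allclose(ps1[45:-21], ps2[45:-21])

    def test_trimmed_mean_is_exactly_one(self, null_sim):
        for orf in null_sim["retained"][:20]:
            ps = pause_scores(null_sim["track"], orf)
            assert np.nanmean(ps) == pytest.approx(1.0, abs=1e-12)


class TestCalibration:
    @pytest.mark.parametrize("offset", [-16, -11, -8])
    def test_simulated_offset_recovered_exactly(self, offset):
        spec = RiboSimSpec(seed=9, depth=200_000, n_orfs=60, offset=offset)
        genome, _ = gen_genome(spec)
        aln, _ = simulate_footprints(genome, spec)
        track = density_track(aln, genome.contig_lengths)
        retained = filter_orfs(genome, track)
        cal = calibrate_asite_offset(genome, track, retained)
        assert cal.offset == offset

    def test_flat_profile_raises(self):
        ann, track = uniform_annotation_and_track([300] * 60, [3] * 60)
        with pytest.raises(CalibrationError):
            calibrate_asite_offset(ann, track, ann.orfs)

    def test_too_few_orfs_raises(self, null_sim):
        with pytest.raises(CalibrationError):
            calibrate_asite_offset(
                null_sim["genome"], null_sim["track"], null_sim["retained"][:10]
            )


class TestCodonMPS:
    def test_hand_computed_single_orf(self):
        """Brute-force oracle: one ORF, hand-placed densities."""
        ann, track = uniform_annotation_and_track([300], [1])
        orf = ann.orfs[0]
        counts = track.counts[("chr1", "+")]
        offset = -11
        # boost the window of codon 25 (a GGC) at the A site: positions
        # c - offset .. +2 with c = 75
        w = orf.start + 75 + 11
        counts[w : w + 3] = 7
        ps = pause_scores(track, orf)
        # independent hand computation over all GGC codons
        seq = orf.sequence(ann.contigs)
        vals = []
        for c in range(0, orf.length - 3, 3):
            if seq[c : c + 3] != "GGC":
                continue
            lo, hi = c + 0 - offset, c + 3 - offset
            if lo < 45 or hi > orf.length - 21:
                continue
            vals.extend(ps[lo:hi])
        expected = float(np.mean(vals))
        table = codon_mps(ann, track, [orf], offset, "A").set_index("codon")
        assert table.loc["GGC", "mps"] == pytest.approx(expected)
        assert table.loc["GGC", "n_orfs"] == 1

    def test_site_consistency_on_null_simulation(self, null_sim):
        mps = mps_matrix(
            null_sim["genome"], null_sim["track"], null_sim["retained"], -11
        )
        wide = mps.pivot(index="codon", columns="site", values="mps").dropna()
        assert np.allclose(wide["A"], wide["P"], atol=0.1)
        assert np.allclose(wide["A"], wide["E"], atol=0.1)

    def test_stall_dose_response_is_monotone(self):
        values = []
        for mult in (2.0, 4.0, 8.0):
            spec = RiboSimSpec(
                seed=13, depth=200_000, n_orfs=40, stalls={"GGA": mult}
            )
            genome, _ = gen_genome(spec)
            aln, _ = simulate_footprints(genome, spec)
            track = density_track(aln, genome.contig_lengths)
            retained = filter_orfs(genome, track)
            table = codon_mps(genome, track, retained, -11, "A").set_index("codon")
            values.append(table.loc["GGA", "mps"])
            others = table.drop(index="GGA").mps
            assert table.loc["GGA", "mps"] > others.max()
        assert values[0] < values[1] < values[2]

    def test_strand_symmetry(self):
        spec = RiboSimSpec(seed=21, depth=50_000, n_orfs=20, orf_len_codons=80,
                           frac_minus=0.0, stalls={"GGA": 4.0})
        genome, _ = gen_genome(spec)
        aln, _ = simulate_footprints(genome, spec)
        track = density_track(aln, genome.contig_lengths)
        retained = filter_orfs(genome, track)
        fwd = codon_mps(genome, track, retained, -11, "A")

        # mirror the world: reverse-complement the contig, flip ORFs and reads
        contig = genome.contigs["chr1"]
        L = len(contig)
        rc = contig.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        orfs_rc = [
            ORF(o.orf_id, "chr1", L - o.end, L - o.start, "-") for o in genome.orfs
        ]
        genome_rc = GenomeAnnotation({"chr1": rc}, orfs_rc)
        aln_rc = Alignments(
            aln.contig_names,
            aln.contig,
            ~aln.is_reverse,
            L - 1 - aln.pos3,
            aln.length,
        )
        track_rc = density_track(aln_rc, genome_rc.contig_lengths)
        retained_rc = filter_orfs(genome_rc, track_rc)
        rev = codon_mps(genome_rc, track_rc, retained_rc, -11, "A")
        assert [o.orf_id for o in retained] == [o.orf_id for o in retained_rc]
        assert fwd.codon.tolist() == rev.codon.tolist()
        assert fwd.n_orfs.tolist() == rev.n_orfs.tolist()
        # identical up to summation order of the reversed-profile means
        assert np.allclose(fwd.mps, rev.mps, rtol=1e-9, equal_nan=True)


class TestBinProfile:
    def test_uniform_density_gives_flat_deciles(self):
        ann, track = uniform_annotation_and_track([300], [4])
        out = bin_profile(ann, track, ann.orfs)
        assert np.allclose(out.geo_mean_fraction, 0.1, atol=0.01)

    def test_all_reads_in_first_decile(self):
        ann, track = uniform_annotation_and_track([300], [0])
        counts = track.counts[("chr1", "+")]
        orf = ann.orfs[0]
        counts[orf.start : orf.start + 30] = 100
        track.total_unique = int(counts.sum())
        out = bin_profile(ann, track, [orf])
        assert out.geo_mean_fraction.iloc[0] > 0.9
        assert out.geo_mean_fraction.iloc[1:].max() < 0.01

    def test_orf_order_invariance(self):
        ann, track = uniform_annotation_and_track([300, 330], [2, 7])
        a = bin_profile(ann, track, ann.orfs)
        b = bin_profile(ann, track, ann.orfs[::-1])
        assert np.allclose(a.geo_mean_fraction, b.geo_mean_fraction)

    def test_short_orf_rejected(self):
        ann, track = uniform_annotation_and_track([300], [2])
        with pytest.raises(ValueError):
            bin_profile(ann, track, ann.orfs, n_bins=200)


class TestMPSContrast:
    @staticmethod
    def _table(values):
        return pd.DataFrame(
            {
                "codon": list(values),
                "site": "A",
                "mps": list(values.values()),
                "n_orfs": 5,
            }
        )

    def test_identical_matrices_give_unit_ratios(self):
        t = self._table({"GGA": 1.2, "GGC": 0.9})
        out = mps_contrast(t, t.copy())
        assert np.allclose(out.ratio, 1.0)

    def test_missing_control_propagates_missing(self):
        toxin = self._table({"GGA": 6.0, "GGC": 1.0})
        control = self._table({"GGA": 1.2, "GGC": np.nan})
        out = mps_contrast(toxin, control).set_index("codon")
        assert out.loc["GGA", "ratio"] == pytest.approx(5.0)
        assert np.isnan(out.loc["GGC", "ratio"])

    def test_disjoint_codon_sets_rejected(self):
        with pytest.raises(ValueError):
            mps_contrast(self._table({"GGA": 1.0}), self._table({"AAA": 1.0}))
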