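"""Binned depth CNV calling: binning, scoring, calls, dosage, trio, SV."""

import itertools

import numpy as np
import pytest
from helpers import FATHER, MOTHER

from embryoscreen.cnv import (
    CnvCall,
    CnvConfig,
    DosageGene,
    assign_dosage,
    bin_depths,
    call_cnvs,
    crosscheck_recessive,
    ingest_sv_calls,
    read_dosage_table,
    score_bins,
    trio_cnv_inheritance,
)

E = "EMBRYO1"


def uniform_tracks(depths, length=2_000_000, res=2_000, chrom="chr1"):
    tracks = {}
    for sid, depth in depths.items():
        tracks[sid] = [(chrom, i, i + res, float(depth(i) if callable(depth) else depth))
                       for i in range(0, length, res)]
    return tracks


class TestBinning:
    def test_uniform_coverage_gives_unit_ratio_and_zero_z(self):
        tracks = uniform_tracks({FATHER: 46, MOTHER: 46, E: 46})
        bins = bin_depths(tracks)
        assert all(b.end - b.start == 10_000 for b in bins)
        scored = score_bins(bins, E, [FATHER, MOTHER])
        assert np.allclose([b.ratio for b in scored], 1.0)
        assert all(abs(b.z) < 1e-6 for b in scored)

    def test_three_copy_region_ratio_1_5_below_call_threshold(self):
        def emb(i):
            return 69 if 1_000_000 <= i < 1_200_000 else 46
        tracks = uniform_tracks({FATHER: 46, MOTHER: 46, E: emb})
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        region = [b for b in bins if 1_000_000 <= b.start < 1_200_000]
        assert all(abs(b.ratio - 1.5) < 0.01 for b in region)
        calls = call_cnvs(bins, E, [FATHER, MOTHER])
        assert calls == []  # 3 copies vs 2 stays under the >2.0 gate

    def test_homozygous_deletion_ratio_near_zero(self):
        def emb(i):
            return 0 if 1_000_000 <= i < 1_200_000 else 46
        tracks = uniform_tracks({FATHER: 46, MOTHER: 46, E: emb})
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        region = [b for b in bins if 1_000_000 <= b.start < 1_200_000]
        assert all(b.ratio == 0.0 for b in region)

    def test_weighted_mean_across_interval_boundaries(self):
        tracks = {E: [("chr1", 0, 5_000, 10.0), ("chr1", 5_000, 10_000, 30.0)],
                  FATHER: [("chr1", 0, 10_000, 20.0)], MOTHER: [("chr1", 0, 10_000, 20.0)]}
        bins = bin_depths(tracks)
        assert bins[0].depth[E] == pytest.approx(20.0)


class TestScoring:
    def test_z_sign_tracks_direction(self):
        rng = np.random.default_rng(0)
        def noisy(base):
            return lambda i: rng.normal(base, 3)
        def emb(i):
            if 1_000_000 <= i < 1_100_000:
                return 150.0
            return rng.normal(46, 3)
        tracks = uniform_tracks({FATHER: noisy(46), MOTHER: noisy(46), E: emb})
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        dup = [b for b in bins if 1_000_000 <= b.start < 1_100_000]
        assert all(b.z > 0 for b in dup)

    def test_high_control_variation_flag(self):
        def father(i):
            return 1.0 if 1_000_000 <= i < 1_100_000 else 46.0
        tracks = uniform_tracks({FATHER: father, MOTHER: 46, E: 46})
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        flagged = [b for b in bins if 1_000_000 <= b.start < 1_100_000]
        assert all("high_control_variation" in b.qc_flags for b in flagged)

    def test_low_control_depth_flag_on_missing_contig(self):
        tracks = {E: [("chr1", 0, 100_000, 46.0), ("chr2", 0, 100_000, 46.0)],
                  FATHER: [("chr1", 0, 100_000, 46.0)],
                  MOTHER: [("chr1", 0, 100_000, 46.0)]}
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        chr2 = [b for b in bins if b.chrom == "chr2"]
        assert chr2 and all("low_control_depth" in b.qc_flags for b in chr2)

    def test_simulated_high_copy_duplication_all_bins_qualify(self, tmp_path):
        """A 1 Mb copy-6 duplication at 40x on artifact-free depth: every
        member bin exceeds the duplication ratio with positive Z."""
        from embryoscreen.simulate import CnvSpec, SimParams, simulate_family

        params = SimParams(
            seed=19, mean_depth_embryo=40.0, embryo_nb_size=60.0, wave_sigma=0.02,
            embryo_sexes=("female",), planted_variants=[],
            planted_cnvs=[CnvSpec("chr2", 4_000_000, 5_000_000, {"embryo": 6})],
        )
        fam = simulate_family(params)
        tracks = {
            FATHER: [("%s" % c, i * 2000, (i + 1) * 2000, float(v))
                     for c, vals in fam.parents.depth_tracks[FATHER].items()
                     for i, v in enumerate(vals)],
            MOTHER: [(c, i * 2000, (i + 1) * 2000, float(v))
                     for c, vals in fam.parents.depth_tracks[MOTHER].items()
                     for i, v in enumerate(vals)],
            E: [(c, i * 2000, (i + 1) * 2000, float(v))
                for c, vals in fam.embryos[0].depth_track.items()
                for i, v in enumerate(vals)],
        }
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        member = [b for b in bins if b.chrom == "chr2" and 4_000_000 <= b.start < 5_000_000]
        assert len(member) == 100
        assert all(b.ratio > 2.0 and b.z > 0 for b in member)


class TestCalling:
    def qualifying_bins(self, n, state="duplication", chrom="chr1", start=0):
        from embryoscreen.cnv import DepthBin

        bins = []
        ratio = 3.0 if state == "duplication" else 0.05
        z = 10.0 if state == "duplication" else -8.0
        for i in range(n):
            b = DepthBin(chrom, start + i * 10_000, start + (i + 1) * 10_000,
                         {E: 46.0 * ratio, FATHER: 46.0, MOTHER: 46.0})
            b.ratio, b.z, b.qc_flags = ratio, z, set()
            bins.append(b)
        return bins

    def test_twelve_consecutive_bins_merge_to_one_call(self):
        calls = call_cnvs(self.qualifying_bins(12), E, [FATHER, MOTHER])
        assert len(calls) == 1
        assert calls[0].end - calls[0].start == 120_000
        assert calls[0].n_bins == 12

    def test_flagged_bin_splits_the_run(self):
        bins = self.qualifying_bins(12)
        bins[5].qc_flags = {"within_regional_iqr"}
        calls = call_cnvs(bins, E, [FATHER, MOTHER])
        assert [c.n_bins for c in calls] == [5, 6]

    def test_low_control_depth_call_discarded(self):
        bins = self.qualifying_bins(5)
        for b in bins:
            b.depth[FATHER] = b.depth[MOTHER] = 4.0
        assert call_cnvs(bins, E, [FATHER, MOTHER]) == []

    def test_no_call_overlaps_flagged_or_nonqualifying_bin(self):
        bins = self.qualifying_bins(6) + self.qualifying_bins(6, start=70_000)
        bins.sort(key=lambda b: b.start)
        bins[3].qc_flags = {"low_z_score"}
        bins[8].ratio = 1.0
        calls = call_cnvs(bins, E, [FATHER, MOTHER])
        for c in calls:
            for b in bins:
                overlaps = b.chrom == c.chrom and b.start < c.end and c.start < b.end
                if overlaps:
                    assert not b.qc_flags and b.ratio > 2.0

    def test_recall_on_planted_cnvs_with_mda_noise(self, default_family, default_report):
        """All six planted embryo CNVs >=200 kb are recovered (>=50% of
        each planted span covered by same-state calls) and no called
        interval >=100 kb lies outside a planted region."""
        fam, _ = default_family
        planted = fam.params.planted_cnvs
        for rep in default_report["reports"]:
            calls = rep["cnv"]["calls"]
            for spec in planted:
                state = "deletion" if spec.copy_for("embryo") < 2 else "duplication"
                cover = sum(
                    max(0, min(c["end"], spec.end) - max(c["start"], spec.start))
                    for c in calls if c["chrom"] == spec.chrom and c["state"] == state
                )
                assert cover / (spec.end - spec.start) >= 0.5, (rep["embryo_id"], spec)
            for c in calls:
                if c["end"] - c["start"] >= 100_000:
                    inside = any(
                        c["chrom"] == s.chrom
                        and min(c["end"], s.end) - max(c["start"], s.start)
                        > 0.5 * (c["end"] - c["start"])
                        for s in planted
                    )
                    assert inside, (rep["embryo_id"], c)

    def test_boundaries_within_one_bin_on_artifact_free_depth(self):
        """Planted CNV boundaries recovered to +-1 bin without MDA noise."""
        from embryoscreen.simulate import CnvSpec, SimParams, simulate_family

        spec = CnvSpec("chr3", 2_000_000, 2_500_000, {"embryo": 0})
        params = SimParams(seed=23, embryo_nb_size=60.0, wave_sigma=0.02,
                           embryo_sexes=("female",), planted_variants=[],
                           planted_cnvs=[spec])
        fam = simulate_family(params)
        tracks = {}
        for sid, track in {**fam.parents.depth_tracks,
                           "EMBRYO1": fam.embryos[0].depth_track}.items():
            tracks[sid] = [(c, i * 2000, (i + 1) * 2000, float(v))
                           for c, vals in track.items() for i, v in enumerate(vals)]
        bins = score_bins(bin_depths(tracks), E, [FATHER, MOTHER])
        calls = [c for c in call_cnvs(bins, E, [FATHER, MOTHER])
                 if c.chrom == "chr3" and c.state == "deletion"]
        assert len(calls) == 1
        assert abs(calls[0].start - spec.start) <= 10_000
        assert abs(calls[0].end - spec.end) <= 10_000


class TestDosage:
    TABLE = [
        DosageGene("HI1", "chr1", 100_000, 200_000, "sufficient_evidence", "none"),
        DosageGene("TS1", "chr1", 500_000, 600_000, "none", "sufficient_evidence"),
        DosageGene("AR1", "chr1", 800_000, 900_000, "autosomal_recessive_gene", "none"),
    ]

    def call(self, start, end, state):
        return CnvCall("chr1", start, end, state, 0.0 if state == "deletion" else 3.0,
                       -5.0 if state == "deletion" else 5.0, 46.0, (end - start) // 10_000)

    def test_deletion_over_haploinsufficiency_gene_reportable(self):
        (c,) = assign_dosage([self.call(90_000, 250_000, "deletion")], self.TABLE)
        assert c.dosage_category == "haploinsufficiency"
        assert c.dosage_evidence == "sufficient_evidence"

    def test_duplication_without_entry_has_no_dosage(self):
        (c,) = assign_dosage([self.call(1_000_000, 1_100_000, "duplication")], self.TABLE)
        assert c.dosage_category == "none"

    def test_recessive_evidence_routes_not_autoreported(self):
        (c,) = assign_dosage([self.call(790_000, 950_000, "deletion")], self.TABLE)
        assert c.dosage_category == "haploinsufficiency"
        assert c.dosage_evidence == "autosomal_recessive_gene"

    def test_malformed_table_row_fatal(self, tmp_path):
        p = tmp_path / "dosage.tsv"
        p.write_text("gene\tchrom\tstart\tend\thaploinsufficiency\ttriplosensitivity\n"
                     "G1\tchr1\tnotanumber\t10\tnone\tnone\n")
        with pytest.raises(ValueError):
            read_dosage_table(p)


class TestTrioInheritance:
    def call(self, start, end, state, sample=E):
        return CnvCall("chr1", start, end, state, 3.0, 5.0, 46.0,
                       (end - start) // 10_000, sample_id=sample)

    def test_embryo_deletion_matching_paternal_is_paternal(self):
        (c,) = trio_cnv_inheritance(
            [self.call(0, 100_000, "deletion")],
            [self.call(0, 100_000, "deletion", FATHER)], [])
        assert c.inheritance == "paternal"

    def test_embryo_only_duplication_is_de_novo(self):
        (c,) = trio_cnv_inheritance([self.call(0, 100_000, "duplication")], [], [])
        assert c.inheritance == "de_novo"

    def test_state_must_match(self):
        (c,) = trio_cnv_inheritance(
            [self.call(0, 100_000, "duplication")],
            [self.call(0, 100_000, "deletion", FATHER)], [])
        assert c.inheritance == "de_novo"

    def test_planted_inherited_and_de_novo_labels_match_truth(self, default_family,
                                                              default_report):
        fam, _ = default_family
        for rep in default_report["reports"]:
            calls = rep["cnv"]["calls"]
            for spec in fam.params.planted_cnvs:
                expected = ("paternal" if spec.copy_for("father") != 2 else
                            "maternal" if spec.copy_for("mother") != 2 else "de_novo")
                state = "deletion" if spec.copy_for("embryo") < 2 else "duplication"
                overlapping = [
                    c for c in calls
                    if c["chrom"] == spec.chrom and c["state"] == state
                    and min(c["end"], spec.end) - max(c["start"], spec.start)
                    > 0.5 * (spec.end - spec.start)
                ]
                for c in overlapping:
                    assert c["inheritance"] == expected, (rep["embryo_id"], spec, c)


class TestCrosscheckRecessive:
    class Hit:
        def __init__(self, gene, origin):
            self.gene, self.origin = gene, origin

    def cnv(self, gene, inheritance, state="deletion"):
        c = CnvCall("chr1", 0, 100_000, state, 0.0, -5.0, 46.0, 10,
                    dosage_evidence="autosomal_recessive_gene",
                    inheritance=inheritance, genes=(gene,))
        return c

    def test_trans_pair_found(self):
        out = crosscheck_recessive([self.cnv("G", "maternal")],
                                   [self.Hit("G", "paternal")])
        assert len(out) == 1

    def test_cis_pair_not_called(self):
        assert crosscheck_recessive([self.cnv("G", "paternal")],
                                    [self.Hit("G", "paternal")]) == []

    def test_matches_exhaustive_pairing_oracle(self):
        """Brute force over a 20-gene random table."""
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(20)]
        cnvs = [self.cnv(genes[rng.integers(0, 20)],
                         ["paternal", "maternal", "de_novo"][rng.integers(0, 3)])
                for _ in range(15)]
        hits = [self.Hit(genes[rng.integers(0, 20)],
                         ["paternal", "maternal", "de_novo"][rng.integers(0, 3)])
                for _ in range(25)]
        got = {(id(c), id(h)) for f in [crosscheck_recessive(cnvs, hits)]
               for c, h in [(x.cnv, x.snv) for x in f]}
        opposite = {"paternal": "maternal", "maternal": "paternal"}
        expected = set()
        for c, h in itertools.product(cnvs, hits):
            if h.gene in c.genes and c.state == "deletion":
                want = opposite.get(c.inheritance)
                if (want is None or h.origin == want or h.origin == "de_novo") \
                        and h.origin != c.inheritance:
                    expected.add((id(c), id(h)))
        assert got == expected
        assert expected


class TestSvIngestion:
    def write_sv(self, tmp_path, rows):
        p = tmp_path / "sv.bed"
        p.write_text("".join(rows))
        return str(p)

    def test_deletion_gets_dosage_logic(self, tmp_path):
        path = self.write_sv(tmp_path, ["chr1\t90000\t250000\tDEL\n"])
        (c,) = ingest_sv_calls(path, "external_caller")
        assign_dosage([c], TestDosage.TABLE)
        assert c.state == "deletion"
        assert c.dosage_category == "haploinsufficiency"

    def test_inversion_annotated_without_dosage(self, tmp_path):
        path = self.write_sv(tmp_path, ["chr1\t90000\t250000\tINV\n"])
        (c,) = ingest_sv_calls(path, "external_caller")
        assert c.state == "other"
        assert c.sv_type == "INV"

    def test_interchromosomal_kept_in_sv_section_only(self, tmp_path):
        path = self.write_sv(tmp_path, ["chr1\t90000\t250000\tCTX\n"])
        (c,) = ingest_sv_calls(path, "external_caller")
        assert c.state == "other"
        assert c.sv_type == "CTX"
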