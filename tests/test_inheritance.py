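"""Inheritance-mode filters: transmission oracle, mode filters, failsafe."""

import itertools

import numpy as np
import pytest
from helpers import EMBRYO, FATHER, MOTHER, mk_annotation, mk_call, mk_record

from embryoscreen.inheritance import (
    FilterConfig,
    classify_transmission,
    filter_compound_het,
    filter_denovo,
    filter_dominant,
    filter_failsafe,
    filter_recessive,
    filter_xlinked,
    infer_embryo_sex,
)

GTS = ["0/0", "0/1", "1/1"]


def oracle_origin(father_gt, mother_gt, embryo_gt):
    """Independent set-logic rule for the transmission label."""
    if "1" not in embryo_gt:
        return "none"
    f_has, m_has = "1" in father_gt, "1" in mother_gt
    if f_has and m_has:
        return "ambiguous"
    if f_has:
        return "paternal"
    if m_has:
        return "maternal"
    return "de_novo"


class TestClassifyTransmission:
    def test_matches_brute_force_over_all_27_diploid_combinations(self):
        for f, m, e in itertools.product(GTS, repeat=3):
            rec = mk_record(f, m, e)
            got = classify_transmission(rec, EMBRYO, FATHER, MOTHER)
            assert got == oracle_origin(f, m, e), (f, m, e)

    @pytest.mark.parametrize("f,m,e,expected", [
        ("0/1", "0/0", "0/1", "paternal"),
        ("0/0", "0/0", "0/1", "de_novo"),
        ("0/1", "0/1", "0/1", "ambiguous"),
    ])
    def test_canonical_cases(self, f, m, e, expected):
        assert classify_transmission(mk_record(f, m, e), EMBRYO, FATHER, MOTHER) == expected

    def test_missing_embryo_unclassifiable(self):
        assert classify_transmission(mk_record("0/1", "0/0", "./."),
                                     EMBRYO, FATHER, MOTHER) == "unclassifiable"

    def test_missing_parent_is_ambiguous(self):
        assert classify_transmission(mk_record("./.", "0/0", "0/1"),
                                     EMBRYO, FATHER, MOTHER) == "ambiguous"


class TestDominant:
    def run(self, rec, ann):
        return filter_dominant([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)

    def test_transmitted_pathogenic_het_retained_in_dbsnp_subfilter(self):
        rec = mk_record("0/1", "0/0", mk_call("0/1", ad=(15, 15)))
        cands, _ = self.run(rec, mk_annotation(rec, in_dbsnp=True))
        assert len(cands) == 1
        assert cands[0].subfilter == "dbsnp"
        assert cands[0].origin == "paternal"

    def test_low_depth_excluded_with_failed_trail(self):
        rec = mk_record("0/1", "0/0", mk_call("0/1", ad=(4, 4)))
        cands, rejected = self.run(rec, mk_annotation(rec))
        assert not cands
        assert dict(rejected[0].trail)["depth"] is False

    def test_benign_excluded_by_grade(self):
        rec = mk_record("0/1", "0/0", "0/1")
        cands, rejected = self.run(rec, mk_annotation(rec, clinvar="benign"))
        assert not cands
        assert dict(rejected[0].trail)["pathogenic_grade"] is False


class TestRecessive:
    def run(self, rec, ann):
        return filter_recessive([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)

    def test_biparental_hom_retained(self):
        rec = mk_record("0/1", "0/1", "1/1")
        res = self.run(rec, mk_annotation(rec))
        assert len(res.affected) == 1

    def test_mendelian_violation_flagged_as_dropout_suspect(self):
        rec = mk_record("0/1", mk_call("0/0", ad=(40, 0)), "1/1")
        res = self.run(rec, mk_annotation(rec))
        assert not res.affected
        assert len(res.dropout_suspects) == 1

    def test_het_is_carrier_finding_only(self):
        rec = mk_record("0/1", "0/1", "0/1")
        res = self.run(rec, mk_annotation(rec))
        assert not res.affected
        assert len(res.carriers) == 1


class TestCompoundHet:
    def hit(self, gene, origin, pos):
        rec = mk_record("0/1" if origin == "paternal" else "0/0",
                        "0/1" if origin == "maternal" else "0/0",
                        "0/1", pos=pos)
        ann = mk_annotation(rec, gene=gene)
        cands, _ = filter_dominant([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)
        if not cands:  # de novo / ambiguous constructed directly
            cands, _ = filter_denovo([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)
            for c in cands:
                c.gene = gene
        (c,) = cands
        c.origin = origin
        return c

    def test_opposite_origin_pair_called(self):
        pairs, _ = filter_compound_het([
            self.hit("G", "paternal", 100), self.hit("G", "maternal", 200),
        ])
        assert len(pairs) == 1

    def test_same_origin_no_pair(self):
        pairs, _ = filter_compound_het([
            self.hit("G", "paternal", 100), self.hit("G", "paternal", 200),
        ])
        assert not pairs

    def test_ambiguous_origin_goes_to_curation(self):
        pairs, curation = filter_compound_het([
            self.hit("G", "paternal", 100), self.hit("G", "ambiguous", 200),
        ])
        assert not pairs and len(curation) == 1

    def test_matches_exhaustive_pairing_oracle(self):
        """Brute-force enumeration over a 50-variant, 8-gene table."""
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(8)]
        hits = []
        for pos in range(100, 100 + 50 * 10, 10):
            gene = genes[rng.integers(0, 8)]
            origin = ["paternal", "maternal", "de_novo"][rng.integers(0, 3)]
            hits.append(self.hit(gene, origin, pos))
        pairs, _ = filter_compound_het(hits)
        got = {tuple(sorted((p.hit_a.key, p.hit_b.key))) for p in pairs}
        expected = set()
        for a, b in itertools.combinations(hits, 2):
            if a.gene != b.gene:
                continue
            origins = {a.origin, b.origin}
            if origins == {"paternal", "maternal"} or (
                    "de_novo" in origins and origins & {"paternal", "maternal"}):
                expected.add(tuple(sorted((a.key, b.key))))
        assert got == expected
        assert expected  # the random table must actually contain pairs


class TestXLinked:
    def xrec(self, f, m, e, pos=5000):
        return mk_record(f, m, e, chrom="chrX", pos=pos)

    def test_male_hemizygous_maternal_alt_affected(self):
        rec = self.xrec(mk_call("0"), "0/1", mk_call("1"))
        res = filter_xlinked([rec], {rec.key: mk_annotation(rec)},
                             EMBRYO, FATHER, MOTHER, "male")
        assert len(res.affected) == 1

    def test_female_het_is_carrier(self):
        rec = self.xrec(mk_call("0"), "0/1", "0/1")
        res = filter_xlinked([rec], {rec.key: mk_annotation(rec)},
                             EMBRYO, FATHER, MOTHER, "female")
        assert not res.affected and len(res.carriers) == 1

    def test_autosomal_record_never_emitted(self):
        rec = mk_record("0/0", "0/1", "0/1", chrom="chr2")
        res = filter_xlinked([rec], {rec.key: mk_annotation(rec)},
                             EMBRYO, FATHER, MOTHER, "male")
        assert not (res.affected or res.carriers or res.curation or res.rejected)

    def test_unknown_sex_routes_to_curation(self):
        rec = self.xrec(mk_call("0"), "0/1", "0/1")
        res = filter_xlinked([rec], {rec.key: mk_annotation(rec)},
                             EMBRYO, FATHER, MOTHER, "unknown")
        assert len(res.curation) == 1

    def test_sex_inference_from_x_heterozygosity(self, loaded_records, default_family):
        pedigree, records, _ = loaded_records
        fam, _ = default_family
        for emb in fam.embryos:
            assert infer_embryo_sex(records, emb.sample_id) == emb.sex


class TestFailsafe:
    def test_low_quality_hit_in_actionable_gene_retained(self):
        rec = mk_record("0/0", "0/0", mk_call("0/1", ad=(1, 1), gq=3))
        ann = mk_annotation(rec, gene="ACT1")
        out = filter_failsafe([rec], {rec.key: ann}, EMBRYO, ["ACT1"])
        assert len(out) == 1
        # the same record fails every strict filter
        dom, _ = filter_dominant([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)
        dn, _ = filter_denovo([rec], {rec.key: ann}, EMBRYO, FATHER, MOTHER)
        assert not dom and not dn

    def test_depth_1_excluded(self):
        rec = mk_record("0/0", "0/0", mk_call("0/1", ad=(0, 1), gq=3))
        ann = mk_annotation(rec, gene="ACT1")
        assert not filter_failsafe([rec], {rec.key: ann}, EMBRYO, ["ACT1"])

    def test_superset_of_strict_filters_on_actionable_genes(self, loaded_records):
        """Failsafe output contains every strict-filter hit in an
        actionable gene, for every embryo of the default family."""
        pedigree, records, annotations = loaded_records
        actionable = {a.gene for a in annotations.values() if a.gene}
        cfg = FilterConfig()
        for emb in [s for s in pedigree if s.role == "embryo"]:
            eid = emb.sample_id
            fs_keys = {c.key for c in filter_failsafe(records, annotations, eid, actionable, cfg)}
            dom, _ = filter_dominant(records, annotations, eid, FATHER, MOTHER, cfg)
            rec_res = filter_recessive(records, annotations, eid, FATHER, MOTHER, cfg)
            dn, _ = filter_denovo(records, annotations, eid, FATHER, MOTHER, cfg)
            xl = filter_xlinked(records, annotations, eid, FATHER, MOTHER, emb.sex, cfg)
            strict = dom + rec_res.affected + rec_res.carriers + dn + xl.affected + xl.carriers
            strict_keys = {c.key for c in strict if c.gene in actionable}
            assert strict_keys <= fs_keys


class TestEngineProperties:
    def test_strict_retained_sets_respect_depth_floor(self, loaded_records):
        pedigree, records, annotations = loaded_records
        dom, _ = filter_dominant(records, annotations, "EMBRYO1", FATHER, MOTHER)
        rec_res = filter_recessive(records, annotations, "EMBRYO1", FATHER, MOTHER)
        dn, _ = filter_denovo(records, annotations, "EMBRYO1", FATHER, MOTHER)
        for c in dom + rec_res.affected + rec_res.carriers + dn:
            assert c.record.calls["EMBRYO1"].total_depth >= 10

    def test_union_exhaustiveness_nothing_vanishes(self, loaded_records):
        """Every embryo alt-bearing autosomal record lands in at least one
        candidate, carrier, dropout-suspect or rejected-with-trail list."""
        pedigree, records, annotations = loaded_records
        eid = "EMBRYO1"
        dom, dom_rej = filter_dominant(records, annotations, eid, FATHER, MOTHER)
        rec_res = filter_recessive(records, annotations, eid, FATHER, MOTHER)
        dn, dn_rej = filter_denovo(records, annotations, eid, FATHER, MOTHER)
        routed = {c.key for c in dom + dom_rej + rec_res.affected + rec_res.carriers
                  + rec_res.dropout_suspects + rec_res.rejected + dn + dn_rej}
        for r in records:
            if r.chrom == "chrX":
                continue
            call = r.calls.get(eid)
            if call is not None and call.has_alt:
                assert r.key in routed, r.key

    def test_clean_trio_de_novo_origin_matches_planted_exactly(self, clean_family):
        """Without artifacts/dropout, de novo candidates == planted de novos
        with adequate coverage (sensitivity 1.0, FDR 0 at the origin level)."""
        from embryoscreen.trio_io import read_annotations, read_pedigree, read_trio_vcf

        fam, paths = clean_family
        ped = read_pedigree(paths["pedigree"])
        records = list(read_trio_vcf(paths["vcf"], ped))
        annotations = read_annotations(paths["annotations"])
        cfg = FilterConfig(depth_min=0, gq_min=0)
        cands, rejected = filter_denovo(records, annotations, "EMBRYO1",
                                        FATHER, MOTHER, cfg)
        got = {(c.record.chrom, c.record.pos) for c in cands + rejected}
        priv = fam.embryos[0].private
        planted = set(zip(priv.chrom, priv.pos))
        emitted = {(c, p) for c, p in planted
                   if ((priv.chrom == c) & (priv.pos == p)).any()
                   and int(priv[(priv.chrom == c) & (priv.pos == p)].e_alt.iloc[0]) > 0}
        assert got == emitted
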