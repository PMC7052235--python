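"""Pipeline orchestration and per-embryo screening reports.

Stage order: I/O -> pathogenicity grading -> inheritance-mode filters ->
de novo MDA gates -> LoH detection and expected-but-missing rescue ->
CNV / SV -> tandem repeats -> report assembly.  Each embryo receives a
report with per-mode candidate tables, carrier findings, compound-het
pairs, the de novo retained/rejected split, the expected-but-missing
ledger with rescue statuses, CNV/SV calls, the repeat concordance
table, the incidental-findings section and summary counts; a cohort
summary aggregates means and standard deviations across embryos.

Embryo status per screened condition uses the clinical three-way
vocabulary: ``affected`` (qualifying genotype for the condition's
inheritance mode), ``carrier`` (single pathogenic allele under
recessive or X-linked modes) or ``unaffected`` — with ``undetermined``
reserved for conditions that land in the expected-but-missing ledger
without a phase rescue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from embryoscreen import cnv as cnvmod
from embryoscreen import denovo as dnmod
from embryoscreen import inheritance as inh
from embryoscreen import loh as lohmod
from embryoscreen import repeats as strmod
from embryoscreen.pathogenicity import grade_variant, screen_incidental
from embryoscreen.trio_io import (
    pedigree_roles,
    read_annotations,
    read_pedigree,
    read_trio_vcf,
)

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class ParentalPathogenic:
    key: tuple
    expected_from: str  # paternal | maternal | either
    gene: str
    grade: str


def _load_gene_list(path):
    if not path:
        return []
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def parental_pathogenic_set(records, annotations, father_id, mother_id):
    """Qualifying variants carried by either parent."""
    out = []
    for r in records:
        ann = annotations.get(r.key)
        g = grade_variant(ann)
        if not g.qualifies:
            continue
        father, mother = r.calls.get(father_id), r.calls.get(mother_id)
        f_has = father is not None and father.has_alt
        m_has = mother is not None and mother.has_alt
        if not (f_has or m_has):
            continue
        origin = "either" if (f_has and m_has) else ("paternal" if f_has else "maternal")
        out.append(ParentalPathogenic(r.key, origin, ann.gene if ann else "", g.grade))
    return out


def _candidate_row(c):
    return {
        "chrom": c.record.chrom, "pos": c.record.pos, "ref": c.record.ref,
        "alt": c.record.alt, "mode": c.mode, "subfilter": c.subfilter,
        "grade": c.grade.grade, "basis": c.grade.basis, "stars": c.grade.stars,
        "origin": c.origin, "gene": c.gene,
        "vaf": round(c.vaf, 3) if c.vaf is not None else None,
        "qd": c.record.qd,
        "trail": [[name, bool(ok)] for name, ok in c.trail],
    }


def _gate_denovo(candidates, vaf_threshold, qd_threshold):
    """VAF gate on all de novo candidates; QD gate on the novel subfilter."""
    vres = dnmod.vaf_gate(candidates, vaf_threshold)
    dbsnp_part = [c for c in vres.retained if c.subfilter == "dbsnp"]
    novel_part = [c for c in vres.retained if c.subfilter == "novel"]
    qres = dnmod.qd_gate(novel_part, qd_threshold)
    retained = dbsnp_part + qres.retained
    rejected = vres.rejected + qres.rejected
    return retained, rejected


def screen_embryo(records, records_by_key, annotations, embryo, father_id, mother_id,
                  actionable_genes, incidental_genes, parental_pathogenic,
                  cfg: inh.FilterConfig, vaf_threshold=0.35, qd_threshold=12.0,
                  run_loh=True):
    """All SNV/indel stages for one embryo; returns the report dict."""
    eid = embryo.sample_id
    sex = embryo.sex
    if sex not in ("male", "female"):
        sex = inh.infer_embryo_sex(records, eid, cfg)

    dom, dom_rej = inh.filter_dominant(records, annotations, eid, father_id, mother_id, cfg)
    rec = inh.filter_recessive(records, annotations, eid, father_id, mother_id, cfg)
    dn_cands, dn_rej = inh.filter_denovo(records, annotations, eid, father_id, mother_id, cfg)
    dn_retained, dn_gate_rejected = _gate_denovo(dn_cands, vaf_threshold, qd_threshold)
    xl = inh.filter_xlinked(records, annotations, eid, father_id, mother_id, sex, cfg)
    failsafe = inh.filter_failsafe(records, annotations, eid, actionable_genes, cfg)

    het_hits = {c.key: c for c in dom if c.record.calls[eid].is_het}
    for c in rec.carriers:
        het_hits.setdefault(c.key, c)
    for c in dn_retained:
        if c.grade.qualifies and c.record.calls[eid].is_het:
            het_hits.setdefault(c.key, c)
    ch_pairs, ch_curation = inh.filter_compound_het(list(het_hits.values()))

    # LoH + expected-but-missing ledger + phase rescue
    embryo_segs = father_segs = mother_segs = []
    ledger = []
    if run_loh:
        embryo_segs = lohmod.detect_loh_segments(records, eid, father_id, mother_id)
        father_segs = lohmod.detect_loh_segments(records, father_id, father_id, mother_id)
        mother_segs = lohmod.detect_loh_segments(records, mother_id, father_id, mother_id)
        lohmod.trio_call_loh(embryo_segs, father_segs, mother_segs)
        ledger = lohmod.ledger_expected_missing(
            parental_pathogenic, records_by_key, eid, embryo_segs, cfg.depth_min)
        dropout_segs = [s for s in embryo_segs if s.label == "embryo_only"]
        by_chrom: dict = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        pp_by_key = {p.key: p for p in parental_pathogenic}
        for entry in ledger:
            pp = pp_by_key[entry.key]
            if pp.expected_from == "either":
                continue  # both parents carry: flank phasing cannot single out a haplotype
            carrier = father_id if pp.expected_from == "paternal" else mother_id
            other = mother_id if carrier == father_id else father_id
            lohmod.phase_rescue(entry, by_chrom.get(entry.key[0], []), carrier, other,
                                eid, depth_min=cfg.depth_min,
                                exclude_segments=dropout_segs)

    incidental = screen_incidental(
        dom + rec.affected + rec.carriers + xl.affected + xl.carriers + dn_retained,
        [type("P", (), {"gene": p.gene, "grade": p.grade})() for p in parental_pathogenic],
        incidental_genes,
    )

    report = {
        "embryo_id": eid,
        "sex": sex,
        "dominant": [_candidate_row(c) for c in dom],
        "recessive_affected": [_candidate_row(c) for c in rec.affected],
        "recessive_carriers": [_candidate_row(c) for c in rec.carriers],
        "dropout_suspects": [_candidate_row(c) for c in rec.dropout_suspects],
        "x_linked_affected": [_candidate_row(c) for c in xl.affected],
        "x_linked_carriers": [_candidate_row(c) for c in xl.carriers],
        "x_linked_curation": [_candidate_row(c) for c in xl.curation],
        "compound_het_pairs": [
            {"gene": p.gene, "hit_a": _candidate_row(p.hit_a), "hit_b": _candidate_row(p.hit_b)}
            for p in ch_pairs
        ],
        "compound_het_curation": [
            {"gene": p.gene, "hit_a": _candidate_row(p.hit_a), "hit_b": _candidate_row(p.hit_b)}
            for p in ch_curation
        ],
        "de_novo_retained": [_candidate_row(c) for c in dn_retained],
        "de_novo_rejected": [
            dict(_candidate_row(c), reject_reason=reason) for c, reason in dn_gate_rejected
        ],
        "failsafe": [_candidate_row(c) for c in failsafe],
        "loh_segments": [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "variant_count": s.variant_count, "loh_fraction": round(s.loh_fraction, 4),
             "label": s.label}
            for s in embryo_segs
        ],
        "expected_but_missing": [
            {"chrom": e.key[0], "pos": e.key[1], "ref": e.key[2], "alt": e.key[3],
             "expected_from": e.expected_from, "reason": e.reason,
             "rescue_status": e.rescue_status, "gene": e.gene, "grade": e.grade}
            for e in ledger
        ],
        "incidental_findings": (
            incidental if "notice" in incidental else {
                "embryo": [_candidate_row(c) for c in incidental["embryo"]],
                "parental": [{"gene": c.gene, "grade": c.grade} for c in incidental["parental"]],
            }
        ),
    }
    # per-embryo heterozygote VAF histogram (bin width 0.02), mirroring
    # the per-sample VAF distributions used to motivate the artifact gate
    het_vafs = [dnmod.compute_vaf(r.calls[eid]).vaf for r in records
                if r.calls.get(eid) is not None and r.calls[eid].is_het]
    centers, counts = dnmod.vaf_histogram(het_vafs)
    report["vaf_histogram"] = {
        "bin_centers": [round(float(c), 2) for c in centers],
        "counts": [int(n) for n in counts],
    }
    report["summary"] = {
        k: len(v) for k, v in report.items()
        if isinstance(v, list)
    }
    return report


def _condition_status(report, gene, mode):
    """Three-way status of one screened condition for one embryo."""
    def hits(section):
        return [row for row in report[section] if row["gene"] == gene]

    ledger = [row for row in report["expected_but_missing"] if row["gene"] == gene]
    if mode == "dominant_het":
        if hits("dominant"):
            return "affected"
    elif mode == "recessive_hom":
        if hits("recessive_affected"):
            return "affected"
        if hits("recessive_carriers"):
            return "carrier"
    elif mode == "compound_het":
        if any(p["gene"] == gene for p in report["compound_het_pairs"]):
            return "affected"
        if hits("dominant") or hits("recessive_carriers"):
            return "carrier"
    elif mode == "x_linked":
        if hits("x_linked_affected"):
            return "affected"
        if hits("x_linked_carriers"):
            return "carrier"
    elif mode == "de_novo":
        if [row for row in hits("de_novo_retained")
                if row["grade"] in ("pathogenic", "likely_pathogenic", "predicted_pathogenic")]:
            return "affected"
    if ledger:
        status = {"carrier_inferred": "carrier", "noncarrier_inferred": "unaffected"}
        resolved = {status[e["rescue_status"]] for e in ledger if e["rescue_status"] in status}
        if len(resolved) == 1:
            return resolved.pop()
        return "undetermined"
    return "unaffected"


def run_pipeline(config: dict) -> dict:
    """Execute every stage per the config; returns reports + summary.

    See the package README for the config schema.  Stage toggles live
    under ``stages``; a disabled stage simply omits its report section.
    """
    stages = config.get("stages", {})
    thresholds = config.get("thresholds", {})
    cfg = inh.FilterConfig(
        depth_min=int(thresholds.get("depth_min", 10)),
        gq_min=float(thresholds.get("gq_min", 20)),
        failsafe_depth_min=int(thresholds.get("failsafe_depth_min", 2)),
    )
    pedigree = read_pedigree(config["pedigree"])
    father_id, mother_id, embryos = pedigree_roles(pedigree)
    records = list(read_trio_vcf(config["vcf"], pedigree))
    records_by_key = {r.key: r for r in records}
    annotations = read_annotations(config["annotations"])
    actionable = _load_gene_list(config.get("actionable_genes"))
    incidental = _load_gene_list(config.get("incidental_genes"))
    log.info("loaded %d records, %d annotations, %d embryos",
             len(records), len(annotations), len(embryos))

    parental = parental_pathogenic_set(records, annotations, father_id, mother_id)

    # ---- CNV stage shared across embryos
    cnv_inputs = None
    if stages.get("cnv", True) and config.get("depth_tracks"):
        tracks = {sid: cnvmod.read_bedgraph(path)
                  for sid, path in config["depth_tracks"].items()}
        bins = cnvmod.bin_depths(tracks)
        dosage = (cnvmod.read_dosage_table(config["dosage_table"])
                  if config.get("dosage_table") else [])
        ccfg = cnvmod.CnvConfig()
        sexes = {s.sample_id: s.sex for s in pedigree}
        father_calls = cnvmod.call_cnvs(
            cnvmod.score_bins([b for b in bins], father_id, [mother_id], ccfg, sexes),
            father_id, [mother_id], ccfg)
        mother_calls = cnvmod.call_cnvs(
            cnvmod.score_bins([b for b in bins], mother_id, [father_id], ccfg, sexes),
            mother_id, [father_id], ccfg)
        cnv_inputs = (bins, dosage, ccfg, father_calls, mother_calls, sexes)

    repeats = None
    if stages.get("str", True) and config.get("repeats"):
        repeats = strmod.read_repeat_genotypes(config["repeats"])

    reports = []
    for emb in embryos:
        rep = screen_embryo(records, records_by_key, annotations, emb, father_id,
                            mother_id, actionable, incidental, parental, cfg,
                            vaf_threshold=float(thresholds.get("vaf", 0.35)),
                            qd_threshold=float(thresholds.get("qd", 12)),
                            run_loh=stages.get("loh", True))
        if cnv_inputs is not None:
            rep["cnv"] = _cnv_section(cnv_inputs, emb, father_id, mother_id,
                                      rep, config)
            rep["summary"]["cnv_calls"] = len(rep["cnv"]["calls"])
        if repeats is not None:
            rep["str_concordance"] = _str_section(repeats, emb.sample_id,
                                                  father_id, mother_id)
            rep["summary"]["str_loci"] = len(rep["str_concordance"])
        if config.get("conditions"):
            rep["condition_status"] = {
                c["gene"]: _condition_status(rep, c["gene"], c["mode"])
                for c in config["conditions"]
            }
        reports.append(rep)

    out = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "family": {"father": father_id, "mother": mother_id,
                   "embryos": [e.sample_id for e in embryos]},
        "reports": reports,
        "cohort_summary": summarize_counts(reports),
    }
    if config.get("out_dir"):
        import os

        os.makedirs(config["out_dir"], exist_ok=True)
        with open(os.path.join(config["out_dir"], "report.json"), "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True, default=str)
        with open(os.path.join(config["out_dir"], "report.txt"), "w") as fh:
            fh.write(render_text(out))
        for rep in reports:
            _write_candidate_tsv(
                os.path.join(config["out_dir"], f"{rep['embryo_id']}_candidates.tsv"), rep)
    return out


_TSV_SECTIONS = ("dominant", "recessive_affected", "recessive_carriers",
                 "dropout_suspects", "x_linked_affected", "x_linked_carriers",
                 "de_novo_retained", "de_novo_rejected", "failsafe")


def _write_candidate_tsv(path, rep) -> None:
    """Candidate tables as one TSV with the full filter trail per row."""
    cols = ["section", "chrom", "pos", "ref", "alt", "mode", "subfilter", "grade",
            "origin", "gene", "vaf", "qd", "reject_reason", "trail"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for section in _TSV_SECTIONS:
            for row in rep.get(section, []):
                trail = ";".join(f"{name}={'pass' if ok else 'fail'}"
                                 for name, ok in row["trail"])
                fh.write("\t".join(str(x) for x in [
                    section, row["chrom"], row["pos"], row["ref"], row["alt"],
                    row["mode"], row["subfilter"], row["grade"], row["origin"],
                    row["gene"], row["vaf"], row["qd"],
                    row.get("reject_reason", ""), trail,
                ]) + "\n")


def _cnv_section(cnv_inputs, emb, father_id, mother_id, rep, config):
    bins, dosage, ccfg, father_calls, mother_calls, sexes = cnv_inputs
    eid = emb.sample_id
    parental_cnv_intervals = [(c.chrom, c.start, c.end)
                              for c in father_calls + mother_calls]
    scored = cnvmod.score_bins(list(bins), eid, [father_id, mother_id], ccfg, sexes,
                               known_control_cnvs=parental_cnv_intervals)
    calls = cnvmod.call_cnvs(scored, eid, [father_id, mother_id], ccfg)
    cnvmod.assign_dosage(calls, dosage)
    cnvmod.trio_cnv_inheritance(calls, father_calls, mother_calls)
    svs = []
    for sv in config.get("sv_calls", []):
        ext = cnvmod.ingest_sv_calls(sv["path"], sv.get("source", "external"))
        cnvmod.assign_dosage([c for c in ext if c.state in ("deletion", "duplication")], dosage)
        cnvmod.trio_cnv_inheritance([c for c in ext if c.state in ("deletion", "duplication")],
                                    father_calls, mother_calls)
        svs.extend(ext)

    class _Hit:
        def __init__(self, row):
            self.gene = row["gene"]
            self.origin = row["origin"]

    recessive_targets = [c for c in calls + [s for s in svs if s.state == "deletion"]
                         if c.dosage_evidence == "autosomal_recessive_gene"
                         or c.state == "deletion"]
    het_rows = rep["recessive_carriers"] + rep["dominant"]
    compound = cnvmod.crosscheck_recessive(recessive_targets, [_Hit(r) for r in het_rows])

    def call_row(c):
        return {
            "chrom": c.chrom, "start": c.start, "end": c.end, "state": c.state,
            "mean_ratio": None if np.isnan(c.mean_ratio) else round(c.mean_ratio, 3),
            "mean_z": None if c.mean_z is None or np.isnan(c.mean_z) else round(c.mean_z, 2),
            "n_bins": c.n_bins, "dosage_category": c.dosage_category,
            "dosage_evidence": c.dosage_evidence, "inheritance": c.inheritance,
            "genes": list(c.genes), "source": c.source, "sv_type": c.sv_type,
        }

    return {
        "calls": [call_row(c) for c in calls],
        "sv": [call_row(c) for c in svs],
        "compound_cnv_snv": [
            {"gene": f.gene, "cnv": call_row(f.cnv),
             "snv_gene": f.snv.gene, "snv_origin": f.snv.origin}
            for f in compound
        ],
    }


def _str_section(repeats, embryo_id, father_id, mother_id):
    by = {}
    for g in repeats:
        by[(g.locus, g.sample_id)] = g
    section = []
    for locus, thresh in strmod.DEFAULT_PANEL.items():
        emb = by.get((locus, embryo_id))
        if emb is None:
            continue
        father = by.get((locus, father_id))
        mother = by.get((locus, mother_id))
        labels = strmod.transmission_concordance(emb, father, mother)
        path_flags = strmod.flag_pathogenic_repeats(emb)
        section.append({
            "locus": locus, "alleles": list(emb.alleles),
            "range_class": path_flags, "transmission": labels,
        })
    return section


def summarize_counts(reports) -> dict:
    """Mean and SD of every per-embryo summary count across the cohort."""
    if not reports:
        return {}
    keys = sorted({k for r in reports for k in r.get("summary", {})})
    out = {}
    for k in keys:
        values = [r["summary"].get(k, 0) for r in reports]
        out[k] = {
            "mean": round(float(np.mean(values)), 3),
            "sd": round(float(np.std(values, ddof=0)), 3),
            "n": len(values),
        }
        if len(values) == 1:
            out[k]["notice"] = "single embryo; SD is 0 by definition"
    return out


def render_text(out: dict) -> str:
    """Human-readable report."""
    lines = [f"embryoscreen report (schema v{out['schema_version']})",
             f"family: father={out['family']['father']} mother={out['family']['mother']}"]
    for rep in out["reports"]:
        lines.append("")
        lines.append(f"== embryo {rep['embryo_id']} (sex {rep['sex']}) ==")
        for k, v in sorted(rep["summary"].items()):
            lines.append(f"  {k}: {v}")
        if "condition_status" in rep:
            for gene, status in sorted(rep["condition_status"].items()):
                lines.append(f"  condition {gene}: {status}")
    lines.append("")
    lines.append("cohort summary (mean +- sd):")
    for k, v in sorted(out["cohort_summary"].items()):
        lines.append(f"  {k}: {v['mean']} +- {v['sd']} (n={v['n']})")
    return "\n".join(lines) + "\n"
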