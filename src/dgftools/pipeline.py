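"""End-to-end pipeline orchestration over an on-disk workspace.

A workspace directory holds the inputs (genome.fa, footprints_<cell>.bed,
conservation.bedgraph, genes.tsv, regulated_genes.tsv, peak_manifest.tsv and
optionally motifs.transfac / motifs.jaspar); outputs and a JSON run manifest
land in <workspace>/output. Stages run in dependency order (scan -> call ->
annotate / enrich / coreg / common); a resumed run skips stages whose
recorded outputs are still present.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional

import pandas as pd

from . import io as dio
from .config import AnalysisConfig
from .context import (assign_categories, category_counts, coverage_curve,
                      random_gene_control, tss_profile)
from .coreg import (RegulatedGene, footprints_near_regulated_tss,
                    results_table, screen_factors)
from .footprints import (call_footprints, footprints_to_intervalset,
                         summarize_callset, supporting_footprints, write_audit)
from .intervals import GenomicInterval, IntervalSet
from .motifs import (MotifHit, hits_to_intervalset, read_motifs, scan_genome,
                     synthetic_mre_motif)
from .multicell import CellFootprintPanel, common_footprints, random_panel_control
from .stats import adjust_results, monte_carlo_test

log = logging.getLogger("dgftools")

STAGES = ("scan", "call", "annotate", "enrich", "coreg", "common")


class PipelineError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(f"stage {stage}: missing input file {path}")
    return path


class Workspace:
    def __init__(self, root: str) -> None:
        self.root = root
        self.outdir = os.path.join(root, "output")
        os.makedirs(self.outdir, exist_ok=True)

    def inp(self, name: str) -> str:
        return os.path.join(self.root, name)

    def out(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def cell_types(self) -> List[str]:
        cells = []
        for fn in sorted(os.listdir(self.root)):
            if fn.startswith("footprints_") and fn.endswith(".bed"):
                cells.append(fn[len("footprints_"):-len(".bed")])
        return cells


class RunManifest:
    def __init__(self, path: str) -> None:
        self.path = path
        self.data: dict = {"version": dio.__version__, "stages": {}, "inputs": {}}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)

    def record_stage(self, stage: str, outputs: List[str]) -> None:
        self.data["stages"][stage] = {
            "outputs": outputs,
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.save()

    def stage_done(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        return bool(rec) and all(os.path.exists(p) for p in rec["outputs"])

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _load_motifs(ws: Workspace, config: AnalysisConfig):
    for fn, fmt in (("motifs.transfac", "transfac"), ("motifs.jaspar", "jaspar")):
        path = ws.inp(fn)
        if os.path.exists(path):
            models = read_motifs(path, fmt)
            return [m.with_cutoffs(config.core_cutoff, config.matrix_cutoff) for m in models]
    log.info("no motif file in workspace; using the built-in synthetic MRE motif")
    return [synthetic_mre_motif(core_cutoff=config.core_cutoff,
                                matrix_cutoff=config.matrix_cutoff)]


def _read_hits(path: str) -> List[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(r.chrom, int(r.start), int(r.end), r.strand, r.motif_id,
                 float(r.matrix_score), float(r.core_score))
        for r in df.itertuples()
    ]


def _calls_bed_to_set(path: str, label: str) -> IntervalSet:
    return dio.read_bed(path, min_fields=6, label=label)


def _category_interval_sets(genes, config: AnalysisConfig) -> Dict[str, IntervalSet]:
    proms, exons, utr3 = [], [], []
    for g in genes:
        ps, pe = g.promoter(config.promoter_upstream, config.promoter_downstream)
        proms.append(GenomicInterval(g.chrom, ps, pe, name=g.gene_id))
        exons.extend(GenomicInterval(g.chrom, s, e, name=g.gene_id) for s, e in g.exons)
        utr3.extend(GenomicInterval(g.chrom, s, e, name=g.gene_id) for s, e in g.utr3)
    return {
        "promoter": IntervalSet(proms, label="promoter"),
        "exon": IntervalSet(exons, label="exon"),
        "3utr": IntervalSet(utr3, label="3utr"),
    }


def run_pipeline(
    config: AnalysisConfig,
    workspace: str,
    stages: Optional[List[str]] = None,
    resume: bool = False,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run the requested stages (default: all) over a workspace; returns the
    run manifest. With ``resume=True``, completed stages with intact outputs
    are skipped."""
    ws = Workspace(workspace)
    manifest = RunManifest(ws.out("manifest.json"))
    seed = config.seed if seed is None else seed
    manifest.data["seed"] = seed
    manifest.data["config"] = config.to_dict()
    todo = list(stages) if stages else list(STAGES)
    for st in todo:
        if st not in STAGES:
            raise PipelineError(f"unknown stage {st!r}")

    genome_path = _require(ws.inp("genome.fa"), "scan")
    for name in ("genome.fa", "conservation.bedgraph", "genes.tsv"):
        p = ws.inp(name)
        if os.path.exists(p):
            manifest.data["inputs"][name] = _sha256(p)
    manifest.save()

    cells = ws.cell_types()
    if not cells:
        raise PipelineError("no footprints_<cell>.bed files found in workspace")

    motifs = _load_motifs(ws, config)
    motif_map = {m.motif_id: m for m in motifs}

    if "scan" in todo and not (resume and manifest.stage_done("scan")):
        log.info("stage=scan seed=%d motifs=%s", seed, [m.motif_id for m in motifs])
        genome = dio.read_fasta(genome_path)
        hits = scan_genome(genome, motifs)
        df = pd.DataFrame(
            [(h.chrom, h.start, h.end, h.strand, h.motif_id, h.matrix_score, h.core_score)
             for h in hits],
            columns=["chrom", "start", "end", "strand", "motif_id", "matrix_score", "core_score"],
        )
        df.to_csv(ws.out("hits.tsv"), sep="\t", index=False)
        dio.write_bed(hits_to_intervalset(hits, "hits"), ws.out("hits.bed"),
                      params={"stage": "scan"})
        manifest.record_stage("scan", [ws.out("hits.tsv"), ws.out("hits.bed")])

    if "call" in todo and not (resume and manifest.stage_done("call")):
        log.info("stage=call cells=%s overlap>=%.2f conservation>=%.2f",
                 cells, config.overlap_threshold, config.conservation_threshold)
        hits = _read_hits(_require(ws.out("hits.tsv"), "call"))
        track = dio.read_conservation(_require(ws.inp("conservation.bedgraph"), "call"),
                                      default=config.conservation_default)
        outputs = []
        summaries = []
        for cell in cells:
            fps = dio.read_bed(ws.inp(f"footprints_{cell}.bed"), label=cell)
            calls, audit = call_footprints(hits, fps, track, config,
                                           motifs=motif_map, cell_type=cell)
            bed = ws.out(f"calls_{cell}.bed")
            dio.write_bed(
                IntervalSet(
                    (GenomicInterval(c.chrom, c.start, c.end, strand=c.strand,
                                     name=c.motif_id,
                                     score=float(int(round(c.conservation * 1000))))
                     for c in calls),
                    label=cell),
                bed, params={"stage": "call", "cell": cell})
            write_audit(audit, ws.out(f"audit_{cell}.tsv"))
            support = supporting_footprints(calls, fps, label=cell)
            dio.write_bed(support, ws.out(f"support_{cell}.bed"),
                          params={"stage": "call", "cell": cell, "kind": "supporting-dnase"})
            summaries.append({"cell": cell, **summarize_callset(hits, fps, calls, config)})
            outputs += [bed, ws.out(f"audit_{cell}.tsv"), ws.out(f"support_{cell}.bed")]
        pd.DataFrame(summaries).to_csv(ws.out("call_summary.tsv"), sep="\t", index=False)
        manifest.record_stage("call", outputs + [ws.out("call_summary.tsv")])

    genes = dio.read_gene_table(_require(ws.inp("genes.tsv"), "annotate"))
    regulated_rows = []
    if os.path.exists(ws.inp("regulated_genes.tsv")):
        regulated_rows = dio.read_regulated_genes(ws.inp("regulated_genes.tsv"))

    if "annotate" in todo and not (resume and manifest.stage_done("annotate")):
        log.info("stage=annotate bins=%dbp window=%dbp", config.tss_bin_width, config.tss_window)
        outputs = []
        for cell in cells:
            calls = _calls_bed_to_set(_require(ws.out(f"calls_{cell}.bed"), "annotate"), cell)
            mids = [(iv.chrom, iv.midpoint) for iv in calls]
            counts = category_counts(assign_categories(mids, genes, config))
            total = max(1, sum(counts.values()))
            pd.DataFrame(
                [{"category": k, "count": v, "fraction": v / total} for k, v in counts.items()]
            ).to_csv(ws.out(f"categories_{cell}.tsv"), sep="\t", index=False)
            prof = tss_profile(mids, genes, config)
            bins, vals = prof.as_arrays()
            pd.DataFrame({"bin_start": bins, "count": vals}).to_csv(
                ws.out(f"tss_profile_{cell}.tsv"), sep="\t", index=False)
            outputs += [ws.out(f"categories_{cell}.tsv"), ws.out(f"tss_profile_{cell}.tsv")]
            if regulated_rows:
                reg_ids = [g for g, _, _ in regulated_rows]
                cc = coverage_curve(mids, reg_ids, genes, label="regulated")
                ctrl_size = min(100, len(genes))
                ctrl = random_gene_control(mids, genes, sample_size=ctrl_size,
                                           repetitions=10, seed=seed)
                pd.DataFrame({
                    "distance": cc.distances, "regulated": cc.fractions,
                    "random_control": ctrl.fractions,
                }).to_csv(ws.out(f"coverage_{cell}.tsv"), sep="\t", index=False)
                outputs.append(ws.out(f"coverage_{cell}.tsv"))
        manifest.record_stage("annotate", outputs)

    if "enrich" in todo and not (resume and manifest.stage_done("enrich")):
        log.info("stage=enrich repetitions=%d", config.mc_repetitions)
        queries = _category_interval_sets(genes, config)
        rows = []
        results, groups = [], []
        for cell in cells:
            pool = dio.read_bed(ws.inp(f"footprints_{cell}.bed"), label=cell)
            case = dio.read_bed(_require(ws.out(f"support_{cell}.bed"), "enrich"),
                                min_fields=6, label=cell)
            if len(case) == 0 or len(case) >= len(pool):
                log.warning("cell %s: degenerate case/pool sizes, skipping enrichment", cell)
                continue
            for qname, query in queries.items():
                res = monte_carlo_test(case, pool, query,
                                       repetitions=config.mc_repetitions,
                                       seed=seed, alternative=config.mc_alternative)
                res.label = f"{cell}:{qname}"
                results.append(res)
                groups.append(cell)
        adjust_results(results, groups)  # per-cell FDR family
        for res in results:
            c = res.contingency
            rows.append({
                "label": res.label, "X": c.X, "Y": c.Y, "n": c.n, "m": c.m,
                "r": res.ratio, "direction": res.direction, "p": res.p_value,
                "p_adjusted": res.p_adjusted, "repetitions": res.repetitions,
                "seed": seed,
            })
        pd.DataFrame(rows).to_csv(ws.out("enrichment.tsv"), sep="\t", index=False)
        manifest.record_stage("enrich", [ws.out("enrichment.tsv")])

    if "coreg" in todo and not (resume and manifest.stage_done("coreg")):
        manifest_path = ws.inp("peak_manifest.tsv")
        if regulated_rows and os.path.exists(manifest_path) and cells:
            cell = cells[0]
            log.info("stage=coreg cell=%s window=%dbp", cell, config.coreg_window)
            pool = dio.read_bed(ws.inp(f"footprints_{cell}.bed"), label=cell)
            case = dio.read_bed(ws.out(f"support_{cell}.bed"), min_fields=6, label=cell)
            regulated = [RegulatedGene(g, d, r) for g, d, r in regulated_rows]
            pos, neg = footprints_near_regulated_tss(case, regulated, genes,
                                                     window=config.coreg_window)
            peaks = {name: dio.read_bed(path, label=name)
                     for name, path in dio.read_peak_manifest(manifest_path)}
            res = screen_factors(peaks, pos, neg, pool, config, seed=seed)
            results_table(res).to_csv(ws.out("coreg_screen.tsv"), sep="\t", index=False)
            manifest.record_stage("coreg", [ws.out("coreg_screen.tsv")])
        else:
            log.info("stage=coreg skipped: missing regulated genes or peak manifest")
            manifest.record_stage("coreg", [])

    if "common" in todo and not (resume and manifest.stage_done("common")):
        log.info("stage=common min_overlap=%dbp flank=%dbp",
                 config.min_cross_cell_overlap, config.midpoint_flank)
        panel = CellFootprintPanel([
            (cell, _calls_bed_to_set(_require(ws.out(f"calls_{cell}.bed"), "common"), cell))
            for cell in cells
        ]) if len(cells) >= 2 else None
        outputs = []
        if panel is not None:
            common, steps = common_footprints(panel, config.min_cross_cell_overlap,
                                              config.midpoint_flank)
            dio.write_bed(common, ws.out("common_footprints.bed"),
                          params={"stage": "common"})
            pd.DataFrame(steps, columns=["cell", "retained"]).to_csv(
                ws.out("common_steps.tsv"), sep="\t", index=False)
            pools = [(cell, dio.read_bed(ws.inp(f"footprints_{cell}.bed"), label=cell))
                     for cell in cells]
            sizes = [min(len(panel.cells[i][1]), len(pools[i][1])) for i in range(len(cells))]
            if all(s > 0 for s in sizes):
                curves = random_panel_control(pools, sizes, repetitions=10, seed=seed,
                                              min_overlap=config.min_cross_cell_overlap,
                                              flank=config.midpoint_flank)
                rows = [
                    {"repetition": i, "cell": cell, "retained": kept}
                    for i, curve in enumerate(curves) for cell, kept in curve
                ]
                pd.DataFrame(rows).to_csv(ws.out("common_random_control.tsv"),
                                          sep="\t", index=False)
                outputs.append(ws.out("common_random_control.tsv"))
            outputs += [ws.out("common_footprints.bed"), ws.out("common_steps.tsv")]
        manifest.record_stage("common", outputs)

    return manifest
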