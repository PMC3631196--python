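"""End-to-end orchestration: simulate -> preprocess -> annotate -> novel ->
diffexp -> qpcr -> report, with a machine-readable run manifest and read-count
conservation checks at every stage.  Reruns with the same config and seed
reproduce byte-identical tables (the manifest's timestamp is the one
deliberately non-deterministic field)."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationResult, MiRNACountRow, annotate_tags
from .diffexp import TestConfig, call_de, venn_classify
from .novel import HairpinCall, NovelMiRNA, predict_novel
from .preprocess import (
    LibraryAccounting,
    SmallRNATag,
    clean_reads,
    collapse,
    subtract_contaminants,
    write_collapsed_fasta,
)
from .qpcr import concordance, ddct
from .report import annotation_summary, top_n_table, venn_summary
from .simulate import (
    DEFAULT_ADAPTER,
    ReferenceBundle,
    SimResult,
    default_config,
    make_reference_bundle,
    simulate_ct_table,
    simulate_libraries,
    write_bundle,
    write_libraries,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "esimir_run"
    seed: int = 1
    # reference bundle
    n_known: int = 30
    n_kc: int = 10
    n_novel_loci: int = 10
    n_contaminants: int = 20
    genome_len: int = 30_000
    # simulation
    depth: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    sim_overrides: dict = field(default_factory=dict)
    # preprocessing
    min_overlap: int = 6
    min_len: int = 15
    max_len: int = 26
    # novel prediction
    dg_max: float = -15.0
    flank: int = 70
    max_genome_hits: int = 10
    min_tag_paired: int = 14
    # differential expression
    alpha: float = 1e-4
    correction: str = "bonferroni"
    rule: str = "all"
    # reporting / validation
    top_n: int = 20
    qpcr_targets: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: ReferenceBundle
    sim: SimResult
    tags: list[SmallRNATag]
    annotation: AnnotationResult
    hairpin_calls: list[HairpinCall]
    novel_mirnas: list[NovelMiRNA]
    accounting: dict[str, LibraryAccounting]
    de_records: list
    qpcr_table: pd.DataFrame
    qpcr_agreement: float | None
    manifest: dict
    outdir: Path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # --- simulate -----------------------------------------------------------
    try:
        bundle = make_reference_bundle(
            config.n_known, config.n_kc, config.n_novel_loci,
            config.n_contaminants, seed=config.seed,
            genome_len=config.genome_len,
        )
        sim_cfg = default_config(
            bundle, depth=config.depth, seed=config.seed + 1000,
            adapter=config.adapter, **config.sim_overrides,
        )
        sim = simulate_libraries(bundle, sim_cfg)
        write_bundle(bundle, out / "refs")
        write_libraries(sim, out / "reads")
        sim_cfg.to_yaml(out / "reads" / "sim_config.yaml")
        manifest["stages"]["simulate"] = {
            "reads_female": len(sim.reads_female),
            "reads_male": len(sim.reads_male),
            "truth_rows": len(sim.truth),
        }
        assert len(sim.truth) == len(sim.reads_female) + len(sim.reads_male)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # --- preprocess ---------------------------------------------------------
    try:
        inserts, stats, contam = {}, {}, {}
        for lib, reads in (("female", sim.reads_female), ("male", sim.reads_male)):
            inserts[lib], stats[lib] = clean_reads(
                (seq for _rid, seq in reads), sim_cfg.adapter,
                config.min_overlap, config.min_len, config.max_len,
            )
        tags_all = collapse(inserts["female"], inserts["male"])
        assert sum(t.count_female for t in tags_all) == len(inserts["female"])
        assert sum(t.count_male for t in tags_all) == len(inserts["male"])
        tags, contaminant_hits = subtract_contaminants(tags_all, bundle.contaminants)
        contam_seqs = {seq for seq, _n, _c in contaminant_hits}
        by_seq = {t.sequence: t for t in tags_all}
        for lib in ("female", "male"):
            contam[lib] = sum(
                getattr(by_seq[s], f"count_{lib}") for s in contam_seqs
            )
        for lib in ("female", "male"):
            write_collapsed_fasta(out / f"collapsed_{lib}.fa", tags, lib)
        _write_tsv(
            pd.DataFrame(contaminant_hits, columns=["tag", "ref", "class"]),
            out / "contaminant_hits.tsv",
        )
        manifest["stages"]["preprocess"] = {
            lib: dataclasses.asdict(stats[lib]) | {"contaminant_reads": contam[lib]}
            for lib in ("female", "male")
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    # --- annotate -----------------------------------------------------------
    try:
        ann = annotate_tags(tags, bundle.mature, bundle.precursor_by_mature,
                            bundle.genome)
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(r) for r in ann.records]),
            out / "annotation.tsv",
        )
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(r) for r in ann.count_rows]),
            out / "mirna_counts.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mature": s.mature_name,
                        "precursor": s.precursor_name,
                        "count_female": s.count_female,
                        "count_male": s.count_male,
                        "star_mature_ratio": s.ratio,
                        "dominant_star": s.dominant,
                    }
                    for s in ann.star_records
                ]
            ),
            out / "star_records.tsv",
        )
        _write_tsv(
            pd.DataFrame([ann.first_base]) if ann.first_base else pd.DataFrame(),
            out / "first_base_composition.tsv",
        )
        manifest["stages"]["annotate"] = {
            "tags_in": len(tags),
            "records": len(ann.records),
            "mirna_rows": len(ann.count_rows),
            "star_pairs": len(ann.star_records),
            "unassigned": len(ann.unassigned),
        }
        assert len(ann.records) == len(tags), "every clean tag needs a status"
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    # --- novel --------------------------------------------------------------
    try:
        calls, novels = predict_novel(
            ann.unassigned, bundle.genome, dg_max=config.dg_max,
            flank=config.flank, max_hits=config.max_genome_hits,
            min_tag_paired=config.min_tag_paired,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "tag": c.tag,
                        "contig": c.locus.contig,
                        "start": c.locus.start,
                        "end": c.locus.end,
                        "strand": c.locus.strand,
                        "dg": c.dg,
                        "decision": c.decision,
                        "reason": c.reason,
                        "structure": c.structure,
                    }
                    for c in calls
                ]
            ),
            out / "hairpin_calls.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "name": nv.name,
                        "contig": nv.locus.contig,
                        "start": nv.locus.start,
                        "end": nv.locus.end,
                        "strand": nv.locus.strand,
                        "tag": nv.tag,
                        "dg": nv.dg,
                        "count_female": nv.count_female,
                        "count_male": nv.count_male,
                    }
                    for nv in novels
                ]
            ),
            out / "novel_mirnas.tsv",
        )
        with open(out / "novel_precursors.fa", "w") as fh:
            for nv in novels:
                fh.write(f">{nv.name} dG={nv.dg}\n{nv.window}\n{nv.structure}\n")
        manifest["stages"]["novel"] = {
            "candidate_windows": len(calls),
            "accepted": sum(c.accepted for c in calls),
            "novel_mirnas": len(novels),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("novel", exc) from exc

    # --- accounting ---------------------------------------------------------
    try:
        status_by_tag = {r.tag: r.status for r in ann.records}
        novel_tags = {nv.tag for nv in novels}
        accounting: dict[str, LibraryAccounting] = {}
        for lib in ("female", "male"):
            get = lambda t: getattr(t, f"count_{lib}")  # noqa: E731
            cats = {k: 0 for k in ("conserved miRNA candidates",
                                   "known miRNA candidates",
                                   "specific miRNA candidates",
                                   "unknown small RNAs")}
            for t in tags:
                status = status_by_tag[t.sequence]
                if status in ("known", "star"):
                    cats["conserved miRNA candidates"] += get(t)
                elif status == "KC":
                    cats["known miRNA candidates"] += get(t)
                elif t.sequence in novel_tags:
                    cats["specific miRNA candidates"] += get(t)
                else:
                    cats["unknown small RNAs"] += get(t)
            acct = LibraryAccounting(
                library=lib,
                raw_reads=stats[lib].raw_reads,
                after_filter_reads=stats[lib].filtered_reads,
                mappable_reads=stats[lib].filtered_reads - contam[lib],
                categories=cats,
            )
            acct.validate()
            accounting[lib] = acct
            _write_tsv(annotation_summary(acct), out / f"accounting_{lib}.tsv")
        manifest["stages"]["accounting"] = {
            lib: {"mappable_reads": accounting[lib].mappable_reads}
            for lib in accounting
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("accounting", exc) from exc

    # --- diffexp ------------------------------------------------------------
    try:
        n1 = accounting["female"].mappable_reads
        n2 = accounting["male"].mappable_reads
        de_rows = list(ann.count_rows) + [
            MiRNACountRow(
                name=nv.name, representative=nv.tag,
                count_female=nv.count_female, count_male=nv.count_male,
                status="novel",
            )
            for nv in novels
        ]
        de_records = call_de(
            de_rows, n1, n2,
            TestConfig(config.alpha, config.correction, config.rule),
        )
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(r) for r in de_records]),
            out / "diffexp.tsv",
        )
        _write_tsv(venn_summary(venn_classify(de_rows)), out / "venn.tsv")
        _write_tsv(top_n_table(de_rows, n1, n2, config.top_n),
                   out / f"top{config.top_n}.tsv")
        manifest["stages"]["diffexp"] = {
            "rows": len(de_records),
            "co_expressed": sum(r.venn == "co_expressed" for r in de_records),
            "significant": sum(r.significant for r in de_records),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexp", exc) from exc

    # --- qpcr validation arm ------------------------------------------------
    try:
        sig = [r for r in de_records if r.significant][: config.qpcr_targets]
        agreement = None
        qpcr_df = pd.DataFrame()
        if sig:
            true_folds = {
                r.name: max(r.cpm_male, 0.5) / max(r.cpm_female, 0.5) for r in sig
            }
            ct = simulate_ct_table(true_folds, seed=config.seed + 2000)
            res = ddct(ct, calibrator="female")
            qpcr_df = res
            folds = {
                row.target: row.fold
                for row in res.itertuples()
                if row.sample == "male"
            }
            _conc, agreement = concordance(folds, true_folds)
            _write_tsv(res, out / "qpcr_folds.tsv")
            _write_tsv(_conc, out / "qpcr_concordance.tsv")
        manifest["stages"]["qpcr"] = {
            "targets": len(sig),
            "direction_agreement": agreement,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("qpcr", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config, bundle=bundle, sim=sim, tags=tags, annotation=ann,
        hairpin_calls=calls, novel_mirnas=novels, accounting=accounting,
        de_records=de_records, qpcr_table=qpcr_df, qpcr_agreement=agreement,
        manifest=manifest, outdir=out,
    )
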