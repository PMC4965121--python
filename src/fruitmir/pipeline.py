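"""End-to-end orchestration from a single YAML config.

Stages (in order): simulate -> preprocess -> annotate -> known -> novel ->
targets -> degradome -> quantify -> report.  Each stage reads its inputs
from and writes its outputs to the run directory in plain-text formats
(FASTA/FASTQ/GFF3/TSV), so any stage can be skipped or the run resumed; a
manifest records the seed, a parameter hash and per-stage record counts so
the read accounting is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, annotate, degradome, known, novel, preprocess
from . import quantify, simulate, targets
from ._seq import dna_to_rna, rna_to_dna
from .io import (read_fasta, read_fastq, read_gff3, read_tsv, write_fasta,
                 write_fastq, write_gff3, write_tsv)

STAGES = (
    "simulate", "preprocess", "annotate", "known", "novel", "targets",
    "degradome", "quantify", "report",
)


def default_config(outdir: str | Path, seed: int = 0) -> dict:
    return {
        "seed": seed,
        "outdir": str(outdir),
        "simulate": {"enabled": True},
        "preprocess": {
            "adapter3": simulate.ADAPTER3,
            "adapter5": simulate.ADAPTER5,
            "quality_threshold": 20.0,
            "min_length": 18,
            "max_length": 30,
        },
        "annotate": {"max_mismatches": 0, "mirna_max_mismatches": 1},
        "known": {"max_mismatches": 2},
        "novel": dataclasses.asdict(novel.NovelCriteria()),
        "targets": dataclasses.asdict(targets.TargetRules()),
        "degradome": {"min_peak": 1, "background_rate": 0.05},
        "quantify": {
            "reference_gene": "5S_rRNA",
            "target_gene": "miR156",
            "calibrator_sample": "fruit_35DAFB",
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config(cfg.get("outdir", "."), cfg.get("seed", 0))
    for key, val in cfg.items():
        if isinstance(val, Mapping) and key in base:
            base[key].update(val)
        else:
            base[key] = val
    return base


def _param_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _tags_to_fasta_records(tags):
    return [(f"t{i + 1:06d}_x{t.count}", t.sequence) for i, t in enumerate(tags)]


def _tags_from_fasta(path):
    recs = read_fasta(path)
    out = []
    for name in recs:
        count = int(name.rsplit("_x", 1)[1])
        out.append(preprocess.SmallRNATag(recs[name], count))
    return out


def run_pipeline(
    config: Mapping,
    skip: tuple[str, ...] = (),
    resume: bool = False,
) -> dict:
    """Execute the pipeline; returns a manifest dict (also written to
    ``manifest.json``).  ``skip`` omits stages; ``resume`` re-uses stage
    outputs that already exist."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameter_hash": _param_hash(config),
        "stages": {},
    }

    def done(stage: str, marker: str) -> bool:
        if stage in skip:
            return True
        return resume and (outdir / marker).exists()

    counts: dict[str, int] = {}

    # ---- simulate -----------------------------------------------------
    if config.get("simulate", {}).get("enabled", False) and not done(
        "simulate", "reads.fastq"
    ):
        sim_cfg = {
            k: v for k, v in config["simulate"].items() if k != "enabled"
        }
        spec = simulate.SimulationSpec(seed=seed, **sim_cfg)
        genome0, features = simulate.generate_genome(spec)
        genome, truth = simulate.plant_hairpins(genome0, spec, features)
        known_db = simulate.make_known_mirna_db(
            seed, spec.n_known_mirnas,
            avoid=[h.mature_seq for h in truth.planted_hairpins],
        )
        reads, sidecar = simulate.simulate_srna_library(
            truth, spec, genome, features, known_db
        )
        write_fasta(outdir / "genome.fa", sorted(genome.items()))
        write_gff3(outdir / "annotation.gff3", features)
        write_fasta(outdir / "known_mature.fa", sorted(known_db.items()))
        write_fastq(outdir / "reads.fastq", reads)
        write_tsv(outdir / "read_truth.tsv", sidecar)
        write_tsv(outdir / "hairpin_truth.tsv", truth.hairpin_frame())
        mirnas = {
            h.hairpin_id: h.mature_seq
            for h in truth.planted_hairpins
            if h.label == "pass"
        }
        rules = targets.TargetRules(**config["targets"])
        transcripts, t_truth = simulate.simulate_transcriptome_with_targets(
            mirnas, rules, seed
        )
        write_fasta(outdir / "transcripts.fa", sorted(transcripts.items()))
        write_tsv(
            outdir / "target_truth.tsv",
            pd.DataFrame([dataclasses.asdict(t) for t in t_truth.planted_targets]),
        )
        write_tsv(
            outdir / "cleavage_truth.tsv",
            pd.DataFrame([dataclasses.asdict(c) for c in t_truth.planted_cleavages]),
        )
        deg_reads = simulate.simulate_degradome(
            transcripts, t_truth.planted_cleavages,
            background_rate=config["degradome"].get("background_rate", 0.0),
            seed=seed,
        )
        write_fasta(
            outdir / "degradome.fa",
            [(f"d{i + 1:06d}", r) for i, r in enumerate(deg_reads)],
        )
        samples = ["fruit_35DAFB", "fruit_55DAFB", "fruit_75DAFB",
                   "fruit_90DAFB", "fruit_105DAFB"]
        effects = {s: e for s, e in zip(samples, (0.0, 0.8, 1.5, 0.6, -0.5))}
        ct = simulate.simulate_ct_table(
            {
                "samples": samples, "replicates": 9,
                "target_gene": config["quantify"]["target_gene"],
                "reference_gene": config["quantify"]["reference_gene"],
            },
            effects, noise_sd=0.2, seed=seed,
        )
        write_tsv(outdir / "ct_table.tsv", ct)
        counts["simulated_reads"] = len(reads)
        manifest["stages"]["simulate"] = {"reads": len(reads)}

    # ---- preprocess ---------------------------------------------------
    if not done("preprocess", "tags.fa"):
        pc = config["preprocess"]
        raw = read_fastq(outdir / "reads.fastq")
        clean, summary = preprocess.filter_reads(
            raw, pc["adapter3"], pc["adapter5"],
            quality_threshold=pc.get("quality_threshold", 20.0),
            min_length=pc.get("min_length", 18),
            max_length=pc.get("max_length", 30),
        )
        tags = preprocess.collapse_tags(clean)
        comp = preprocess.composition_stats(tags)
        write_tsv(outdir / "filter_summary.tsv", summary.to_frame())
        write_fasta(outdir / "tags.fa", _tags_to_fasta_records(tags))
        write_tsv(
            outdir / "length_distribution.tsv",
            pd.DataFrame(
                sorted(comp.length_counts_redundant.items()),
                columns=["length", "redundant_count"],
            ),
        )
        first_nt = pd.DataFrame(
            [(L, nt, n) for (L, nt), n in sorted(comp.first_nt_redundant.items())],
            columns=["length", "first_nt", "redundant_count"],
        )
        write_tsv(outdir / "first_nt.tsv", first_nt)
        manifest["stages"]["preprocess"] = {
            "total_reads": summary.total_reads,
            "clean_reads": summary.clean_reads,
            "unique_tags": len(tags),
        }

    # ---- annotate -----------------------------------------------------
    if not done("annotate", "category_summary.tsv"):
        genome = read_fasta(outdir / "genome.fa")
        features = read_gff3(outdir / "annotation.gff3")
        known_db = read_fasta(outdir / "known_mature.fa")
        tags = _tags_from_fasta(outdir / "tags.fa")
        ac = config["annotate"]
        hits = annotate.map_tags(tags, genome, ac.get("max_mismatches", 0))
        assignment, summary = annotate.classify_tags(
            tags, hits, features, known_db,
            mirna_max_mismatches=ac.get("mirna_max_mismatches", 1),
        )
        write_tsv(outdir / "category_summary.tsv", summary.table)
        per_tag = pd.DataFrame(
            [(t.sequence, t.count, assignment[t.sequence]) for t in tags],
            columns=["sequence", "count", "category"],
        )
        write_tsv(outdir / "tag_categories.tsv", per_tag)
        hit_rows = pd.DataFrame(
            [dataclasses.asdict(h) for h in hits],
            columns=["tag_sequence", "scaffold", "start", "end", "strand",
                     "mismatches"],
        )
        write_tsv(outdir / "genome_hits.tsv", hit_rows)
        manifest["stages"]["annotate"] = {
            "tags": len(tags), "genome_hits": len(hits),
        }

    # ---- known --------------------------------------------------------
    if not done("known", "known_hits.tsv"):
        known_db = read_fasta(outdir / "known_mature.fa")
        tags = _tags_from_fasta(outdir / "tags.fa")
        cats = read_tsv(outdir / "tag_categories.tsv").set_index("sequence")
        category = cats["category"].to_dict()
        mirna_tags = [t for t in tags if category.get(t.sequence) == "miRNA"]
        hits = known.identify_known(
            mirna_tags, known_db,
            max_mismatches=config["known"].get("max_mismatches", 2),
        )
        write_tsv(outdir / "known_hits.tsv", known.hits_to_frame(hits))
        write_tsv(outdir / "known_families.tsv", known.family_counts(hits))
        manifest["stages"]["known"] = {"hits": len(hits)}

    # ---- novel --------------------------------------------------------
    if not done("novel", "novel_mirnas.tsv"):
        genome = read_fasta(outdir / "genome.fa")
        tags = _tags_from_fasta(outdir / "tags.fa")
        category = (
            read_tsv(outdir / "tag_categories.tsv")
            .set_index("sequence")["category"].to_dict()
        )
        unannot = [t for t in tags if category.get(t.sequence) == "unannotated"]
        hits_df = read_tsv(outdir / "genome_hits.tsv")
        unannot_seqs = {t.sequence for t in unannot}
        ghits = [
            annotate.GenomeHit(r.tag_sequence, r.scaffold, int(r.start),
                               int(r.end), r.strand, int(r.mismatches))
            for r in hits_df.itertuples()
            if r.tag_sequence in unannot_seqs
        ]
        criteria = novel.NovelCriteria(**config["novel"])
        predictions = novel.predict_novel(genome, unannot, ghits, criteria)
        rows = []
        structure_lines = []
        for p in predictions:
            c = p.candidate
            rows.append({
                "id": p.id, "scaffold": c.scaffold, "start": c.start,
                "end": c.end, "strand": c.strand, "mfe": c.mfe,
                "mature": rna_to_dna(p.mature_sequence),
                "star": rna_to_dna(p.star_sequence or ""),
                "read_count": p.read_count,
            })
            structure_lines += [f">{p.id}", c.precursor, c.structure, ""]
        write_tsv(outdir / "novel_mirnas.tsv", pd.DataFrame(
            rows, columns=["id", "scaffold", "start", "end", "strand", "mfe",
                           "mature", "star", "read_count"]))
        (outdir / "novel_structures.txt").write_text("\n".join(structure_lines))
        write_fasta(
            outdir / "novel_mature.fa",
            [(p.id, rna_to_dna(p.mature_sequence)) for p in predictions],
        )
        manifest["stages"]["novel"] = {"predicted": len(predictions)}

    # ---- targets ------------------------------------------------------
    if not done("targets", "targets.tsv"):
        transcripts = read_fasta(outdir / "transcripts.fa")
        mirnas = read_fasta(outdir / "novel_mature.fa")
        rules = targets.TargetRules(**config["targets"])
        alns = targets.scan_transcriptome(mirnas, transcripts, rules)
        rows = [
            {
                "mirna_id": a.mirna_id, "transcript_id": a.transcript_id,
                "site_start": a.site_start, "site_end": a.site_end,
                "mismatch_score": a.mismatch_score,
                "duplex_mfe": a.duplex_mfe, "perfect_mfe": a.perfect_mfe,
                "mfe_ratio": round(a.mfe_ratio, 4) if a.mfe_ratio else None,
                "alignment": targets.render_alignment(a).replace("\n", "; "),
            }
            for a in alns
        ]
        write_tsv(outdir / "targets.tsv", pd.DataFrame(
            rows, columns=["mirna_id", "transcript_id", "site_start",
                           "site_end", "mismatch_score", "duplex_mfe",
                           "perfect_mfe", "mfe_ratio", "alignment"]))
        manifest["stages"]["targets"] = {"sites": len(alns)}

    # ---- degradome ----------------------------------------------------
    if not done("degradome", "cleavage_events.tsv"):
        transcripts = read_fasta(outdir / "transcripts.fa")
        deg = read_fasta(outdir / "degradome.fa")
        density = degradome.build_density(
            [deg[k] for k in sorted(deg)], transcripts
        )
        tdf = read_tsv(outdir / "targets.tsv")
        mirnas = read_fasta(outdir / "novel_mature.fa")
        alns = []
        for r in tdf.itertuples():
            mseq = dna_to_rna(mirnas[r.mirna_id])
            window = dna_to_rna(
                transcripts[r.transcript_id][r.site_start - 1:r.site_end]
            )
            states = targets.align_site(mseq, window)
            alns.append(targets.TargetAlignment(
                r.mirna_id, mseq, r.transcript_id, int(r.site_start),
                int(r.site_end), states, targets.mismatch_score(states),
                site_sequence=window,
            ))
        events = degradome.detect_cleavage(
            alns, density, min_peak=config["degradome"].get("min_peak", 1)
        )
        write_tsv(outdir / "cleavage_events.tsv", degradome.events_to_frame(events))
        dens_rows = [
            {"transcript_id": tid, "position": i + 1, "count": v}
            for tid in sorted(density)
            for i, v in enumerate(density[tid])
            if v > 0
        ]
        write_tsv(outdir / "degradome_density.tsv", pd.DataFrame(
            dens_rows, columns=["transcript_id", "position", "count"]))
        manifest["stages"]["degradome"] = {"events": len(events)}

    # ---- quantify -----------------------------------------------------
    if not done("quantify", "expression.tsv"):
        qc = config["quantify"]
        ct = read_tsv(outdir / "ct_table.tsv")
        result = quantify.ddct(
            ct, qc["target_gene"], qc["reference_gene"],
            qc["calibrator_sample"],
        )
        write_tsv(outdir / "expression.tsv", result)
        manifest["stages"]["quantify"] = {"samples": len(result)}

    # ---- report -------------------------------------------------------
    if not done("report", "report.md"):
        manifest["stages"]["report"] = {"written": 1}
        write_report(outdir)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_report(outdir: str | Path) -> str:
    """Single summary document over whatever stage outputs exist."""
    outdir = Path(outdir)
    lines = ["# Pipeline summary", ""]

    def table(path: Path, title: str) -> None:
        if path.exists():
            df = read_tsv(path)
            lines.append(f"## {title}")
            lines.append("")
            lines.append(df.to_string(index=False))
            lines.append("")

    table(outdir / "filter_summary.tsv", "Read filtering")
    table(outdir / "category_summary.tsv", "Annotation categories")
    for name, title in [
        ("known_families.tsv", "Known miRNA families"),
        ("novel_mirnas.tsv", "Novel miRNAs"),
        ("targets.tsv", "Predicted targets"),
        ("cleavage_events.tsv", "Degradome-validated cleavages"),
        ("expression.tsv", "Relative expression (2^-ddCt)"),
    ]:
        path = outdir / name
        if path.exists():
            df = read_tsv(path)
            lines.append(f"## {title}: {len(df)} records")
            lines.append("")
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
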