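"""End-to-end orchestration: simulate -> MITE library -> clusters ->
validation ladder -> MITE homology/context -> targets -> expression.

`run_synthetic_pipeline` executes every stage on generator output and
returns all intermediate objects, plus recovery metrics against the
planted ground truth.  Reruns with an identical config produce
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._types import MirnaLocus, MirnaRecord, MiteAnnotation, MiteElement, SrnaCluster, TargetSite
from .expression import records_to_frame, rpm_normalize, targets_to_frame
from .fileio import (
    TranscriptModel,
    mite_annotations_to_gff,
    transcript_models_from_gff,
    write_gff3,
)
from .homology import build_mirna_records
from .mirna_validator import code_frequencies, evaluate_cohort, write_mirna_tsv
from .mite_library import annotate_genome, cluster_representatives
from .simulate import SimConfig, SimOutput, simulate, write_simulation
from .srna_clusters import deduplicate_clusters, find_clusters, place_reads, quantify_loci
from .targets import (
    ScoringConfig,
    annotate_sites,
    degradome_evidence,
    merge_evidence,
    profiles_from_table,
    scan_transcripts,
)


@dataclass
class PipelineResult:
    sim: SimOutput
    library: list[MiteElement]
    mite_annotations: list[MiteAnnotation]
    clusters: list[SrnaCluster]
    loci: list[MirnaLocus]
    records: list[MirnaRecord]
    merged_sites: list[TargetSite]
    expression: pd.DataFrame
    summary: dict = field(default_factory=dict)


def pooled_reads(libraries: dict[str, list[tuple[str, int]]]) -> list[tuple[str, int]]:
    pooled: dict[str, int] = {}
    for reads in libraries.values():
        for seq, count in reads:
            pooled[seq] = pooled.get(seq, 0) + count
    return sorted(pooled.items())


def run_synthetic_pipeline(
    config: SimConfig,
    n_perm: int = 1000,
    outdir: str | Path | None = None,
) -> PipelineResult:
    sim = simulate(config)

    # MITE library and annotation (candidate source marked by id prefix)
    candidates = [
        MiteElement(name, seq, "curated" if name.startswith("DTT_") else "de_novo")
        for name, seq in sorted(sim.mite_candidates.items())
    ]
    library = cluster_representatives(candidates)
    mite_annotations = annotate_genome(sim.genome, library)

    # sRNA clusters: de-novo plus the MITE-interval second pass, deduplicated
    alignments = place_reads(pooled_reads(sim.libraries), sim.genome)
    de_novo = find_clusters(alignments)
    second_pass = quantify_loci(alignments, mite_annotations_to_gff(mite_annotations))
    clusters = deduplicate_clusters(de_novo + second_pass, tolerance=5)

    # validation ladder and annotation of valid loci
    loci = evaluate_cohort(clusters, sim.genome)
    records = build_mirna_records(loci, library, sim.features)

    # target analysis on the valid matures
    models = transcript_models_from_gff(sim.features)
    profiles = profiles_from_table(sim.degradome, sim.transcripts)
    scoring = ScoringConfig()
    mirnas_dna = {r.name: r.mature.replace("U", "T") for r in records}
    candidates_sites = []
    for name in sorted(mirnas_dna):
        candidates_sites.extend(scan_transcripts(name, mirnas_dna[name], sim.transcripts, scoring))
    degradome_sites = degradome_evidence(
        candidates_sites, sim.transcripts, profiles, mirnas_dna,
        n_perm=n_perm, seed=config.seed, scoring=scoring,
    )
    merged = merge_evidence(degradome_sites, candidates_sites, scoring)
    merged = annotate_sites(merged, models, sim.genome, library)

    # expression: per-library mature read counts, RPM-normalised
    raw = pd.DataFrame(
        {
            lib: {
                r.name: sum(c for s, c in reads if s == r.mature.replace("U", "T"))
                for r in records
            }
            for lib, reads in sim.libraries.items()
        }
    )
    totals = {lib: sum(c for _, c in reads) for lib, reads in sim.libraries.items()}
    expression = rpm_normalize(raw, totals) if len(raw) else raw

    result = PipelineResult(
        sim, library, mite_annotations, clusters, loci, records, merged, expression
    )
    result.summary = summarize_run(result)
    if outdir is not None:
        write_run(result, outdir)
    return result


def recovery_metrics(result: PipelineResult) -> dict:
    """Recovery of the planted truth by the pipeline output."""
    truth = result.sim.truth
    y_loci = [l for l in result.loci if l.is_valid]

    def overlaps(locus, planted) -> bool:
        return (
            locus.cluster.chrom == planted.chrom
            and locus.cluster.start <= planted.end
            and planted.start <= locus.cluster.end
        )

    recovered = [m for m in truth.planted_mirnas if any(overlaps(l, m) for l in y_loci)]
    noise_y = [l for l in y_loci if not any(overlaps(l, m) for m in truth.planted_mirnas)]

    eligible_mites = [
        m for m in truth.planted_mites if 50 <= m.end - m.start + 1 <= 1100
    ]
    ann = result.mite_annotations

    def mite_found(m) -> bool:
        return any(
            a.chrom == m.chrom and abs(a.start - m.start) < 25 and abs(a.end - m.end) < 25
            for a in ann
        )

    def ann_is_planted(a) -> bool:
        return any(
            a.chrom == m.chrom and a.start <= m.end and m.start <= a.end
            for m in truth.planted_mites
        )

    merged_keys = {(s.transcript_id, s.cleavage_position) for s in result.merged_sites}
    found_targets = [
        t for t in truth.planted_targets if (t.transcript_id, t.cleavage_position) in merged_keys
    ]
    mite_in_target_ok = [
        t
        for t in found_targets
        if not t.has_mite_in_target
        or any(
            s.transcript_id == t.transcript_id
            and s.cleavage_position == t.cleavage_position
            and s.mite_in_target
            for s in result.merged_sites
        )
    ]
    n_planted = len(truth.planted_mirnas)
    return {
        "n_planted_mirnas": n_planted,
        "n_recovered_mirnas": len(recovered),
        "mirna_recall": len(recovered) / n_planted if n_planted else 1.0,
        "n_noise_y": len(noise_y),
        "n_planted_mites": len(eligible_mites),
        "mite_recall": (
            sum(mite_found(m) for m in eligible_mites) / len(eligible_mites)
            if eligible_mites else 1.0
        ),
        "mite_precision": (
            sum(ann_is_planted(a) for a in ann) / len(ann) if ann else 1.0
        ),
        "n_planted_targets": len(truth.planted_targets),
        "n_recovered_targets": len(found_targets),
        "target_recall": (
            len(found_targets) / len(truth.planted_targets)
            if truth.planted_targets else 1.0
        ),
        "n_mite_in_target_concordant": len(mite_in_target_ok),
    }


def summarize_run(result: PipelineResult) -> dict:
    freqs = code_frequencies(result.loci)
    records = result.records
    n_valid = sum(freqs[c] for c in ("Y",))
    n_mite = sum(1 for r in records if r.mite_id)
    with_target = {s.mirna_id for s in result.merged_sites}
    with_mite_target = {s.mirna_id for s in result.merged_sites if s.mite_in_target}
    from .expression import percent

    return {
        "n_clusters": len(result.clusters),
        "code_frequencies": freqs,
        "n_valid_mirnas": n_valid,
        "n_mite_derived": n_mite,
        "pct_mite_derived": percent(n_mite, n_valid) if n_valid else 0.0,
        "n_mirnas_with_target": len(with_target),
        "pct_mirnas_with_target": percent(len(with_target), n_valid) if n_valid else 0.0,
        "n_target_sites": len(result.merged_sites),
        "n_mirnas_with_mite_in_target": len(with_mite_target),
        "recovery": recovery_metrics(result),
    }


def _config_hash(config: SimConfig) -> str:
    doc = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def write_run(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_simulation(result.sim, outdir / "sim")
    from .fileio import write_fasta

    write_fasta({e.id: e.sequence for e in result.library}, outdir / "lib.fa")
    write_gff3(mite_annotations_to_gff(result.mite_annotations), outdir / "mites.gff3")
    write_mirna_tsv(result.loci, outdir / "mirnas.tsv", outdir / "structures.txt")
    records_to_frame(result.records).to_csv(outdir / "mirna_records.tsv", sep="\t", index=False)
    targets_to_frame(result.merged_sites).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    result.expression.round(3).to_csv(outdir / "expression_rpm.tsv", sep="\t")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(result.sim.config).items()},
        "config_hash": _config_hash(result.sim.config),
        "summary": result.summary,
    }
    (outdir / "summary.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
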