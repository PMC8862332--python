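"""Expression summarisation: RPM normalisation and cohort statistics.

RPM (reads per million mapped reads) divides each miRNA's raw read count
by the library's total mapped reads (multiplicity-weighted) and scales
by 1e6.  Cohort summaries count report rows by size class, genomic
context and MITE association, with percentages rounded half-up to one
decimal place.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def rpm_normalize(raw_counts: pd.DataFrame, library_totals: dict[str, int]) -> pd.DataFrame:
    """RPM matrix from a raw-count matrix (rows miRNAs, columns libraries).

    ``library_totals`` are total mapped read counts per library; every
    total must be >= 1.
    """
    out = raw_counts.astype(float).copy()
    for lib in out.columns:
        total = library_totals[lib]
        if total < 1:
            raise ValueError(f"library total for {lib!r} must be >= 1")
        out[lib] = out[lib] / total * 1e6
    return out


def percent(part: int, whole: int) -> float:
    """One-decimal percentage, rounded half-up; 0.0 when the whole is 0."""
    if whole == 0:
        return 0.0
    value = Decimal(part) / Decimal(whole) * Decimal(100)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    records: pd.DataFrame,
    targets: pd.DataFrame,
    cohort_counts: dict[str, int] | None = None,
) -> dict:
    """Headline statistics of a miRNA report plus its target table.

    ``records`` has one row per MITE-derived miRNA (columns: name,
    sequence, size, context, ...); ``targets`` one row per validated
    cleavage site (columns: mirna, transcript, region, category, p_value,
    mite_in_target, ...).  ``cohort_counts`` carries the cohort-level
    totals the row tables are a subset of (n_valid_mirnas,
    n_mirnas_with_target).
    """
    summary: dict = {}
    if "mite" in records.columns:
        summary["n_mite_derived"] = int((records["mite"].astype(str) != "").sum())
    else:
        summary["n_mite_derived"] = int(len(records))
    summary["size_counts"] = {
        int(size): int(n) for size, n in records["size"].value_counts().sort_index().items()
    }
    context_counts: dict[str, int] = {}
    for ctx in records["context"]:
        key = str(ctx).strip()
        context_counts[key] = context_counts.get(key, 0) + 1
    summary["context_counts"] = dict(sorted(context_counts.items()))

    with_mite_target = targets.loc[targets["mite_in_target"].notna() & (targets["mite_in_target"] != "")]
    summary["n_target_sites"] = int(len(targets))
    summary["n_target_transcripts"] = int(targets["transcript"].nunique())
    summary["n_mirnas_with_mite_in_target"] = int(with_mite_target["mirna"].nunique())
    summary["target_region_counts"] = {
        str(k): int(v) for k, v in targets["region"].value_counts().sort_index().items()
    }

    if cohort_counts:
        n_valid = cohort_counts["n_valid_mirnas"]
        summary["n_valid_mirnas"] = int(n_valid)
        summary["pct_mite_derived"] = percent(summary["n_mite_derived"], n_valid)
        if "n_mirnas_with_target" in cohort_counts:
            n_with = cohort_counts["n_mirnas_with_target"]
            summary["n_mirnas_with_target"] = int(n_with)
            summary["pct_mirnas_with_target"] = percent(n_with, n_valid)
    return summary


def records_to_frame(records) -> pd.DataFrame:
    """MirnaRecord list -> the tabular report schema used by summaries."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "locus": r.locus,
                "strand": r.strand,
                "sequence": r.mature,
                "size": r.size,
                "mite": r.mite_id or "",
                "annotation": r.known_annotation or "",
                "context": ", ".join(r.contexts),
                "genes": ",".join(r.gene_ids),
            }
            for r in records
        ]
    )


def targets_to_frame(sites) -> pd.DataFrame:
    """TargetSite list -> the tabular target report schema."""
    return pd.DataFrame(
        [
            {
                "mirna": s.mirna_id,
                "transcript": s.transcript_id,
                "region": s.region,
                "category": s.category,
                "p_value": s.p_value,
                "cleavage": "+",
                "cleavage_position": s.cleavage_position,
                "expectation": s.expectation,
                "mite_in_target": s.mite_in_target or "",
            }
            for s in sites
        ],
        columns=["mirna", "transcript", "region", "category", "p_value", "cleavage",
                 "cleavage_position", "expectation", "mite_in_target"],
    )
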