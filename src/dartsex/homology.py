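"""Filtering and annotation of pre-computed homology-search hits.

Candidate sex-linked tags are short (~69 bp) restriction fragments; their
BLAST hits against reference genomes and repeat libraries arrive as
standard 12-column tabular output (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore), optionally with a 13th
``qcovs`` query-coverage column.  No alignment search is executed here —
the pipeline consumes hit tables only, which keeps runs deterministic and
download-free.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

GENE = "GENE"
TRANSPOSABLE_ELEMENT = "TRANSPOSABLE_ELEMENT"
NONCODING = "NONCODING"
UNKNOWN = "UNKNOWN"

SUBJECT_CLASSES = (GENE, TRANSPOSABLE_ELEMENT, NONCODING, UNKNOWN)

BLAST6_COLUMNS = [
    "query_locus_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]

#: default regex → class rules for common repeat families; repeat libraries
#: themselves cannot be redistributed, so classification is name-based and
#: user-extensible
DEFAULT_CLASS_RULES: tuple[tuple[str, str], ...] = (
    (r"(?i)gypsy", TRANSPOSABLE_ELEMENT),
    (r"(?i)\brex\d*\b", TRANSPOSABLE_ELEMENT),
    (r"(?i)tc1|mariner", TRANSPOSABLE_ELEMENT),
    (r"(?i)\bsine\b|\bline\b|\bltr\b|transpos|retroelement", TRANSPOSABLE_ELEMENT),
    (r"(?i)non-?coding|ncRNA", NONCODING),
)


class HitParseError(ValueError):
    """Raised for malformed rows in a tabular hit file."""


def read_blast_table(
    path: Union[str, Path],
    default_query_length: Optional[int] = None,
) -> pd.DataFrame:
    """Parse outfmt-6-style tabular hits.

    Rows must have 12 columns, or 13 with ``qcovs`` (query coverage, %)
    appended.  When the coverage column is absent it is computed as
    alignment_length / default_query_length × 100 (DArT tags have a known
    uniform length), or left NaN if no length is given.  Malformed rows
    raise with their line number.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise HitParseError(
                    f"line {lineno}: expected 12 or 13 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                row = {
                    "query_locus_id": parts[0],
                    "subject_id": parts[1],
                    "percent_identity": float(parts[2]),
                    "alignment_length": int(parts[3]),
                    "mismatches": int(parts[4]),
                    "gap_opens": int(parts[5]),
                    "q_start": int(parts[6]),
                    "q_end": int(parts[7]),
                    "s_start": int(parts[8]),
                    "s_end": int(parts[9]),
                    "e_value": float(parts[10]),
                    "bit_score": float(parts[11]),
                }
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: {exc}") from None
            if len(parts) == 13:
                try:
                    row["query_coverage"] = float(parts[12])
                except ValueError as exc:
                    raise HitParseError(f"line {lineno}: {exc}") from None
            rows.append(row)
    hits = pd.DataFrame(rows, columns=BLAST6_COLUMNS + ["query_coverage"])
    if hits["query_coverage"].isna().any() and default_query_length:
        computed = hits["alignment_length"] / default_query_length * 100.0
        hits["query_coverage"] = hits["query_coverage"].fillna(computed)
    if "subject_description" not in hits.columns:
        hits["subject_description"] = ""
    return hits


def filter_homology_hits(
    hits: pd.DataFrame,
    max_e: float = 0.05,
    min_coverage: float = 50.0,
    min_identity: float = 50.0,
    best_per_query: bool = True,
) -> pd.DataFrame:
    """Keep hits with e_value < max_e, query_coverage > min_coverage and
    percent_identity > min_identity (all strict inequalities), then retain
    the best hit per query (lowest e-value, ties broken by identity).

    Idempotent; output rows are a subset of input rows in input order.
    """
    required = {"query_locus_id", "e_value", "query_coverage", "percent_identity"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    kept = hits[
        (hits["e_value"] < max_e)
        & (hits["query_coverage"] > min_coverage)
        & (hits["percent_identity"] > min_identity)
    ]
    if not best_per_query:
        return kept.copy()
    best_rows = []
    for _, group in kept.groupby("query_locus_id", sort=False):
        ordered = group.sort_values(
            ["e_value", "percent_identity"],
            ascending=[True, False],
            kind="mergesort",
        )
        best_rows.append(ordered.index[0])
    return kept.loc[sorted(best_rows, key=list(kept.index).index)].copy()


def classify_subjects(
    hits: pd.DataFrame,
    rules: Optional[Sequence[tuple[str, str]]] = None,
    default_class: str = GENE,
) -> pd.DataFrame:
    """Assign a subject_class to each hit from regex rules.

    Rules are (pattern, class) pairs matched against subject_id and
    subject_description, first match wins; unmatched hits get
    ``default_class`` (a hit that survived the e-value/coverage filters
    against an annotated genome is a putative gene unless it looks like a
    repeat).  Pass ``default_class=UNKNOWN`` for conservative behaviour.
    """
    compiled = [
        (re.compile(pat), cls)
        for pat, cls in (tuple(rules) if rules is not None else DEFAULT_CLASS_RULES)
    ]
    for _, cls in compiled:
        if cls not in SUBJECT_CLASSES:
            raise ValueError(f"unknown subject class {cls!r}")

    def _classify(row) -> str:
        text = f"{row['subject_id']} {row.get('subject_description', '')}"
        for pattern, cls in compiled:
            if pattern.search(text):
                return cls
        return default_class

    out = hits.copy()
    out["subject_class"] = [_classify(r) for _, r in out.iterrows()] if len(out) else []
    return out


@dataclass
class AnnotationReport:
    """Per-candidate annotation plus per-(hypothesis, class) summary."""

    table: pd.DataFrame
    summary: dict

    def count(self, hypothesis: str, subject_class: str) -> int:
        return self.summary.get(hypothesis, {}).get(subject_class, 0)


def annotate_candidates(
    classification: pd.DataFrame, hits: pd.DataFrame
) -> AnnotationReport:
    """Join classified candidate loci to their (filtered, classified) hits.

    ``classification`` is the per-locus table from ``classify_loci`` (index
    locus_id, columns xy_category / zw_category, ...); ``hits`` should
    already be filtered to best-per-query and carry ``subject_class``.
    Candidates without a hit are UNKNOWN.  Summary counts are per
    hypothesis ("XY" = loci not UNLINKED under xy_category, likewise "ZW")
    per subject class, so a locus classified under both hypotheses counts
    in each without double counting inside one hypothesis.
    """
    if len(hits) and "subject_class" not in hits.columns:
        hits = classify_subjects(hits)
    best = (
        hits.drop_duplicates("query_locus_id").set_index("query_locus_id")
        if len(hits)
        else pd.DataFrame(columns=["subject_id", "subject_class",
                                   "e_value", "percent_identity",
                                   "query_coverage", "subject_description"])
    )
    rows = []
    for locus, rec in classification.iterrows():
        hit = best.loc[locus] if locus in best.index else None
        rows.append(
            {
                "locus_id": locus,
                "marker_type": rec.get("marker_type", ""),
                "xy_category": rec.get("xy_category", ""),
                "zw_category": rec.get("zw_category", ""),
                "subject_class": UNKNOWN if hit is None else hit["subject_class"],
                "subject_id": "" if hit is None else hit["subject_id"],
                "e_value": math.nan if hit is None else hit["e_value"],
                "percent_identity": math.nan if hit is None else hit["percent_identity"],
                "query_coverage": math.nan if hit is None else hit["query_coverage"],
                "subject_description": "" if hit is None
                else hit.get("subject_description", ""),
            }
        )
    table = pd.DataFrame(rows).set_index("locus_id")
    summary: dict = {}
    for hyp, column in (("XY", "xy_category"), ("ZW", "zw_category")):
        if column not in classification.columns:
            continue
        linked = table[classification[column].ne("UNLINKED").reindex(table.index,
                                                                     fill_value=False)]
        counts = linked["subject_class"].value_counts().to_dict()
        summary[hyp] = {cls: int(counts.get(cls, 0)) for cls in SUBJECT_CLASSES}
        summary[hyp]["n_candidates"] = int(len(linked))
    return AnnotationReport(table=table, summary=summary)

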