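"""Labeling reads and phase sets as rearranged (CGR) vs wild-type (WT)
haplotype, and allele-specific expression counting.

Long reads carry two independent labels: a haplotype tag (H1/H2, from
SNP-based phasing) and a breakpoint class derived from their alignment at a
rearrangement breakpoint.  A read spanning +/-90 bp of a breakpoint with
MAPQ >= 20 in one contiguous alignment is WT; a read that enters the locus
but stops on one side and continues elsewhere as a supplementary alignment
is CGR; everything else (including reads simply ending inside the +/-90 bp
margin) is uninformative.  Because all rearrangements are assumed to sit on
one allele, the reads of a phase set vote between two scenarios
(WT/H1 + CGR/H2 vs WT/H2 + CGR/H1); the majority labels the phase set and
labeled sets combine across chromosomes into a genome-wide CGR/WT
assignment.  Phased RNA-seq read counts per gene and allele then feed an
allelic-imbalance call: |log2FC| > 1 and padj < 0.05, from an external
differential-expression table when available or an internal exact binomial
test (BH-adjusted) as a self-contained stand-in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WT = "WT"
CGR = "CGR"
NO_BP_INFO = "NoBpInfo"


class HaplotypeError(ValueError):
    pass


@dataclass
class PhaseSetLabel:
    phase_set: str
    label: str  # CGR=H1 | CGR=H2 | unresolved
    votes_wt_h1: int
    votes_wt_h2: int
    votes_cgr_h1: int
    votes_cgr_h2: int
    conflicts: int
    conflict_fraction: float


def classify_read_at_breakpoint(start: int, end: int, mapq: int,
                                has_supplementary: bool, breakpoint: int,
                                margin: int = 90, minq: int = 20) -> str:
    """Breakpoint class of one read alignment (0-based half-open interval)."""
    if mapq < minq:
        return NO_BP_INFO
    lo, hi = breakpoint - margin, breakpoint + margin
    if start <= lo and end >= hi:
        return WT
    enters_left = start <= lo and lo <= end < hi
    enters_right = end >= hi and lo < start <= hi
    if (enters_left or enters_right) and has_supplementary:
        return CGR
    return NO_BP_INFO


def classify_reads(reads: pd.DataFrame, breakpoints: dict[str, list[int]],
                   margin: int = 90, minq: int = 20) -> pd.DataFrame:
    """Classify every read at every breakpoint it overlaps (+/- margin).

    ``reads`` columns: read_id, chrom, start, end, mapq, has_supplementary,
    hap, phase_set.  Returns one row per (read, breakpoint) with a ``bp_class``
    column.
    """
    rows = []
    for chrom, bps in breakpoints.items():
        sub = reads[reads["chrom"] == chrom]
        for bp in bps:
            near = sub[(sub["end"] >= bp - margin) & (sub["start"] <= bp + margin)]
            for rec in near.itertuples():
                cls = classify_read_at_breakpoint(
                    rec.start, rec.end, rec.mapq, rec.has_supplementary, bp,
                    margin=margin, minq=minq,
                )
                rows.append(
                    {
                        "read_id": rec.read_id,
                        "phase_set": rec.phase_set,
                        "hap": rec.hap,
                        "chrom": chrom,
                        "breakpoint": bp,
                        "bp_class": cls,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["read_id", "phase_set", "hap", "chrom", "breakpoint", "bp_class"],
    )


def vote_phase_set(classified: pd.DataFrame, phase_set: str,
                   conflict_warn: float = 0.2) -> PhaseSetLabel:
    """Majority vote between the two allele scenarios for one phase set.

    Scenario A (CGR=H2) collects WT/H1 and CGR/H2 reads; scenario B (CGR=H1)
    the mirror.  Ties (including zero informative reads) are unresolved.
    """
    sub = classified[classified["phase_set"] == phase_set]
    informative = sub[(sub["hap"].isin(["H1", "H2"])) & (sub["bp_class"].isin([WT, CGR]))]
    v = {
        (w, h): int(((informative["bp_class"] == w) & (informative["hap"] == h)).sum())
        for w in (WT, CGR)
        for h in ("H1", "H2")
    }
    a = v[(WT, "H1")] + v[(CGR, "H2")]
    b = v[(WT, "H2")] + v[(CGR, "H1")]
    if a > b:
        label, conflicts = "CGR=H2", b
    elif b > a:
        label, conflicts = "CGR=H1", a
    else:
        label, conflicts = "unresolved", min(a, b)
    total = a + b
    frac = conflicts / total if total else 0.0
    if label != "unresolved" and frac > conflict_warn:
        warnings.warn(
            f"phase set {phase_set}: conflict fraction {frac:.2f} exceeds {conflict_warn}"
        )
    return PhaseSetLabel(
        phase_set=phase_set,
        label=label,
        votes_wt_h1=v[(WT, "H1")],
        votes_wt_h2=v[(WT, "H2")],
        votes_cgr_h1=v[(CGR, "H1")],
        votes_cgr_h2=v[(CGR, "H2")],
        conflicts=conflicts,
        conflict_fraction=frac,
    )


def label_phase_sets(classified: pd.DataFrame, conflict_warn: float = 0.2):
    return [
        vote_phase_set(classified, ps, conflict_warn)
        for ps in sorted(classified["phase_set"].dropna().unique())
    ]


def expand_labels(labels: list[PhaseSetLabel]) -> dict[str, dict[str, str]]:
    """Genome-wide allele assignment per phase set: maps phase set ->
    {H1: CGR|WT, H2: CGR|WT}.  Assumes all rearrangements originate from one
    allele; unresolved sets are excluded (logged by omission)."""
    out: dict[str, dict[str, str]] = {}
    for lab in labels:
        if lab.label == "unresolved":
            continue
        if lab.phase_set in out:
            prev = out[lab.phase_set]
            want = {"H1": CGR, "H2": WT} if lab.label == "CGR=H1" else {"H1": WT, "H2": CGR}
            if prev != want:
                raise HaplotypeError(f"contradictory labels for phase set {lab.phase_set}")
            continue
        if lab.label == "CGR=H1":
            out[lab.phase_set] = {"H1": CGR, "H2": WT}
        else:
            out[lab.phase_set] = {"H1": WT, "H2": CGR}
    return out


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------

def count_alleles(rna_reads: pd.DataFrame, min_reads: int = 16) -> pd.DataFrame:
    """Per-gene per-allele per-replicate phased read counts.

    ``rna_reads`` columns: gene, allele (CGR|WT), replicate.  Genes with
    fewer than ``min_reads`` total phased reads are dropped.
    """
    counts = (
        rna_reads.groupby(["gene", "replicate", "allele"], sort=True)
        .size()
        .unstack("allele", fill_value=0)
        .reset_index()
    )
    for col in (CGR, WT):
        if col not in counts.columns:
            counts[col] = 0
    totals = counts.groupby("gene")[[CGR, WT]].sum().sum(axis=1)
    keep = totals[totals >= min_reads].index
    return counts[counts["gene"].isin(keep)].reset_index(drop=True)[
        ["gene", "replicate", CGR, WT]
    ]


def binomial_imbalance(counts: pd.DataFrame) -> pd.DataFrame:
    """Self-contained stand-in for the external differential-expression
    table: per-gene exact binomial test of pooled CGR vs WT counts with
    Benjamini-Hochberg adjustment.  log2FC is log2(CGR/WT) of pooled counts.
    """
    from scipy.stats import binomtest
    from statsmodels.stats.multitest import multipletests

    pooled = counts.groupby("gene")[[CGR, WT]].sum()
    rows = []
    for gene, rec in pooled.iterrows():
        c, w = int(rec[CGR]), int(rec[WT])
        n = c + w
        if n == 0:
            rows.append({"gene": gene, "log2fc": np.nan, "pvalue": np.nan})
            continue
        p = binomtest(c, n, 0.5).pvalue
        if w == 0:
            lfc = math.inf
        elif c == 0:
            lfc = -math.inf
        else:
            lfc = math.log2(c / w)
        rows.append({"gene": gene, "log2fc": lfc, "pvalue": p})
    df = pd.DataFrame(rows)
    valid = df["pvalue"].notna()
    df["padj"] = np.nan
    if valid.any():
        df.loc[valid, "padj"] = multipletests(df.loc[valid, "pvalue"], method="fdr_bh")[1]
    return df


def call_aig(table: pd.DataFrame, lfc: float = 1.0, alpha: float = 0.05,
             gene_chroms: dict[str, str] | None = None,
             exclude_chroms: tuple = ("chrX", "chrY")) -> pd.DataFrame:
    """Flag allelic-imbalance genes: |log2FC| > lfc and padj < alpha.

    ``table`` needs gene, log2fc, padj columns (an external differential-
    expression result or the binomial stand-in).  Genes without a padj are
    excluded; genes on sex chromosomes are excluded when coordinates are
    known.
    """
    df = table.copy()
    df = df[df["padj"].notna()]
    if gene_chroms:
        df = df[~df["gene"].map(gene_chroms).isin(exclude_chroms)]
    df = df.copy()
    df["aig"] = (df["log2fc"].abs() > lfc) & (df["padj"] < alpha)
    return df.reset_index(drop=True)


def write_phase_set_tsv(labels: list[PhaseSetLabel], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "phase_set\tlabel\twt_h1\twt_h2\tcgr_h1\tcgr_h2\tconflicts\tconflict_fraction\n"
        )
        for lab in labels:
            fh.write(
                f"{lab.phase_set}\t{lab.label}\t{lab.votes_wt_h1}\t{lab.votes_wt_h2}\t"
                f"{lab.votes_cgr_h1}\t{lab.votes_cgr_h2}\t{lab.conflicts}\t"
                f"{lab.conflict_fraction:.4f}\n"
            )
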