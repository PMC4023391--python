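"""Joining 3' sites to full-length isoforms and gene models.

A poly(A) site only fixes the 3' boundary of a transcript; its coding
potential depends on where the matching full-length isoform (TIF)
starts.  Each matched TIF is classified into one of eight categories by
its coverage of annotated CDS intervals and SUTs; a site inherits one
assignment per matched TIF, so the same 3'UTR position can be both a
coding and a non-coding isoform end.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import FullLengthIsoform, GeneModel, GenomeCoordinate

CODING_1ORF = "coding_1orf"
CODING_2PLUS = "coding_2plus_orf"
PARTIAL_2ORF = "partial_2orf"
INTRAGENIC = "intragenic"
OVERLAP_3P = "overlap_3prime"
OVERLAP_5P = "overlap_5prime"
SUT = "sut"
INTERGENIC = "intergenic"
CATEGORIES = (
    CODING_1ORF, CODING_2PLUS, PARTIAL_2ORF, INTRAGENIC,
    OVERLAP_3P, OVERLAP_5P, SUT, INTERGENIC,
)
CODING_CATEGORIES = frozenset({CODING_1ORF, CODING_2PLUS})


def match_tifs(
    site: GenomeCoordinate,
    tifs: Sequence[FullLengthIsoform],
    tolerance: int = 0,
) -> list[FullLengthIsoform]:
    """TIFs whose 3' end lies within +/- tolerance nt of the site.

    The default tolerance of 0 matches at nucleotide resolution, the
    working resolution of the whole pipeline.
    """
    return [
        t
        for t in tifs
        if t.chrom == site.chrom
        and t.strand == site.strand
        and abs(t.end3 - site.pos) <= tolerance
    ]


def _overlap(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    return max(0, min(hi1, hi2) - max(lo1, lo2))


def utr3_length(site_pos: int, gene: GeneModel) -> int:
    """Transcript-orientation distance from the base after the stop codon
    to the poly(A) site, inclusive (site one base past the stop -> 1)."""
    if gene.strand == "+":
        return site_pos - gene.cds_end + 1
    return gene.cds_start - site_pos


def classify_tif(
    tif: FullLengthIsoform,
    genes: Sequence[GeneModel],
    sut_reciprocal_overlap: float = 0.5,
) -> tuple[str, list[GeneModel]]:
    """Assign one of the eight coverage categories to a single TIF.

    Precedence when several labels could apply:
    coding > partial_2orf > sut > overlap_{3,5}prime > intragenic >
    intergenic.  Only same-strand gene models are considered.
    """
    lo, hi = tif.lo, tif.hi
    orfs = [
        g for g in genes
        if g.biotype == "ORF" and g.chrom == tif.chrom and g.strand == tif.strand
        and _overlap(lo, hi, g.cds_start, g.cds_end) > 0
    ]
    covered = [g for g in orfs if lo <= g.cds_start and g.cds_end <= hi]
    if covered:
        cat = CODING_1ORF if len(covered) == 1 else CODING_2PLUS
        return cat, covered
    if len(orfs) >= 2:
        return PARTIAL_2ORF, orfs

    suts = [
        g for g in genes
        if g.biotype == "SUT" and g.chrom == tif.chrom and g.strand == tif.strand
    ]
    for s in suts:
        ov = _overlap(lo, hi, s.cds_start, s.cds_end)
        if ov >= sut_reciprocal_overlap * (hi - lo) and ov >= sut_reciprocal_overlap * (
            s.cds_end - s.cds_start
        ):
            return SUT, [s]

    if len(orfs) == 1:
        g = orfs[0]
        if g.cds_start <= lo and hi <= g.cds_end:
            return INTRAGENIC, [g]
        has5 = lo <= g.five_prime_point < hi
        has3 = lo <= g.three_prime_point < hi
        if has3 and not has5:
            return OVERLAP_3P, [g]
        if has5 and not has3:
            return OVERLAP_5P, [g]
        # touches the interior but neither boundary cannot happen for
        # intervals; containing both boundaries means covered.
        return INTRAGENIC, [g]
    return INTERGENIC, []


def _coding_gene(site_pos: int, covered: Sequence[GeneModel], strand: str) -> GeneModel:
    """The covered ORF whose stop codon is closest upstream of the site."""
    if strand == "+":
        return max(covered, key=lambda g: g.cds_end)
    return min(covered, key=lambda g: g.cds_start)


def _site_only_category(
    site: GenomeCoordinate, genes: Sequence[GeneModel], max_utr: int = 400
) -> tuple[str, str]:
    """Fallback heuristic for sites with no matched TIF."""
    for g in genes:
        if g.chrom != site.chrom or g.strand != site.strand:
            continue
        if g.biotype == "ORF" and g.cds_start <= site.pos < g.cds_end:
            return INTRAGENIC, g.gene_id
    for g in genes:
        if g.chrom != site.chrom or g.strand != site.strand:
            continue
        if g.biotype == "ORF" and 1 <= utr3_length(site.pos, g) <= max_utr:
            return CODING_1ORF, g.gene_id
        if g.biotype == "SUT" and g.cds_start <= site.pos < g.cds_end:
            return SUT, g.gene_id
    return INTERGENIC, ""


def classify(
    site: GenomeCoordinate,
    matched: Sequence[FullLengthIsoform],
    genes: Sequence[GeneModel],
    sut_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """One annotation row per (site, matched TIF).

    Unmatched sites get a single row classified by a site-only heuristic
    and flagged ``site_only``.
    """
    rows = []
    if not matched:
        cat, gene_id = _site_only_category(site, genes)
        rows.append(
            (site.chrom, site.pos, site.strand, "", gene_id, cat,
             cat in CODING_CATEGORIES, np.nan, True)
        )
    for tif in matched:
        cat, hits = classify_tif(tif, genes, sut_reciprocal_overlap)
        coding = cat in CODING_CATEGORIES
        utr = np.nan
        gene_id = ";".join(g.gene_id for g in hits)
        if coding:
            primary = _coding_gene(site.pos, hits, site.strand)
            gene_id = primary.gene_id
            utr = utr3_length(site.pos, primary)
        rows.append(
            (site.chrom, site.pos, site.strand, tif.tif_id, gene_id, cat, coding,
             utr, False)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "tif_id", "gene_id", "category", "coding",
                 "utr3_length", "site_only"],
    )


def annotate_sites(
    sites: Iterable[GenomeCoordinate],
    tifs: Sequence[FullLengthIsoform],
    genes: Sequence[GeneModel],
    tolerance: int = 0,
    sut_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Match and classify every site; returns the concatenated annotation."""
    frames = []
    by_key: dict = {}
    for t in tifs:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    for site in sites:
        pool = by_key.get((site.chrom, site.strand), [])
        if tolerance == 0:
            matched = [t for t in pool if t.end3 == site.pos]
        else:
            matched = [t for t in pool if abs(t.end3 - site.pos) <= tolerance]
        frames.append(classify(site, matched, genes, sut_reciprocal_overlap))
    if not frames:
        return classify(GenomeCoordinate("x", 0, "+"), [], []).iloc[0:0]
    out = pd.concat(frames, ignore_index=True)
    out["site"] = out["chrom"] + ":" + out["pos"].astype(str) + ":" + out["strand"]
    return out


def census(annotations: pd.DataFrame) -> dict:
    """Category counts and per-gene coding-isoform tallies."""
    counts = {cat: 0 for cat in CATEGORIES}
    if len(annotations):
        counts.update(annotations["category"].value_counts().to_dict())
    coding = annotations[annotations["coding"].astype(bool)] if len(annotations) else annotations
    per_gene = (
        coding.drop_duplicates(["gene_id", "site"]).groupby("gene_id").size()
        if len(coding)
        else pd.Series(dtype=int)
    )
    return {
        "category_counts": counts,
        "per_gene_coding_isoforms": per_gene,
        "genes_ge2_coding": int((per_gene >= 2).sum()),
        "genes_ge3_coding": int((per_gene >= 3).sum()),
    }
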