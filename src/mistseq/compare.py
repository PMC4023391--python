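"""Category-level and sequence-feature statistics on decay fits.

Covers: ANOVA with pairwise Welch t-tests across isoform coverage
categories, the 3'UTR-length/stability relation, the distance profile of
differentially stable isoform pairs, IUPAC motif scanning of 3'UTRs with
with/without-motif group comparisons, and the decay correlation of
divergent (head-to-head) gene pairs.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GeneModel, ValidationError
from .sites import revcomp

DISTANCE_BINS = ((1, 1), (2, 5), (6, 10), (11, 100), (101, np.inf))


# ---------------------------------------------------------------------------
# Category statistics
# ---------------------------------------------------------------------------
@dataclass
class CategoryStats:
    medians: pd.DataFrame
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame


def category_anova(
    fits_annotated: pd.DataFrame, min_n: int = 20, equal_var: bool = False
) -> CategoryStats:
    """One-way ANOVA on decay rates across isoform categories.

    Only categories with at least ``min_n`` members enter (the display
    rule used for category-level reporting); pairwise comparisons are
    Welch t-tests by default, BH-adjusted.
    """
    df = fits_annotated[np.isfinite(fits_annotated["k"])]
    sizes = df.groupby("category").size()
    cats = sorted(sizes[sizes >= min_n].index)
    if len(cats) < 2:
        raise ValidationError(
            f"need at least two categories with n >= {min_n}; have {list(cats)}"
        )
    groups = [df.loc[df["category"] == c, "k"].to_numpy() for c in cats]
    f, p = stats.f_oneway(*groups)
    med = pd.DataFrame(
        {
            "category": cats,
            "n": [len(g) for g in groups],
            "median_k": [float(np.median(g)) for g in groups],
            "median_half_life": [float(np.median(np.log(2) / g[g > 0])) for g in groups],
        }
    )
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            t, tp = stats.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            rows.append((cats[i], cats[j], float(t), float(tp)))
    pairwise = pd.DataFrame(rows, columns=["category_a", "category_b", "t", "p"])
    if len(pairwise):
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    n = sum(len(g) for g in groups)
    return CategoryStats(med, float(f), float(p), len(cats) - 1, n - len(cats), pairwise)


# ---------------------------------------------------------------------------
# UTR length and pair distance
# ---------------------------------------------------------------------------
def utr_length_relation(
    coding_fits: pd.DataFrame, pair_tests: Optional[pd.DataFrame] = None
) -> dict:
    """Relation between 3'UTR length and decay rate for coding isoforms.

    Reports the global Spearman correlation and, per gene, the
    proximal/distal isoform pair (min/max UTR length) with its length
    and rate differences.
    """
    df = coding_fits.dropna(subset=["utr3_length"])
    df = df[np.isfinite(df["k"])]
    if len(df) < 10:
        raise ValidationError("need at least 10 coding isoforms with UTR lengths")
    rho, p = stats.spearmanr(df["utr3_length"], df["k"])

    rows = []
    for gene, sub in df.drop_duplicates(["gene_id", "site"]).groupby("gene_id"):
        if len(sub) < 2:
            continue
        prox = sub.loc[sub["utr3_length"].idxmin()]
        dist = sub.loc[sub["utr3_length"].idxmax()]
        rows.append(
            (gene, prox["site"], dist["site"],
             dist["utr3_length"] - prox["utr3_length"], dist["k"] - prox["k"])
        )
    pairs = pd.DataFrame(
        rows, columns=["gene_id", "site_proximal", "site_distal", "delta_length",
                       "delta_k"]
    )
    if pair_tests is not None and len(pairs):
        key = pair_tests.set_index(["site_a", "site_b"])["q"]
        qs = []
        for r in pairs.itertuples():
            q = key.get((r.site_proximal, r.site_distal))
            if q is None:
                q = key.get((r.site_distal, r.site_proximal), np.nan)
            qs.append(q)
        pairs["q"] = qs
    return {"spearman": float(rho), "p": float(p), "n": len(df), "pairs": pairs}


def pair_distance_profile(pair_tests: pd.DataFrame) -> dict:
    """Distance vs significance for within-gene isoform pairs.

    Returns the per-pair table with -log10 p and significant-pair counts
    in distance bins (1, 2-5, 6-10, 11-100, >100 nt); distance-zero
    pairs are impossible for distinct sites and are excluded.
    """
    df = pair_tests[pair_tests["distance_nt"] >= 1].copy()
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p"])
    sig = df[df["significant"]] if "significant" in df.columns else df.iloc[0:0]
    counts = {}
    for lo, hi in DISTANCE_BINS:
        label = f"{lo}" if lo == hi else (f"{lo}-{int(hi)}" if np.isfinite(hi) else f">{lo - 1}")
        counts[label] = int(((sig["distance_nt"] >= lo) & (sig["distance_nt"] <= hi)).sum())
    return {"table": df, "significant_by_distance": counts,
            "n_significant": int(len(sig))}


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------
def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC degenerate DNA string to a regex."""
    parts = []
    for ch in motif.upper():
        if ch not in ambiguous_dna_values:
            raise ValidationError(f"invalid IUPAC letter {ch!r} in motif {motif!r}")
        vals = ambiguous_dna_values[ch]
        parts.append(vals if len(vals) == 1 else f"[{vals}]")
    return re.compile("".join(parts))


def scan_motifs(
    genome,
    motifs: pd.DataFrame,
    annotations: pd.DataFrame,
    max_downstream: int = 0,
) -> pd.DataFrame:
    """Scan coding isoforms' 3'UTRs for IUPAC motif occurrences.

    For each gene the sense-strand region from the base after the stop
    codon to its most distal poly(A) site is scanned once (overlapping
    matches included); each coding isoform of the gene then receives
    ``contained`` flags: a hit is contained when it lies entirely
    upstream of (or ending at) that isoform's site.
    ``distance_to_3prime`` is the transcript-orientation distance from
    the hit's 3'-most base to the site (negative for hits beyond it).
    """
    coding = annotations[annotations["coding"].astype(bool)].drop_duplicates(
        ["gene_id", "site"]
    )
    patterns = [(r.motif_id, len(r.iupac), iupac_regex(r.iupac)) for r in motifs.itertuples()]
    rows = []
    for (gene_id, chrom, strand), sub in coding.groupby(["gene_id", "chrom", "strand"]):
        max_utr = int(sub["utr3_length"].max()) + max_downstream
        if max_utr < 1:
            continue
        # genomic region of the scanned UTR stretch, then sense strand
        first = sub.iloc[0]
        if strand == "+":
            stop_end = int(first["pos"]) - int(first["utr3_length"]) + 1
            region = str(genome[chrom][stop_end : stop_end + max_utr]).upper()
        else:
            stop_end = int(first["pos"]) + int(first["utr3_length"]) - 1
            region = revcomp(str(genome[chrom][stop_end + 1 - max_utr : stop_end + 1]).upper())
        hits = []
        for motif_id, mlen, pat in patterns:
            for m in _finditer_overlapping(pat, region):
                hits.append((motif_id, m, mlen))
        for r in sub.itertuples():
            utr = int(r.utr3_length)
            for motif_id, h, mlen in hits:
                end_off = h + mlen - 1  # 0-based transcript offset of hit 3' base
                distance = (utr - 1) - end_off
                contained = distance >= 0
                if strand == "+":
                    gpos = stop_end + h
                else:
                    gpos = stop_end - h - (mlen - 1)
                rows.append(
                    (motif_id, r.site, gene_id, chrom, gpos, strand, distance, contained)
                )
    return pd.DataFrame(
        rows,
        columns=["motif_id", "site", "gene_id", "chrom", "hit_pos", "strand",
                 "distance_to_3prime", "contained"],
    )


def _finditer_overlapping(pat: re.Pattern, seq: str):
    start = 0
    while True:
        m = pat.search(seq, start)
        if m is None:
            return
        yield m.start()
        start = m.start() + 1


def brute_force_iupac_hits(motif: str, seq: str) -> list[int]:
    """Position-by-position IUPAC matcher (independent of the regex path)."""
    seq = seq.upper()
    allowed = [set(ambiguous_dna_values[ch]) for ch in motif.upper()]
    L = len(motif)
    return [
        i
        for i in range(len(seq) - L + 1)
        if all(seq[i + j] in allowed[j] for j in range(L))
    ]


def motif_stability_split(
    fits_annotated: pd.DataFrame, hits: pd.DataFrame, motif_id: str
) -> dict:
    """Compare decay rates of isoforms with vs without a motif.

    Restricted to genes with at least one motif-containing coding
    isoform; within those genes, isoforms are split by whether the motif
    is contained in their 3'UTR.  Also reports the distance-vs-k
    relation for the contained group.
    """
    mh = hits[(hits["motif_id"] == motif_id) & hits["contained"]]
    genes = set(mh["gene_id"])
    df = fits_annotated[
        fits_annotated["coding"].astype(bool)
        & fits_annotated["gene_id"].isin(genes)
        & np.isfinite(fits_annotated["k"])
    ].drop_duplicates(["gene_id", "site"])
    contained_sites = set(mh["site"])
    with_m = df[df["site"].isin(contained_sites)]
    without = df[~df["site"].isin(contained_sites)]
    out = {
        "motif_id": motif_id,
        "n_with": len(with_m),
        "n_without": len(without),
        "median_k_with": float(with_m["k"].median()) if len(with_m) else np.nan,
        "median_k_without": float(without["k"].median()) if len(without) else np.nan,
    }
    if len(with_m) and len(without):
        t, p = stats.ttest_ind(with_m["k"], without["k"], equal_var=False)
        out.update(t=float(t), p=float(p),
                   median_ratio=out["median_k_with"] / out["median_k_without"])
    else:
        out.update(t=np.nan, p=np.nan, median_ratio=np.nan)
    dist = mh.merge(df[["site", "k"]], on="site")
    if len(dist) >= 5:
        rho, rp = stats.spearmanr(dist["distance_to_3prime"], dist["k"])
        out.update(distance_spearman=float(rho), distance_p=float(rp))
    out["distance_table"] = dist[["site", "distance_to_3prime", "k"]]
    return out


# ---------------------------------------------------------------------------
# Divergent gene pairs
# ---------------------------------------------------------------------------
def divergent_pair_correlation(
    genes: Sequence[GeneModel], gene_k: pd.Series, max_gap: int = 200
) -> dict:
    """Decay correlation of divergent gene pairs.

    Pairs are opposite-strand ORFs transcribed head-to-head whose 5'
    starts lie within ``max_gap`` nt; convergent (tail-to-tail) and
    same-strand neighbors are excluded.
    """
    orfs = [g for g in genes if g.biotype == "ORF"]
    rows = []
    for a in orfs:
        if a.strand != "-":
            continue
        for b in orfs:
            if b.strand != "+" or b.chrom != a.chrom:
                continue
            gap = b.cds_start - a.cds_end
            if 0 <= gap <= max_gap:
                rows.append((a.gene_id, b.gene_id, gap))
    pairs = pd.DataFrame(rows, columns=["gene_minus", "gene_plus", "gap"])
    pairs["k_minus"] = pairs["gene_minus"].map(gene_k)
    pairs["k_plus"] = pairs["gene_plus"].map(gene_k)
    pairs = pairs.dropna()
    out = {"pairs": pairs, "n": len(pairs)}
    if len(pairs) >= 5:
        rho, p = stats.spearmanr(pairs["k_minus"], pairs["k_plus"])
        out.update(spearman=float(rho), p=float(p))
    return out
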