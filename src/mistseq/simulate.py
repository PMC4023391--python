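"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the structure of a spike-in calibrated 3' end
sequencing decay time course: genes on both strands with 1-4 poly(A)
isoforms, a full-length-isoform (TIF) annotation realizing all eight
coverage categories, A-rich internal-priming artifact sites, spike-in
sites carrying one ninth of the sample's expected molecules, RBP motifs
planted so that for some genes only the distal isoform contains one, and
negative-binomially distributed counts decaying exponentially per
isoform with library-specific size factors.  Everything is driven by a
single seed and is byte-identical across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .model import (
    CountTable,
    FullLengthIsoform,
    GeneModel,
    RunConfig,
    ValidationError,
)

PUF3_MOTIF = "TGTAAATA"
DECOY_MOTIF = "ACGCGTCA"
DEFAULT_ALPHA = (0.02, 0.04, 0.08, 0.14, 0.20)
SPIKE_CHROM = "spike_I"

_BASES = np.array(list("ACGT"))

# per-category decay-rate multipliers applied on top of the gene baseline;
# non-coding classes decay faster, partial two-ORF overlaps fastest
CATEGORY_K_MULT = {
    "coding_1orf": 1.0,
    "coding_2plus_orf": 1.0,
    "partial_2orf": 1.7,
    "sut": 1.35,
    "intragenic": 1.0,
    "intergenic": 1.0,
    "overlap_3prime": 1.3,
    "overlap_5prime": 1.3,
}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _break_a_runs(seq: str, max_run: int = 3) -> str:
    """Cap homopolymer-A runs so clean sites never trip the mispriming rule."""
    out = list(seq)
    run = 0
    for i, ch in enumerate(out):
        if ch == "A":
            run += 1
            if run > max_run:
                out[i] = "C"
                run = 0
        else:
            run = 0
    return "".join(out)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class _Cassette:
    """A plus-strand local layout, flippable to the minus strand."""

    seq: str
    genes: list = field(default_factory=list)  # (gene_id, cs, ce, biotype)
    tifs: list = field(default_factory=list)  # (tif_id, start5, end3)
    truth: list = field(default_factory=list)  # dicts keyed by tif_id
    artifacts: list = field(default_factory=list)  # (pos, A0)

    def flip(self) -> "_Cassette":
        L = len(self.seq)
        flipped = _Cassette(seq=_revcomp(self.seq))
        flipped.genes = [
            (gid, L - ce, L - cs, bt) for (gid, cs, ce, bt) in self.genes
        ]
        flipped.tifs = [
            (tid, L - 1 - s5, L - 1 - e3) for (tid, s5, e3) in self.tifs
        ]
        flipped.truth = list(self.truth)
        flipped.artifacts = [(L - 1 - p, a0) for (p, a0) in self.artifacts]
        return flipped


@dataclass
class SimWorld:
    """Generated genome, annotation, and per-isoform ground truth."""

    genome: dict
    genes: list
    tifs: list
    motifs: pd.DataFrame
    truth: pd.DataFrame
    spike_sites: pd.DataFrame
    seed: int

    def write(self, out_dir, config: Optional[RunConfig] = None) -> dict:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "genes": os.path.join(out_dir, "genes.gff3"),
            "tifs": os.path.join(out_dir, "tifs.tsv"),
            "motifs": os.path.join(out_dir, "motifs.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        mio.write_fasta(self.genome, paths["genome"])
        mio.write_gene_models(self.genes, paths["genes"])
        mio.write_tif_annotation(self.tifs, paths["tifs"])
        self.motifs.to_csv(paths["motifs"], sep="\t", index=False)
        mio.write_table(self.truth, paths["truth"], config)
        return paths


def _standard_gene(
    rng: np.random.Generator,
    gene_id: str,
    motif_mode: str,
    motif_seq: str,
    max_iso: int = 4,
) -> _Cassette:
    """One ORF with 1-4 coding 3' isoforms; optional planted motif."""
    u5 = 50
    cds_len = int(rng.integers(300, 901))
    n_iso = int(rng.integers(1, max_iso + 1))
    if motif_mode == "distal" and n_iso < 2:
        n_iso = 2
    utrs = np.sort(rng.choice(np.arange(30, 181), size=n_iso, replace=False))
    if motif_mode == "distal":
        # keep enough room between the two most distal sites for the motif
        for _ in range(50):
            if utrs[-1] - utrs[-2] >= len(motif_seq) + 2:
                break
            utrs = np.sort(rng.choice(np.arange(30, 181), size=n_iso, replace=False))
    cs, ce = u5, u5 + cds_len
    sites = [int(ce + u - 1) for u in utrs]
    L = ce + int(utrs[-1]) + 30
    seq = _break_a_runs(_rand_seq(rng, L))

    m_off = None
    mlen = len(motif_seq)
    if motif_mode == "distal":
        # between the second-most-distal and the distal site
        lo, hi = sites[-2] + 2, sites[-1] - mlen
        if hi < lo:
            motif_mode = "all"
        else:
            m_off = int(rng.integers(lo, hi + 1))
    if motif_mode == "all":
        lo, hi = ce + 1, sites[0] - mlen
        m_off = int(rng.integers(lo, hi + 1)) if hi >= lo else None
    if m_off is not None:
        seq = seq[:m_off] + motif_seq + seq[m_off + mlen :]

    cass = _Cassette(seq=seq)
    cass.genes.append((gene_id, cs, ce, "ORF"))
    for i, (utr, site) in enumerate(zip(utrs, sites)):
        tid = f"{gene_id}.t{i + 1}"
        cass.tifs.append((tid, 10, site))
        present = m_off is not None and (m_off + mlen - 1) <= site
        cass.truth.append(
            dict(tif_id=tid, gene_id=gene_id, category="coding_1orf", coding=True,
                 motif_present=present, utr3_length=int(utr))
        )
    return cass


def _bicistronic(rng, gid1, gid2) -> _Cassette:
    u5, l1, gap, l2 = 50, int(rng.integers(300, 601)), 60, int(rng.integers(300, 601))
    cs1, ce1 = u5, u5 + l1
    cs2, ce2 = ce1 + gap, ce1 + gap + l2
    utr = int(rng.integers(40, 120))
    site_both = ce2 + utr - 1
    site_first = cs2 - 20  # within the intergenic gap, past gene 1's stop
    L = site_both + 30
    cass = _Cassette(seq=_break_a_runs(_rand_seq(rng, L)))
    cass.genes += [(gid1, cs1, ce1, "ORF"), (gid2, cs2, ce2, "ORF")]
    cass.tifs += [(f"{gid1}.t1", 10, site_first), (f"{gid2}.bi", 10, site_both)]
    cass.truth += [
        dict(tif_id=f"{gid1}.t1", gene_id=gid1, category="coding_1orf", coding=True,
             motif_present=False, utr3_length=site_first - ce1 + 1),
        dict(tif_id=f"{gid2}.bi", gene_id=gid2, category="coding_2plus_orf",
             coding=True, motif_present=False, utr3_length=utr),
    ]
    return cass


def _partial_pair(rng, gid1, gid2) -> _Cassette:
    u5, l1, gap, l2 = 50, int(rng.integers(300, 601)), 50, int(rng.integers(300, 601))
    cs1, ce1 = u5, u5 + l1
    cs2, ce2 = ce1 + gap, ce1 + gap + l2
    start5 = cs1 + int(rng.integers(50, l1 - 50))
    end3 = cs2 + int(rng.integers(50, l2 - 50))
    L = ce2 + 80
    cass = _Cassette(seq=_break_a_runs(_rand_seq(rng, L)))
    cass.genes += [(gid1, cs1, ce1, "ORF"), (gid2, cs2, ce2, "ORF")]
    tid = f"{gid1}_{gid2}.part"
    cass.tifs.append((tid, start5, end3))
    cass.truth.append(
        dict(tif_id=tid, gene_id=f"{gid1};{gid2}", category="partial_2orf",
             coding=False, motif_present=False, utr3_length=np.nan)
    )
    return cass


def _overlap_cassette(rng, gid) -> _Cassette:
    """One ORF carrying a coding TIF plus intragenic / 3'- / 5'-overlap TIFs."""
    u5, cds_len = 50, int(rng.integers(500, 801))
    cs, ce = u5, u5 + cds_len
    utr = int(rng.integers(40, 140))
    site = ce + utr - 1
    L = site + 60
    cass = _Cassette(seq=_break_a_runs(_rand_seq(rng, L)))
    cass.genes.append((gid, cs, ce, "ORF"))
    specs = [
        (f"{gid}.t1", 10, site, "coding_1orf", True, utr),
        (f"{gid}.intra", cs + 60, cs + 300, "intragenic", False, np.nan),
        (f"{gid}.ov3", cs + 200, ce + 30, "overlap_3prime", False, np.nan),
        (f"{gid}.ov5", cs - 30, cs + 250, "overlap_5prime", False, np.nan),
    ]
    for tid, s5, e3, cat, coding, u in specs:
        cass.tifs.append((tid, s5, e3))
        cass.truth.append(
            dict(tif_id=tid, gene_id=gid, category=cat, coding=coding,
                 motif_present=False, utr3_length=u)
        )
    return cass


def _sut_cassette(rng, sut_id, with_motif: bool, motif_seq: str) -> _Cassette:
    length = int(rng.integers(250, 451))
    s0, s1 = 40, 40 + length
    site = s1 - 11
    L = s1 + 40
    seq = _break_a_runs(_rand_seq(rng, L))
    mlen = len(motif_seq)
    if with_motif:
        m_off = site - mlen - int(rng.integers(5, 40))
        seq = seq[:m_off] + motif_seq + seq[m_off + mlen :]
    cass = _Cassette(seq=seq)
    cass.genes.append((sut_id, s0, s1, "SUT"))
    tid = f"{sut_id}.t1"
    cass.tifs.append((tid, s0 + 5, site))
    cass.truth.append(
        dict(tif_id=tid, gene_id=sut_id, category="sut", coding=False,
             motif_present=with_motif, utr3_length=np.nan)
    )
    return cass


def _intergenic_cassette(rng, tid) -> _Cassette:
    length = int(rng.integers(150, 300))
    site = length - 30
    cass = _Cassette(seq=_break_a_runs(_rand_seq(rng, length)))
    cass.tifs.append((tid, 20, site))
    cass.truth.append(
        dict(tif_id=tid, gene_id="", category="intergenic", coding=False,
             motif_present=False, utr3_length=np.nan)
    )
    return cass


def _artifact_cassette(rng, a0: float) -> _Cassette:
    """A standalone false site with a 20-nt A tract directly downstream."""
    pre = _break_a_runs(_rand_seq(rng, 60))
    post = _break_a_runs(_rand_seq(rng, 30))
    seq = pre + "A" * 20 + post
    cass = _Cassette(seq=seq)
    cass.artifacts.append((len(pre) - 1, a0))
    return cass


def simulate_genome_and_annotation(
    n_genes: int = 60,
    seed: int = 0,
    p_motif_gene: float = 0.30,
    motif_all_fraction: float = 0.0,
    motif: str = PUF3_MOTIF,
    effect_multiplier: float = 2.0,
    half_life_range: tuple = (4.0, 180.0),
    depth: float = 200.0,
    a0_sigma: float = 0.7,
    n_spike: int = 24,
    spike_fraction: float = 1.0 / 9.0,
) -> SimWorld:
    """Generate a genome, annotations, and per-isoform ground truth.

    Standard coding genes carry 1-4 isoforms; additional cassettes
    realize every coverage category, divergent gene pairs, spike-in
    sites, and A-tract artifact sites.  Motif-carrying coding isoforms
    are destabilized ``effect_multiplier``-fold in the WT condition and
    revert to baseline in the mutant; motif-carrying non-coding isoforms
    are bound but not destabilized.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    n_special_pairs = max(1, n_genes // 16)  # bicistronic and partial pairs
    n_overlap = max(1, n_genes // 8)
    n_sut = max(3, n_genes // 8)
    n_intergenic = max(2, n_genes // 10)
    n_artifact = max(1, n_genes // 30)
    n_div_pairs = max(2, n_genes // 12)

    # motif placement is isoform-specific: only the distal isoform of a
    # motif gene carries it, so binding discriminates between isoforms
    # of the same gene (motif_all_fraction > 0 plants it upstream of
    # every site for that share of motif genes instead)
    n_motif = int(round(p_motif_gene * n_genes))
    motif_modes = {}
    motif_gene_ids = rng.choice(n_genes, size=n_motif, replace=False)
    n_all = int(round(motif_all_fraction * n_motif))
    for idx, g in enumerate(np.sort(motif_gene_ids)):
        motif_modes[int(g)] = "all" if idx < n_all else "distal"

    cassettes: list[_Cassette] = []
    # divergent pairs are built from the first 2 * n_div_pairs standard genes
    gene_idx = 0

    def next_gene_cassette() -> _Cassette:
        nonlocal gene_idx
        gid = f"gene{gene_idx + 1:04d}"
        mode = motif_modes.get(gene_idx, "none")
        cass = _standard_gene(rng, gid, mode, motif)
        gene_idx += 1
        return cass

    for _ in range(n_div_pairs):
        if gene_idx + 2 > n_genes:
            break
        left = next_gene_cassette().flip()  # minus strand, 5' at its right edge
        right = next_gene_cassette()
        spacer = _break_a_runs(_rand_seq(rng, int(rng.integers(5, 61))))
        merged = _Cassette(seq=left.seq + spacer + right.seq)
        off = len(left.seq) + len(spacer)
        merged.genes = left.genes + [(g, cs + off, ce + off, bt) for g, cs, ce, bt in right.genes]
        merged.tifs = [(t, s5, e3) for t, s5, e3 in left.tifs] + [
            (t, s5 + off, e3 + off) for t, s5, e3 in right.tifs
        ]
        merged.truth = left.truth + right.truth
        merged._strands = ["-"] * len(left.tifs) + ["+"] * len(right.tifs)
        merged._gene_strands = ["-"] * len(left.genes) + ["+"] * len(right.genes)
        cassettes.append(merged)
    while gene_idx < n_genes:
        cass = next_gene_cassette()
        if rng.random() < 0.5:
            cass = cass.flip()
            cass._strands = ["-"] * len(cass.tifs)
            cass._gene_strands = ["-"] * len(cass.genes)
        cassettes.append(cass)

    extra: list[_Cassette] = []
    for i in range(n_special_pairs):
        extra.append(_bicistronic(rng, f"bic{i + 1}a", f"bic{i + 1}b"))
        extra.append(_partial_pair(rng, f"par{i + 1}a", f"par{i + 1}b"))
    for i in range(n_overlap):
        extra.append(_overlap_cassette(rng, f"ovl{i + 1}"))
    for i in range(n_sut):
        extra.append(_sut_cassette(rng, f"SUT{i + 1:03d}", i % 2 == 0, motif))
    for i in range(n_intergenic):
        extra.append(_intergenic_cassette(rng, f"ig{i + 1}.t1"))
    for cass in extra:
        if rng.random() < 0.5:
            cass = cass.flip()
            cass._strands = ["-"] * len(cass.tifs)
            cass._gene_strands = ["-"] * len(cass.genes)
        cassettes.append(cass)
    # artifact tracts sit genomically downstream of plus-strand sites, so
    # these cassettes are never flipped
    for i in range(n_artifact):
        cassettes.append(_artifact_cassette(rng, a0=float(depth)))

    # --- assemble the chromosome -------------------------------------------
    chrom = "chrI"
    parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    tifs: list[FullLengthIsoform] = []
    truth_rows: list[dict] = []
    artifact_rows: list[dict] = []
    for cass in cassettes:
        spacer = _break_a_runs(_rand_seq(rng, int(rng.integers(40, 101))))
        parts += [spacer, cass.seq]
        cursor += len(spacer)
        strands = getattr(cass, "_strands", ["+"] * len(cass.tifs))
        gstrands = getattr(cass, "_gene_strands", ["+"] * len(cass.genes))
        for (gid, cs, ce, bt), st in zip(cass.genes, gstrands):
            genes.append(GeneModel(gid, chrom, cs + cursor, ce + cursor, st, bt))
        for (tid, s5, e3), st, tr in zip(cass.tifs, strands, cass.truth):
            tif = FullLengthIsoform(tid, chrom, st, s5 + cursor, e3 + cursor,
                                    support=int(rng.integers(1, 40)))
            tifs.append(tif)
            row = dict(tr)
            row.update(chrom=chrom, pos=tif.end3, strand=st, artifact=False)
            truth_rows.append(row)
        for (p, a0), st in zip(cass.artifacts, strands or ["+"]):
            artifact_rows.append(
                dict(chrom=chrom, pos=p + cursor, strand=st if cass.tifs else "+",
                     tif_id="", gene_id="", category="intergenic", coding=False,
                     motif_present=False, utr3_length=np.nan, artifact=True, A0_art=a0)
            )
        cursor += len(cass.seq)
    genome = {chrom: "".join(parts)}

    truth = pd.DataFrame(truth_rows + artifact_rows)
    # artifact strand handling: artifacts always plus strand of their tract
    truth["artifact"] = truth["artifact"].astype(bool)

    # --- ground-truth kinetics ---------------------------------------------
    lo, hi = np.log(half_life_range[0]), np.log(half_life_range[1])
    gene_ids = truth["gene_id"].fillna("")
    unique_genes = list(dict.fromkeys(gene_ids))
    t_half = {g: float(np.exp(rng.uniform(lo, hi))) for g in unique_genes}
    k_gene = truth["gene_id"].map(lambda g: np.log(2) / t_half[g])
    cat_mult = truth["category"].map(CATEGORY_K_MULT).fillna(1.0)
    truth["k_base"] = k_gene * cat_mult
    truth["bound"] = truth["motif_present"].astype(bool)
    truth["destabilized"] = truth["bound"] & truth["coding"].astype(bool)
    truth["k_wt"] = truth["k_base"] * np.where(truth["destabilized"], effect_multiplier, 1.0)
    truth["k_mut"] = truth["k_base"]
    truth["A0"] = np.where(
        truth["artifact"], truth.get("A0_art", depth),
        rng.lognormal(mean=np.log(depth), sigma=a0_sigma, size=len(truth)),
    )
    truth = truth.drop(columns=["A0_art"], errors="ignore")
    truth["site"] = truth["chrom"] + ":" + truth["pos"].astype(str) + ":" + truth["strand"]
    if truth["site"].duplicated().any():
        truth = truth[~truth["site"].duplicated()].reset_index(drop=True)

    # --- spike-in chromosome ------------------------------------------------
    spike_seq = _break_a_runs(_rand_seq(rng, 100 * (n_spike + 2)))
    spike_pos = [100 * (i + 1) for i in range(n_spike)]
    weights = rng.lognormal(0.0, 0.5, size=n_spike)
    total_sample = float(truth.loc[~truth["artifact"], "A0"].sum())
    spike_a0 = weights / weights.sum() * total_sample * spike_fraction
    spike_sites = pd.DataFrame(
        {"chrom": SPIKE_CHROM, "pos": spike_pos, "strand": "+", "A0": spike_a0}
    )
    genome[SPIKE_CHROM] = spike_seq

    motifs = pd.DataFrame(
        {"motif_id": ["PUF3", "DECOY"], "iupac": [motif, DECOY_MOTIF]}
    )
    missing = set(CATEGORY_K_MULT) - set(truth["category"])
    if missing:
        import warnings

        warnings.warn(
            f"n_genes={n_genes} too small to realize categories: {sorted(missing)}"
        )
    return SimWorld(genome, genes, tifs, motifs, truth, spike_sites, seed)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------
def nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts parameterized by mean and dispersion (Var = mu + alpha mu^2)."""
    if alpha < 0:
        raise ValidationError("dispersion must be non-negative")
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_decay_counts(
    world: SimWorld,
    config: RunConfig,
    conditions: Sequence[str] = ("WT",),
    alpha: Sequence[float] = DEFAULT_ALPHA,
    size_factor_sigma: float = 0.25,
    seed: Optional[int] = None,
) -> tuple[CountTable, pd.Series, dict]:
    """Simulate the decay time-course count table for a generated world.

    Returns (table, true size factors, true dispersion per (condition,
    timepoint)).  Sample isoforms decay as A0 * exp(-k t) with k from
    the condition-appropriate truth column; spike-in sites keep a
    constant expectation so they carry the calibration signal; all
    expectations are scaled by library size factors drawn log-normally
    around one.
    """
    alpha = list(alpha)
    if len(alpha) != len(config.timepoints):
        raise ValidationError("need one dispersion per timepoint")
    if any(a < 0 for a in alpha):
        raise ValidationError("dispersion must be non-negative")
    rng = np.random.default_rng(world.seed + 1 if seed is None else seed)

    libs = [
        (c, float(t), r)
        for c in conditions
        for t in config.timepoints
        for r in config.replicates
    ]
    s_true = pd.Series(
        rng.lognormal(0.0, size_factor_sigma, size=len(libs)),
        index=pd.MultiIndex.from_tuples(libs, names=["condition", "timepoint", "replicate"]),
        name="size_factor",
    )
    alpha_map = {
        (c, float(t)): float(a)
        for c in conditions
        for t, a in zip(config.timepoints, alpha)
    }

    truth = world.truth
    k_cols = {"WT": "k_wt", "mutant": "k_mut"}
    data = {}
    for (c, t, r), s in s_true.items():
        k = truth[k_cols.get(c, "k_wt")].to_numpy()
        mu_sample = s * truth["A0"].to_numpy() * np.exp(-k * t)
        mu_spike = s * world.spike_sites["A0"].to_numpy()
        a = alpha_map[(c, t)]
        data[(c, t, r)] = np.concatenate(
            [nb_draw(rng, mu_sample, a), nb_draw(rng, mu_spike, a)]
        )
    index = pd.MultiIndex.from_frame(
        pd.concat(
            [truth[["chrom", "pos", "strand"]],
             world.spike_sites[["chrom", "pos", "strand"]]],
            ignore_index=True,
        )
    )
    counts = pd.DataFrame(data, index=index)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    species = pd.Series(
        [config.sample_species] * len(truth) + [config.spike_species] * len(world.spike_sites),
        index=index,
    )
    return CountTable(counts, species), s_true, alpha_map


def simulate_rip_counts(
    world: SimWorld,
    enrichment: float = 8.0,
    background: float = 1.0,
    alpha: float = 0.05,
    n_rep: int = 3,
    size_factor_sigma: float = 0.15,
    seed: Optional[int] = None,
    sample_species: str = "scer",
) -> CountTable:
    """Simulate IP and input libraries with a planted bound set.

    Input counts are NB around steady-state abundance; IP expectations
    are multiplied by ``enrichment`` for bound isoforms and by
    ``background`` otherwise.
    """
    if enrichment <= 0:
        raise ValidationError("enrichment must be positive")
    rng = np.random.default_rng(world.seed + 2 if seed is None else seed)
    truth = world.truth
    libs = [(c, 0.0, f"R{r + 1}") for c in ("input", "IP") for r in range(n_rep)]
    s = rng.lognormal(0.0, size_factor_sigma, size=len(libs))
    fold = np.where(truth["bound"].to_numpy(), enrichment, background)
    data = {}
    for (c, t, r), sf in zip(libs, s):
        mu = sf * truth["A0"].to_numpy()
        if c == "IP":
            mu = mu * fold
        data[(c, t, r)] = nb_draw(rng, mu, alpha)
    index = pd.MultiIndex.from_frame(truth[["chrom", "pos", "strand"]])
    counts = pd.DataFrame(data, index=index)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    species = pd.Series(sample_species, index=index)
    return CountTable(counts, species)


# ---------------------------------------------------------------------------
# Lightweight isoform-level simulation (no genome needed)
# ---------------------------------------------------------------------------
def simulate_isoform_counts(
    n_isoforms: int = 500,
    seed: int = 0,
    timepoints: Sequence[float] = (0, 5, 10, 20, 40),
    n_reps: int = 2,
    half_life_range: tuple = (4.0, 180.0),
    depth: float = 200.0,
    alpha: Sequence[float] = DEFAULT_ALPHA,
    size_factor_sigma: float = 0.25,
    k_true: Optional[np.ndarray] = None,
    isoforms_per_gene: int = 1,
    n_spike: int = 24,
    spike_fraction: float = 1.0 / 9.0,
    condition: str = "WT",
    a0_sigma: float = 0.7,
) -> tuple[CountTable, pd.DataFrame, pd.Series]:
    """Direct isoform-level count simulation with known decay rates.

    Half-lives are drawn log-uniformly (shared within gene when
    ``isoforms_per_gene`` > 1 and ``k_true`` is not given), abundances
    log-normally around ``depth``.  Returns (table, truth, true size
    factors); species tags are ``sample`` and ``spike``.
    """
    rng = np.random.default_rng(seed)
    timepoints = [float(t) for t in timepoints]
    if k_true is None:
        n_genes = int(np.ceil(n_isoforms / isoforms_per_gene))
        lo, hi = np.log(half_life_range[0]), np.log(half_life_range[1])
        k_gene = np.log(2) / np.exp(rng.uniform(lo, hi, size=n_genes))
        k_true = np.repeat(k_gene, isoforms_per_gene)[:n_isoforms]
    else:
        k_true = np.asarray(k_true, dtype=float)
        n_isoforms = len(k_true)
    A0 = rng.lognormal(np.log(depth), a0_sigma, size=n_isoforms)
    gene_id = [f"g{i // isoforms_per_gene + 1:05d}" for i in range(n_isoforms)]
    pos = 10 + 7 * np.arange(n_isoforms) + rng.integers(0, 3, size=n_isoforms)

    spike_a0 = rng.lognormal(0.0, 0.5, size=n_spike)
    spike_a0 = spike_a0 / spike_a0.sum() * A0.sum() * spike_fraction

    libs = [(condition, t, f"R{r + 1}") for t in timepoints for r in range(n_reps)]
    s_true = pd.Series(
        rng.lognormal(0.0, size_factor_sigma, size=len(libs)),
        index=pd.MultiIndex.from_tuples(libs, names=["condition", "timepoint", "replicate"]),
        name="size_factor",
    )
    data = {}
    for (c, t, r), s in s_true.items():
        a = alpha[timepoints.index(t)]
        mu = s * A0 * np.exp(-k_true * t)
        data[(c, t, r)] = np.concatenate(
            [nb_draw(rng, mu, a), nb_draw(rng, s * spike_a0, a)]
        )
    chroms = ["sim"] * n_isoforms + ["spike_sim"] * n_spike
    positions = list(pos) + [100 * (i + 1) for i in range(n_spike)]
    strands = ["+"] * (n_isoforms + n_spike)
    index = pd.MultiIndex.from_arrays(
        [chroms, positions, strands], names=["chrom", "pos", "strand"]
    )
    counts = pd.DataFrame(data, index=index)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    species = pd.Series(["sample"] * n_isoforms + ["spike"] * n_spike, index=index)
    truth = pd.DataFrame(
        {
            "chrom": chroms[:n_isoforms],
            "pos": positions[:n_isoforms],
            "strand": "+",
            "gene_id": gene_id,
            "k_true": k_true,
            "A0": A0,
        }
    )
    truth["site"] = truth["chrom"] + ":" + truth["pos"].astype(str) + ":" + truth["strand"]
    return CountTable(counts, species), truth, s_true
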