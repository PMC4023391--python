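"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open on the forward genomic strand
(BED-style).  A poly(A) site is the single genomic position of the last
templated transcript nucleotide; "downstream" of a site is strand-aware.
Count tables are keyed by (chrom, pos, strand) and carry one count column
per sequencing library, a library being a (condition, timepoint,
replicate) triple.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
SITE_INDEX = ["chrom", "pos", "strand"]
LIBRARY_LEVELS = ["condition", "timepoint", "replicate"]


class ValidationError(ValueError):
    """A record violated a domain-type invariant."""


class FormatError(ValueError):
    """An input file did not match the expected layout."""


@dataclass(frozen=True)
class GenomeCoordinate:
    """A stranded single-nucleotide genomic position."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: an ORF with a CDS interval, or a SUT transcript."""

    gene_id: str
    chrom: str
    cds_start: int
    cds_end: int
    strand: str
    biotype: str = "ORF"

    def __post_init__(self) -> None:
        if self.cds_start < 0 or not self.cds_start < self.cds_end:
            raise ValidationError(
                f"{self.gene_id}: invalid interval [{self.cds_start}, {self.cds_end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.biotype not in ("ORF", "SUT"):
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def five_prime_point(self) -> int:
        """Genomic position of the transcript-orientation first CDS base."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    @property
    def three_prime_point(self) -> int:
        """Genomic position of the transcript-orientation last CDS base."""
        return self.cds_end - 1 if self.strand == "+" else self.cds_start


@dataclass(frozen=True)
class FullLengthIsoform:
    """A full-length transcript isoform, defined by a joint 5'-start/3'-end pair.

    ``start5`` and ``end3`` are genomic positions of the first and last
    transcribed bases in transcript orientation, so on the minus strand
    ``start5 >= end3`` in genomic order.
    """

    tif_id: str
    chrom: str
    strand: str
    start5: int
    end3: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.tif_id}: invalid strand {self.strand!r}")
        if self.support < 1:
            raise ValidationError(f"{self.tif_id}: support must be >= 1")
        if min(self.start5, self.end3) < 0:
            raise ValidationError(f"{self.tif_id}: negative coordinate")
        if self.strand == "+" and self.start5 > self.end3:
            raise ValidationError(f"{self.tif_id}: plus-strand 5' end downstream of 3' end")
        if self.strand == "-" and self.start5 < self.end3:
            raise ValidationError(f"{self.tif_id}: minus-strand 5' end downstream of 3' end")

    @property
    def lo(self) -> int:
        """Genomic interval start (0-based, inclusive)."""
        return min(self.start5, self.end3)

    @property
    def hi(self) -> int:
        """Genomic interval end (half-open)."""
        return max(self.start5, self.end3) + 1

    @property
    def site(self) -> GenomeCoordinate:
        return GenomeCoordinate(self.chrom, self.end3, self.strand)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults encode the standard study design."""

    timepoints: tuple = (0, 5, 10, 20, 40)
    replicates: tuple = ("R1", "R2")
    spike_species: str = "spombe"
    sample_species: str = "scer"
    mispriming_window: int = 18
    mispriming_max_a_frac: float = 0.67
    mispriming_max_run: int = 6
    min_count: float = 16.0
    min_timepoints: int = 3
    fdr_level: float = 0.1
    rip_fc_cutoff: float = 4.0
    tif_match_tolerance: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValidationError("fdr_level must be in (0, 1)")
        self.replicates = tuple(str(r) for r in self.replicates)

    def to_header_dict(self) -> dict:
        return {
            "timepoints": ",".join(str(t) for t in self.timepoints),
            "replicates": ",".join(self.replicates),
            "spike_species": self.spike_species,
            "fdr_level": self.fdr_level,
            "rip_fc_cutoff": self.rip_fc_cutoff,
            "seed": self.seed,
        }


def library_columns(
    conditions: Sequence[str], timepoints: Sequence[float], replicates: Sequence[str]
) -> pd.MultiIndex:
    tuples = [
        (c, float(t), str(r)) for c in conditions for t in timepoints for r in replicates
    ]
    return pd.MultiIndex.from_tuples(tuples, names=LIBRARY_LEVELS)


class CountTable:
    """Per-site 3' end read counts over sequencing libraries.

    Attributes
    ----------
    counts : DataFrame indexed by (chrom, pos, strand) with a column
        MultiIndex of (condition, timepoint, replicate); values are
        non-negative counts.
    species : Series aligned with ``counts`` giving the species tag of
        each site (spike-in sites never enter decay fitting).
    """

    def __init__(self, counts: pd.DataFrame, species: pd.Series):
        if not isinstance(counts.columns, pd.MultiIndex) or counts.columns.nlevels != 3:
            raise ValidationError("count columns must be (condition, timepoint, replicate)")
        counts = counts.copy()
        counts.columns = counts.columns.set_names(LIBRARY_LEVELS)
        counts.index = counts.index.set_names(SITE_INDEX)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts are not allowed")
        strands = counts.index.get_level_values("strand")
        bad = ~strands.isin(STRANDS)
        if bad.any():
            raise ValidationError(
                f"invalid strand value(s): {sorted(set(strands[bad]))}"
            )
        self.counts = counts
        self.species = species.reindex(counts.index)
        if self.species.isna().any():
            raise ValidationError("every site needs a species tag")

    # -- basic introspection -------------------------------------------------
    @property
    def libraries(self) -> list:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.counts.columns.get_level_values("condition")))

    @property
    def timepoints(self) -> list:
        return sorted(set(self.counts.columns.get_level_values("timepoint")))

    @property
    def replicates(self) -> list:
        return list(dict.fromkeys(self.counts.columns.get_level_values("replicate")))

    def spike_mask(self, spike_species: str) -> pd.Series:
        return self.species == spike_species

    def sample_counts(self, spike_species: str) -> pd.DataFrame:
        return self.counts.loc[~self.spike_mask(spike_species)]

    def spike_counts(self, spike_species: str) -> pd.DataFrame:
        return self.counts.loc[self.spike_mask(spike_species)]

    def subset(self, mask) -> "CountTable":
        return CountTable(self.counts.loc[mask], self.species.loc[mask])

    def __len__(self) -> int:
        return len(self.counts)

    def equals(self, other: "CountTable") -> bool:
        return self.counts.equals(other.counts) and self.species.equals(other.species)

    def normalized(self, factors: pd.Series) -> pd.DataFrame:
        """Counts divided by per-library size factors (float-valued)."""
        s = factors.reindex(self.counts.columns)
        if s.isna().any():
            missing = list(self.counts.columns[s.isna()])
            raise ValidationError(f"missing size factors for libraries {missing}")
        return self.counts / s


@dataclass
class DispersionModel:
    """Per-(condition, timepoint) NB dispersion trend alpha(mu) = a0 + a1/mu.

    Coefficients are clipped at zero and predictions floored at
    ``floor`` so the variance model Var = mu + alpha * mu^2 stays valid
    over the whole data range.
    """

    trends: Mapping[tuple, tuple]
    floor: float = 0.0

    def alpha(self, condition: str, timepoint: float, mu) -> np.ndarray:
        a0, a1 = self.trends[(condition, float(timepoint))]
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            a = a0 + a1 / np.where(mu > 0, mu, np.nan)
        a = np.where(np.isfinite(a), a, self.floor)
        return np.maximum(a, self.floor)


def site_frame(sites: Iterable[GenomeCoordinate]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(s.chrom, s.pos, s.strand) for s in sites], names=SITE_INDEX
    )
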