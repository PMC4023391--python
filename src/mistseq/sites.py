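"""Cleaning and calibration of poly(A)-site count tables.

Three concerns live here: removal of internal-mispriming artifacts
(sites whose downstream genomic sequence is A-rich enough to capture the
oligo-dT primer directly), spike-in based size-factor estimation, and
the per-timepoint negative-binomial dispersion trend that downstream
regression weights are built from.
"""
from __future__ import annotations

import logging
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gmean

from .model import CountTable, DispersionModel, RunConfig, ValidationError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _chrom_seq(genome, chrom: str) -> str:
    return str(genome[chrom][:])


def downstream_window(genome, chrom: str, pos: int, strand: str, window: int) -> str:
    """Sense-strand sequence of the ``window`` nt downstream of a site.

    Downstream means 3' of the site in transcript orientation: genomic
    right of ``pos`` on plus-strand sites, genomic left (reverse
    complemented) on minus-strand sites.  Windows running off the
    chromosome end are truncated.
    """
    n = len(genome[chrom])
    if strand == "+":
        a, b = pos + 1, min(pos + 1 + window, n)
        if a >= b:
            return ""
        return str(genome[chrom][a:b]).upper()
    a, b = max(pos - window, 0), pos
    if a >= b:
        return ""
    return revcomp(str(genome[chrom][a:b]).upper())


def _max_a_run(seq: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best


def filter_mispriming(
    table: CountTable,
    genome,
    window: int = 18,
    max_a_frac: float = 0.67,
    max_run: int = 6,
) -> tuple[CountTable, pd.DataFrame]:
    """Remove sites whose downstream window is A-rich on the sense strand.

    A site is removed when the downstream ``window`` nt (default 18)
    have an A fraction above ``max_a_frac`` (default 0.67) or contain a
    run of ``max_run`` (default 6) or more consecutive A.  Returns the
    filtered table and a removal report.
    """
    keep = np.ones(len(table), dtype=bool)
    report_rows = []
    for i, (chrom, pos, strand) in enumerate(table.counts.index):
        win = downstream_window(genome, chrom, pos, strand, window)
        if not win:
            continue
        if len(win) < window:
            log.info("site %s:%s:%s window truncated to %d nt", chrom, pos, strand, len(win))
        a_frac = win.count("A") / len(win)
        run = _max_a_run(win)
        if a_frac > max_a_frac or run >= max_run:
            keep[i] = False
            reason = "a_fraction" if a_frac > max_a_frac else "a_run"
            report_rows.append((chrom, pos, strand, reason, round(a_frac, 4), run, win))
    report = pd.DataFrame(
        report_rows,
        columns=["chrom", "pos", "strand", "reason", "a_frac", "a_run", "window_seq"],
    )
    log.info("mispriming filter removed %d of %d sites", (~keep).sum(), len(keep))
    return table.subset(keep), report


def spike_size_factors(
    table: CountTable,
    spike_species: str,
    anchor: str = "nominal",
    nominal: float = 1e4,
) -> pd.Series:
    """Library size factors from total spike-in counts.

    The spike-in population represents the same number of molecules in
    every library, so per-library spike totals are direct measures of
    capture efficiency and s is proportional to them.  Anchoring fixes
    the proportionality constant:

    - ``nominal`` (default): s = spike total / ``nominal``, i.e.
      normalized counts are counts per ``nominal`` spike reads.  The
      anchor is data-independent, so rescaling one library's raw counts
      leaves its normalized counts exactly unchanged.
    - ``condition`` / ``all``: s = spike total / geometric mean of spike
      totals over the libraries of the same condition (or all
      libraries), giving factors with geometric mean one; here the
      anchor shifts when any library is rescaled.
    """
    spikes = table.spike_counts(spike_species)
    totals = spikes.sum(axis=0).astype(float)
    if len(spikes) == 0 or (totals == 0).any():
        zero = list(totals.index[totals == 0]) if len(spikes) else list(totals.index)
        raise ValidationError(
            f"normalization impossible: zero spike-in counts in libraries {zero}"
        )
    if anchor == "nominal":
        s = totals / float(nominal)
    elif anchor == "condition":
        s = totals.groupby(level="condition", group_keys=False).apply(
            lambda t: t / gmean(t)
        )
        s = s.reindex(totals.index)
    elif anchor == "all":
        s = totals / gmean(totals)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    s.name = "size_factor"
    return s


def mom_dispersion(mean: np.ndarray, var: np.ndarray, clip: bool = True) -> np.ndarray:
    """Method-of-moments NB dispersion (v - m) / m^2, clipped at 0 by default.

    For trend fitting the unclipped values must be used: with few
    replicates the estimates are strongly right-skewed, and clipping the
    negative half before averaging biases any fitted trend upward while
    robust location estimates of the clipped values are biased downward.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (var - mean) / mean**2
    a = np.where(np.isfinite(a), a, 0.0)
    return np.maximum(a, 0.0) if clip else a


def fit_dispersion_trend(
    mean: np.ndarray,
    alpha_hat: np.ndarray,
    min_mean: float = 8.0,
    robust: bool = False,
) -> tuple[float, float]:
    """Fit the trend alpha(mu) = a0 + a1 / mu over per-site estimates.

    Plain least squares on the (unclipped) moment estimates is the
    default: the estimates are noisy but nearly unbiased, so their
    conditional mean is the trend, whereas robust location targets
    their (much lower) center.  Coefficients are clipped at zero so the
    trend never predicts a negative dispersion.
    """
    mean = np.asarray(mean, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    use = mean > min_mean
    if use.sum() < 5:
        fallback = alpha_hat[mean > 0].mean() if (mean > 0).any() else 0.0
        return float(np.clip(fallback, 0, None)), 0.0
    x = sm.add_constant(1.0 / mean[use])
    if robust:
        fit = sm.RLM(alpha_hat[use], x, M=sm.robust.norms.HuberT()).fit()
    else:
        fit = sm.OLS(alpha_hat[use], x).fit()
    a0, a1 = fit.params
    return float(max(a0, 0.0)), float(max(a1, 0.0))


def estimate_dispersion(
    table: CountTable,
    factors: pd.Series,
    spike_species: str,
    min_mean: float = 8.0,
    floor: float = 0.0,
) -> DispersionModel:
    """Per-(condition, timepoint) dispersion trend from replicate scatter.

    For every site and timepoint the replicate mean m and variance v of
    normalized counts give a method-of-moments estimate
    alpha = max(0, (v - m)/m^2); the parametric trend a0 + a1/mu is then
    fit robustly over sites with m > ``min_mean``.  Per-site estimates
    are far too noisy with few replicates, so only the trend is ever
    used downstream.
    """
    norm = table.normalized(factors)
    norm = norm.loc[~table.spike_mask(spike_species)]
    trends = {}
    for (cond, tp), sub in norm.T.groupby(level=["condition", "timepoint"], sort=False):
        reps = sub.T  # sites x replicates
        if reps.shape[1] < 2:
            raise ValidationError(
                f"timepoint {tp} in condition {cond} has a single replicate; "
                "use a pooled-dispersion fallback"
            )
        m = reps.mean(axis=1).to_numpy()
        v = reps.var(axis=1, ddof=1).to_numpy()
        ok = m > 0
        a_hat = mom_dispersion(m[ok], v[ok], clip=False)
        trends[(cond, float(tp))] = fit_dispersion_trend(m[ok], a_hat, min_mean)
    return DispersionModel(trends=trends, floor=floor)


def filter_reliable(
    table: CountTable,
    factors: pd.Series,
    spike_species: str,
    min_count: float = 16.0,
    min_timepoints: int = 3,
) -> CountTable:
    """Keep sample sites quantified reliably in every condition.

    Reliability per condition: mean normalized count across replicates
    at the first timepoint >= ``min_count`` and at least
    ``min_timepoints`` timepoints with a nonzero replicate-mean count.
    Spike-in sites pass through untouched.
    """
    norm = table.normalized(factors)
    keep = pd.Series(True, index=table.counts.index)
    for cond in table.conditions:
        sub = norm.xs(cond, axis=1, level="condition")
        by_tp = sub.T.groupby(level="timepoint").mean().T  # sites x timepoints
        first_tp = by_tp.columns.min()
        ok = (by_tp[first_tp] >= min_count) & ((by_tp > 0).sum(axis=1) >= min_timepoints)
        keep &= ok
    keep |= table.spike_mask(spike_species)
    removed = int((~keep).sum())
    log.info("reliability filter removed %d of %d sites", removed, len(keep))
    return table.subset(keep)


def clean_and_normalize(
    table: CountTable, genome, config: RunConfig
) -> tuple[CountTable, pd.Series, DispersionModel, pd.DataFrame]:
    """Convenience wrapper chaining the full site-level stage."""
    filtered, report = filter_mispriming(
        table,
        genome,
        window=config.mispriming_window,
        max_a_frac=config.mispriming_max_a_frac,
        max_run=config.mispriming_max_run,
    )
    factors = spike_size_factors(filtered, config.spike_species)
    disp = estimate_dispersion(filtered, factors, config.spike_species)
    reliable = filter_reliable(
        filtered,
        factors,
        config.spike_species,
        min_count=config.min_count,
        min_timepoints=config.min_timepoints,
    )
    return reliable, factors, disp, report
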