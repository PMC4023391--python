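"""Per-isoform decay-rate estimation and differential-stability testing.

The model: after transcriptional arrest, the expected normalized count
of an isoform follows mu(t) = A0 * exp(-k t), so log counts are linear
in time with slope -k.  Counts are negative-binomially distributed
(Var = mu + alpha mu^2), and by the delta method the variance of a log
count is approximately Var(ln K) = 1/mu_raw + alpha(mu_norm).  Fits are
weighted least squares with those inverse variances as weights, a slope
shared across replicates and replicate-specific intercepts.  Because the
weights come from an external variance model (not from residuals), the
coefficient covariance is (X' W X)^-1 without a residual-variance
scale, which is what makes the downstream z-tests calibrated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm as normal, spearmanr
from statsmodels.stats.multitest import multipletests

from .model import CountTable, DispersionModel, RunConfig, ValidationError

QC_OK = "ok"
QC_NONDECAYING = "nondecaying"
QC_INSUFFICIENT = "insufficient_points"


def wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form weighted least squares with known weights.

    Returns (beta, cov) with beta = (X'WX)^-1 X'Wy and cov = (X'WX)^-1.
    """
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ y)
    cov = np.linalg.inv(xtx)
    return beta, cov


@dataclass
class DecayFit:
    k: float
    se_k: float
    half_life: float
    n_points: int
    qc: str
    intercepts: dict
    n0: float  # fitted normalized abundance at t = 0 (mean over replicates)


def fit_decay(
    timepoints: np.ndarray,
    raw: np.ndarray,
    size_factors: np.ndarray,
    alpha_fn: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
    weighted: bool = True,
    n_iter: int = 2,
    bias_correction: bool = True,
    replicates: Optional[list] = None,
) -> DecayFit:
    """Fit a single isoform's decay rate.

    Parameters
    ----------
    timepoints : (T,) minutes.
    raw : (T, R) raw counts; zeros are dropped from the fit (log of
        zero is undefined and the weighting already down-weights small
        expectations).
    size_factors : (T, R) per-library size factors.
    alpha_fn : maps (timepoints, mu_norm) -> dispersion; required when
        ``weighted``.
    weighted : if False, ordinary least squares (all weights one) on the
        raw log counts; the uncorrected "traditional" fit.
    n_iter : weighted refinement passes after the initial OLS pass.
        Weights always come from fitted means, never from the observed
        counts themselves: plugging single noisy observations into the
        variance formula couples the weights to the noise and makes the
        standard errors anticonservative.
    bias_correction : second-order Taylor correction of the log-count
        mean, E[ln K] ~ ln mu - (1/mu + alpha)/2.  Because the
        dispersion rises at late timepoints, the uncorrected log
        systematically sags there, steepening slopes; the correction
        removes that drift.  Only applies to the weighted fit (it needs
        the same variance model the weights use).
    """
    timepoints = np.asarray(timepoints, dtype=float)
    raw = np.asarray(raw, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    T, R = raw.shape
    if replicates is None:
        replicates = [f"R{r + 1}" for r in range(R)]

    t_idx, r_idx = np.nonzero(raw > 0)
    n_points = len(t_idx)
    if n_points < 3 or len(np.unique(t_idx)) < 2:
        return DecayFit(np.nan, np.nan, np.nan, n_points, QC_INSUFFICIENT, {}, np.nan)

    t = timepoints[t_idx]
    K = raw[t_idx, r_idx]
    s = size_factors[t_idx, r_idx]
    y = np.log(K / s)

    reps_used = np.unique(r_idx)
    X = np.zeros((n_points, len(reps_used) + 1))
    for j, r in enumerate(reps_used):
        X[r_idx == r, j] = 1.0
    X[:, -1] = t

    beta, cov = wls_fit(X, y, np.ones(n_points))  # OLS pilot fit
    if weighted:
        for _ in range(max(n_iter, 1)):
            mu_norm = np.exp(X @ beta)
            mu_raw = mu_norm * s
            alpha = alpha_fn(t, mu_norm)
            var_log = 1.0 / mu_raw + alpha
            w = 1.0 / var_log
            y_fit = y + 0.5 * var_log if bias_correction else y
            beta, cov = wls_fit(X, y_fit, w)

    k = -beta[-1]
    se_k = float(np.sqrt(cov[-1, -1]))
    intercepts = {replicates[r]: float(beta[j]) for j, r in enumerate(reps_used)}
    n0 = float(np.exp(np.mean(beta[:-1])))
    if abs(k) < 1e-12:  # numerically flat slope
        k = 0.0
    if k <= 0:
        return DecayFit(float(k), se_k, np.inf, n_points, QC_NONDECAYING, intercepts, n0)
    return DecayFit(float(k), se_k, float(np.log(2) / k), n_points, QC_OK, intercepts, n0)


def _alpha_fn(disp: DispersionModel, condition: str):
    def fn(t: np.ndarray, mu: np.ndarray) -> np.ndarray:
        out = np.empty(len(t))
        for tp in np.unique(t):
            sel = t == tp
            out[sel] = disp.alpha(condition, tp, mu[sel])
        return out

    return fn


def fit_all(
    table: CountTable,
    factors: pd.Series,
    disp: Optional[DispersionModel],
    config: RunConfig,
    condition: str,
    replicate: Optional[str] = None,
    weighted: bool = True,
    bias_correction: bool = True,
    include_t0: bool = True,
) -> pd.DataFrame:
    """Fit every sample site of one condition; returns a tidy fit table.

    ``replicate`` restricts to a single replicate (independent-replicate
    mode, used for concordance analysis); the default joint fit shares
    the slope across replicates.
    """
    counts = table.sample_counts(config.spike_species)
    cols = counts.columns
    sel = cols.get_level_values("condition") == condition
    if replicate is not None:
        sel &= cols.get_level_values("replicate") == replicate
    cols = cols[sel]
    if not include_t0:
        cols = cols[cols.get_level_values("timepoint") > min(config.timepoints)]
    timepoints = np.array(sorted(set(cols.get_level_values("timepoint"))))
    reps = list(dict.fromkeys(cols.get_level_values("replicate")))
    ordered = [(condition, tp, r) for tp in timepoints for r in reps]
    raw = counts[ordered].to_numpy(dtype=float)
    s = factors.reindex(ordered).to_numpy(dtype=float)
    s_mat = np.broadcast_to(s, (len(raw), len(s)))

    alpha_fn = _alpha_fn(disp, condition) if weighted else None
    rows = []
    for i, key in enumerate(counts.index):
        fit = fit_decay(
            timepoints,
            raw[i].reshape(len(timepoints), len(reps)),
            s_mat[i].reshape(len(timepoints), len(reps)),
            alpha_fn=alpha_fn,
            weighted=weighted,
            bias_correction=bias_correction,
            replicates=reps,
        )
        rows.append(
            (*key, condition, fit.k, fit.se_k, fit.half_life, fit.n_points, fit.qc, fit.n0)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "condition", "k", "se_k", "half_life",
            "n_points", "qc", "n0",
        ],
    )
    out["site"] = out["chrom"] + ":" + out["pos"].astype(str) + ":" + out["strand"]
    return out


def replicate_concordance(fits_rep1: pd.DataFrame, fits_rep2: pd.DataFrame) -> dict:
    """Spearman correlation of decay rates fit independently per replicate."""
    a = fits_rep1[fits_rep1["qc"] == QC_OK].set_index("site")["k"]
    b = fits_rep2[fits_rep2["qc"] == QC_OK].set_index("site")["k"]
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValidationError(
            f"only {len(shared)} sites fit in both replicates; need at least 10"
        )
    rho, p = spearmanr(a.loc[shared], b.loc[shared])
    scatter = pd.DataFrame({"k_rep1": a.loc[shared], "k_rep2": b.loc[shared]})
    return {"spearman": float(rho), "p": float(p), "n": len(shared), "table": scatter}


def test_pairs(
    fits: pd.DataFrame,
    fdr_level: float = 0.1,
    coding_only: bool = True,
    per_gene_bh: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided z-tests for differential stability between isoform pairs.

    ``fits`` must carry ``gene_id`` (and ``coding`` when
    ``coding_only``).  Every unordered pair of qc-pass fits within a
    gene is tested with z = (k_A - k_B) / sqrt(se_A^2 + se_B^2);
    Benjamini-Hochberg adjustment is applied across all pairs
    genome-wide (per-gene adjustment behind ``per_gene_bh``).  The gene
    summary flags genes with any significant pair and reports the
    maximum half-life fold ratio.
    """
    df = fits[fits["qc"] == QC_OK].copy()
    if coding_only and "coding" in df.columns:
        df = df[df["coding"].astype(bool)]
    if (df["se_k"] <= 0).any():
        raise ValidationError("degenerate fit with se_k <= 0 passed to test_pairs")
    rows = []
    for gene, sub in df.groupby("gene_id", sort=True):
        sub = sub.drop_duplicates("site").sort_values("pos")
        recs = list(sub.itertuples())
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                dk = a.k - b.k
                se = np.hypot(a.se_k, b.se_k)
                z = dk / se
                p = 2.0 * normal.sf(abs(z))
                rows.append(
                    (gene, a.site, b.site, dk, z, p, abs(a.pos - b.pos),
                     a.k, b.k, a.half_life, b.half_life)
                )
    pairs = pd.DataFrame(
        rows,
        columns=["gene_id", "site_a", "site_b", "delta_k", "z", "p", "distance_nt",
                 "k_a", "k_b", "half_life_a", "half_life_b"],
    )
    if len(pairs):
        if per_gene_bh:
            pairs["q"] = pairs.groupby("gene_id")["p"].transform(
                lambda p: multipletests(p, method="fdr_bh")[1]
            )
        else:
            pairs["q"] = multipletests(pairs["p"], method="fdr_bh")[1]
        pairs["significant"] = pairs["q"] < fdr_level
    else:
        pairs["q"] = pd.Series(dtype=float)
        pairs["significant"] = pd.Series(dtype=bool)

    summaries = []
    for gene, sub in df.groupby("gene_id", sort=True):
        ks = sub.drop_duplicates("site")["k"]
        pair_sub = pairs[pairs["gene_id"] == gene]
        fold = float(ks.max() / ks.min()) if len(ks) > 1 and ks.min() > 0 else np.nan
        summaries.append(
            (gene, len(ks), bool(pair_sub["significant"].any()) if len(pair_sub) else False,
             fold)
        )
    genes = pd.DataFrame(
        summaries, columns=["gene_id", "n_isoforms", "any_significant", "max_fold_ratio"]
    )
    genes["over_fourfold"] = genes["any_significant"] & (genes["max_fold_ratio"] > 4)
    return pairs, genes


def aggregate_gene_decay(fits: pd.DataFrame, weight_col: str = "n0") -> pd.DataFrame:
    """Abundance-weighted mean decay rate per gene.

    A gene's overall decay is the composite of its isoforms' rates,
    weighted by fitted time-zero abundance.
    """
    df = fits[(fits["qc"] == QC_OK)].copy()
    if "gene_id" not in df.columns:
        raise ValidationError("fits need a gene_id column for gene aggregation")
    df = df.drop_duplicates(["gene_id", "site"])

    def agg(sub: pd.DataFrame) -> pd.Series:
        w = sub[weight_col].to_numpy(dtype=float)
        if not np.isfinite(w).all() or w.sum() <= 0:
            w = np.ones(len(sub))
        k = float(np.average(sub["k"], weights=w))
        return pd.Series({"k": k, "half_life": np.log(2) / k if k > 0 else np.inf,
                          "n_isoforms": len(sub)})

    out = df.groupby("gene_id").apply(agg, include_groups=False).reset_index()
    return out


def relative_decay_ratio(fits_mutant: pd.DataFrame, fits_wt: pd.DataFrame) -> pd.DataFrame:
    """Per-isoform mutant/WT decay-rate ratio table.

    Ratios are undefined (row flagged and excluded from ``usable``) when
    either condition failed qc or the WT rate is non-positive.
    """
    m = fits_mutant.set_index("site")
    w = fits_wt.set_index("site")
    shared = m.index.intersection(w.index)
    out = pd.DataFrame(index=shared)
    out["k_mutant"] = m.loc[shared, "k"]
    out["k_wt"] = w.loc[shared, "k"]
    out["qc_pass"] = (m.loc[shared, "qc"] == QC_OK) & (w.loc[shared, "qc"] == QC_OK)
    out["usable"] = out["qc_pass"] & (out["k_wt"] > 0)
    out["ratio"] = np.where(out["usable"], out["k_mutant"] / out["k_wt"], np.nan)
    for col in ("gene_id", "coding"):
        if col in w.columns:
            out[col] = w.loc[shared, col]
    return out.reset_index()
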