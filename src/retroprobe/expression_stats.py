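"""Probe-level expression preprocessing and selection statistics.

Implements the probe-level half of an RMA-style workflow (background
correction under an exponential-signal + Gaussian-noise convolution model,
quantile normalization, log2) together with the summarization and selection
statistics applied downstream: one-step Tukey biweight probeset
summarization (c=5, eps=1e-4), per-probe fixed-effects ANOVA with blocking
factors eliminated first, Holm-Bonferroni concordance testing of single
RE-probe probesets, nearest-gene regression, and hierarchical clustering on
correlation distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .models import (
    BiweightParams,
    ExpressionMatrix,
    PlatformManifest,
    REAnnotationRow,
    Scale,
)

logger = logging.getLogger(__name__)


# ------------------------------------------------------- background correction

def _estimate_convolution_params(x: np.ndarray) -> tuple[float, float, float]:
    """Ad hoc (mode-based) estimate of (alpha, mu, sigma) for the
    observed = Exponential(alpha) + Normal(mu, sigma^2) model."""
    if np.ptp(x) == 0:
        raise ValueError(
            "array has zero variance; background parameters are degenerate "
            "(rerun with background correction disabled, --no-bgcorrect)"
        )
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    mu = float(grid[np.argmax(kde(grid))])
    below = x[x < mu]
    if below.size < 2:
        below = x[x <= np.quantile(x, 0.25)]
    # half-normal spread of the sub-mode tail
    sigma = float(np.sqrt(np.mean((below - mu) ** 2) * 2.0))
    above = x[x > mu]
    mean_excess = float(np.mean(above - mu)) if above.size else float(np.mean(np.abs(x - mu)))
    alpha = 1.0 / max(mean_excess, 1e-12)
    sigma = max(sigma, 1e-12)
    return alpha, mu, sigma


def _posterior_signal(x: np.ndarray, alpha: float, mu: float, sigma: float) -> np.ndarray:
    """Posterior expected signal E[s | o = s + n]; strictly positive and
    monotone increasing in x (computed via the stable log-Mills ratio)."""
    a = x - mu - sigma * sigma * alpha
    r = a / sigma
    mills = np.exp(stats.norm.logpdf(r) - stats.norm.logcdf(r))
    return a + sigma * mills


def background_correct(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-array signal/noise deconvolution of linear-scale intensities."""
    if m.scale is not Scale.LINEAR:
        raise ValueError("background correction expects a linear-scale matrix")
    out = m.values.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        alpha, mu, sigma = _estimate_convolution_params(x)
        out[col] = _posterior_signal(x, alpha, mu, sigma)
    return ExpressionMatrix(out, Scale.LINEAR, m.sample_factors)


# --------------------------------------------------------- quantile normalize

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force identical value distributions across arrays.

    Every array's sorted vector becomes the across-array mean of sorted
    vectors; ties within an array receive the mean of the quantile values
    they span.
    """
    X = m.values.to_numpy(dtype=float)
    n, k = X.shape
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        order = np.argsort(X[:, j], kind="stable")
        assigned = np.empty(n)
        assigned[order] = mean_sorted
        # ties span a run of order statistics; give them the run mean
        col = X[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if counts.max() > 1:
            sums = np.bincount(inv, weights=assigned)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, m.scale, m.sample_factors)


# ------------------------------------------------------------- Tukey biweight

def tukey_biweight(x, params: BiweightParams | None = None) -> float:
    """One-step Tukey biweight location estimate of a vector.

    With M the median and S the median absolute deviation of x, residuals are
    scaled as u_i = (x_i - M) / (c*S + eps) and weighted by (1 - u_i^2)^2
    for |u_i| < 1 (zero otherwise); the estimate is the weighted mean.
    """
    params = params or BiweightParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("tukey_biweight expects a 1-D vector")
    if x.size == 0:
        raise ValueError("tukey_biweight: empty vector")
    if x.size == 1:
        return float(x[0])
    M = np.median(x)
    S = np.median(np.abs(x - M))
    u = (x - M) / (params.c * S + params.epsilon)
    w = np.where(np.abs(u) < 1, (1 - u * u) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def summarize_probeset(
    m: ExpressionMatrix,
    manifest: PlatformManifest,
    params: BiweightParams | None = None,
) -> pd.DataFrame:
    """Collapse probe rows into probeset rows by the one-step biweight,
    per sample.  Probesets with no probe present in the matrix are omitted
    with a warning."""
    params = params or BiweightParams()
    present = set(m.values.index)
    records = {}
    for ps, members in sorted(manifest.probesets().items()):
        pids = [p.pid for p in members if p.pid in present]
        if not pids:
            warnings.warn(f"probeset {ps}: no member probes in expression matrix; omitted")
            continue
        sub = m.values.loc[pids].to_numpy(dtype=float)
        records[ps] = [tukey_biweight(sub[:, j], params) for j in range(sub.shape[1])]
    return pd.DataFrame.from_dict(records, orient="index", columns=m.values.columns)


# -------------------------------------------------------------- ANOVA selection

@dataclass
class SelectionResult:
    probe_id: str
    f_statistic: float
    p_value: float
    factor: str
    eliminated: tuple[str, ...]
    retained: bool


def _design_matrix(factors: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    """Intercept + treatment-coded dummies for the named factors."""
    n = len(factors)
    cols = [np.ones((n, 1))]
    for name in names:
        d = pd.get_dummies(factors[name].astype(str), drop_first=True)
        if not d.empty:
            cols.append(d.to_numpy(dtype=float))
    return np.hstack(cols)


def _rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of Y (samples x probes) on design X, and
    the design rank."""
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(X.shape)))
    fitted = Q @ (Q.T @ Y)
    resid = Y - fitted
    return np.sum(resid * resid, axis=0), rank


def anova_select(
    m: ExpressionMatrix,
    factor: str,
    eliminate: Sequence[str] = (),
    alpha: float = 0.01,
    fdr: bool = False,
) -> list[SelectionResult]:
    """Per-probe fixed-effects ANOVA on ``factor`` after eliminating blocking
    factors (sequential extra sum of squares).  Probes with p < alpha are
    retained; no multiple-testing correction unless ``fdr``.
    """
    for name in (factor, *eliminate):
        if name not in m.sample_factors.columns:
            raise ValueError(f"factor {name!r} not in sample metadata")
    if m.sample_factors[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")

    Y = m.values.to_numpy(dtype=float).T  # samples x probes
    X0 = _design_matrix(m.sample_factors, list(eliminate))
    X1 = _design_matrix(m.sample_factors, [*eliminate, factor])
    rss0, rank0 = _rss(Y, X0)
    rss1, rank1 = _rss(Y, X1)
    df1 = rank1 - rank0
    df2 = Y.shape[0] - rank1
    if df1 == 0:
        raise ValueError(
            f"factor {factor!r} is aliased with eliminated factors {tuple(eliminate)}: "
            "no degrees of freedom remain for the test"
        )
    if df2 <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = np.where(np.isfinite(F), F, 0.0)
    p = stats.f.sf(F, df1, df2)
    if fdr:
        retained = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        retained = p < alpha
    return [
        SelectionResult(
            probe_id=pid, f_statistic=float(F[i]), p_value=float(p[i]),
            factor=factor, eliminated=tuple(eliminate), retained=bool(retained[i]),
        )
        for i, pid in enumerate(m.values.index)
    ]


# --------------------------------------------- probe vs probeset concordance

def probe_vs_probeset_concordance(
    m: ExpressionMatrix,
    manifest: PlatformManifest,
    re_rows: Sequence[REAnnotationRow],
    factor: str,
    alpha: float = 0.05,
    params: BiweightParams | None = None,
) -> pd.DataFrame:
    """Test whether a lone RE-reporting probe behaves like the rest of its
    probeset.

    For each probeset containing exactly one RE-reporting probe, the RE
    probe's values are compared (Welch t test) with the biweight summary of
    the remaining probes, per factor level with >=2 replicate samples;
    Holm-Bonferroni correction is applied across levels within the probeset.
    Verdict is "concordant" iff every corrected p > alpha.
    """
    params = params or BiweightParams()
    re_pids = {r.pid for r in re_rows}
    levels = m.sample_factors[factor].astype(str)
    out = []
    for ps, members in sorted(manifest.probesets().items()):
        ps_re = [p.pid for p in members if p.pid in re_pids and p.pid in m.values.index]
        if len(ps_re) != 1:
            continue
        others = [p.pid for p in members
                  if p.pid not in re_pids and p.pid in m.values.index]
        if len(others) < 2:
            warnings.warn(f"probeset {ps}: fewer than 2 non-RE probes; skipped")
            continue
        re_vals = m.values.loc[ps_re[0]]
        other_mat = m.values.loc[others]
        pvals = []
        for level in sorted(levels.unique()):
            samples = levels.index[levels == level]
            if len(samples) < 2:
                continue
            x = re_vals[samples].to_numpy(dtype=float)
            y = np.array([
                tukey_biweight(other_mat[s].to_numpy(dtype=float), params)
                for s in samples
            ])
            if np.allclose(x, y):
                pvals.append(1.0)
                continue
            t = stats.ttest_ind(x, y, equal_var=False)
            pvals.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
        if not pvals:
            continue
        corrected = multipletests(pvals, alpha=alpha, method="holm")[1]
        concordant = bool(np.all(corrected > alpha))
        out.append({"probeset": ps, "re_probe": ps_re[0], "n_tests": len(pvals),
                    "min_corrected_p": float(np.min(corrected)),
                    "concordant": concordant})
    df = pd.DataFrame(out)
    if not df.empty:
        frac = df["concordant"].mean()
        df.attrs["fraction_concordant"] = float(frac)
        logger.info("concordant probesets: %.1f%%", 100 * frac)
    else:
        df.attrs["fraction_concordant"] = float("nan")
    return df


# ------------------------------------------------------ nearest-gene regression

def _nearer_gene(row: REAnnotationRow) -> Optional[str]:
    """Symbol of the nearer of the 5'/3' flanking genes (tie -> 5')."""
    five_gap = row.sstart - row.five_stop if row.five_id is not None else None
    three_gap = row.three_start - row.send if row.three_id is not None else None
    if five_gap is None and three_gap is None:
        return None
    if three_gap is None:
        return row.five_id
    if five_gap is None:
        return row.three_id
    return row.five_id if five_gap <= three_gap else row.three_id


def nearest_gene_regression(
    re_matrix: pd.DataFrame,
    gene_summaries: pd.DataFrame,
    annot: Sequence[REAnnotationRow],
    sample_factors: pd.DataFrame,
    tissue_factor: str,
    tissue: str,
) -> pd.DataFrame:
    """Regress RE-probe values against the biweight summary of each probe's
    nearest gene, over the samples of one tissue.

    One point per (RE probe, sample); points whose nearest gene is absent
    from ``gene_summaries`` are omitted and counted.  A least-squares line is
    fitted per top-level repeat class (LTR / LINE / SINE) and for all points
    pooled.
    """
    samples = sample_factors.index[sample_factors[tissue_factor].astype(str) == tissue]
    samples = [s for s in samples if s in re_matrix.columns and s in gene_summaries.columns]
    if not samples:
        raise ValueError(f"no samples with {tissue_factor} == {tissue!r}")
    pts: dict[str, list[tuple[float, float]]] = {}
    omitted = 0
    for row in annot:
        if not row.has_context or row.pid not in re_matrix.index:
            continue
        gene = _nearer_gene(row)
        if gene is None or gene not in gene_summaries.index:
            omitted += 1
            continue
        top = row.repclass.split("/", 1)[0]
        for s in samples:
            pts.setdefault(top, []).append(
                (float(gene_summaries.at[gene, s]), float(re_matrix.at[row.pid, s]))
            )
    recs = []
    all_pts: list[tuple[float, float]] = []
    for cls in sorted(pts):
        all_pts.extend(pts[cls])
    for cls, data in [*sorted(pts.items()), ("all", all_pts)]:
        if len(data) < 3:
            recs.append({"class": cls, "n_points": len(data), "slope": np.nan,
                         "r": np.nan, "r2": np.nan, "p": np.nan})
            continue
        g, r_ = np.array(data).T
        res = stats.linregress(g, r_)
        recs.append({"class": cls, "n_points": len(data),
                     "slope": float(res.slope), "r": float(res.rvalue),
                     "r2": float(res.rvalue ** 2), "p": float(res.pvalue)})
    df = pd.DataFrame(recs).set_index("class")
    df.attrs["omitted_points"] = omitted
    return df


# ------------------------------------------------------- hierarchical clustering

def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "rows"):
    """Average-linkage agglomeration on Pearson correlation distance (1 - r).

    Returns (leaf order as a list of identifiers, scipy linkage matrix).
    Rows/columns are sorted by identifier first so the result is
    deterministic; a constant vector has undefined correlation and is placed
    at distance 1 from everything (with a warning).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    data = data.sort_index()
    ids = list(data.index)
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant vector(s): correlation undefined; "
                      "using distance 1 to all others")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(Z)
    return [ids[i] for i in order], Z
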