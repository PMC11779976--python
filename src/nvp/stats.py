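"""Cross-measure statistics.

Two analyses: (1) Pearson correlation of every neurovascular measure with
per-mouse exercise (normalized within timepoint), each transformed to
Fisher's Z, with a one-sample location test of the Z distribution against 0
and Benjamini-Hochberg adjustment of the individual correlation p-values;
(2) PCA preparation — exclusion of variables with > 20% missing values,
imputation, standardization, eigendecomposition of the correlation matrix,
retention of components with eigenvalue > 1, and per-variable contributions.

Linear mixed models are not re-implemented here: :func:`tidy_observations`
emits a per-observation table ready for any standard mixed-model tool
(factors genotype x exercise x duration x vessel type, animal ID random).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def fisher_z(r):
    """Fisher's Z transform, Z = 0.5 * ln((1+r)/(1-r)) = atanh(r).

    Odd in r; requires |r| < 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    """Inverse transform, r = tanh(Z); round-trips with :func:`fisher_z`."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


@dataclass
class CorrelationResult:
    measure: str
    r: float
    ci95: tuple
    z: float
    n: int
    p: float
    p_adj: float | None = None
    flagged: bool = False


@dataclass
class CorrelationSummary:
    results: list
    mean_z: float
    z_ci95: tuple
    t_stat: float
    p_value: float


def _pearson_ci(r: float, n: int, conf: float = 0.95) -> tuple:
    """Fisher-Z based confidence interval for Pearson's r."""
    if n <= 3:
        return (-1.0, 1.0)
    z = fisher_z(r)
    se = 1.0 / np.sqrt(n - 3)
    q = sps.norm.ppf(0.5 + conf / 2.0)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def normalize_exercise(exercise: pd.DataFrame, value_col: str = "distance",
                       timepoint_col: str = "timepoint") -> pd.Series:
    """Z-score exercise across the cohort within each timepoint."""
    def zs(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0
    return exercise.groupby(timepoint_col)[value_col].transform(zs)


def correlate_measures(measures: pd.DataFrame, exercise: pd.Series,
                       mouse_col: str = "mouse",
                       min_pairs: int = 3) -> CorrelationSummary:
    """Pairwise-complete Pearson correlation of each measure with exercise.

    ``measures``: one row per mouse, one column per measure (plus the mouse
    id column).  ``exercise``: normalized exercise indexed like measures'
    rows.  Mice must be unique.  Correlations with fewer than ``min_pairs``
    complete pairs are flagged and excluded from the Z summary; BH-adjusted
    p-values are reported alongside raw ones.
    """
    if measures[mouse_col].duplicated().any():
        raise ValueError("duplicate mouse rows in measures table")
    ex = np.asarray(exercise, dtype=float)
    results = []
    for col in measures.columns:
        if col == mouse_col:
            continue
        y = measures[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(ex)
        n = int(ok.sum())
        if n < min_pairs:
            results.append(CorrelationResult(
                measure=col, r=np.nan, ci95=(np.nan, np.nan), z=np.nan,
                n=n, p=np.nan, flagged=True))
            continue
        r, p = sps.pearsonr(ex[ok], y[ok])
        r = float(np.clip(r, -0.999999999, 0.999999999))
        results.append(CorrelationResult(
            measure=col, r=r, ci95=_pearson_ci(r, n), z=fisher_z(r),
            n=n, p=float(p)))
    ps = [res.p for res in results if not res.flagged]
    if ps:
        adj = multipletests([p for p in ps], method="fdr_bh")[1]
        it = iter(adj)
        for res in results:
            if not res.flagged:
                res.p_adj = float(next(it))
    zs = np.array([res.z for res in results if not res.flagged])
    if len(zs) < 2:
        raise ValueError("need >= 2 usable correlations for a Z summary")
    t_stat, p_val = sps.ttest_1samp(zs, 0.0)
    se = zs.std(ddof=1) / np.sqrt(len(zs))
    q = sps.t.ppf(0.975, len(zs) - 1)
    return CorrelationSummary(results=results, mean_z=float(zs.mean()),
                              z_ci95=(float(zs.mean() - q * se),
                                      float(zs.mean() + q * se)),
                              t_stat=float(t_stat), p_value=float(p_val))


# ---------------------------------------------------------------------------
# PCA preparation


@dataclass
class PCAPrep:
    retained_variables: list
    excluded_variables: dict          # name -> missing fraction
    imputation: str
    eigenvalues: np.ndarray           # all, descending
    retained_pcs: list                # indices with eigenvalue > 1
    variance_fractions: np.ndarray    # per retained PC
    loadings: np.ndarray              # variables x all PCs
    contributions: pd.DataFrame       # variable contribution per retained PC
    scores: np.ndarray                # observations x retained PCs
    standardized: np.ndarray = field(repr=False, default=None)


def prepare_pca(table: pd.DataFrame, missing_cutoff: float = 0.20,
                imputation: str = "mean", seed: int = 0) -> PCAPrep:
    """Missingness screening, imputation and correlation-matrix PCA.

    Variables missing in strictly more than ``missing_cutoff`` of rows are
    excluded; remaining missing values are imputed (``mean``: column mean,
    deterministic default; ``iterative``: chained-equation regression with
    a fixed seed).  Variables are standardized, the correlation matrix is
    eigendecomposed, and components with eigenvalue strictly > 1 are
    retained.  Per-variable contribution to a PC = squared loading as a
    fraction of that PC's total squared loading.

    With no missing data the result equals plain standardized PCA, and the
    eigenvalues sum to the number of retained variables.
    """
    num = table.select_dtypes(include=[np.number])
    miss = num.isna().mean()
    excluded = {c: float(miss[c]) for c in num.columns
                if miss[c] > missing_cutoff}
    kept = [c for c in num.columns if c not in excluded]
    if len(kept) < 2:
        raise ValueError("fewer than 2 variables survive the missingness "
                         "exclusion")
    x = num[kept].to_numpy(dtype=float)

    if imputation == "mean":
        mu = np.nanmean(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(mu, inds[1])
    elif imputation == "iterative":
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        x = IterativeImputer(random_state=seed).fit_transform(x)
    else:
        raise ValueError(f"unknown imputation '{imputation}'")

    sd = x.std(axis=0, ddof=0)
    zero = [kept[i] for i in range(len(kept)) if sd[i] == 0]
    if zero:
        raise ValueError(f"retained variables with zero variance: {zero}")
    z = (x - x.mean(axis=0)) / sd

    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    retained = [i for i, ev in enumerate(evals) if ev > 1.0]
    varfrac = evals[retained] / len(kept) if retained else np.array([])

    contrib = pd.DataFrame(
        {f"PC{i + 1}": evecs[:, i] ** 2 / np.sum(evecs[:, i] ** 2)
         for i in retained},
        index=kept)
    scores = z @ evecs[:, retained] if retained else np.empty((len(z), 0))

    return PCAPrep(retained_variables=kept, excluded_variables=excluded,
                   imputation=imputation, eigenvalues=evals,
                   retained_pcs=retained, variance_fractions=varfrac,
                   loadings=evecs, contributions=contrib, scores=scores,
                   standardized=z)


def tidy_observations(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and pass through a per-observation table for mixed-model
    tools: requires mouse, genotype, exercise, timepoint plus at least one
    measure column.  The factor structure used downstream is genotype x
    exercise x duration x vessel type with animal ID as a random effect.
    """
    required = {"mouse", "genotype", "exercise", "timepoint"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    return records.copy()
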