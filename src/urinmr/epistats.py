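"""Epidemiological and genetic statistics.

Log/SD scaling of metabolic measures, sex-adjusted partial correlations and
correlation maps, the PCA-based effective number of tests with Bonferroni
thresholds, exposure associations in SD units, inverse rank-based normal
transformation, and an additive dosage association scan with MAF/info
filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import ndtri

__all__ = [
    "ScaledMatrix",
    "CorrelationMap",
    "GenotypeMatrix",
    "log_sd_scale",
    "partial_correlation",
    "correlation_map",
    "effective_tests",
    "bonferroni_threshold",
    "exposure_association",
    "inverse_normal_transform",
    "genetic_scan",
    "genomic_principal_components",
]


@dataclass
class ScaledMatrix:
    """Individuals x measures matrix after log transform and SD scaling."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    fluid: dict = field(default_factory=dict)  # measure -> "urine" | "serum"

    @property
    def measures(self) -> list:
        return list(self.data.columns)


@dataclass
class CorrelationMap:
    """Pairwise (partial) correlations with p-values and an ordering."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    significant: pd.DataFrame
    ordering: list
    threshold: float
    median_abs_r: float
    iqr_abs_r: tuple


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix in [0, 2] with QC metrics."""

    dosages: pd.DataFrame
    info: pd.Series           # imputation info per variant, in [0, 1]
    chrom: pd.Series | None = None
    pos: pd.Series | None = None

    def __post_init__(self):
        d = self.dosages.values
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if not self.info.index.equals(self.dosages.columns):
            raise ValueError("info index must match variant columns")

    @property
    def maf(self) -> pd.Series:
        p = self.dosages.mean(axis=0) / 2.0
        return pd.concat([p, 1 - p], axis=1).min(axis=1)


def log_sd_scale(table: pd.DataFrame, pseudo_policy: str = "strict",
                 fluid: dict | None = None, log: bool = True) -> ScaledMatrix:
    """Natural log then column standardization (mean 0, SD 1, n-1 basis).

    ``pseudo_policy``: ``"strict"`` errors on non-positive values;
    ``"drop"`` turns them into missing entries (excluded columnwise).
    Pass ``log=False`` to rescale already-logged data (scaling twice must
    not reapply the log).
    """
    df = table.astype(float).copy()
    if log:
        bad = df <= 0
        if bad.any().any():
            if pseudo_policy == "strict":
                r, c = np.argwhere(bad.values)[0]
                raise ValueError(
                    f"non-positive value at sample {df.index[r]!r}, "
                    f"measure {df.columns[c]!r} under strict policy"
                )
            if pseudo_policy == "drop":
                df = df.mask(bad)
            else:
                raise ValueError(f"unknown pseudo_policy {pseudo_policy!r}")
        df = np.log(df)
    means = df.mean()
    sds = df.std(ddof=1)
    if (sds == 0).any():
        const = list(sds.index[sds == 0])
        raise ValueError(f"constant column(s): {const}")
    return ScaledMatrix((df - means) / sds, means, sds, dict(fluid or {}))


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(x, y, covariates=None) -> tuple:
    """Pearson correlation of x and y after removing covariates by OLS.

    Returns ``(r, p, n)``; p from ``t = r sqrt((n-2-q)/(1-r^2))`` on
    ``n-2-q`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[ok], y[ok], cov[ok]
    n, q = len(x), cov.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q+2 complete cases (n={n}, q={q})")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance")
    r = float(rx @ ry) / denom
    r = max(-1.0, min(1.0, r))
    df = n - 2 - q
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return r, p, n


def correlation_map(scaled: ScaledMatrix, covariates=None, subset_a=None,
                    subset_b=None, ordering="cluster",
                    threshold: float = 0.05) -> CorrelationMap:
    """All pairwise partial correlations (pairwise-complete) between two
    measure subsets (the full square matrix when ``subset_b`` is omitted).

    ``ordering`` is either a list of measure names or ``"cluster"`` for
    average-linkage hierarchical clustering on distance ``1 - |r|`` (square
    maps only; cross maps fall back to the given order).
    """
    a = list(subset_a or scaled.measures)
    b = list(subset_b) if subset_b is not None else None
    square = b is None
    cols = a if square else sorted(set(a) | set(b))
    rmat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols)
    pairs = (
        [(cols[i], cols[j]) for i in range(len(cols)) for j in range(i + 1, len(cols))]
        if square
        else [(u, v) for u in a for v in b if u != v]
    )
    for u, v in pairs:
        r, p, n = partial_correlation(scaled.data[u], scaled.data[v], covariates)
        rmat.loc[u, v] = rmat.loc[v, u] = r
        pmat.loc[u, v] = pmat.loc[v, u] = p
        nmat.loc[u, v] = nmat.loc[v, u] = n

    if isinstance(ordering, str) and ordering == "cluster" and square and len(cols) > 2:
        dist = 1.0 - np.abs(rmat.values)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        order = [cols[i] for i in hierarchy.leaves_list(link)]
    elif isinstance(ordering, (list, tuple)):
        if sorted(ordering) != sorted(cols):
            raise ValueError("manual ordering must be a permutation of the measures")
        order = list(ordering)
    else:
        order = cols

    if square:
        tri = rmat.values[np.triu_indices(len(cols), k=1)]
    else:
        tri = np.array([rmat.loc[u, v] for u, v in pairs])
    abs_r = np.abs(tri)
    return CorrelationMap(
        r=rmat.loc[order, order],
        p=pmat.loc[order, order],
        n=nmat.loc[order, order],
        significant=(pmat < threshold).loc[order, order],
        ordering=order,
        threshold=threshold,
        median_abs_r=float(np.median(abs_r)),
        iqr_abs_r=(float(np.quantile(abs_r, 0.25)), float(np.quantile(abs_r, 0.75))),
    )


def effective_tests(data, threshold: float = 0.99) -> int:
    """Number of principal components needed to explain strictly more than
    ``threshold`` of the variance of the column correlation matrix."""
    if isinstance(data, ScaledMatrix):
        mat = data.data.values
    else:
        mat = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("input contains NaN/inf")
    if mat.shape[0] < 2:
        raise ValueError("need > 1 observation")
    corr = np.corrcoef(mat, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    share = np.cumsum(eig) / eig.sum()
    return int(np.argmax(share > threshold) + 1)


def bonferroni_threshold(alpha: float, m_eff: int, rounding: bool = False) -> float:
    """``alpha / m_eff``, optionally rounded to one significant figure
    (the reporting convention: 0.05/40 -> 0.001, 0.05/27 -> 0.002)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    t = alpha / m_eff
    if rounding:
        exp = math.floor(math.log10(t))
        t = round(t / 10**exp) * 10**exp
    return t


def exposure_association(outcomes, exposure, scale_exposure: bool = True,
                         covariates=None) -> pd.DataFrame:
    """OLS of each (already-scaled) outcome on an exposure.

    With ``scale_exposure`` (default) the exposure is SD-standardized so
    betas are outcome-SD per exposure-SD. Returns per-outcome beta, SE, p, n.
    """
    if isinstance(outcomes, ScaledMatrix):
        outcomes = outcomes.data
    expo = np.asarray(exposure, dtype=float)
    if np.nanstd(expo) == 0:
        raise ValueError("constant exposure")
    rows = {}
    for name in outcomes.columns:
        y = outcomes[name].values.astype(float)
        ok = np.isfinite(y) & np.isfinite(expo)
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            ok &= np.all(np.isfinite(cov), axis=1)
            cov = cov[ok]
        yy, xx = y[ok], expo[ok]
        if scale_exposure:
            xx = (xx - xx.mean()) / xx.std(ddof=1)
        design = np.column_stack(
            [np.ones(len(xx)), xx] + ([cov] if cov is not None and cov.size else [])
        )
        beta, *_ = np.linalg.lstsq(design, yy, rcond=None)
        resid = yy - design @ beta
        dof = len(yy) - design.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov_beta = sigma2 * np.linalg.inv(design.T @ design)
        se = math.sqrt(cov_beta[1, 1])
        t = beta[1] / se
        rows[name] = {
            "beta": float(beta[1]),
            "se": se,
            "p": 2.0 * stats.t.sf(abs(t), dof),
            "n": int(len(yy)),
        }
    return pd.DataFrame(rows).T


def inverse_normal_transform(values) -> np.ndarray:
    """Blom inverse rank-based normal scores:
    ``Phi^-1((rank - 3/8) / (n + 1/4))`` with average ranks for ties."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need n >= 3")
    if np.all(v == v[0]):
        return np.zeros(len(v))  # degenerate: every observation tied
    ranks = stats.rankdata(v, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (len(v) + 0.25))


def genomic_principal_components(dosages: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """First principal components of the centred dosage matrix (thin SVD
    helper, not a GWAS-grade PCA)."""
    x = dosages.values - dosages.values.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    pcs = u[:, :k] * s[:k]
    return pd.DataFrame(
        pcs, index=dosages.index, columns=[f"PC{i+1}" for i in range(k)]
    )


def genetic_scan(phenotype: pd.Series, covariates: pd.DataFrame,
                 genotypes: GenotypeMatrix, maf_min: float = 0.05,
                 info_min: float = 0.8, apply_int: bool = True) -> pd.DataFrame:
    """Additive dosage association scan.

    The phenotype is residualized on the covariates (sex, genomic PCs, ...),
    the residuals are inverse-normal transformed, and each variant passing
    the MAF/info filters is tested by OLS of the transformed residuals on
    dosage (Wald p). Returns per-variant beta, SE, p, maf, info.
    """
    ids = phenotype.index
    if not ids.equals(genotypes.dosages.index) or not ids.equals(covariates.index):
        raise ValueError("phenotype, covariates and genotypes must share individuals")
    maf = genotypes.maf
    keep = (maf >= maf_min) & (genotypes.info >= info_min)
    dos = genotypes.dosages.loc[:, keep]

    y = _residualize(phenotype.values.astype(float), covariates.values.astype(float))
    if apply_int:
        y = inverse_normal_transform(y)
    n = len(y)
    g = dos.values - dos.values.mean(axis=0)
    ssg = (g**2).sum(axis=0)
    ssg[ssg == 0] = np.nan
    yc = y - y.mean()
    beta = (g * yc[:, None]).sum(axis=0) / ssg
    resid_ss = float(yc @ yc) - beta**2 * ssg
    dof = n - 2
    se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / ssg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "maf": maf[keep], "info": genotypes.info[keep]},
        index=dos.columns,
    )
    if genotypes.chrom is not None:
        out["chrom"] = genotypes.chrom[keep]
    if genotypes.pos is not None:
        out["pos"] = genotypes.pos[keep]
    return out
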