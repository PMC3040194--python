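"""Generalized least squares ANCOVA with dummy-coded categorical predictors.

The model is y = X beta + e with e ~ N(0, sigma^2 V), where y is a vector of
species-mean hematocrit values (% packed cell volume), X is a dummy-coded
design built from Habitat and Clade factors, and V is one of the covariance
structures in :mod:`phyloancova.phylocov` (identity for OLS, the Brownian
tree matrix for PGLS, or an OU transform indexed by d for RegOU).

Conventions, chosen to keep all twelve model fits on one likelihood scale:

* the reported log-likelihood is the multivariate-normal likelihood profiled
  over the ML variance estimate sigma^2 = SSE_V / n:
  lnML = -(n/2)(ln(2 pi SSE_V / n) + 1) - (1/2) ln|V|;
* MSE is SSE_V / (n - p) and SEE = sqrt(MSE);
* AIC = -2 lnML + 2k and AICc = AIC + 2k(k+1)/(n-k-1), with k counting the
  p regression coefficients plus the residual variance, plus d for RegOU;
* r^2 = 1 - SSE_V / SSE_V0, where SSE_V0 is the residual of the
  intercept-only GLS fit under the same V;
* the OU parameter d is estimated by restricted maximum likelihood (REML)
  by default, but the likelihood reported at the optimum is the ML quantity
  above, mirroring common practice for this estimator family.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .phylocov import CovarianceSpec, bm_covariance, ou_transform
from .treeio import PhyloTree, canonical_label

__all__ = [
    "HABITAT_LEVELS",
    "CLADE_LEVELS",
    "HABITAT_BASE",
    "CLADE_BASE",
    "HABITAT_DUMMIES",
    "CLADE_DUMMIES",
    "TraitTable",
    "DesignMatrix",
    "FitResult",
    "FTestResult",
    "LRTResult",
    "RankDeficiencyError",
    "SingularCovarianceError",
    "SpeciesMismatchError",
    "build_design",
    "fit_gls",
    "log_likelihood",
    "profiled_lnml",
    "reml_log_likelihood",
    "aicc",
    "partial_f_test",
    "estimate_d",
    "reml_estimate_d",
    "lrt_signal",
    "align_traits_to_tree",
]

HABITAT_LEVELS = ("Terrestrial", "Semi-aquatic", "Aquatic", "Marine")
CLADE_LEVELS = (
    "Colubrinae",
    "Natricinae",
    "Elapidae",
    "Homalopsidae",
    "Viperidae",
    "Acrochordidae",
    "Boidae",
)
HABITAT_BASE = "Terrestrial"
CLADE_BASE = "Colubrinae"
# dummy column order used in reports (base groups Terrestrial / Colubrinae)
HABITAT_DUMMIES = ("Semi-aquatic", "Aquatic", "Marine")
CLADE_DUMMIES = ("Boidae", "Acrochordidae", "Viperidae", "Homalopsidae", "Elapidae", "Natricinae")


class RankDeficiencyError(ValueError):
    """Design matrix not of full column rank under the given weighting."""


class SingularCovarianceError(ValueError):
    """Residual covariance matrix is singular (no Cholesky factor)."""


class SpeciesMismatchError(ValueError):
    """Trait table and tree do not describe the same species set."""


# -- trait table ------------------------------------------------------------


class TraitTable:
    """Per-species trait data: hematocrit plus Habitat and Clade factors.

    Parameters
    ----------
    data
        DataFrame with columns ``species``, ``hct``, ``habitat``, ``clade``.
    check_range
        Enforce hct in (0, 100), the physiological range of a percentage
        measurement.  Synthetic tables drawn from an unbounded Gaussian
        model may disable this check.
    """

    COLUMNS = ("species", "hct", "habitat", "clade")

    def __init__(self, data: pd.DataFrame, check_range: bool = True):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"trait table missing column(s): {', '.join(missing)}")
        df = data.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        df["species"] = df["species"].astype(str).map(canonical_label)
        df["hct"] = df["hct"].astype(float)
        dupes = df["species"][df["species"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate species: {', '.join(sorted(set(dupes)))}")
        if not np.all(np.isfinite(df["hct"])):
            bad = df.loc[~np.isfinite(df["hct"]), "species"].tolist()
            raise ValueError(f"non-finite hct for: {', '.join(bad)}")
        if check_range and not ((df["hct"] > 0) & (df["hct"] < 100)).all():
            bad = df.loc[~((df["hct"] > 0) & (df["hct"] < 100)), "species"].tolist()
            raise ValueError(f"hct outside (0, 100) for: {', '.join(bad)}")
        for col, levels in (("habitat", HABITAT_LEVELS), ("clade", CLADE_LEVELS)):
            bad_rows = df.index[~df[col].isin(levels)]
            if len(bad_rows):
                detail = "; ".join(
                    f"row {i} ({df.loc[i, 'species']}): {df.loc[i, col]!r}" for i in bad_rows
                )
                raise ValueError(f"unknown {col} level(s): {detail}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data["species"])

    @property
    def hct(self) -> np.ndarray:
        return self.data["hct"].to_numpy(dtype=float)

    def reorder(self, species_order: Sequence[str]) -> "TraitTable":
        order = [canonical_label(s) for s in species_order]
        missing = sorted(set(order) - set(self.species))
        if missing:
            raise SpeciesMismatchError(f"species not in trait table: {', '.join(missing)}")
        extra = sorted(set(self.species) - set(order))
        if extra:
            raise SpeciesMismatchError(f"trait table species not requested: {', '.join(extra)}")
        df = self.data.set_index("species").loc[order].reset_index()
        out = object.__new__(TraitTable)
        out.data = df
        return out

    @classmethod
    def from_csv(cls, path: str | Path, check_range: bool = False, **kwargs) -> "TraitTable":
        """Load from CSV/TSV with header species,hct,habitat,clade.

        The range check defaults off so that simulated datasets (which may
        stray outside the physiological range) round-trip through files.
        """
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        return cls(pd.read_csv(path, sep=sep, **kwargs), check_range=check_range)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.data.to_csv(path, sep=sep, index=False)


def align_traits_to_tree(traits: TraitTable, tree: PhyloTree) -> TraitTable:
    """Reorder the trait table to the tree's tip order; hard error on mismatch.

    Matching is exact after canonicalizing whitespace/underscores.
    """
    tip_names = [canonical_label(lab) for lab in tree.tip_labels]
    table_names = set(traits.species)
    only_tree = sorted(set(tip_names) - table_names)
    only_table = sorted(table_names - set(tip_names))
    if only_tree or only_table:
        parts = []
        if only_tree:
            parts.append(f"in tree only: {', '.join(only_tree)}")
        if only_table:
            parts.append(f"in trait table only: {', '.join(only_table)}")
        raise SpeciesMismatchError("species mismatch between tree and trait table; " + "; ".join(parts))
    return traits.reorder(tip_names)


# -- design matrices --------------------------------------------------------


@dataclass
class DesignMatrix:
    """Dummy-coded design: intercept first, then habitat then clade dummies."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    factors: tuple[str, ...]
    base_levels: Mapping[str, str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def drop(self, columns: Iterable[str]) -> "DesignMatrix":
        drop = set(columns)
        unknown = drop - set(self.columns)
        if unknown:
            raise ValueError(f"unknown design column(s): {', '.join(sorted(unknown))}")
        keep = [i for i, c in enumerate(self.columns) if c not in drop]
        return DesignMatrix(
            self.matrix[:, keep],
            tuple(self.columns[i] for i in keep),
            self.factors,
            self.base_levels,
        )


def build_design(
    traits: TraitTable,
    factors: Sequence[str] = ("habitat", "clade"),
    drop_unobserved: bool = False,
) -> DesignMatrix:
    """Intercept plus 0/1 dummies for the requested factors.

    Base levels (Terrestrial, Colubrinae) carry no dummy; column order is
    intercept, Semi-aquatic, Aquatic, Marine, Boidae, Acrochordidae,
    Viperidae, Homalopsidae, Elapidae, Natricinae, restricted to the
    requested factors.  With ``drop_unobserved`` a level absent from the
    table contributes no (all-zero, inestimable) column — useful for
    simulated datasets that happen to miss a level.
    """
    factors = tuple(factors)
    unknown = set(factors) - {"habitat", "clade"}
    if unknown:
        raise ValueError(f"unknown factor(s): {', '.join(sorted(unknown))}")
    n = len(traits)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Y-intercept"]
    if "habitat" in factors:
        for level in HABITAT_DUMMIES:
            col = (traits.data["habitat"] == level).to_numpy(dtype=float)
            if drop_unobserved and not col.any():
                continue
            cols.append(col)
            names.append(level)
    if "clade" in factors:
        for level in CLADE_DUMMIES:
            col = (traits.data["clade"] == level).to_numpy(dtype=float)
            if drop_unobserved and not col.any():
                continue
            cols.append(col)
            names.append(level)
    ordered = tuple(f for f in ("habitat", "clade") if f in factors)
    return DesignMatrix(
        np.column_stack(cols),
        tuple(names),
        ordered,
        {"habitat": HABITAT_BASE, "clade": CLADE_BASE},
    )


# -- fitting ----------------------------------------------------------------


@dataclass
class FitResult:
    """One fitted GLS regression and its model-selection summaries."""

    beta: np.ndarray
    se_beta: np.ndarray
    columns: tuple[str, ...]
    lnml: float
    aic: float
    aicc: float
    mse: float
    see: float
    r2: float
    n: int
    p: int
    k: int
    sse: float
    logdet_v: float
    kind: str
    d: float | None = None

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.columns, "coefficient": self.beta, "se": self.se_beta})

    def to_dict(self) -> dict:
        out = {
            "lnML": self.lnml,
            "AIC": self.aic,
            "AICc": self.aicc,
            "MSE": self.mse,
            "SEE": self.see,
            "r2": self.r2,
            "n": self.n,
            "p": self.p,
            "k": self.k,
        }
        if self.d is not None:
            out["REML_d"] = self.d
        return out


FTestResult = namedtuple("FTestResult", ["f", "df_num", "df_den", "p_value"])
LRTResult = namedtuple("LRTResult", ["statistic", "p_value"])


def _whiten(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance matrix is singular or indefinite") from exc
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    return yw, Xw, logdet_v


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray, columns: tuple[str, ...] | None = None):
    """Whitened least squares: beta, SSE_V, ln|V| and the R factor of X_w."""
    yw, Xw, logdet_v = _whiten(y, X, V)
    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        bad = np.nonzero(diag < 1e-10 * max(diag.max(), 1.0))[0]
        names = [columns[i] if columns else str(i) for i in bad]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(names)}"
        )
    beta = solve_triangular(R, Q.T @ yw, lower=False)
    resid = yw - Xw @ beta
    sse = float(resid @ resid)
    return beta, sse, logdet_v, R


def profiled_lnml(sse: float, n: int, logdet_v: float = 0.0) -> float:
    """ML log-likelihood profiled over the variance: sigma^2_ML = SSE_V / n."""
    if sse <= 0:
        raise ValueError("SSE must be positive")
    return -(n / 2.0) * (np.log(2.0 * np.pi * sse / n) + 1.0) - 0.5 * logdet_v


def log_likelihood(y: np.ndarray, X: DesignMatrix | np.ndarray, V: CovarianceSpec) -> float:
    """Profiled ML log-likelihood of the GLS model at its own beta-hat."""
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    _, sse, logdet_v, _ = _gls_core(np.asarray(y, dtype=float), Xm, V.matrix)
    return profiled_lnml(sse, len(y), logdet_v)


def reml_log_likelihood(y: np.ndarray, X: DesignMatrix | np.ndarray, V: CovarianceSpec) -> float:
    """Restricted log-likelihood, profiled over sigma^2_REML = SSE_V / (n - p)."""
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _, sse, logdet_v, R = _gls_core(y, Xm, V.matrix)
    n, p = Xm.shape
    logdet_xvx = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
    return (
        -((n - p) / 2.0) * (np.log(2.0 * np.pi * sse / (n - p)) + 1.0)
        - 0.5 * logdet_v
        - 0.5 * logdet_xvx
    )


def aicc(lnml: float, k: int, n: int) -> tuple[float, float]:
    """AIC and small-sample-corrected AICc from a log-likelihood."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    aic = -2.0 * lnml + 2.0 * k
    return aic, aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_gls(y: np.ndarray, X: DesignMatrix, V: CovarianceSpec) -> FitResult:
    """Fit y = X beta + e, e ~ N(0, sigma^2 V), and summarize the fit.

    The parameter count k is p + 1 (coefficients plus residual variance),
    plus one more when V is an OU covariance whose d was estimated.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.matrix.shape
    if len(y) != n:
        raise ValueError(f"y has length {len(y)}, design has {n} rows")
    beta, sse, logdet_v, R = _gls_core(y, X.matrix, V.matrix, X.columns)
    mse = sse / (n - p)
    Rinv = solve_triangular(R, np.eye(p), lower=False)
    xtvx_inv = Rinv @ Rinv.T
    se_beta = np.sqrt(mse * np.diag(xtvx_inv))
    lnml = profiled_lnml(sse, n, logdet_v)
    if p == 1 and np.allclose(X.matrix, 1.0):
        r2 = 0.0
    else:
        ones = np.ones((n, 1))
        _, sse0, _, _ = _gls_core(y, ones, V.matrix)
        r2 = 1.0 - sse / sse0
    k = p + 1 + (1 if V.kind == "ou" else 0)
    if n - k - 1 > 0:
        aic, aicc_ = aicc(lnml, k, n)
    else:  # AICc undefined for tiny n; keep the fit usable
        aic, aicc_ = -2.0 * lnml + 2.0 * k, np.nan
    return FitResult(
        beta=beta,
        se_beta=se_beta,
        columns=X.columns,
        lnml=lnml,
        aic=aic,
        aicc=aicc_,
        mse=mse,
        see=float(np.sqrt(mse)),
        r2=float(r2),
        n=n,
        p=p,
        k=k,
        sse=sse,
        logdet_v=logdet_v,
        kind=V.kind,
        d=V.d,
    )


def partial_f_test(
    y: np.ndarray, X: DesignMatrix, V: CovarianceSpec, columns: Sequence[str]
) -> FTestResult:
    """Partial F-test of a block of design columns under covariance V.

    Compares the full model against the model with ``columns`` removed:
    F = ((SSE_reduced - SSE_full) / q) / (SSE_full / (n - p)).
    """
    columns = list(columns)
    if not columns:
        raise ValueError("no columns to test")
    y = np.asarray(y, dtype=float)
    n, p = X.matrix.shape
    _, sse_full, _, _ = _gls_core(y, X.matrix, V.matrix, X.columns)
    reduced = X.drop(columns)
    _, sse_red, _, _ = _gls_core(y, reduced.matrix, V.matrix, reduced.columns)
    q = len(columns)
    f = ((sse_red - sse_full) / q) / (sse_full / (n - p))
    f = max(float(f), 0.0)
    return FTestResult(f, q, n - p, float(stats.f.sf(f, q, n - p)))


# -- OU parameter estimation ------------------------------------------------


def estimate_d(
    y: np.ndarray,
    X: DesignMatrix,
    tree: PhyloTree,
    criterion: str = "reml",
    grid_size: int = 21,
    xatol: float = 1e-6,
) -> tuple[float, FitResult]:
    """Estimate the OU transform parameter d on [0, 1] and refit at the optimum.

    A coarse grid warm-starts a bounded scalar search on the REML (default)
    or ML profile.  If the profile is flat within 1e-8, the smallest
    maximizing d is returned (preferring the simpler, star-ward model).  The
    returned FitResult is the ML fit at d-hat with k = p + 2.
    """
    if criterion not in {"reml", "ml"}:
        raise ValueError("criterion must be 'reml' or 'ml'")
    y = np.asarray(y, dtype=float)
    bm = bm_covariance(tree.rescaled_to_unit_height(), validate=False)
    S = bm.matrix
    species = bm.species
    objective = reml_log_likelihood if criterion == "reml" else log_likelihood

    def profile(d: float) -> float:
        V = CovarianceSpec("ou", ou_transform(S, d), species, d=d)
        return objective(y, X, V)

    ds = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([profile(d) for d in ds])
    if not np.all(np.isfinite(lls)):
        raise RuntimeError(
            "likelihood profile over d contains non-finite values; grid:\n"
            + "\n".join(f"  d={d:.3f} ll={ll:.6g}" for d, ll in zip(ds, lls))
        )
    best = int(np.argmax(lls))
    lo = ds[max(best - 1, 0)]
    hi = ds[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda d: -profile(d), bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    cand_d = np.append(ds, res.x)
    cand_ll = np.append(lls, -res.fun)
    top = cand_ll.max()
    d_hat = float(cand_d[cand_ll >= top - 1e-8].min())
    V_hat = CovarianceSpec("ou", ou_transform(S, d_hat), species, d=d_hat)
    return d_hat, fit_gls(y, X, V_hat)


def reml_estimate_d(y: np.ndarray, X: DesignMatrix, tree: PhyloTree) -> tuple[float, FitResult]:
    """REML estimate of d (the reported convention); see :func:`estimate_d`."""
    return estimate_d(y, X, tree, criterion="reml")


def lrt_signal(lnml_regou: float, lnml_ols: float) -> LRTResult:
    """Likelihood-ratio test for phylogenetic signal: RegOU vs OLS, chi^2(1).

    The models share the same design; RegOU adds the single OU parameter d,
    and d -> 0 recovers OLS, so the models are nested.
    """
    statistic = 2.0 * (lnml_regou - lnml_ols)
    if statistic < -1e-9:
        raise ValueError(
            f"RegOU log-likelihood below OLS by {-statistic / 2:.3g}; models not nested as fitted"
        )
    statistic = float(statistic)
    return LRTResult(statistic, float(stats.chi2.sf(max(statistic, 0.0), df=1)))
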