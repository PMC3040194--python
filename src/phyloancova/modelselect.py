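"""Model grid, AICc ranking and report rendering.

Runs the 4-predictor-set x 3-estimator grid (no predictors, Clade, Habitat,
Clade+Habitat; each fitted by OLS, PGLS and RegOU), ranks the twelve fits by
AICc, attaches Burnham-Anderson-style support labels, and renders the
model-comparison table, the full-model coefficient table with partial
F-tests, and simple group means — the three summaries a comparative
hematocrit analysis reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gls import (
    CLADE_DUMMIES,
    FitResult,
    HABITAT_DUMMIES,
    TraitTable,
    align_traits_to_tree,
    build_design,
    estimate_d,
    fit_gls,
    lrt_signal,
    partial_f_test,
    reml_estimate_d,
)
from .phylocov import bm_covariance, star_covariance
from .treeio import PhyloTree

__all__ = [
    "PREDICTOR_SETS",
    "ESTIMATORS",
    "GridRow",
    "ModelComparisonTable",
    "support_label",
    "run_model_grid",
    "lrt_signal_block",
    "group_means",
    "full_model_report",
    "render_reports",
]

PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "none": (),
    "clade": ("clade",),
    "habitat": ("habitat",),
    "clade+habitat": ("habitat", "clade"),
}
ESTIMATORS = ("OLS", "PGLS", "RegOU")

# Burnham-Anderson rough rules of thumb for delta-AICc support
_SUPPORT_BANDS = (
    (2.0, "substantial"),
    (4.0, "weaker"),
    (7.0, "considerably less"),
    (10.0, "little"),
)


def support_label(delta_aicc: float) -> str:
    for edge, label in _SUPPORT_BANDS:
        if delta_aicc <= edge:
            return label
    return "virtually none"


@dataclass
class GridRow:
    predictors: str
    estimator: str
    fit: FitResult
    delta_aicc: float = np.nan
    support: str = ""


@dataclass
class ModelComparisonTable:
    rows: list[GridRow]

    @property
    def best(self) -> GridRow:
        # ties broken toward fewer parameters
        return min(self.rows, key=lambda r: (r.fit.aicc, r.fit.k))

    def row(self, predictors: str, estimator: str) -> GridRow:
        for r in self.rows:
            if r.predictors == predictors and r.estimator == estimator:
                return r
        raise KeyError((predictors, estimator))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            f = r.fit
            recs.append(
                {
                    "predictors": r.predictors,
                    "estimator": r.estimator,
                    "lnML": f.lnml,
                    "AIC": f.aic,
                    "AICc": f.aicc,
                    "MSE": f.mse,
                    "SEE": f.see,
                    "r2": f.r2,
                    "REML_d": f.d if f.d is not None else np.nan,
                    "k": f.k,
                    "delta_AICc": r.delta_aicc,
                    "support": r.support,
                }
            )
        return pd.DataFrame(recs)



def run_model_grid(
    traits: TraitTable,
    tree: PhyloTree,
    predictor_sets: Sequence[str] | None = None,
    estimators: Sequence[str] = ESTIMATORS,
) -> ModelComparisonTable:
    """Fit every (predictor set, estimator) cell and rank by AICc.

    The tree must carry branch lengths (assign Pagel lengths first if the
    topology has none); it is rescaled to height 1 internally.  The trait
    table is aligned to the tree's tip order, with a hard error on any
    species mismatch.
    """
    psets = list(predictor_sets) if predictor_sets is not None else list(PREDICTOR_SETS)
    unknown = set(psets) - set(PREDICTOR_SETS)
    if unknown:
        raise ValueError(f"unknown predictor set(s): {', '.join(sorted(unknown))}")
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator(s): {', '.join(sorted(unknown))}")
    if any(tree.nodes[nid].length is None for nid in tree.preorder() if nid != tree.root):
        raise ValueError(
            "tree has no branch lengths; call assign_pagel_branch_lengths first"
        )
    unit_tree = tree.rescaled_to_unit_height()
    traits = align_traits_to_tree(traits, unit_tree)
    y = traits.hct
    v_star = star_covariance(traits.species)
    v_bm = bm_covariance(unit_tree)

    rows: list[GridRow] = []
    for pset in psets:
        X = build_design(traits, PREDICTOR_SETS[pset], drop_unobserved=True)
        for est in estimators:
            if est == "OLS":
                fit = fit_gls(y, X, v_star)
            elif est == "PGLS":
                fit = fit_gls(y, X, v_bm)
            else:
                _, fit = reml_estimate_d(y, X, unit_tree)
            rows.append(GridRow(pset, est, fit))
    best_aicc = min(r.fit.aicc for r in rows)
    for r in rows:
        r.delta_aicc = r.fit.aicc - best_aicc
        r.support = support_label(r.delta_aicc)
    return ModelComparisonTable(rows)


def lrt_signal_block(
    traits: TraitTable,
    tree: PhyloTree,
    predictor_sets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio tests for phylogenetic signal, one per predictor set.

    Each row compares the RegOU model against OLS with the same design.  For
    a genuine likelihood *ratio*, d is optimized here on the ML surface
    (the REML d-hat reported in the comparison table does not maximize the
    ML profile, and the statistic could otherwise come out negative).
    """
    psets = list(predictor_sets) if predictor_sets is not None else list(PREDICTOR_SETS)
    unit_tree = tree.rescaled_to_unit_height()
    traits = align_traits_to_tree(traits, unit_tree)
    y = traits.hct
    v_star = star_covariance(traits.species)
    recs = []
    for pset in psets:
        X = build_design(traits, PREDICTOR_SETS[pset], drop_unobserved=True)
        ols = fit_gls(y, X, v_star)
        _, regou = estimate_d(y, X, unit_tree, criterion="ml")
        stat, p = lrt_signal(regou.lnml, ols.lnml)
        recs.append({"predictors": pset, "LRT": stat, "P": p})
    return pd.DataFrame(recs)


def group_means(traits: TraitTable, by: str) -> pd.DataFrame:
    """Simple (non-phylogenetic) group means of hematocrit with standard errors.

    ``by`` is 'habitat', 'clade', or 'clade×habitat'.  SE is the sample SD
    over sqrt(n); singleton groups get SE = NaN (absent).
    """
    key = by.replace("x", "×").replace(" ", "")
    keys = {"habitat": ["habitat"], "clade": ["clade"], "clade×habitat": ["clade", "habitat"]}
    if key not in keys:
        raise ValueError(f"unknown grouping {by!r}; use habitat, clade, or clade×habitat")
    cols = keys[key]
    grouped = traits.data.groupby(cols, sort=True, observed=True)["hct"]
    out = grouped.agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out.drop(columns="sd")


# -- full-model report (coefficient table with partial F-tests) --------------


def full_model_report(
    traits: TraitTable, tree: PhyloTree, estimator: str = "OLS"
) -> tuple[FitResult, pd.DataFrame]:
    """Coefficient/SE/F/df/P table for the full Clade+Habitat model.

    Per-coefficient F-tests have 1 numerator df (equivalent to t^2); the
    Habitat and Clade rows are block partial F-tests of the factor's dummy
    columns.  Base groups are Terrestrial and Colubrinae.
    """
    unit_tree = tree.rescaled_to_unit_height()
    traits = align_traits_to_tree(traits, unit_tree)
    y = traits.hct
    X = build_design(traits, ("habitat", "clade"), drop_unobserved=True)
    if estimator == "OLS":
        V = star_covariance(traits.species)
        fit = fit_gls(y, X, V)
    elif estimator == "PGLS":
        V = bm_covariance(unit_tree)
        fit = fit_gls(y, X, V)
    elif estimator == "RegOU":
        d_hat, fit = reml_estimate_d(y, X, unit_tree)
        from .phylocov import ou_covariance

        V = ou_covariance(unit_tree, d_hat)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    recs = []
    for name, b, se in zip(fit.columns, fit.beta, fit.se_beta):
        if name == "Y-intercept":
            recs.append({"term": name, "coefficient": b, "se": se, "F": np.nan,
                         "df": "", "P": np.nan})
        else:
            ft = partial_f_test(y, X, V, [name])
            recs.append({"term": name, "coefficient": b, "se": se, "F": ft.f,
                         "df": f"{ft.df_num}, {ft.df_den}", "P": ft.p_value})
    for factor, dummies in (("Habitat", HABITAT_DUMMIES), ("Clade", CLADE_DUMMIES)):
        present = [c for c in dummies if c in X.columns]
        if not present:
            continue
        ft = partial_f_test(y, X, V, present)
        recs.append({"term": factor, "coefficient": np.nan, "se": np.nan, "F": ft.f,
                     "df": f"{ft.df_num}, {ft.df_den}", "P": ft.p_value})
    return fit, pd.DataFrame(recs)


# -- rendering ---------------------------------------------------------------


def _fmt(x, nd: int) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


def format_model_comparison(table: ModelComparisonTable) -> str:
    """Deterministic TSV of the model grid (2-decimal likelihood-scale values)."""
    df = table.to_frame()
    buf = io.StringIO()
    cols = ["predictors", "estimator", "lnML", "AIC", "AICc", "MSE", "SEE", "r2",
            "REML_d", "delta_AICc", "support"]
    buf.write("\t".join(cols) + "\n")
    for _, row in df.iterrows():
        cells = [
            row["predictors"],
            row["estimator"],
            _fmt(row["lnML"], 2),
            _fmt(row["AIC"], 2),
            _fmt(row["AICc"], 2),
            _fmt(row["MSE"], 2),
            _fmt(row["SEE"], 2),
            _fmt(row["r2"], 2),
            _fmt(row["REML_d"], 3) if not np.isnan(row["REML_d"]) else "",
            _fmt(row["delta_AICc"], 2),
            row["support"],
        ]
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()


def format_coefficients(coef: pd.DataFrame) -> str:
    """Coefficient table TSV (4-decimal coefficients, Table-2-style columns)."""
    buf = io.StringIO()
    buf.write("term\tcoefficient\tse\tF\tdf\tP\n")
    for _, row in coef.iterrows():
        buf.write(
            "\t".join(
                [
                    str(row["term"]),
                    _fmt(row["coefficient"], 4),
                    _fmt(row["se"], 3),
                    _fmt(row["F"], 2),
                    str(row["df"]),
                    _fmt(row["P"], 4),
                ]
            )
            + "\n"
        )
    buf.write("# base groups: Habitat = Terrestrial, Clade = Colubrinae\n")
    return buf.getvalue()


def format_group_means(gm: pd.DataFrame) -> str:
    buf = io.StringIO()
    cols = list(gm.columns)
    buf.write("\t".join(cols) + "\n")
    for _, row in gm.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if c in {"mean", "se"}:
                cells.append(_fmt(v, 2))
            else:
                cells.append(str(v))
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()


def render_reports(
    traits: TraitTable,
    tree: PhyloTree,
    outdir: str | Path,
    estimator_for_coefficients: str = "OLS",
) -> dict[str, Path]:
    """Write the model-comparison, coefficient, LRT and group-mean reports.

    Deterministic: rerunning on identical inputs produces byte-identical
    files.  Returns the mapping of report name to file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = run_model_grid(traits, tree)
    fit, coef = full_model_report(traits, tree, estimator_for_coefficients)
    paths = {
        "model_comparison": outdir / "model_comparison.tsv",
        "coefficients": outdir / "coefficients.tsv",
        "lrt": outdir / "lrt_signal.tsv",
        "group_means_habitat": outdir / "group_means_habitat.tsv",
        "group_means_clade": outdir / "group_means_clade.tsv",
        "summary": outdir / "summary.txt",
    }
    paths["model_comparison"].write_text(format_model_comparison(grid))
    paths["coefficients"].write_text(format_coefficients(coef))
    lrt = lrt_signal_block(traits, tree)
    buf = io.StringIO()
    buf.write("predictors\tLRT\tP\n")
    for _, row in lrt.iterrows():
        buf.write(f"{row['predictors']}\t{row['LRT']:.2f}\t{row['P']:.4f}\n")
    paths["lrt"].write_text(buf.getvalue())
    paths["group_means_habitat"].write_text(format_group_means(group_means(traits, "habitat")))
    paths["group_means_clade"].write_text(format_group_means(group_means(traits, "clade")))

    best = grid.best
    lines = [
        "Model comparison by AICc",
        f"  preferred model: {best.estimator} with predictors '{best.predictors}' "
        f"(AICc {best.fit.aicc:.2f})",
        f"  full {estimator_for_coefficients} model: lnML {fit.lnml:.2f}, "
        f"AICc {fit.aicc:.2f}, r2 {fit.r2:.2f}",
        "  see model_comparison.tsv, coefficients.tsv, lrt_signal.tsv",
    ]
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
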