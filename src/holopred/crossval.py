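"""Cohort-fold cross-validation of hologenomic prediction.

Each rumen-sample cohort is a fold: the three variance-component models
(G only, M only, G + M) are refitted with the fold's phenotypes omitted,
breeding values (BV) and metagenome values (MV) are predicted for the
held-out animals, and compared with the phenotype adjusted for fixed
effects.  Five prediction components are evaluated, named
component_model: G_G, M_M, G_G+M, M_G+M and G+M_G+M (the BV + MV sum
from the joint model).

Per-fold accuracy is the Pearson correlation between prediction and
adjusted phenotype (deliberately not divided by the square root of
heritability); bias is the slope of the adjusted phenotype regressed on
the prediction, 1 meaning unbiased.  Fold results are aggregated by the
cohort-size-weighted mean and SD, and three weighted paired t-tests are
reported: MV accuracy greater than BV accuracy, MV vs BV bias slopes
different, and MV absolute bias (|slope - 1|) smaller than BV's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import RelationshipMatrix, align_matrices
from .varcomp import ModelSpec, build_fixed_design, fit_mixed_model, predict_blup

__all__ = [
    "FoldResult",
    "ValidationSummary",
    "COMPONENTS",
    "cohort_folds",
    "adjusted_phenotype",
    "fold_accuracy",
    "fold_bias",
    "weighted_summary",
    "weighted_paired_ttest",
    "run_validation",
]

# (label, model random terms, which predictions are summed)
COMPONENTS = (
    ("G_G", ("animal",), ("animal",)),
    ("M_M", ("metagenome",), ("metagenome",)),
    ("G_G+M", ("animal", "metagenome"), ("animal",)),
    ("M_G+M", ("animal", "metagenome"), ("metagenome",)),
    ("G+M_G+M", ("animal", "metagenome"), ("animal", "metagenome")),
)


@dataclass
class FoldResult:
    cohort: str
    n: int
    accuracy: dict = field(default_factory=dict)   # component -> r
    bias: dict = field(default_factory=dict)       # component -> slope
    flags: dict = field(default_factory=dict)      # model -> convergence flag
    failed: bool = False
    reason: str = ""


@dataclass
class ValidationSummary:
    folds: list
    accuracy: pd.DataFrame        # component x (mean, sd) weighted
    bias: pd.DataFrame
    ttests: pd.DataFrame          # hypothesis x (t, df, p)
    n_total: int
    n_failed: int


def cohort_folds(cohorts) -> list:
    """One fold per distinct cohort; singleton cohorts are excluded.

    Parameters
    ----------
    cohorts : Series
        Cohort label per sample, indexed by sample id.

    Returns
    -------
    list of (cohort_label, list of held-out ids), ordered by label.
    """
    cohorts = pd.Series(cohorts)
    if cohorts.isna().any():
        raise ValueError("every sample needs a cohort label")
    folds = []
    for c, grp in sorted(cohorts.groupby(cohorts).groups.items()):
        if len(grp) < 2:
            warnings.warn(
                f"cohort {c!r} has fewer than 2 samples; excluded from validation"
            )
            continue
        folds.append((c, list(grp)))
    return folds


def adjusted_phenotype(y, design: np.ndarray, beta) -> np.ndarray:
    """Phenotype adjusted for fixed effects: y - X beta."""
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return y - np.asarray(design, dtype=float) @ beta


def fold_accuracy(pred, y_adj) -> float:
    """Pearson correlation of prediction and adjusted phenotype.

    Returns NaN (fold missing) when either vector is constant.
    """
    pred = np.asarray(pred, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    if len(pred) < 2 or pred.std() == 0 or y_adj.std() == 0:
        return np.nan
    return float(np.corrcoef(pred, y_adj)[0, 1])


def fold_bias(pred, y_adj) -> float:
    """OLS slope of the adjusted phenotype on the prediction.

    cov(y_adj, pred) / var(pred); NaN when the predictor is constant.
    """
    pred = np.asarray(pred, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    v = np.var(pred, ddof=1) if len(pred) > 1 else 0.0
    if v == 0:
        return np.nan
    c = np.cov(y_adj, pred, ddof=1)[0, 1]
    return float(c / v)


def weighted_summary(values, weights) -> tuple[float, float]:
    """Weighted mean and SD with weights = cohort sizes.

    The SD uses the reliability-weights estimator
    ``sqrt( sum w (v - vbar)^2 * W / (W^2 - sum w^2) )`` with
    ``W = sum w``, which reduces to the ordinary ddof=1 SD under equal
    weights.  NaN values are dropped pairwise.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = ~np.isnan(v)
    v, w = v[ok], w[ok]
    if len(v) == 0:
        raise ValueError("all values missing")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mean = float(np.sum(w * v) / wsum)
    if len(v) < 2:
        return mean, np.nan
    denom = wsum**2 - np.sum(w**2)
    if denom <= 0:
        return mean, np.nan
    var = float(np.sum(w * (v - mean) ** 2) * wsum / denom)
    return mean, float(np.sqrt(max(var, 0.0)))


def weighted_paired_ttest(
    a, b, weights, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Weighted paired t-test on per-fold values.

    Differences d = a - b are summarized by their weighted mean and
    weighted SD (reliability weights); ``t = dbar_w / (sd_w / sqrt(k))``
    with k complete pairs and k - 1 degrees of freedom.

    ``alternative`` is ``"two-sided"`` or ``"greater"`` (mean difference
    greater than zero).  With a zero weighted SD the statistic is
    degenerate: t is reported as +/-inf (0 when the mean difference is
    also 0) with the corresponding limiting p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b, w = a[ok], b[ok], w[ok]
    k = len(a)
    if k < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    mean, sd = weighted_summary(d, w)
    df = k - 1
    if sd == 0 or np.isnan(sd):
        if mean == 0:
            t = 0.0
        else:
            t = np.inf if mean > 0 else -np.inf
    else:
        t = mean / (sd / np.sqrt(k))
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else (1.0 if t == 0 else 0.0)
    elif alternative == "greater":
        p = stats.t.sf(t, df) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), df, float(p)


def _check_levels(train: pd.DataFrame, test: pd.DataFrame, terms) -> None:
    for t in terms:
        col = train[t]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            continue
        unseen = set(test[t]) - set(col)
        if unseen:
            raise ValueError(
                f"fixed-effect level(s) of {t!r} unseen in training: "
                f"{sorted(map(str, unseen))}"
            )


def run_validation(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    G: RelationshipMatrix,
    M: RelationshipMatrix,
    cohorts=None,
    max_iter: int = 200,
    models: tuple = ("G", "M", "G+M"),
) -> ValidationSummary:
    """Cohort-fold cross-validation of the G, M and G + M models.

    Parameters
    ----------
    pheno : DataFrame indexed by id, with the trait, fixed-effect
        columns and (unless ``cohorts`` is given) a ``"cohort"`` column.
    spec : ModelSpec naming the trait and fixed terms (its ``random``
        field is ignored; the models in ``models`` are fitted).
    G, M : relationship matrices covering every id (M may be None when
        only the G model is requested, and vice versa).
    models : which of the three models to refit per fold; prediction
        components belonging to omitted models are skipped, and the
        MV-vs-BV t-tests are only reported when both single-effect
        models ran.
    """
    if cohorts is None:
        cohorts = pheno["cohort"]
    cohorts = pd.Series(cohorts, index=pheno.index)
    folds = cohort_folds(cohorts)
    all_ids = list(pheno.index)
    components = [c for c in COMPONENTS
                  if {"G_G": "G", "M_M": "M"}.get(c[0], "G+M") in models]
    g_cross = align_matrices(G, all_ids) if G is not None else None
    m_cross = align_matrices(M, all_ids) if M is not None else None
    gi = {x: i for i, x in enumerate(all_ids)}

    results = []
    for cohort, test_ids in folds:
        train_ids = [i for i in all_ids if i not in set(test_ids)]
        res = FoldResult(cohort=str(cohort), n=len(test_ids))
        try:
            train = pheno.loc[train_ids]
            test = pheno.loc[test_ids]
            _check_levels(train, test, spec.fixed)
            tr_idx = np.array([gi[i] for i in train_ids])
            te_idx = np.array([gi[i] for i in test_ids])

            fits = {}
            for label in models:
                rand = {"G": ("animal",), "M": ("metagenome",),
                        "G+M": ("animal", "metagenome")}[label]
                mspec = ModelSpec(trait=spec.trait, fixed=list(spec.fixed),
                                  random=rand)
                fit = fit_mixed_model(
                    train, mspec,
                    G=G if "animal" in rand else None,
                    M=M if "metagenome" in rand else None,
                    max_iter=max_iter, check_psd=False,
                )
                fits[label] = fit
                res.flags[label] = fit.converged

            # adjusted phenotype on the held-out cohort, per model
            x_test, _ = _design_for(test, train, spec.fixed)
            y_test = test[spec.trait].to_numpy(dtype=float)
            for label, model_terms, pred_terms in components:
                fit = fits[{"G_G": "G", "M_M": "M"}.get(label, "G+M")]
                blocks = {}
                for term in pred_terms:
                    rel = g_cross if term == "animal" else m_cross
                    blocks[term] = rel.values[np.ix_(te_idx, tr_idx)]
                pred_df = predict_blup(fit, blocks, test_ids)
                pred = pred_df.sum(axis=1).to_numpy()
                beta = _match_beta(fit, test, train, spec.fixed)
                y_adj = adjusted_phenotype(y_test, beta[0], beta[1])
                res.accuracy[label] = fold_accuracy(pred, y_adj)
                res.bias[label] = fold_bias(pred, y_adj)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            res.failed = True
            res.reason = str(exc)
        results.append(res)

    ok = [r for r in results if not r.failed]
    if not ok:
        raise ValueError("every fold failed; no summary possible")
    weights = np.array([r.n for r in ok], dtype=float)
    comp_names = [c[0] for c in components]
    acc = pd.DataFrame(
        [weighted_summary([r.accuracy[c] for r in ok], weights)
         for c in comp_names],
        index=comp_names, columns=["mean", "sd"],
    )
    bias = pd.DataFrame(
        [weighted_summary([r.bias[c] for r in ok], weights)
         for c in comp_names],
        index=comp_names, columns=["mean", "sd"],
    )

    rows = []
    if "G" in models and "M" in models:
        acc_m = np.array([r.accuracy["M_M"] for r in ok])
        acc_g = np.array([r.accuracy["G_G"] for r in ok])
        b_m = np.array([r.bias["M_M"] for r in ok])
        b_g = np.array([r.bias["G_G"] for r in ok])
        for name, a, b, alt in (
            ("accuracy_MV_gt_BV", acc_m, acc_g, "greater"),
            ("bias_MV_ne_BV", b_m, b_g, "two-sided"),
            ("absbias_MV_lt_BV", np.abs(b_g - 1.0), np.abs(b_m - 1.0), "greater"),
        ):
            try:
                t, df, p = weighted_paired_ttest(a, b, weights, alternative=alt)
            except ValueError:
                t, df, p = np.nan, 0, np.nan
            rows.append((name, t, df, p))
    ttests = pd.DataFrame(rows, columns=["hypothesis", "t", "df", "p"]).set_index(
        "hypothesis"
    )

    return ValidationSummary(
        folds=results,
        accuracy=acc,
        bias=bias,
        ttests=ttests,
        n_total=int(sum(r.n for r in ok)),
        n_failed=len(results) - len(ok),
    )


def _design_for(test: pd.DataFrame, train: pd.DataFrame, terms):
    """Design rows for test data using the training data's level coding."""
    combined = pd.concat([train, test])
    x, names = build_fixed_design(combined, terms)
    return x[len(train):], names


def _match_beta(fit, test, train, terms):
    """(test design, beta) restricted to the columns the fit retained."""
    x, names = _design_for(test, train, terms)
    cols = [names.index(nm) for nm in fit.beta.index if nm in names]
    keep_beta = fit.beta[[nm for nm in fit.beta.index if nm in names]]
    return x[:, cols], keep_beta.to_numpy()
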