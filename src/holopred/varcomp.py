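"""REML variance components and BLUP for host-genetic and metagenome effects.

The model is the standard animal model extended with a metagenome random
effect::

    y = X b + g + m + e,   g ~ N(0, G sg2),  m ~ N(0, M sm2),  e ~ N(0, I se2)

where G is a genomic relationship matrix and M a metagenome relationship
matrix; g and m are assumed independent.  Any subset of {g, m} may be
fitted.  Variance components are estimated by average-information (AI)
REML with expectation-maximization fallback steps; the restricted
log-likelihood maximized is::

    lR = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

with V the phenotypic covariance and P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.

Derived quantities follow the quantitative-genetics conventions:
heritability h2 = sg2 / sp2, microbiability m2 = sm2 / sp2, and the
combined share (sg2 + sm2) / sp2, with sp2 = sg2 + sm2 + se2.  BLUPs of
the random effects (breeding values BV, metagenome values MV) are
u_hat = s2_hat * K * V^-1 (y - X b_hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import RelationshipMatrix, align_matrices

__all__ = [
    "ModelSpec",
    "VarCompFit",
    "build_fixed_design",
    "reml",
    "fit_mixed_model",
    "variance_ratios",
    "predict_blup",
]

MAX_ITER = 200
REL_TOL = 1e-6       # max relative parameter change at convergence
LOGLIK_TOL = 1e-8    # log-likelihood change at convergence
PSD_TOL = -1e-8      # most-negative admissible kernel eigenvalue (relative)


@dataclass
class ModelSpec:
    """What to fit: trait column, fixed terms, random terms.

    Fixed terms name columns of the phenotype table; columns with an
    object/categorical dtype enter as treatment-coded class effects,
    numeric columns as covariates.  Random terms are a subset of
    ``{"animal", "metagenome"}`` requiring the G and M matrices
    respectively.
    """

    trait: str
    fixed: list = field(default_factory=list)
    random: tuple = ("animal", "metagenome")

    def __post_init__(self):
        self.random = tuple(self.random)
        if not self.random:
            raise ValueError("at least one random term is required")
        bad = set(self.random) - {"animal", "metagenome"}
        if bad:
            raise ValueError(f"unknown random term(s): {sorted(bad)}")


@dataclass
class VarCompFit:
    """REML estimates, ratios, BLUPs and diagnostics for one model."""

    components: dict            # name -> variance estimate (incl. "residual")
    se: dict                    # name -> SE of the variance estimate
    ratios: dict                # h2 / m2 / combined -> (estimate, se)
    sigma_p2: float
    loglik: float
    converged: str              # converged | max-iter | boundary | singular
    n_iter: int
    beta: pd.Series             # fixed-effect solutions
    blups: dict                 # "animal" -> BV Series, "metagenome" -> MV Series
    ids: list
    _py: np.ndarray = None      # V^-1 (y - X beta), kept for prediction

    @property
    def h2(self):
        return self.ratios.get("h2", (np.nan, np.nan))[0]

    @property
    def m2(self):
        return self.ratios.get("m2", (np.nan, np.nan))[0]


def build_fixed_design(pheno: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    """Treatment-coded fixed-effect design with intercept.

    Class terms (object/categorical dtype) are dummy-coded dropping the
    first level; numeric terms enter as covariates.  Aliased columns are
    removed (with a warning) so the returned design has full column rank.
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["mu"]
    for t in terms:
        if t not in pheno.columns:
            raise KeyError(f"fixed term {t!r} not in phenotype table")
        col = pheno[t]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            cols.append(col.to_numpy(dtype=float))
            names.append(t)
        else:
            d = pd.get_dummies(col, drop_first=True)
            for lev in d.columns:
                cols.append(d[lev].to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r, piv = linalg.qr(x, pivoting=True)
        keep = np.sort(piv[:rank])
        dropped = [names[i] for i in piv[rank:]]
        warnings.warn(f"dropped aliased fixed-effect column(s): {dropped}")
        x = x[:, keep]
        names = [names[i] for i in keep]
    return x, names


def _check_psd(k: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(k)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < PSD_TOL * scale * 100:
        raise ValueError(
            f"{name} matrix is not positive semi-definite "
            f"(min eigenvalue {w[0]:.3e})"
        )


def reml(
    y: np.ndarray,
    x: np.ndarray,
    kernels: dict,
    max_iter: int = MAX_ITER,
    verbose: bool = False,
) -> dict:
    """AI-REML with EM fallback for V = sum_k Kk * s2_k + I * s2_e.

    Parameters
    ----------
    y : (n,) response.
    x : (n, p) full-rank fixed design.
    kernels : dict name -> (n, n) PSD matrix (residual identity is
        implicit and reported as ``"residual"``).

    Returns
    -------
    dict with components, SEs (from the inverse AI matrix), loglik,
    convergence flag, iteration count, beta, and the projected residual
    ``py = V^-1 (y - X beta)`` used for BLUP.
    """
    n = len(y)
    p = x.shape[1]
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} fixed effects")
    names = list(kernels) + ["residual"]
    ks = [np.asarray(kernels[nm], dtype=float) for nm in kernels]
    k_all = ks + [np.eye(n)]
    nk = len(k_all)

    vary = float(np.var(y, ddof=1))
    theta = np.full(nk, vary / nk)
    floor = 1e-10 * vary
    neg_count = np.zeros(nk, dtype=int)
    pinned = np.zeros(nk, dtype=bool)
    ridge_used = False
    loglik = -np.inf
    flag = "max-iter"
    ai = np.eye(nk)

    def _vmats(th):
        nonlocal ridge_used
        v = th[-1] * np.eye(n)
        for j in range(nk - 1):
            v += th[j] * k_all[j]
        try:
            c, low = linalg.cho_factor(v, lower=True)
        except linalg.LinAlgError:
            ridge_used = True
            v = v + 1e-8 * np.mean(np.diag(v)) * np.eye(n)
            c, low = linalg.cho_factor(v, lower=True)
        vinv = linalg.cho_solve((c, low), np.eye(n))
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vinvx = vinv @ x
        xtvx = x.T @ vinvx
        cx, lowx = linalg.cho_factor(xtvx, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx)))
        beta = linalg.cho_solve((cx, lowx), vinvx.T @ y)
        pmat = vinv - vinvx @ linalg.cho_solve((cx, lowx), vinvx.T)
        py = pmat @ y
        ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
        return pmat, py, beta, ll

    def _score_ai(pmat, py):
        kpy = [k @ py for k in k_all]
        score = np.array(
            [
                -0.5 * (np.sum(pmat * k_all[j]) - float(py @ kpy[j]))
                for j in range(nk)
            ]
        )
        ai_m = np.empty((nk, nk))
        pkpy = [pmat @ v for v in kpy]
        for a in range(nk):
            for b in range(a, nk):
                ai_m[a, b] = ai_m[b, a] = 0.5 * float(kpy[a] @ pkpy[b])
        return score, ai_m

    pmat, py, beta, loglik = _vmats(theta)
    it = 0
    for it in range(1, max_iter + 1):
        score, ai = _score_ai(pmat, py)
        free = ~pinned
        step = np.zeros(nk)
        singular_ai = False
        try:
            sub = ai[np.ix_(free, free)]
            if np.linalg.cond(sub) > 1e12:
                singular_ai = True
            step[free] = np.linalg.solve(sub, score[free])
        except np.linalg.LinAlgError:
            singular_ai = True

        accepted = False
        if not singular_ai:
            # AI step with step-halving; reject proposals with negatives
            h = 1.0
            for _ in range(8):
                prop = theta + h * step
                prop[pinned] = 0.0
                if (prop[free] < 0).any():
                    h *= 0.5
                    continue
                prop = np.maximum(prop, 0.0)
                prop[free] = np.maximum(prop[free], floor)
                try:
                    pm2, py2, b2, ll2 = _vmats(prop)
                except linalg.LinAlgError:
                    h *= 0.5
                    continue
                if ll2 >= loglik - 1e-12:
                    accepted = True
                    break
                h *= 0.5
            if not accepted and (theta + step)[free].min() < 0:
                neg_count[free & ((theta + step) < 0)] += 1

        if not accepted:
            # EM fallback: guaranteed uphill, keeps components positive
            prop = theta.copy()
            for j in np.where(free)[0]:
                tr = np.sum(pmat * k_all[j])
                upd = theta[j] + theta[j] ** 2 * (float(py @ (k_all[j] @ py)) - tr) / n
                if upd < 0:
                    neg_count[j] += 1
                    upd = floor
                else:
                    neg_count[j] = 0
                prop[j] = upd
            prop[pinned] = 0.0
            pm2, py2, b2, ll2 = _vmats(prop)

        # pin components that keep trying to go negative
        newly = (neg_count >= 2) & free
        if newly.any():
            prop[newly] = 0.0
            pinned |= newly
            pm2, py2, b2, ll2 = _vmats(prop)

        denom = np.maximum(np.abs(theta), floor)
        rel_change = np.max(np.abs(prop - theta) / denom)
        dll = ll2 - loglik
        theta, pmat, py, beta, loglik = prop, pm2, py2, b2, ll2
        if verbose:
            print(f"iter {it}: loglik={loglik:.6f} theta={theta}")
        if rel_change < REL_TOL and abs(dll) < LOGLIK_TOL:
            flag = "converged"
            break

    if flag == "converged" and pinned.any():
        flag = "boundary"
    score, ai = _score_ai(pmat, py)
    try:
        if np.linalg.cond(ai) > 1e12:
            se = np.full(nk, np.nan)
            if flag == "converged":
                flag = "singular"
            ai_inv = np.linalg.pinv(ai)
        else:
            ai_inv = np.linalg.inv(ai)
            se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except np.linalg.LinAlgError:
        ai_inv = np.full((nk, nk), np.nan)
        se = np.full(nk, np.nan)
        flag = "singular"

    theta = np.where(theta < floor * 10, 0.0, theta)
    return {
        "names": names,
        "theta": theta,
        "se": se,
        "ai_inv": ai_inv,
        "loglik": loglik,
        "flag": flag,
        "n_iter": it,
        "beta": beta,
        "py": py,
        "ridge_used": ridge_used,
    }


def variance_ratios(
    components, ai_inv: np.ndarray | None = None, names: list | None = None
) -> dict:
    """h2, m2 and combined variance shares with delta-method SEs.

    Accepts either a fitted :class:`VarCompFit` (ratios recomputed from
    its stored components) or a component dict together with the
    component covariance matrix (inverse AI) and component names.
    """
    if isinstance(components, VarCompFit):
        fit = components
        names = list(fit.components)
        theta_d = fit.components
        ai_inv = None
        components = theta_d
    if names is None:
        names = list(components)
    theta = np.array([components[nm] for nm in names])
    sp2 = float(theta.sum())
    if sp2 <= 0:
        raise ValueError("phenotypic variance is zero; ratios undefined")

    def _ratio(num_idx):
        num = theta[num_idx].sum()
        r = num / sp2
        if ai_inv is None or np.isnan(ai_inv).any():
            return r, np.nan
        grad = np.full(len(theta), -num / sp2**2)
        grad[num_idx] += 1.0 / sp2
        var = float(grad @ ai_inv @ grad)
        return r, np.sqrt(max(var, 0.0))

    out = {}
    if "animal" in names:
        out["h2"] = _ratio([names.index("animal")])
    if "metagenome" in names:
        out["m2"] = _ratio([names.index("metagenome")])
    idx = [i for i, nm in enumerate(names) if nm != "residual"]
    out["combined"] = _ratio(idx)
    return out


def fit_mixed_model(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    G: RelationshipMatrix | None = None,
    M: RelationshipMatrix | None = None,
    max_iter: int = MAX_ITER,
    check_psd: bool = True,
) -> VarCompFit:
    """Fit one variance-component model to a phenotype table.

    The table must be indexed by id; G and M are aligned to that index.
    Rows with a missing trait value or missing fixed-effect covariates
    are dropped before fitting.
    """
    needed = [spec.trait] + list(spec.fixed)
    data = pheno.dropna(subset=[c for c in needed if c in pheno.columns])
    ids = list(data.index)
    y = data[spec.trait].to_numpy(dtype=float)
    x, xnames = build_fixed_design(data, spec.fixed)

    kernels = {}
    for term, rel in (("animal", G), ("metagenome", M)):
        if term in spec.random:
            if rel is None:
                raise ValueError(f"random term {term!r} requires its matrix")
            sub = align_matrices(rel, ids)
            if check_psd:
                _check_psd(sub.values, term)
            kernels[term] = sub.values

    res = reml(y, x, kernels, max_iter=max_iter)
    comp = dict(zip(res["names"], res["theta"]))
    se = dict(zip(res["names"], res["se"]))
    ratios = variance_ratios(comp, res["ai_inv"], res["names"])
    blups = {
        term: pd.Series(comp[term] * (kernels[term] @ res["py"]), index=ids)
        for term in kernels
    }
    return VarCompFit(
        components=comp,
        se=se,
        ratios=ratios,
        sigma_p2=float(sum(comp.values())),
        loglik=res["loglik"],
        converged=res["flag"],
        n_iter=res["n_iter"],
        beta=pd.Series(res["beta"], index=xnames),
        blups=blups,
        ids=ids,
        _py=res["py"],
    )


def predict_blup(
    fit: VarCompFit,
    rel_to_train: dict,
    test_ids,
) -> pd.DataFrame:
    """Predict random effects for new individuals from a training fit.

    ``u_test = s2_hat * K_test,train * V_train^-1 (y_train - X_train b_hat)``

    Parameters
    ----------
    rel_to_train : dict
        term name -> (n_test, n_train) cross-relationship block, columns
        ordered like the training fit's ids.
    test_ids : identifiers for the rows of each block.

    Returns
    -------
    DataFrame with one column per random term ("animal" -> BV,
    "metagenome" -> MV), indexed by ``test_ids``.
    """
    test_ids = list(test_ids)
    out = {}
    for term, block in rel_to_train.items():
        if term not in fit.components:
            raise KeyError(f"term {term!r} was not in the training fit")
        block = np.asarray(block, dtype=float)
        if block.shape != (len(test_ids), len(fit.ids)):
            raise ValueError(
                f"cross block for {term!r} has shape {block.shape}, "
                f"expected ({len(test_ids)}, {len(fit.ids)})"
            )
        out[term] = fit.components[term] * (block @ fit._py)
    return pd.DataFrame(out, index=test_ids)
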