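"""Phenotype derivations for gas, feed-efficiency and health traits.

Covers the trait transforms applied before mixed-model analysis:
within-lot scaling of chamber gas measures (to absorb time-off-feed
differences between measurement lots), the methane ratio
CH4/(CH4 + CO2) in mM/Mol, the log transform of faecal egg counts, and
residual feed intake as the residual of intake regressed on metabolic
weight, growth rate and management classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "scale_within_lot",
    "methane_ratio",
    "transform_fec",
    "compute_rfi",
]

# molar masses, g/mol
_M_CH4 = 16.04
_M_CO2 = 44.01


def scale_within_lot(values, lots):
    """Scale each measurement by its lot mean times the grand mean.

    ``scaled_i = value_i / mean(lot of i) * grand_mean``, where the grand
    mean is taken over all non-missing values.  After scaling, every
    lot's mean equals the grand mean, removing lot-level shifts such as
    differing time off feed.

    Parameters
    ----------
    values : array-like of float
        Per-animal measurements; NaN entries propagate.
    lots : array-like
        Lot label per animal.

    Returns
    -------
    np.ndarray of scaled values.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    lots = pd.Series(np.asarray(lots), index=v.index)
    grand = v.mean()
    lot_means = v.groupby(lots).transform("mean")
    if (lot_means == 0).any():
        bad = sorted(set(lots[lot_means == 0]))
        raise ValueError(f"lot mean of zero in lot(s): {bad}")
    return (v / lot_means * grand).to_numpy()


def methane_ratio(ch4_gpd, co2_gpd, basis: str = "molar"):
    """Methane ratio CH4/(CH4 + CO2), expressed in mM/Mol.

    With ``basis="molar"`` (default) the gas masses in g/day are first
    converted to moles (CH4 16.04 g/mol, CO2 44.01 g/mol); the ratio of
    moles is then scaled by 1000, so it lies in [0, 1000].  A mM/Mol
    figure is a mole ratio, hence the molar default; ``basis="mass"``
    computes the plain mass ratio x 1000 for sensitivity analyses.
    """
    ch4 = np.asarray(ch4_gpd, dtype=float)
    co2 = np.asarray(co2_gpd, dtype=float)
    if (ch4 < 0).any() or (co2 < 0).any():
        raise ValueError("gas measures must be non-negative")
    if basis == "molar":
        a = ch4 / _M_CH4
        b = co2 / _M_CO2
    elif basis == "mass":
        a, b = ch4, co2
    else:
        raise ValueError(f"unknown basis {basis!r}")
    tot = a + b
    if np.any(tot == 0):
        raise ValueError("CH4 and CO2 both zero: ratio undefined")
    return 1000.0 * a / tot


def transform_fec(count_epg):
    """Log-transform a faecal egg count: ln(count + 50)."""
    c = np.asarray(count_epg, dtype=float)
    if (c < 0).any():
        raise ValueError("egg counts must be non-negative")
    return np.log(c + 50.0)


def compute_rfi(
    intake,
    liveweight,
    growth_rate,
    cohort,
    flock,
    pen,
    metabolic_exponent: float = 0.75,
):
    """Residual feed intake: OLS residuals of intake on energy sinks.

    Intake is regressed on metabolic weight (liveweight**0.75, the
    Kleiber exponent), growth rate, and the management classes cohort,
    flock and pen; the residual is the animal's feed intake unexplained
    by size, growth and management, i.e. its (in)efficiency.

    Returns
    -------
    np.ndarray of per-animal residuals.

    Raises
    ------
    ValueError
        If the design is rank deficient (aliased class levels), with the
        offending columns named.
    """
    intake = np.asarray(intake, dtype=float)
    n = intake.shape[0]
    mw = np.asarray(liveweight, dtype=float) ** metabolic_exponent
    gr = np.asarray(growth_rate, dtype=float)

    cols = [np.ones(n), mw, gr]
    names = ["intercept", "metabolic_weight", "growth_rate"]
    for term, labels in (("cohort", cohort), ("flock", flock), ("pen", pen)):
        d = pd.get_dummies(pd.Series(np.asarray(labels)), drop_first=True)
        for lev in d.columns:
            cols.append(d[lev].to_numpy(dtype=float))
            names.append(f"{term}[{lev}]")
    x = np.column_stack(cols)
    if n <= x.shape[1]:
        raise ValueError(
            f"n={n} rows cannot identify {x.shape[1]} model parameters"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the aliased columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(x, pivoting=True)
        aliased = [names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient RFI design; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(x, intake, rcond=None)
    return intake - x @ beta
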