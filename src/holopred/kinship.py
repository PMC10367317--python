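"""Relationship matrices from metagenome profiles and SNP genotypes.

Two kinds of similarity matrix drive the variance-component models:

* the genomic relationship matrix (GRM), built from SNP dosages with
  VanRaden's method 1, and
* the metagenome relationship matrix (MRM), built as the sample-by-sample
  Pearson correlation of normalized log10 feature proportions.

The MRM chain is: raw counts -> smoothed proportions
``p_ij = (c_ij + 1) / (row_sum_i + n_features)`` -> ``log10(p_ij)`` ->
column z-scores, either globally ("L10") or within each rumen-sample
cohort ("CA") -> Pearson correlation across features for every pair of
samples.  The cohort-adjusted variant removes cohort-level location and
scale differences per feature, which is what makes it robust when cohorts
were sequenced or sampled under different conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "log_proportions",
    "normalize_l10",
    "normalize_ca",
    "build_mrm",
    "build_grm",
    "align_matrices",
]


@dataclass
class RelationshipMatrix:
    """An n x n symmetric similarity matrix keyed by sample/animal ids.

    Attributes
    ----------
    values : np.ndarray
        Symmetric (n, n) matrix.
    ids : list of str
        Row/column identifiers, in order.
    kind : str
        ``"GRM"`` or ``"MRM"``.
    provenance : dict
        Free-form description of how the matrix was built
        (normalization, feature set, allele-frequency source...).
    """

    values: np.ndarray
    ids: list
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        # enforce exact symmetry so downstream solvers see a clean matrix
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def log_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Smoothed log10 proportions of a samples-x-features count table.

    Each count is incremented by one and divided by its row total plus the
    number of features, so every proportion is strictly inside (0, 1) and
    each row's proportions sum to one exactly.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, rows = samples, columns = features.

    Returns
    -------
    DataFrame of log10 proportions, same index/columns.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("count table must be 2-D with at least 2 features")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if np.any(arr != np.floor(arr)):
        raise ValueError("counts must be integers")
    n_features = arr.shape[1]
    row_tot = arr.sum(axis=1, keepdims=True) + n_features
    p = (arr + 1.0) / row_tot
    return pd.DataFrame(np.log10(p), index=counts.index, columns=counts.columns)


def _zscore_columns(block: np.ndarray) -> np.ndarray:
    """Column z-scores with sample SD (ddof=1); constant columns -> 0."""
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    out = np.zeros_like(block)
    ok = sd > 0
    out[:, ok] = (block[:, ok] - mu[ok]) / sd[ok]
    return out, int((~ok).sum())


def normalize_l10(logp: pd.DataFrame) -> pd.DataFrame:
    """Global column standardization (mean 0, sample SD 1 per feature).

    Zero-variance columns are set to all zeros with a warning rather than
    dropped, so the feature set is preserved.
    """
    if logp.shape[0] < 2:
        raise ValueError("at least 2 samples are required for normalization")
    out, n_const = _zscore_columns(np.asarray(logp, dtype=float))
    if n_const:
        warnings.warn(
            f"{n_const} zero-variance column(s) set to 0 during L10 normalization"
        )
    return pd.DataFrame(out, index=logp.index, columns=logp.columns)


def normalize_ca(logp: pd.DataFrame, cohorts) -> pd.DataFrame:
    """Within-cohort column standardization (cohort-adjusted, "CA").

    Every feature column is z-scored independently inside each cohort, so
    each (cohort, feature) cell has mean 0 and sample SD 1.  Columns that
    are constant within a cohort are zeroed within that cohort.

    Parameters
    ----------
    logp : DataFrame
        Log10 proportion matrix, samples x features.
    cohorts : sequence
        Cohort label per sample, aligned with ``logp``'s rows.
    """
    cohorts = np.asarray(cohorts)
    if len(cohorts) != logp.shape[0]:
        raise ValueError("cohort labels must align with the sample rows")
    arr = np.asarray(logp, dtype=float)
    out = np.empty_like(arr)
    n_const = 0
    for c in pd.unique(cohorts):
        mask = cohorts == c
        if mask.sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 samples")
        out[mask], k = _zscore_columns(arr[mask])
        n_const += k
    if n_const:
        warnings.warn(
            f"{n_const} (cohort, column) cell(s) constant and set to 0 "
            "during CA normalization"
        )
    return pd.DataFrame(out, index=logp.index, columns=logp.columns)


def build_mrm(x: pd.DataFrame, provenance: dict | None = None) -> RelationshipMatrix:
    """Metagenome relationship matrix: row-wise Pearson correlation.

    ``M[a, b]`` is the correlation of sample a's and sample b's normalized
    profiles across features (the correlation of the columns of X^T).
    The diagonal is set to exactly 1.
    """
    arr = np.asarray(x, dtype=float)
    row_sd = arr.std(axis=1)
    if (row_sd == 0).any():
        bad = [str(x.index[i]) for i in np.where(row_sd == 0)[0]]
        raise ValueError(
            f"sample row(s) constant across features, correlation undefined: {bad}"
        )
    m = np.corrcoef(arr)
    np.fill_diagonal(m, 1.0)
    return RelationshipMatrix(
        values=m, ids=list(x.index), kind="MRM", provenance=provenance or {}
    )


def build_grm(
    dosages: pd.DataFrame,
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix by VanRaden's method 1.

    With dosage matrix W (animals x SNPs, entries 0/1/2) and allele
    frequencies p_j, Z = W - 2p and G = Z Z' / (2 * sum_j p_j (1 - p_j)).

    Parameters
    ----------
    dosages : DataFrame
        Animals x SNPs, entries in {0, 1, 2}.
    freqs : array, optional
        Allele frequencies per SNP.  If omitted, observed frequencies
        (column mean / 2) are used and monomorphic SNPs are dropped with
        a warning, since they contribute nothing and would only inflate
        nothing in the denominator.
    """
    w = np.asarray(dosages, dtype=float)
    if not np.isin(w, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    if freqs is None:
        p = w.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if not poly.any():
            raise ValueError("all SNPs are monomorphic; GRM undefined")
        if (~poly).any():
            warnings.warn(f"dropped {int((~poly).sum())} monomorphic SNP(s)")
        w = w[:, poly]
        p = p[poly]
        freq_source = "observed"
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape[0] != w.shape[1]:
            raise ValueError("freqs length must equal the number of SNPs")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("supplied frequencies must be strictly inside (0, 1)")
        freq_source = "supplied"
    z = w - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = (z @ z.T) / denom
    return RelationshipMatrix(
        values=g,
        ids=list(dosages.index),
        kind="GRM",
        provenance={"method": "vanraden1", "freq_source": freq_source,
                    "n_snps": w.shape[1]},
    )


def align_matrices(rel: RelationshipMatrix, ids) -> RelationshipMatrix:
    """Symmetric subset/permutation of a relationship matrix to ``ids``."""
    ids = list(ids)
    pos = {x: i for i, x in enumerate(rel.ids)}
    missing = [x for x in ids if x not in pos]
    if missing:
        raise KeyError(f"ids not present in matrix: {missing}")
    idx = np.array([pos[x] for x in ids])
    return RelationshipMatrix(
        values=rel.values[np.ix_(idx, idx)],
        ids=ids,
        kind=rel.kind,
        provenance=dict(rel.provenance),
    )
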