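"""Alpha and beta diversity of abundance profiles.

Alpha diversity per sample: Shannon entropy (natural log by default),
Simpson concentration (dominance form, lambda = sum p_i^2 — reported as
such because a community that loses diversity shows a *higher* Simpson
value in this form), richness, Berger-Parker dominance (largest relative
abundance) and Gini inequality from the Lorenz curve. Beta diversity is
Bray-Curtis dissimilarity. Rarefaction curves average indices over repeated
without-replacement subsamples at increasing depths; PCA scores are emitted
as plot-ready tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .exceptions import InputError

logger = logging.getLogger(__name__)


def _proportions(row: np.ndarray) -> np.ndarray:
    total = row.sum()
    if total <= 0:
        raise InputError("all-zero sample has no diversity")
    return row / total


def shannon(p: Sequence[float], base: float = math.e) -> float:
    """Shannon entropy -sum p ln p over positive entries."""
    p = _proportions(np.asarray(p, dtype=float))
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


def simpson_dominance(p: Sequence[float]) -> float:
    """Simpson concentration lambda = sum p_i^2 (higher = more dominated)."""
    p = _proportions(np.asarray(p, dtype=float))
    return float((p**2).sum())


def berger_parker(p: Sequence[float]) -> float:
    """Relative abundance of the single most abundant feature."""
    p = _proportions(np.asarray(p, dtype=float))
    return float(p.max())


def richness(p: Sequence[float]) -> int:
    """Number of features with positive abundance."""
    return int((np.asarray(p, dtype=float) > 0).sum())


def lorenz_gini(p: Sequence[float]) -> tuple[np.ndarray, float]:
    """Lorenz curve points and the Gini coefficient of an abundance vector.

    The curve is cumulative abundance share versus cumulative feature share
    with features in ascending abundance order, from (0, 0) to (1, 1);
    Gini = 1 - 2 * area under the curve (trapezoidal).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise InputError("abundances must be nonnegative")
    p = _proportions(p)
    sorted_p = np.sort(p)
    x = np.arange(0, len(p) + 1) / len(p)
    y = np.concatenate([[0.0], np.cumsum(sorted_p)])
    area = np.trapezoid(y, x)
    return np.column_stack([x, y]), float(1.0 - 2.0 * area)


def alpha_diversity(matrix: pd.DataFrame, base: float = math.e) -> pd.DataFrame:
    """Per-sample diversity table from a samples x features matrix.

    All-zero samples are excluded with a logged warning; the returned table
    records them in ``.attrs['excluded_samples']``.
    """
    rows = {}
    excluded = []
    for sample, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.sum() <= 0:
            excluded.append(sample)
            continue
        _, gini = lorenz_gini(vals)
        rows[sample] = {
            "shannon": shannon(vals, base),
            "simpson_dominance": simpson_dominance(vals),
            "simpson_diversity": 1.0 - simpson_dominance(vals),
            "richness": richness(vals),
            "berger_parker": berger_parker(vals),
            "gini": gini,
        }
    if excluded:
        logger.warning("excluded %d all-zero samples from diversity", len(excluded))
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    out.attrs["excluded_samples"] = excluded
    return out


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity; NaN where both rows are zero."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise InputError("abundances must be nonnegative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dm = squareform(pdist(vals, metric="braycurtis"))
    zero = vals.sum(axis=1) == 0
    if zero.any():
        logger.warning("Bray-Curtis undefined for all-zero sample pairs; flagged as NaN")
        dm[np.ix_(zero, zero)] = np.nan
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)


def rarefaction_curve(
    counts: pd.DataFrame,
    depths: Sequence[int],
    reps: int = 20,
    seed: int = 0,
    base: float = math.e,
) -> pd.DataFrame:
    """Mean Shannon and richness per sample at each subsampling depth.

    ``counts`` is samples x features of integers; depths above a sample's
    total are skipped for that sample.
    """
    rng = np.random.default_rng(seed)
    records = []
    for sample, row in counts.iterrows():
        col = row.to_numpy(dtype=int)
        total = int(col.sum())
        for depth in depths:
            if depth > total or depth <= 0:
                continue
            sh, ri = [], []
            for _ in range(reps):
                sub = rng.multivariate_hypergeometric(col, depth)
                sh.append(shannon(sub, base))
                ri.append(richness(sub))
            records.append(
                {
                    "sample_id": sample,
                    "depth": int(depth),
                    "mean_shannon": float(np.mean(sh)),
                    "mean_richness": float(np.mean(ri)),
                }
            )
    return pd.DataFrame(records, columns=["sample_id", "depth", "mean_shannon", "mean_richness"])


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA sample scores and explained-variance fractions."""
    if len(matrix) < 2:
        raise InputError("PCA needs at least two samples")
    max_comp = min(len(matrix) - 1, matrix.shape[1])
    if n_components > max_comp:
        logger.warning("n_components truncated from %d to matrix rank bound %d", n_components, max_comp)
        n_components = max_comp
    vals = matrix.to_numpy(dtype=float)
    if np.allclose(vals.std(axis=0), 0):
        logger.warning("constant matrix: zero variance, PCA scores are all zero")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(vals)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), pca.explained_variance_ratio_
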