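"""Phylogenetic signal in environmental niches via Mantel correlograms.

Reading assembly processes from phylogenetic metrics presupposes niche
conservatism: close relatives should have more similar niches than
expected by chance. The Mantel correlogram bins taxon pairs into
phylogenetic distance classes and, within each class, correlates class
membership with niche distance under a taxon-permutation null.

Sign convention: the raw Mantel statistic between a class indicator and
niche *distances* is negative when taxa in the class are ecologically
similar; the reported ``r`` is the raw value flipped so that positive
means "more similar than chance" (phylogenetic signal at short
distances). Both are emitted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .io import CommunityTable

logger = logging.getLogger(__name__)

__all__ = ["niche_values", "niche_distance_matrix", "mantel_correlogram"]


def niche_values(
    table: CommunityTable, metadata: pd.DataFrame, variable: str
) -> pd.Series:
    """Abundance-weighted mean environment per taxon (its realized niche).

    ``niche(i) = sum_s a_is env_s / sum_s a_is`` over the samples present
    in the metadata. Taxa with zero total abundance are excluded and
    logged.
    """
    if variable not in metadata.columns:
        raise ValueError(f"metadata has no variable {variable!r}")
    env = metadata.set_index(metadata["sample_id"].astype(str))[variable]
    missing = [s for s in table.sample_ids if s not in env.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:10]}")
    e = env.loc[table.sample_ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError(f"variable {variable!r} has non-finite values")
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.info("excluding %d zero-abundance taxa from niche values",
                    int((~keep).sum()))
    vals = (counts[keep] @ e) / totals[keep]
    return pd.Series(
        vals, index=[t for t, k in zip(table.taxon_ids, keep) if k], name=variable
    )


def niche_distance_matrix(niche: pd.Series) -> pd.DataFrame:
    """|niche_i - niche_j| over taxa, aligned lexicographically."""
    niche = niche.sort_index()
    v = niche.to_numpy(dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=niche.index, columns=niche.index)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def mantel_correlogram(
    phylo_dist: pd.DataFrame,
    niche_dist: pd.DataFrame,
    n_classes: int | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Distance classes are equal-width bins over the range of off-diagonal
    phylogenetic distances; the class count defaults to Sturges' rule on
    the number of pairs. Per class, the Mantel statistic is the Pearson
    correlation between the class-membership indicator and the niche
    distances over all off-diagonal pairs; the permutation test jointly
    permutes the taxon order of the niche matrix (two-tailed, add-one
    p-values). p-values get a progressive Holm correction: class k is
    corrected within classes 1..k, the standard correlogram convention.

    Returns one row per class: bounds, midpoint, n_pairs, r (flipped so
    positive = more similar than chance), r_raw, p_raw, p_corrected,
    significant (p_corrected < 0.05).
    """
    if list(phylo_dist.index) != list(niche_dist.index):
        common = sorted(set(phylo_dist.index) & set(niche_dist.index))
        if len(common) < 3:
            raise ValueError("fewer than 3 shared taxa")
        phylo_dist = phylo_dist.loc[common, common]
        niche_dist = niche_dist.loc[common, common]
    P = phylo_dist.to_numpy(dtype=float)
    Y = niche_dist.to_numpy(dtype=float)
    for name, M in (("phylo", P), ("niche", Y)):
        if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0.0):
            raise ValueError(f"{name} distance matrix must be symmetric, hollow")
    n = P.shape[0]
    pv = squareform(P, checks=False)
    yv = squareform(Y, checks=False)
    m = pv.size
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(m) + 1))  # Sturges
    edges = np.linspace(pv.min(), pv.max(), n_classes + 1)
    # assign every pair to exactly one class (right-closed last bin)
    which = np.clip(np.digitize(pv, edges[1:-1], right=False), 0, n_classes - 1)

    yc = yv - yv.mean()
    ynorm = np.sqrt((yc**2).sum())
    indicators, anorms = [], []
    for k in range(n_classes):
        a = (which == k).astype(float)
        ac = a - a.mean()
        indicators.append(ac)
        anorms.append(np.sqrt((ac**2).sum()))
    A = np.vstack(indicators)  # n_classes x m, centered
    anorms = np.asarray(anorms)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_obs = (A @ yc) / (anorms * ynorm)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_classes)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = squareform(Y[np.ix_(perm, perm)], checks=False)
        ypc = yp - yv.mean()  # permutation preserves the multiset of values
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = (A @ ypc) / (anorms * ynorm)
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-15
    p_raw = (exceed + 1.0) / (n_permutations + 1.0)

    n_pairs = np.array([(which == k).sum() for k in range(n_classes)])
    defined = (n_pairs >= 2) & (anorms > 0) & (ynorm > 0)
    if ynorm == 0:
        logger.warning("niche distances are all equal; correlogram undefined")
    p_raw = np.where(defined, p_raw, np.nan)
    p_corr = np.full(n_classes, np.nan)
    tested = [k for k in range(n_classes) if defined[k]]
    for pos, k in enumerate(tested):
        p_corr[k] = _holm(p_raw[tested[: pos + 1]])[-1]

    mid = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame(
        {
            "class_lower": edges[:-1],
            "class_upper": edges[1:],
            "midpoint": mid,
            "n_pairs": n_pairs,
            "r": np.where(defined, -r_obs, np.nan),
            "r_raw": np.where(defined, r_obs, np.nan),
            "p_raw": p_raw,
            "p_corrected": p_corr,
        }
    )
    out["significant"] = out["p_corrected"] < 0.05
    out.attrs["n_permutations"] = n_permutations
    out.attrs["seed"] = seed
    return out
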