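"""Pairwise turnover under null models: betaMPD/betaNRI and RC_bray.

Phylogenetic turnover between two samples is the between-community mean
pairwise distance (betaMPD): the mean cophenetic distance over all ordered
cross pairs of occupied taxa, shared taxa contributing zero distances. The
betaNRI z-score compares the observed betaMPD with a null built by
shuffling the tip labels of the full tree:

    betaNRI = (betaMPD_obs - mean(betaMPD_null)) / sd(betaMPD_null)

(not sign-flipped, unlike NRI). betaNRI < -2 reads as homogeneous
selection, > +2 as heterogeneous selection.

Taxonomic turnover uses the Raup-Crick null extended to Bray-Curtis:
null communities preserve each sample's observed richness (membership
drawn with probability proportional to occupancy across samples) and
observed read total (reads allocated proportionally to dataset-wide
relative abundance, each drawn taxon getting at least one read). The
observed Bray-Curtis is located within the null distribution and rescaled
to RC_bray in [-1, 1]; > 0.95 reads as dispersal limitation, < -0.95 as
homogenizing dispersal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .alpha import NullModelConfig
from .io import CommunityTable, Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "cophenetic_matrix",
    "beta_mpd",
    "beta_nri",
    "bray_curtis",
    "raup_crick_bray",
    "pairwise_turnover",
]


def cophenetic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Tip-to-tip patristic distances (lexicographic tip order)."""
    return tree.cophenetic_matrix()


def beta_mpd(
    occupied_a: np.ndarray, occupied_b: np.ndarray, distances: np.ndarray
) -> float:
    """Unweighted betaMPD between two communities.

    Mean of d(i, j) over all ordered cross pairs i in a, j in b, shared
    taxa included with their zero self-distances. NaN if either community
    is empty.
    """
    a = np.asarray(occupied_a)
    b = np.asarray(occupied_b)
    if a.size == 0 or b.size == 0:
        return float("nan")
    return float(distances[np.ix_(a, b)].mean())


def _pair_index(sample_ids: list[str]) -> list[tuple[int, int]]:
    n = len(sample_ids)
    return [(a, b) for a in range(n) for b in range(a + 1, n)]


def beta_nri(
    table: CommunityTable, tree: Phylogeny, cfg: NullModelConfig = NullModelConfig()
) -> pd.DataFrame:
    """betaNRI for every unordered sample pair.

    One shared sequence of tip-label permutations is used for all pairs,
    which makes betaNRI exactly symmetric in (a, b) and lets each null
    replicate be computed as a single quadratic form over the incidence
    matrix. The z-score uses the sample (n-1) standard deviation; pairs
    with a degenerate null (sd = 0) or an empty sample are flagged.
    """
    dmat = tree.cophenetic_matrix()
    tips = list(dmat.index)
    tip_pos = {t: i for i, t in enumerate(tips)}
    missing = set(table.taxon_ids) - set(tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:10]}")
    if table.n_samples < 2:
        raise ValueError("betaNRI needs at least 2 samples")
    D = dmat.to_numpy()
    n_tips = len(tips)

    X = np.zeros((n_tips, table.n_samples))
    A = np.zeros((n_tips, table.n_samples))
    for i, taxon in enumerate(table.taxon_ids):
        A[tip_pos[taxon]] = table.counts[i]
    X[A > 0] = 1.0
    sizes = X.sum(axis=0)

    def all_beta_mpd(Xm: np.ndarray, Am: np.ndarray) -> np.ndarray:
        if cfg.weighted:
            P = Am / np.where(Am.sum(axis=0) > 0, Am.sum(axis=0), 1.0)
            return P.T @ D @ P
        M = Xm.T @ D @ Xm
        with np.errstate(invalid="ignore", divide="ignore"):
            return M / np.outer(sizes, sizes)

    obs = all_beta_mpd(X, A)
    rng = np.random.default_rng(cfg.seed)
    pairs = _pair_index(table.sample_ids)
    nulls = np.empty((cfg.n_reps, len(pairs)))
    rows_a = [a for a, _ in pairs]
    rows_b = [b for _, b in pairs]
    for r in range(cfg.n_reps):
        perm = rng.permutation(n_tips)
        null_mat = all_beta_mpd(X[perm], A[perm])
        nulls[r] = null_mat[rows_a, rows_b]

    obs_v = obs[rows_a, rows_b]
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1) if cfg.n_reps > 1 else np.zeros(len(pairs))
    nonempty = (sizes[rows_a] > 0) & (sizes[rows_b] > 0)
    defined = nonempty & (null_sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs_v - null_mean) / null_sd
    out = pd.DataFrame(
        {
            "sample_a": [table.sample_ids[a] for a in rows_a],
            "sample_b": [table.sample_ids[b] for b in rows_b],
            "beta_mpd_obs": np.where(nonempty, obs_v, np.nan),
            "null_mean": np.where(nonempty, null_mean, np.nan),
            "null_sd": np.where(nonempty, null_sd, np.nan),
            "beta_nri": np.where(defined, z, np.nan),
            "beta_nri_defined": defined,
            "n_reps": cfg.n_reps,
        }
    )
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning("betaNRI undefined for %d pairs", n_undef)
    return out


def bray_curtis(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); NaN if both empty."""
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share taxon indexing")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        return float("nan")
    return float(np.abs(x - y).sum() / denom)


def _rc_null_sample(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_prob: np.ndarray,
    abund_prob: np.ndarray,
    n_taxa: int,
) -> np.ndarray:
    """One Raup-Crick null community preserving richness and read total."""
    members = rng.choice(n_taxa, size=richness, replace=False, p=occ_prob)
    counts = np.zeros(n_taxa, dtype=np.int64)
    counts[members] = 1  # each drawn taxon gets at least one read
    remaining = total - richness
    if remaining > 0:
        p = abund_prob[members]
        counts[members] += rng.multinomial(remaining, p / p.sum())
    return counts


def raup_crick_bray(
    table: CommunityTable, cfg: NullModelConfig = NullModelConfig()
) -> pd.DataFrame:
    """RC_bray for every unordered sample pair.

    For each replicate a full set of null communities (one per sample) is
    built and all pairwise null Bray-Curtis values are computed, so the
    statistic is exactly symmetric. Ties between null and observed values
    get half weight:

        RC_raw = (#{null < obs} + 0.5 #{null = obs}) / n_reps
        RC_bray = 2 (RC_raw - 0.5)
    """
    if table.n_samples < 2:
        raise ValueError("RC_bray needs at least 2 samples")
    if not table.rarefied:
        logger.warning("RC_bray on a non-rarefied table; consider rarefying first")
    counts = table.counts
    occ = (counts > 0).sum(axis=1).astype(float)
    totals_taxa = counts.sum(axis=1).astype(float)
    if occ.sum() == 0:
        raise ValueError("empty table")
    occ_prob = occ / occ.sum()
    abund_prob = totals_taxa / totals_taxa.sum()
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    zero_rich = richness == 0
    if zero_rich.any():
        logger.warning("%d samples have zero richness; RC flagged undefined",
                       int(zero_rich.sum()))

    obs_bc = squareform(pdist(counts.T, metric="braycurtis"))
    pairs = _pair_index(table.sample_ids)
    rows_a = [a for a, _ in pairs]
    rows_b = [b for _, b in pairs]
    obs_v = obs_bc[rows_a, rows_b]

    rng = np.random.default_rng(cfg.seed)
    n_lt = np.zeros(len(pairs))
    n_eq = np.zeros(len(pairs))
    tol = 1e-12
    n_taxa = table.n_taxa
    # null draws consumed in lexicographic sample order so results do not
    # depend on input column order (exact pair-swap invariance)
    sample_order = np.argsort(table.sample_ids)
    for _ in range(cfg.n_reps):
        null = np.zeros((n_taxa, table.n_samples), dtype=np.int64)
        for j in sample_order:
            if zero_rich[j]:
                continue
            null[:, j] = _rc_null_sample(
                rng, int(richness[j]), int(totals[j]), occ_prob, abund_prob, n_taxa
            )
            # marginal preservation is the defining constraint of the null
            assert (null[:, j] > 0).sum() == richness[j]
            assert null[:, j].sum() == totals[j]
        null_bc = squareform(pdist(null.T, metric="braycurtis"))
        nv = null_bc[rows_a, rows_b]
        n_lt += nv < obs_v - tol
        n_eq += np.abs(nv - obs_v) <= tol

    rc_raw = (n_lt + 0.5 * n_eq) / cfg.n_reps
    rc = 2.0 * (rc_raw - 0.5)
    defined = ~(zero_rich[rows_a] | zero_rich[rows_b])
    out = pd.DataFrame(
        {
            "sample_a": [table.sample_ids[a] for a in rows_a],
            "sample_b": [table.sample_ids[b] for b in rows_b],
            "bray_curtis_obs": np.where(defined, obs_v, np.nan),
            "rc_bray": np.where(defined, rc, np.nan),
            "rc_defined": defined,
            "n_reps": cfg.n_reps,
        }
    )
    return out


def pairwise_turnover(
    table: CommunityTable, tree: Phylogeny, cfg: NullModelConfig = NullModelConfig()
) -> pd.DataFrame:
    """Combined per-pair record: betaMPD, betaNRI, Bray-Curtis, RC_bray.

    betaNRI and RC_bray use independent permutation streams derived from
    ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    seed_b, seed_r = (int(s.generate_state(1)[0] % 2**31) for s in ss)
    bn = beta_nri(table, tree, NullModelConfig(cfg.n_reps, seed_b, cfg.weighted))
    rc = raup_crick_bray(table, NullModelConfig(cfg.n_reps, seed_r, cfg.weighted))
    return bn.merge(rc.drop(columns="n_reps"), on=["sample_a", "sample_b"])
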