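"""Synthetic ASV communities with known assembly processes.

Each of the five assembly processes of the classification framework
(homogeneous selection, heterogeneous selection, dispersal limitation,
homogenizing dispersal, drift) is realized as an explicit generative
mechanism over a simulated phylogeny whose tips carry Brownian-evolved
niche optima. The generator is the ground-truth source for validating the
null-model pipeline: a dataset built under a process should be classified
as that process by the betaNRI / RC_bray decision rules.

Mechanics per scenario (S samples, depth N reads each, metacommunity
log-normal relative abundances m_i):

* selection (homogeneous / heterogeneous): tips carry multi-dimensional
  niche optima evolved under an early-burst Brownian model (divergence
  concentrated on deep branches -> niches are clade-conserved, the
  premise of the whole framework). Community membership is a weighted
  draw without replacement of k_s taxa with weight
  ``exp(-||niche_i - env_s||^2 / (2 sigma_w^2 d)) * m_i`` (Gaussian niche
  filter of per-axis width sigma_w around the sample's d-dimensional
  environment), then N reads multinomially with the same weights.
  Homogeneous: every sample shares one environment, anchored at the
  realized niche of a randomly chosen taxon; heterogeneous: the two most
  phylogenetically divergent taxa (across the basal split, hence also
  niche-divergent under early burst) anchor two alternating environments.
* drift: each sample is a multinomial draw from the shared metacommunity
  whose log relative abundances receive an independent chance
  fluctuation of scale ``drift_sigma`` (population sizes fluctuate due to
  chance events; no trait dependence).
* dispersal limitation: as drift but with a strong per-sample divergence
  of the metacommunity, scale ``2 (1 - migration)`` with migration ~ 0.
* homogenizing dispersal (migration ~ 1): all samples are near-identical
  aliquots of one realized source community - a deterministic
  largest-remainder allocation of ``(1 - noise_fraction) N`` reads plus
  small multinomial noise on the remaining fraction.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Literal

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import CommunityTable, Phylogeny

logger = logging.getLogger(__name__)

Scenario = Literal[
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
]

SCENARIOS: tuple[str, ...] = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_tree",
    "evolve_niche_trait",
    "evolve_niche_traits",
    "simulate_environment",
    "assemble_communities",
    "selection_weights",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Recipe for one synthetic dataset.

    Defaults reflect a rarefied coastal-plankton metabarcoding survey at
    desk scale: 150 taxa, 20 samples, 1000 reads per sample, a Yule tree,
    unit-rate Brownian niche evolution and a narrow (0.05 on the [0,1]
    environment axis) Gaussian niche filter for selection scenarios.
    """

    scenario: Scenario
    n_taxa: int = 150
    n_samples: int = 20
    depth: int = 1000
    birth_rate: float = 1.0
    death_rate: float = 0.0
    brownian_sigma2: float = 1.0
    filter_width: float = 0.05
    migration: float | None = None
    niche_dims: int = 3
    burst_rate: float = 5.0
    drift_sigma: float = 0.25
    noise_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.brownian_sigma2 <= 0:
            raise ValueError("brownian_sigma2 must be > 0")
        if self.scenario.endswith("selection") and not self.filter_width > 0:
            raise ValueError("filter_width must be > 0 in selection scenarios")
        if self.migration is None:
            mig = {"dispersal_limitation": 0.0, "homogenizing_dispersal": 1.0}.get(
                self.scenario, 0.5
            )
            object.__setattr__(self, "migration", mig)
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration must be in [0, 1]")
        if self.niche_dims < 1:
            raise ValueError("niche_dims must be >= 1")
        if not 0.0 < self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in (0, 1]")
        if self.drift_sigma < 0:
            raise ValueError("drift_sigma must be >= 0")


@dataclass
class SyntheticDataset:
    """A complete synthetic study with per-pair ground-truth labels."""

    table: CommunityTable
    tree: Phylogeny
    metadata: pd.DataFrame
    traits: pd.Series  # taxon -> niche optimum on the [0,1] environment axis
    truth: pd.DataFrame  # sample_a, sample_b, expected_process
    config: ScenarioConfig = field(repr=False, default=None)
    niche_optima: pd.DataFrame | None = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, death_rate: float = 0.0, seed: int = 0
) -> Phylogeny:
    """Birth-death tree conditioned on ``n_taxa`` extant tips.

    Terminal branches are extended by the exponential waiting time to the
    next birth/death event so that all branch lengths are strictly
    positive (the raw simulator stops exactly at the n-th speciation,
    leaving the two newest tips with zero-length branches). Tips are
    relabeled ``t0001`` ... in newick traversal order; deterministic under
    ``seed``.
    """
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0 to reach n_taxa tips")
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # drop the stem edge below the first split: it is not part of the
    # phylogeny among extant taxa and would inflate Faith PD
    tree.seed_node.edge.length = None
    extra = rng.expovariate(n_taxa * (birth_rate + death_rate))
    width = max(4, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"t{i:0{width}d}"
    return Phylogeny(tree)


def evolve_niche_trait(
    tree: Phylogeny,
    brownian_sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Brownian trait evolution along the tree.

    The increment along each branch is an independent Gaussian with mean 0
    and variance ``brownian_sigma2 * branch_length``; returns one value
    per tip, indexed by tip label (lexicographic order).
    """
    if brownian_sigma2 < 0:
        raise ValueError("brownian_sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {tree.tree.seed_node: float(root_value)}
    tips: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is not tree.tree.seed_node:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(brownian_sigma2 * bl)
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[node]
    return pd.Series(tips, name="trait").sort_index()


def evolve_niche_traits(
    tree: Phylogeny,
    n_dims: int = 3,
    burst_rate: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-axis niche optima under an early-burst Brownian model.

    Each axis evolves independently; the Brownian rate decays as
    ``exp(-burst_rate * t/H)`` with relative depth ``t/H`` from the root,
    so most divergence happens on deep branches and clades end up
    occupying distinct, internally conserved niche regions (adaptive
    radiation). ``burst_rate = 0`` recovers plain Brownian motion. Each
    axis is min-max scaled to [0, 1]. Returns taxa x axes (lexicographic
    tip order, columns ``niche_0`` ...).
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    rng = np.random.default_rng(seed)
    root = tree.tree.seed_node
    depth: dict[dendropy.Node, float] = {root: 0.0}
    height = 0.0
    for node in tree.tree.preorder_node_iter():
        if node is not root:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
            height = max(height, depth[node])
    height = height or 1.0

    def branch_var(t0: float, t1: float) -> float:
        # integral of exp(-burst_rate * t/H) over the branch
        if burst_rate == 0:
            return t1 - t0
        r = burst_rate / height
        return (np.exp(-r * t0) - np.exp(-r * t1)) / r

    values: dict[dendropy.Node, np.ndarray] = {root: np.zeros(n_dims)}
    tips: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node is not root:
            v = branch_var(depth[node.parent_node], depth[node])
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(v), n_dims
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[node]
    T = pd.DataFrame.from_dict(tips, orient="index").sort_index()
    T.columns = [f"niche_{d}" for d in range(n_dims)]
    span = T.max() - T.min()
    span = span.replace(0.0, 1.0)
    return (T - T.min()) / span


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------


def simulate_environment(
    n_samples: int, scenario: Scenario, seed: int = 0
) -> pd.DataFrame:
    """Per-sample dates, station and environmental variables.

    Samples are spread evenly over one synthetic year at a single station.
    The "active" axis ``env`` lives on [0,1]: constant (0.5) for
    homogeneous scenarios, two divergent levels (0.25 / 0.75, alternating
    so both levels span the year) for heterogeneous selection, and a
    seasonal sinusoid otherwise. Decoy variables (``temperature`` with an
    annual cycle, ``salinity`` as pure noise) let signal tests be checked
    for non-detection as well as detection.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    day = np.floor(np.linspace(5, 360, n_samples)).astype(int)
    dates = pd.to_datetime("2021-01-01") + pd.to_timedelta(day - 1, unit="D")
    if scenario == "homogeneous_selection":
        env = np.full(n_samples, 0.5)
    elif scenario == "heterogeneous_selection":
        env = np.where(np.arange(n_samples) % 2 == 0, 0.25, 0.75)
    else:
        env = 0.5 + 0.4 * np.sin(2 * np.pi * day / 365.0) + rng.normal(0, 0.02, n_samples)
        env = np.clip(env, 0.0, 1.0)
    md = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1:03d}" for i in range(n_samples)],
            "date": dates,
            "station": "ST1",
            "env": env,
            "temperature": 12.0
            + 5.0 * np.sin(2 * np.pi * (day - 60) / 365.0)
            + rng.normal(0, 0.5, n_samples),
            "salinity": 34.0 + rng.normal(0, 0.3, n_samples),
        }
    )
    md["month"] = md["date"].dt.month
    return md.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------


def selection_weights(
    traits: np.ndarray,
    env: float | np.ndarray,
    filter_width: float,
    metacommunity: np.ndarray,
) -> np.ndarray:
    """Unnormalized sampling weights of the Gaussian niche filter.

    ``w_i = exp(-||trait_i - env||^2 / (2 filter_width^2 d)) * m_i`` where
    d is the number of niche axes (so ``filter_width`` is the per-axis
    width). As ``filter_width -> inf`` the kernel flattens and weights
    reduce to the metacommunity abundances (drift mechanics).
    """
    if filter_width <= 0:
        raise ValueError("filter_width must be > 0")
    T = np.atleast_2d(np.asarray(traits, dtype=float).T).T  # taxa x dims
    e = np.atleast_1d(np.asarray(env, dtype=float))
    d2 = ((T - e[None, :]) ** 2).sum(axis=1)
    kernel = np.exp(-d2 / (2.0 * filter_width**2 * T.shape[1]))
    return kernel * metacommunity


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Deterministic integer allocation of ``total`` proportional to target."""
    base = np.floor(target).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(target - base))
        base[order[:short]] += 1
    return base


def assemble_communities(config: ScenarioConfig) -> SyntheticDataset:
    """Build one synthetic dataset under ``config.scenario``.

    Returns the count table (every column summing exactly to
    ``config.depth``), the tree, metadata, the tip niche optima (Brownian
    values min-max scaled onto the [0,1] environment axis) and per-pair
    ground-truth labels. Fully deterministic under ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    seeds = {k: int(master.integers(2**31)) for k in ("tree", "trait", "env", "asm")}
    tree = simulate_tree(
        config.n_taxa, config.birth_rate, config.death_rate, seeds["tree"]
    )
    optima = evolve_niche_traits(
        tree, config.niche_dims, config.burst_rate, seeds["trait"]
    )
    metadata = simulate_environment(config.n_samples, config.scenario, seeds["env"])
    rng = np.random.default_rng(seeds["asm"])

    taxa = list(optima.index)
    n = len(taxa)
    T = optima.to_numpy()
    meta_abund = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    counts = np.zeros((n, config.n_samples), dtype=np.int64)

    if config.scenario.endswith("selection"):
        # environments anchored at realized taxon niches so the favored
        # niche always corresponds to an actual (clade-conserved) region
        if config.scenario == "homogeneous_selection":
            anchor = T[rng.integers(n)]
            env_targets = [anchor] * config.n_samples
        else:
            # anchors at the most phylogenetically divergent tip pair
            # (across the basal split); under early-burst evolution these
            # also carry the most divergent niches
            D = tree.cophenetic_matrix().to_numpy()
            i, j = np.unravel_index(int(np.argmax(D)), D.shape)
            env_targets = [
                T[i] if s % 2 == 0 else T[j] for s in range(config.n_samples)
            ]
        # expose the axis separating the targets best as the scalar env
        axis = int(np.argmax(np.ptp(np.asarray(env_targets), axis=0))) \
            if config.scenario == "heterogeneous_selection" else 0
        metadata["env"] = [float(e[axis]) for e in env_targets]
        lo, hi = int(np.floor(0.2 * n)), int(np.ceil(0.5 * n))
        for j in range(config.n_samples):
            w = selection_weights(
                T, env_targets[j], config.filter_width, meta_abund
            )
            k = int(rng.integers(lo, hi + 1))
            members = rng.choice(n, size=k, replace=False, p=w / w.sum())
            wm = w[members]
            counts[members, j] = rng.multinomial(config.depth, wm / wm.sum())
    elif config.scenario in ("drift", "dispersal_limitation"):
        # both draw from per-sample fluctuated metacommunities; drift's
        # fluctuation is mild chance variation, dispersal limitation's is
        # a strong divergence (migration ~ 0)
        scale = (
            config.drift_sigma
            if config.scenario == "drift"
            else 2.0 * (1.0 - config.migration)
        )
        for j in range(config.n_samples):
            local = meta_abund * np.exp(rng.normal(0.0, 1.0, size=n) * scale)
            counts[:, j] = rng.multinomial(config.depth, local / local.sum())
    elif config.scenario == "homogenizing_dispersal":
        # migration ~ 1: every sample is a near-deterministic aliquot of
        # one realized source community
        source = rng.multinomial(config.depth * 10, meta_abund / meta_abund.sum())
        q = source / source.sum()
        n_det = int(round(config.depth * (1.0 - config.noise_fraction)))
        det = _largest_remainder(n_det * q, n_det)
        for j in range(config.n_samples):
            counts[:, j] = det + rng.multinomial(config.depth - n_det, q)

    table = CommunityTable(
        taxa, list(metadata["sample_id"]), counts, rarefied=True
    ).drop_empty_taxa()

    truth = _truth_labels(config, metadata)
    return SyntheticDataset(
        table=table, tree=tree, metadata=metadata,
        traits=optima.iloc[:, 0].rename("trait"), truth=truth, config=config,
        niche_optima=optima,
    )


def _truth_labels(config: ScenarioConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Expected dominant process for every unordered sample pair.

    Under heterogeneous selection only cross-environment pairs are pushed
    apart; same-environment pairs share one filter and are expected to
    look like homogeneous selection.
    """
    ids = list(metadata["sample_id"])
    env = metadata["env"].to_numpy()
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            label = config.scenario
            if config.scenario == "heterogeneous_selection" and env[a] == env[b]:
                label = "homogeneous_selection"
            rows.append((ids[a], ids[b], label))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "expected_process"])


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Emit the dataset as the same TSV/newick/CSV files the readers accept."""
    from pathlib import Path

    from .io import write_community_table, write_metadata, write_tree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "table.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.tsv",
        "traits": outdir / "traits.tsv",
    }
    write_community_table(ds.table, paths["table"])
    write_tree(ds.tree, paths["tree"])
    write_metadata(ds.metadata, paths["metadata"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    ds.traits.rename_axis("taxon_id").to_csv(paths["traits"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
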