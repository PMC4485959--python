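"""Synthetic chronograms, traits, communities and productivity responses.

Generates data with the statistical structure the analysis assumes, so
the whole pipeline is testable without any external download:

* a Yule (pure-birth) chronogram — ultrametric by construction — of 61
  tips by default, the size of the boreal/temperate tree and large-shrub
  species pool the package emulates;
* continuous traits evolved by Brownian motion with a per-trait Pagel's
  lambda applied to the tree covariance (lambda defaults mirror
  estimates typical of such pools: near zero for maximum height, high
  for wood density and shade tolerance, intermediate for seed mass and
  leaf N);
* forest plots of 1–10 species (truncated-Poisson richness, so
  monocultures occur) with log-normal basal areas;
* plot covariates (total basal area, organic-horizon depth, mean annual
  temperature) and a productivity response built as a linear function of
  FDis, PSV, CWM and the covariates plus Gaussian noise.

Everything is driven by one master seed: per-stage generators are spawned
from it, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rand import as_rng as _as_rng
from .diversity import DEFAULT_CWM_TRAITS, DEFAULT_FDIS_TRAITS, diversity_profile
from .treeio import Phylogeny, lambda_transform, phylo_vcv, write_newick

__all__ = [
    "TraitSpec",
    "SimConfig",
    "simulate_yule_tree",
    "simulate_two_clade_tree",
    "simulate_bm_trait",
    "simulate_communities",
    "simulate_productivity",
    "simulate_dataset",
    "make_fixture_bundle",
    "Bundle",
]


@dataclass
class TraitSpec:
    """Brownian-motion generator settings for one trait.

    ``sigma2`` is the BM rate (trait units² per unit branch length),
    ``lambda_true`` the phylogenetic-signal multiplier in [0, 1], and
    ``root_state`` the trait value at the root.
    """

    sigma2: float = 1.0
    lambda_true: float = 1.0
    root_state: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")


def _default_traits() -> dict[str, TraitSpec]:
    # scales chosen so trait spreads resemble a northeastern-American tree
    # pool: heights ~5-35 m, wood density ~0.3-0.7 g/cm3, log seed mass
    # spanning a few orders of magnitude, leaf N ~10-30 mg/g, shade
    # tolerance a 1-5 index
    return {
        "maxH": TraitSpec(sigma2=16.0, lambda_true=0.0176, root_state=18.0),
        "Wd": TraitSpec(sigma2=0.005, lambda_true=0.7929, root_state=0.5),
        "Sm": TraitSpec(sigma2=1.0, lambda_true=0.2281, root_state=1.0),
        "N": TraitSpec(sigma2=8.0, lambda_true=0.6503, root_state=20.0),
        "shade_tol": TraitSpec(sigma2=0.4, lambda_true=0.8230, root_state=3.0),
    }


@dataclass
class SimConfig:
    """Full configuration of one synthetic dataset."""

    n_species: int = 61
    birth_rate: float = 1.0
    two_clade: bool = False
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    n_plots: int = 500
    richness_mean: float = 3.0
    max_richness: int = 10
    ba_meanlog: float = 0.0
    ba_sdlog: float = 0.75
    beta0: float = 0.2
    beta_fdis: float = 0.35
    beta_psv: float = 0.15
    beta_cwm: dict[str, float] = field(default_factory=lambda: {"CWM_N": 0.02})
    beta_cov: dict[str, float] = field(
        default_factory=lambda: {
            "total_ba": 0.015,
            "org_depth": -0.02,
            "temp": 0.06,
        }
    )
    noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_plots < 1:
            raise ValueError("need at least 1 plot")
        if self.noise_sd <= 0 or self.ba_sdlog <= 0 or self.birth_rate <= 0:
            raise ValueError("rates and SDs must be positive")
        if not 1 <= self.max_richness <= self.n_species:
            raise ValueError("max_richness must be in [1, n_species]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["traits"] = {k: TraitSpec(**v) for k, v in d.get("traits", {}).items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# tree simulation


def simulate_yule_tree(n_species: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Pure-birth (Yule) chronogram with exactly ``n_species`` tips.

    Starting from two lineages at the root, waiting times between
    speciation events are exponential with rate ``birth_rate * k`` for
    ``k`` extant lineages; the lineage that splits is uniform.  After the
    last split, time runs on for one more exponential waiting time so
    terminal branches are never zero.  Tips are labelled sp001, sp002, …
    in tree order.  Ultrametric by construction.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _as_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    c1.birth_time = c2.birth_time = 0.0
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        v = active.pop(int(rng.integers(k)))
        v.edge.length = t - v.birth_time
        a, b = dendropy.Node(), dendropy.Node()
        a.birth_time = b.birth_time = t
        v.add_child(a)
        v.add_child(b)
        active.extend([a, b])
    T = t + rng.exponential(1.0 / (birth_rate * n_species))
    for v in active:
        v.edge.length = T - v.birth_time
    root.edge.length = None
    taxa = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:03d}")
    return Phylogeny(tree)


def simulate_two_clade_tree(
    n_species: int,
    birth_rate: float = 1.0,
    split_depth_frac: float = 0.9,
    depth: float = 1.0,
    seed=None,
) -> Phylogeny:
    """Chronogram with one deep basal split, emulating two Divisions.

    The root splits the pool into two clades whose stems span
    ``split_depth_frac`` of the total ``depth``; within-clade
    diversification is a Yule process compressed into the remaining
    recent fraction.  Such trees leave wide patristic-distance gaps —
    the situation in which equal-width correlograms report empty classes
    — and concentrate trait similarity at small distances.
    """
    if not 0.0 < split_depth_frac < 1.0:
        raise ValueError("split_depth_frac must be in (0, 1)")
    if n_species < 4:
        raise ValueError("need at least 4 species for two clades")
    rng = _as_rng(seed)
    n1 = n_species // 2
    n2 = n_species - n1
    crown = depth * (1.0 - split_depth_frac)
    stem = depth * split_depth_frac
    tree = dendropy.Tree()
    tree.is_rooted = True
    offset = 0
    for n_clade in (n1, n2):
        sub = simulate_yule_tree(n_clade, birth_rate, seed=rng)
        sub_depth = sub.depth
        for node in sub.tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= crown / sub_depth
        attach = sub.tree.seed_node
        attach.edge.length = stem
        tree.seed_node.add_child(attach)
        for leaf in sub.tree.leaf_node_iter():
            offset += 1
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"sp{offset:03d}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# trait, community and response simulation


def simulate_bm_trait(
    tree: Phylogeny,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    root_state: float = 0.0,
    seed=None,
    name: str | None = None,
) -> pd.Series:
    """One draw of a trait under lambda-scaled Brownian motion.

    Multivariate normal with mean ``root_state`` and covariance
    ``sigma2 * V(lambda_true)`` where V is the tree's BM covariance.
    """
    rng = _as_rng(seed)
    V = lambda_transform(phylo_vcv(tree), lambda_true)
    Vm = sigma2 * V.to_numpy(dtype=float)
    n = Vm.shape[0]
    # tiny jitter keeps Cholesky stable for near-degenerate trees
    L = np.linalg.cholesky(Vm + 1e-12 * np.eye(n))
    x = root_state + L @ rng.standard_normal(n)
    return pd.Series(x, index=V.index, name=name)


def _truncated_poisson(rng, mean: float, lo: int, hi: int, size: int) -> np.ndarray:
    """Rejection-sample Poisson(mean) into [lo, hi]."""
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = rng.poisson(mean, size=2 * (size - filled) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_communities(
    species: list[str],
    n_plots: int,
    richness_mean: float = 3.0,
    max_richness: int = 10,
    ba_meanlog: float = 0.0,
    ba_sdlog: float = 0.75,
    seed=None,
) -> pd.DataFrame:
    """Plot × species basal-area matrix with truncated-Poisson richness.

    Each plot draws a richness from Poisson(``richness_mean``) truncated
    to [1, ``max_richness``], samples that many species uniformly
    without replacement, and assigns independent log-normal basal areas
    (m²/ha).  Monocultures occur whenever richness 1 has positive
    probability — which it always does here.
    """
    if max_richness > len(species):
        raise ValueError("max_richness exceeds the species pool")
    rng = _as_rng(seed)
    richness = _truncated_poisson(rng, richness_mean, 1, max_richness, n_plots)
    mat = np.zeros((n_plots, len(species)))
    for p in range(n_plots):
        chosen = rng.choice(len(species), size=richness[p], replace=False)
        mat[p, chosen] = rng.lognormal(ba_meanlog, ba_sdlog, size=richness[p])
    plots = [f"plot{p + 1:04d}" for p in range(n_plots)]
    out = pd.DataFrame(mat, index=plots, columns=list(species))
    out.index.name = "plot"
    out.columns.name = "species"
    return out


def simulate_covariates(n_plots: int, index, seed=None) -> pd.DataFrame:
    """Plot-level environment: organic-horizon depth (cm, log-normal)
    and mean annual temperature (°C, normal around a cool-temperate 2.5)."""
    rng = _as_rng(seed)
    return pd.DataFrame(
        {
            "org_depth": rng.lognormal(2.0, 0.5, size=n_plots),
            "temp": rng.normal(2.5, 2.0, size=n_plots),
        },
        index=index,
    )


def simulate_productivity(
    plot_table: pd.DataFrame,
    coefficients: dict[str, float],
    beta0: float = 0.0,
    noise_sd: float = 0.35,
    seed=None,
) -> pd.Series:
    """Linear-model response: y = β0 + Σ βⱼ·columnⱼ + N(0, noise_sd²)."""
    missing = [c for c in coefficients if c not in plot_table.columns]
    if missing:
        raise ValueError(f"coefficient columns absent from plot table: {missing}")
    rng = _as_rng(seed)
    y = np.full(len(plot_table), beta0, dtype=float)
    for col, beta in coefficients.items():
        y += beta * plot_table[col].to_numpy(dtype=float)
    y += rng.normal(0.0, noise_sd, size=len(plot_table))
    return pd.Series(y, index=plot_table.index, name="log_productivity")


@dataclass
class Bundle:
    """One synthetic dataset: tree, traits, community, plot table, manifest."""

    tree: Phylogeny
    traits: pd.DataFrame
    community: pd.DataFrame
    plot_table: pd.DataFrame
    config: SimConfig


def simulate_dataset(config: SimConfig | None = None) -> Bundle:
    """Generate a full dataset under ``config`` (defaults emulate the
    61-species, 500-plot study system).

    Stage order and seeding: the master seed spawns independent child
    streams for tree, traits (one per trait), communities, covariates
    and noise, so regenerating any stage alone is reproducible.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_comm, s_cov, s_noise = ss.spawn(5)

    if config.two_clade:
        tree = simulate_two_clade_tree(
            config.n_species, config.birth_rate, seed=np.random.default_rng(s_tree)
        )
    else:
        tree = simulate_yule_tree(
            config.n_species, config.birth_rate, seed=np.random.default_rng(s_tree)
        )

    trait_seeds = s_traits.spawn(len(config.traits))
    traits = pd.DataFrame(
        {
            name: simulate_bm_trait(
                tree,
                sigma2=spec.sigma2,
                lambda_true=spec.lambda_true,
                root_state=spec.root_state,
                seed=np.random.default_rng(trait_seeds[k]),
                name=name,
            )
            for k, (name, spec) in enumerate(config.traits.items())
        }
    )
    traits.index.name = "species"

    community = simulate_communities(
        tree.tip_labels,
        config.n_plots,
        richness_mean=config.richness_mean,
        max_richness=config.max_richness,
        ba_meanlog=config.ba_meanlog,
        ba_sdlog=config.ba_sdlog,
        seed=np.random.default_rng(s_comm),
    )

    fdis_traits = [t for t in DEFAULT_FDIS_TRAITS if t in traits.columns]
    cwm_traits = [t for t in DEFAULT_CWM_TRAITS if t in traits.columns]
    profile = diversity_profile(
        community, traits, tree, fdis_traits=fdis_traits, cwm_traits=cwm_traits
    )

    plot_table = profile.copy()
    plot_table["total_ba"] = community.sum(axis=1)
    env = simulate_covariates(
        config.n_plots, community.index, seed=np.random.default_rng(s_cov)
    )
    plot_table = plot_table.join(env)

    coefficients = {"FDis": config.beta_fdis, "PSV": config.beta_psv}
    coefficients.update(config.beta_cwm)
    coefficients.update(config.beta_cov)
    plot_table["log_productivity"] = simulate_productivity(
        plot_table,
        coefficients,
        beta0=config.beta0,
        noise_sd=config.noise_sd,
        seed=np.random.default_rng(s_noise),
    )
    return Bundle(
        tree=tree, traits=traits, community=community,
        plot_table=plot_table, config=config,
    )


def make_fixture_bundle(config: SimConfig | None = None, outdir: str | Path = ".") -> Path:
    """Write a dataset to disk: newick tree, three CSVs and a JSON manifest.

    The manifest records every generator parameter and the master seed;
    re-running with the manifest's config reproduces the files
    byte-for-byte.
    """
    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_dataset(config)
    write_newick(bundle.tree, outdir / "tree.nwk")
    bundle.traits.to_csv(outdir / "traits.csv")
    bundle.community.to_csv(outdir / "community.csv")
    bundle.plot_table.to_csv(outdir / "plots.csv")
    manifest = {
        "config": config.to_dict(),
        "files": {
            "tree": "tree.nwk",
            "traits": "traits.csv",
            "community": "community.csv",
            "plot_table": "plots.csv",
        },
        "n_species": bundle.tree.n_tips,
        "n_plots": len(bundle.plot_table),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
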