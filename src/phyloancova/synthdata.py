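"""Synthetic trees, factor labels and trait vectors for testing the pipeline.

The generator emulates the statistical structure of a comparative
hematocrit dataset: a pure-birth (Yule) ultrametric tree; clade labels that
are monophyletic blocks; habitat labels assigned by a root-to-tip Markov
walk (so habitat is phylogenetically clumped rather than i.i.d.); and a
continuous trait generated as fixed habitat/clade effects plus residuals
drawn multivariate normal with covariance sigma^2 * V_ou(tree, d_true),
interpolating between a star phylogeny (d = 0) and the Brownian-motion tree
covariance (d = 1).

Default parameters mirror the study conditions the pipeline targets:
67 tips, 7 clades, fixed effects on the empirical coefficient scale
(Hct % units), residual variance 16 %^2 and a weak phylogenetic signal
(d = 0.124).  All randomness flows from SimConfig.seed through spawned
numpy generators, so every artifact is reproducible from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gls import CLADE_LEVELS, HABITAT_LEVELS, TraitTable, build_design
from .phylocov import ou_covariance
from .treeio import Node, PhyloTree, save_tree

__all__ = ["SimConfig", "DEFAULT_BETA", "simulate_tree", "assign_factors",
           "simulate_traits", "simulate_dataset", "write_dataset"]

#: fixed-effect defaults on the empirical coefficient scale (Hct % units)
DEFAULT_BETA: dict[str, float] = {
    "Y-intercept": 27.0,
    "Semi-aquatic": -3.4,
    "Aquatic": -23.5,
    "Marine": 5.3,
    "Boidae": -1.0,
    "Acrochordidae": 17.7,
    "Viperidae": -2.3,
    "Homalopsidae": -0.2,
    "Elapidae": -1.1,
    "Natricinae": 5.7,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    seed drives every random draw; n_tips >= 4; n_clades <= min(n_tips/2, 7)
    (clade labels come from the 7-level vocabulary); habitat_switch_prob is
    the per-branch probability that the Markov habitat walk leaves its
    current state; sigma2 is the residual variance in %^2; d_true indexes
    the residual covariance between star (0) and Brownian (1).
    """

    seed: int = 0
    n_tips: int = 67
    n_clades: int = 7
    habitat_switch_prob: float = 0.15
    sigma2: float = 16.0
    d_true: float = 0.124
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))

    def __post_init__(self) -> None:
        problems = []
        if self.n_tips < 4:
            problems.append("n_tips must be >= 4")
        if not 1 <= self.n_clades <= min(self.n_tips // 2, len(CLADE_LEVELS)):
            problems.append(
                f"n_clades must be in [1, min(n_tips/2, {len(CLADE_LEVELS)})]"
            )
        if not 0.0 <= self.habitat_switch_prob <= 1.0:
            problems.append("habitat_switch_prob must be in [0, 1]")
        if not self.sigma2 > 0:
            problems.append("sigma2 must be > 0")
        if not 0.0 <= self.d_true <= 1.0:
            problems.append("d_true must be in [0, 1]")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def rngs(self, n: int = 3) -> list[np.random.Generator]:
        """Independent child generators split from the single seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def simulate_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth (Yule, rate 1) tree with cfg.n_tips tips, rescaled to height 1.

    Lineages split at exponential waiting times with total rate equal to the
    number of live lineages; after the last split one further waiting time
    sets the present, so all tips are contemporaneous.  Tips are labeled
    s001, s002, ... in left-to-right order.
    """
    rng = rng if rng is not None else cfg.rngs(1)[0]
    nodes = [Node(0, None)]
    birth = {0: 0.0}
    active = [0]
    t = 0.0
    while len(active) < cfg.n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        nid = active.pop(i)
        nodes[nid].length = None if nodes[nid].parent is None else t - birth[nid]
        for _ in range(2):
            child = Node(len(nodes), nid)
            nodes.append(child)
            nodes[nid].children.append(child.id)
            birth[child.id] = t
            active.append(child.id)
    t_end = t + rng.exponential(1.0 / cfg.n_tips)
    for nid in active:
        nodes[nid].length = t_end - birth[nid]
    tree = PhyloTree(nodes=nodes, root=0)
    tree = tree.rescaled_to_unit_height()
    for i, nid in enumerate(tree.tips, start=1):
        tree.nodes[nid].label = f"s{i:03d}"
    return tree


def _clade_blocks(tree: PhyloTree, n_clades: int) -> list[list[int]]:
    """Partition tips into n_clades monophyletic blocks by splitting the largest."""
    if n_clades == 1:
        return [tree.tips]
    tips_below: dict[int, list[int]] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        tips_below[nid] = [nid] if node.is_tip else [
            t for c in node.children for t in tips_below[c]
        ]
    blocks = list(tree.nodes[tree.root].children)
    while len(blocks) < n_clades:
        internal = [b for b in blocks if tree.nodes[b].children]
        if not internal:
            raise ValueError(
                f"cannot cut {n_clades} monophyletic blocks on this topology"
            )
        largest = max(internal, key=lambda b: (len(tips_below[b]), -b))
        blocks.remove(largest)
        blocks.extend(tree.nodes[largest].children)
    return [tips_below[b] for b in blocks]


def assign_factors(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clade and habitat labels for each tip, in tree tip order.

    Clades are monophyletic blocks (largest block gets the first vocabulary
    label); habitat evolves by a root-to-tip Markov walk that leaves its
    state with probability habitat_switch_prob per branch, moving uniformly
    to one of the other three states.  The root state is drawn uniformly.
    """
    rng = rng if rng is not None else cfg.rngs(2)[1]
    blocks = _clade_blocks(tree, cfg.n_clades)
    blocks.sort(key=len, reverse=True)
    clade_of: dict[int, str] = {}
    for label, block in zip(CLADE_LEVELS, blocks):
        for tip in block:
            clade_of[tip] = label

    state_of: dict[int, str] = {tree.root: HABITAT_LEVELS[int(rng.integers(4))]}
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        parent_state = state_of[tree.nodes[nid].parent]
        if rng.random() < cfg.habitat_switch_prob:
            others = [h for h in HABITAT_LEVELS if h != parent_state]
            state_of[nid] = others[int(rng.integers(3))]
        else:
            state_of[nid] = parent_state

    tips = tree.tips
    return pd.DataFrame(
        {
            "species": [tree.nodes[t].label for t in tips],
            "habitat": [state_of[t] for t in tips],
            "clade": [clade_of[t] for t in tips],
        }
    )


def simulate_traits(
    tree: PhyloTree,
    factors: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> TraitTable:
    """Draw y = X beta + e with e ~ N(0, sigma2 * V_ou(tree, d_true)).

    ``factors`` must be aligned to the tree's tip order.  The returned
    TraitTable is constructed without the physiological range check, since
    Gaussian residuals are unbounded.
    """
    rng = rng if rng is not None else cfg.rngs(3)[2]
    if list(factors["species"]) != list(tree.tip_labels):
        raise ValueError("factor table is not aligned to the tree's tip order")
    skeleton = TraitTable(
        factors.assign(hct=np.zeros(len(factors))), check_range=False
    )
    X = build_design(skeleton, ("habitat", "clade"))
    unknown = set(cfg.beta) - set(X.columns)
    if unknown:
        raise ValueError(f"beta names not in design: {', '.join(sorted(unknown))}")
    beta = np.array([cfg.beta.get(c, 0.0) for c in X.columns])
    V = ou_covariance(tree.rescaled_to_unit_height(), cfg.d_true)
    L = np.linalg.cholesky(V.matrix + 1e-12 * np.eye(V.n))
    e = np.sqrt(cfg.sigma2) * (L @ rng.standard_normal(V.n))
    y = X.matrix @ beta + e
    return TraitTable(factors.assign(hct=y), check_range=False)


def simulate_dataset(cfg: SimConfig) -> tuple[PhyloTree, TraitTable]:
    """Tree + trait table from a single seed (tree, factors, traits split off it)."""
    rng_tree, rng_factors, rng_traits = cfg.rngs(3)
    tree = simulate_tree(cfg, rng_tree)
    factors = assign_factors(tree, cfg, rng_factors)
    traits = simulate_traits(tree, factors, cfg, rng_traits)
    return tree, traits


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write traits.csv + tree.nwk (+ the seed in a sidecar) for the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, traits = simulate_dataset(cfg)
    paths = {"tree": outdir / "tree.nwk", "traits": outdir / "traits.csv"}
    save_tree(tree, paths["tree"])
    traits.to_csv(paths["traits"])
    return paths
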