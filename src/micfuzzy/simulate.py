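"""Planted-network simulator producing DREAM-style time-series data.

The generator plants a signed directed network and simulates expression
trajectories whose regulated genes follow the same fuzzy rulebase the
inference engine uses (plus additive Gaussian noise), so edge recovery is
a well-posed exercise that isolates pipeline correctness from model
misspecification.  A second "linear" dynamics mode (clipped weighted
difference of activator and repressor) is available to probe robustness
when the generative model and the scoring model disagree.

Datasets are produced directly on the normalized [0, 1] scale and flagged
as normalized, mirroring data that has already been min-max scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fuzzy import FuzzyConfig, _predict_series
from .io import ExpressionDataset, GoldStandard

__all__ = ["PlantedNetwork", "generate_network", "simulate_expression"]

# mean-reversion rate and long-run mean of the unregulated-gene walk
_WALK_RATE = 0.15
_WALK_MEAN = 0.5


@dataclass
class PlantedNetwork:
    """Ground-truth signed network used to drive the simulator."""

    gene_universe: list[str]
    edges: list[tuple[str, str, str]]  # (regulator, target, "+"/"-")

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for reg, tgt, sign in self.edges:
            if reg == tgt:
                raise ValueError("planted networks contain no self-loops")
            if reg not in universe or tgt not in universe:
                raise ValueError(f"edge ({reg}, {tgt}) outside the gene universe")
            if sign not in ("+", "-"):
                raise ValueError(f"invalid sign {sign!r}")

    def signed_truth(self) -> dict[tuple[str, str], str]:
        return {(reg, tgt): sign for reg, tgt, sign in self.edges}

    def unsigned_gold(self) -> GoldStandard:
        return GoldStandard(
            edges={(reg, tgt) for reg, tgt, _ in self.edges},
            gene_universe=list(self.gene_universe),
        )

    def regulators_of(self, target: str) -> dict[str, str | None]:
        """The target's activator and repressor gene names (or None)."""
        roles: dict[str, str | None] = {"+": None, "-": None}
        for reg, tgt, sign in self.edges:
            if tgt == target:
                roles[sign] = reg
        return roles


def generate_network(n_genes: int, density: int = 2, seed: int = 0) -> PlantedNetwork:
    """Plant a signed network with ``density`` regulators per target.

    ``density=2`` (default) gives every target one activator and one
    repressor drawn without replacement from the other genes; ``density=1``
    gives one regulator with a randomly drawn sign; ``density=0`` plants
    no edges.  Deterministic for a fixed seed.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    if density < 0 or density > min(2, n_genes - 1):
        raise ValueError(f"density {density} infeasible for {n_genes} genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    edges: list[tuple[str, str, str]] = []
    for tgt in genes:
        others = [g for g in genes if g != tgt]
        if density == 0:
            continue
        chosen = rng.choice(len(others), size=density, replace=False)
        if density == 2:
            signs = ["+", "-"]
        else:
            signs = ["+" if rng.random() < 0.5 else "-"]
        for idx, sign in zip(chosen, signs):
            edges.append((others[int(idx)], tgt, sign))
    return PlantedNetwork(gene_universe=genes, edges=edges)


def simulate_expression(
    net: PlantedNetwork,
    timepoints: int = 21,
    series: int = 5,
    noise_sd: float = 0.02,
    seed: int = 0,
    dynamics: str = "fuzzy",
    cfg: FuzzyConfig | None = None,
) -> ExpressionDataset:
    """Simulate DREAM-shaped expression data from a planted network.

    Initial values are Uniform(0, 1) per series.  For t >= 2 a regulated
    target takes the fuzzy rulebase's defuzzified output for its
    (activator, repressor) values at t-1 — a missing role enters as 0 —
    plus Gaussian noise, clipped to [0, 1].  Unregulated genes follow a
    mean-reverting noisy walk.  ``dynamics="linear"`` replaces the fuzzy
    map by clip(0.25 + 0.75 a - 0.75 r).
    """
    if timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    if series < 1:
        raise ValueError("need at least one series")
    if dynamics not in ("fuzzy", "linear"):
        raise ValueError(f"unknown dynamics mode: {dynamics!r}")
    cfg = cfg or FuzzyConfig()
    rng = np.random.default_rng(seed)
    genes = net.gene_universe
    roles = {tgt: net.regulators_of(tgt) for tgt in genes}
    regulated = [g for g in genes if roles[g]["+"] is not None or roles[g]["-"] is not None]
    idx = {g: i for i, g in enumerate(genes)}

    reg_idx = np.asarray([idx[g] for g in regulated], dtype=np.intp)
    act_idx = np.asarray(
        [idx[roles[g]["+"]] if roles[g]["+"] is not None else -1 for g in regulated],
        dtype=np.intp,
    )
    rep_idx = np.asarray(
        [idx[roles[g]["-"]] if roles[g]["-"] is not None else -1 for g in regulated],
        dtype=np.intp,
    )
    free_idx = np.asarray([idx[g] for g in genes if g not in regulated], dtype=np.intp)

    mats: list[np.ndarray] = []
    stamps: list[np.ndarray] = []
    for _ in range(series):
        mat = np.empty((timepoints, len(genes)))
        mat[0] = rng.uniform(0.0, 1.0, size=len(genes))
        for t in range(1, timepoints):
            prev = mat[t - 1]
            row = np.empty(len(genes))
            if len(reg_idx):
                a = np.where(act_idx >= 0, prev[act_idx], 0.0)
                r = np.where(rep_idx >= 0, prev[rep_idx], 0.0)
                if dynamics == "fuzzy":
                    base, _, _ = _predict_series(a, r, cfg)
                else:
                    base = np.clip(0.25 + 0.75 * a - 0.75 * r, 0.0, 1.0)
                row[reg_idx] = base
            if len(free_idx):
                row[free_idx] = prev[free_idx] + _WALK_RATE * (_WALK_MEAN - prev[free_idx])
            noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else 0.0
            mat[t] = np.clip(row + noise, 0.0, 1.0)
        mats.append(mat)
        stamps.append(np.arange(timepoints, dtype=float) * 10.0)
    return ExpressionDataset(gene_ids=list(genes), series=mats, time_stamps=stamps,
                             normalized=True)
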