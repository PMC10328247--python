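"""Activator–repressor fuzzy model for scoring candidate regulator pairs.

For a target gene and an ordered (activator, repressor) candidate pair,
the model predicts the target's normalized expression at time t from the
pair's *regulatory effects* at time t-1.  A regulatory effect is the
product of a regulator's expression level and its regulatory relationship
strength (RRS — the lagged MIC score with respect to the target), scaled
back to [0, 1].  Effects are fuzzified into three triangular levels (Low,
Medium, High), a 3x3 Mamdani rulebase maps activator x repressor levels to
five output levels (Very Low .. Very High), rule outputs are aggregated by
the bounded sum and defuzzified by the centroid.

Each pair is scored by its residual score

    RS = MSE x Variance

where MSE compares predicted and observed target trajectories and
Variance is the population variance of the per-rule firing counts: a pair
that exercises the rulebase evenly (low variance) and predicts well (low
MSE) is a plausible regulator pair.  RS values are min-max normalized per
target (NRS) and edges are selected from the lowest-scoring pairs.
"""

from __future__ import annotations

import functools
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ExpressionDataset
from .mic import CandidateSet, MICMatrix

__all__ = [
    "FuzzyConfig",
    "PairScore",
    "SignedRegulator",
    "NoFireWarning",
    "input_membership",
    "regulatory_effect",
    "infer_target_level",
    "defuzzify",
    "fuzzy_step",
    "score_pair",
    "score_all_pairs",
    "select_regulators",
    "trajectory_mse",
    "firing_variance",
]

logger = logging.getLogger(__name__)

INPUT_LEVELS = ("Low", "Medium", "High")
OUTPUT_LEVELS = ("VL", "L", "Med", "H", "VH")

# Triangles as (foot, peak, foot).  The input family is the unique uniform
# three-triangle partition of unity on [0, 1]; the output family is the
# uniform five-triangle layout.
DEFAULT_INPUT_MFS = ((0.0, 0.0, 0.5), (0.0, 0.5, 1.0), (0.5, 1.0, 1.0))
DEFAULT_OUTPUT_MFS = (
    (0.0, 0.0, 0.25),
    (0.0, 0.25, 0.5),
    (0.25, 0.5, 0.75),
    (0.5, 0.75, 1.0),
    (0.75, 1.0, 1.0),
)
# rows: activator level (Low, Medium, High); cols: repressor level.
# Anchored by the rule (High, Low) -> VH and completed as the unique
# monotone, antisymmetric matrix over the five output levels.
DEFAULT_RULE_MATRIX = ((2, 1, 0), (3, 2, 1), (4, 3, 2))


class NoFireWarning(UserWarning):
    """Emitted when no rule fires and the fallback output 0.5 is used."""


@dataclass(frozen=True)
class FuzzyConfig:
    """Membership layout, rulebase and numerical settings of the model.

    ``rule_matrix[i][j]`` is the output-level index (0 = VL .. 4 = VH)
    fired when the activator is at input level i and the repressor at
    input level j.  The matrix must be monotone: non-decreasing in the
    activator level and non-increasing in the repressor level.
    """

    input_mfs: tuple[tuple[float, float, float], ...] = DEFAULT_INPUT_MFS
    output_mfs: tuple[tuple[float, float, float], ...] = DEFAULT_OUTPUT_MFS
    rule_matrix: tuple[tuple[int, int, int], ...] = DEFAULT_RULE_MATRIX
    defuzz_resolution: float = 0.001
    firing_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if len(self.input_mfs) != 3 or len(self.output_mfs) != 5:
            raise ValueError("expected 3 input and 5 output membership functions")
        rm = self.rule_matrix
        if len(rm) != 3 or any(len(row) != 3 for row in rm):
            raise ValueError("rule matrix must be 3x3")
        for i in range(3):
            for j in range(3):
                if not 0 <= rm[i][j] < 5:
                    raise ValueError("rule outputs must index the 5 output levels")
                if i > 0 and rm[i][j] < rm[i - 1][j]:
                    raise ValueError("rule matrix must be non-decreasing in the activator")
                if j > 0 and rm[i][j] > rm[i][j - 1]:
                    raise ValueError("rule matrix must be non-increasing in the repressor")

    @property
    def universe(self) -> np.ndarray:
        """Midpoint discretization of the output universe [0, 1]."""
        return _universe_cached(self.defuzz_resolution)

    def output_grid(self) -> np.ndarray:
        """Output membership functions sampled on the universe: (5, M)."""
        return _output_grid_cached(self.output_mfs, self.defuzz_resolution)

    # -- flat key-value serialization -------------------------------------

    def to_flat_dict(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, mf in zip(INPUT_LEVELS, self.input_mfs):
            out[f"input.{name}"] = " ".join(f"{v:g}" for v in mf)
        for name, mf in zip(OUTPUT_LEVELS, self.output_mfs):
            out[f"output.{name}"] = " ".join(f"{v:g}" for v in mf)
        for i, act in enumerate(INPUT_LEVELS):
            for j, rep in enumerate(INPUT_LEVELS):
                out[f"rule.{act}.{rep}"] = OUTPUT_LEVELS[self.rule_matrix[i][j]]
        out["defuzz_resolution"] = f"{self.defuzz_resolution:g}"
        out["firing_epsilon"] = f"{self.firing_epsilon:g}"
        return out

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_flat_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyConfig":
        kv: dict[str, str] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        in_mfs = tuple(tuple(float(v) for v in kv[f"input.{n}"].split()) for n in INPUT_LEVELS)
        out_mfs = tuple(tuple(float(v) for v in kv[f"output.{n}"].split()) for n in OUTPUT_LEVELS)
        rm = tuple(
            tuple(OUTPUT_LEVELS.index(kv[f"rule.{a}.{r}"]) for r in INPUT_LEVELS)
            for a in INPUT_LEVELS
        )
        return cls(
            input_mfs=in_mfs,  # type: ignore[arg-type]
            output_mfs=out_mfs,  # type: ignore[arg-type]
            rule_matrix=rm,  # type: ignore[arg-type]
            defuzz_resolution=float(kv.get("defuzz_resolution", "0.001")),
            firing_epsilon=float(kv.get("firing_epsilon", "1e-9")),
        )

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def default_file(cls) -> Path:
        """Path of the shipped flat config reproducing the defaults."""
        return Path(__file__).parent / "data" / "default_fuzzy.cfg"


@functools.lru_cache(maxsize=8)
def _universe_cached(resolution: float) -> np.ndarray:
    m = int(round(1.0 / resolution))
    u = (np.arange(m) + 0.5) * resolution
    u.setflags(write=False)
    return u


@functools.lru_cache(maxsize=8)
def _output_grid_cached(
    output_mfs: tuple[tuple[float, float, float], ...], resolution: float
) -> np.ndarray:
    u = _universe_cached(resolution)
    grid = np.stack([_tri(u, *mf) for mf in output_mfs])
    grid.setflags(write=False)
    return grid


def _tri(x: np.ndarray | float, a: float, b: float, c: float) -> np.ndarray:
    """Triangular membership with feet a, c and peak b; shoulders allowed."""
    x = np.asarray(x, dtype=float)
    left = np.ones_like(x) if a == b else (x - a) / (b - a)
    right = np.ones_like(x) if b == c else (c - x) / (c - b)
    return np.clip(np.minimum(left, right), 0.0, 1.0)


def input_membership(x: float, cfg: FuzzyConfig | None = None) -> tuple[float, float, float]:
    """Fuzzify a normalized regulatory effect into (Low, Medium, High).

    With the default layout the three memberships form a partition of
    unity; e.g. x = 0.4 gives (0.2, 0.8, 0.0).
    """
    cfg = cfg or FuzzyConfig()
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"regulatory effect must lie in [0, 1], got {x}")
    lo, me, hi = (float(_tri(x, *mf)) for mf in cfg.input_mfs)
    return lo, me, hi


def regulatory_effect(expr: np.ndarray, mic_score: float) -> np.ndarray:
    """Regulatory effect of one regulator: RRS x expression, rescaled to [0, 1].

    The raw effect ``mic_score * expr`` lives on [0, mic_score] for
    normalized expression; min-max scaling over that attainable range
    (i.e. division by the RRS) maps it back to [0, 1].  A zero RRS
    annihilates the effect (all zeros, with a warning).
    """
    expr = np.asarray(expr, dtype=float)
    if not 0.0 <= mic_score <= 1.0:
        raise ValueError(f"MIC score must lie in [0, 1], got {mic_score}")
    raw = mic_score * expr
    if mic_score == 0.0:
        warnings.warn("zero regulatory relationship strength: effect is identically 0",
                      UserWarning, stacklevel=2)
        return np.zeros_like(expr)
    return raw / mic_score


def _firing_grid(act: np.ndarray, rep: np.ndarray, cfg: FuzzyConfig) -> np.ndarray:
    """Firing strengths of the 9 rules for arrays of inputs: (P, 3, 3)."""
    act_m = np.stack([_tri(act, *mf) for mf in cfg.input_mfs], axis=-1)  # (P, 3)
    rep_m = np.stack([_tri(rep, *mf) for mf in cfg.input_mfs], axis=-1)
    return np.minimum(act_m[..., :, None], rep_m[..., None, :])


def infer_target_level(
    act_effect: float, rep_effect: float, cfg: FuzzyConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fire the rulebase for one timepoint.

    Returns the aggregated output membership over the discretized universe
    (bounded sum of min-clipped output levels) and the 3x3 firing-strength
    matrix (activator level x repressor level).
    """
    cfg = cfg or FuzzyConfig()
    for name, v in (("activator", act_effect), ("repressor", rep_effect)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} effect must lie in [0, 1], got {v}")
    firing = _firing_grid(np.asarray(act_effect), np.asarray(rep_effect), cfg)
    out_grid = cfg.output_grid()  # (5, M)
    agg = np.zeros(out_grid.shape[1])
    for i in range(3):
        for j in range(3):
            agg += np.minimum(firing[i, j], out_grid[cfg.rule_matrix[i][j]])
    return np.minimum(agg, 1.0), firing


def defuzzify(aggregate: np.ndarray, cfg: FuzzyConfig | None = None) -> float:
    """Centroid of an aggregated membership function over [0, 1].

    An identically-zero aggregate (no rule fired) falls back to 0.5 and
    emits a :class:`NoFireWarning`; under the default partition-of-unity
    input layout this cannot happen.
    """
    cfg = cfg or FuzzyConfig()
    aggregate = np.asarray(aggregate, dtype=float)
    mass = aggregate.sum()
    if mass <= 0.0:
        warnings.warn("no rule fired; returning fallback output 0.5", NoFireWarning,
                      stacklevel=2)
        return 0.5
    return float((cfg.universe * aggregate).sum() / mass)


def fuzzy_step(act_effect: float, rep_effect: float, cfg: FuzzyConfig | None = None) -> float:
    """Crisp predicted target level for one (activator, repressor) input."""
    cfg = cfg or FuzzyConfig()
    agg, _ = infer_target_level(act_effect, rep_effect, cfg)
    return defuzzify(agg, cfg)


def _predict_series(
    act: np.ndarray, rep: np.ndarray, cfg: FuzzyConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized prediction over P timepoints.

    Returns (predictions (P,), firing strengths (P, 9), no-fire count).
    """
    firing = _firing_grid(act, rep, cfg).reshape(len(act), 9)  # (P, 9)
    out_grid = cfg.output_grid()  # (5, M)
    rules_flat = [cfg.rule_matrix[i][j] for i in range(3) for j in range(3)]
    rule_out = out_grid[rules_flat]  # (9, M)
    clipped = np.minimum(firing[:, :, None], rule_out[None, :, :])  # (P, 9, M)
    agg = np.minimum(clipped.sum(axis=1), 1.0)  # (P, M)
    mass = agg.sum(axis=1)
    no_fire = int(np.sum(mass <= 0.0))
    safe = np.where(mass > 0, mass, 1.0)
    centroids = (agg @ cfg.universe) / safe
    centroids = np.where(mass > 0, centroids, 0.5)
    return centroids, firing, no_fire


@dataclass
class PairScore:
    """Score of one (activator, repressor) pair for a target gene."""

    target: str
    activator: str
    repressor: str
    predicted: list[np.ndarray]  # per series, aligned with timepoints 2..T
    mse: float
    firing_counts: np.ndarray  # 9 per-rule counts over predicted timepoints
    variance: float
    rs: float
    nrs: float | None = None
    no_fire_events: int = 0


@dataclass(frozen=True)
class SignedRegulator:
    """A selected regulator-target edge with provenance scores."""

    regulator: str
    target: str
    sign: str  # "+" (activation) or "-" (inhibition)
    rs: float
    nrs: float
    mic: float = float("nan")


def trajectory_mse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error over the predicted timepoints.

    The denominator is the number of predicted points (timepoints 2..T in
    every series), so the score is well defined for stacked multi-series
    data; within one target any fixed positive denominator leaves the
    residual-score ranking unchanged.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("trajectories differ in length")
    if actual.size == 0:
        raise ValueError("no predicted points")
    return float(np.mean((actual - predicted) ** 2))


def firing_variance(counts: np.ndarray) -> float:
    """Population variance of the 9 per-rule firing counts.

    Zero when all rules fire equally often — the evenness criterion that
    marks a pair's predictions as acceptable.
    """
    counts = np.asarray(counts, dtype=float)
    return float(np.var(counts))


def score_pair(
    ds: ExpressionDataset,
    m: MICMatrix,
    target: str,
    activator: str,
    repressor: str,
    cfg: FuzzyConfig | None = None,
    use_rrs: bool = True,
    effect_mode: str = "independent",
) -> PairScore:
    """Score one (activator, repressor, target) triplet.

    Effects at time t-1 predict the target at time t (mirroring the MIC
    lag); the first timepoint of every series is never predicted.

    ``effect_mode="independent"`` scales each regulator's effect over its
    own attainable range (RRS cancels); ``"paired"`` scales both effects
    by the larger of the two RRS values, so a weaker regulatory
    relationship damps its regulator's effect relative to the stronger
    one.  ``use_rrs=False`` fixes both RRS values at 1 (the ablation
    without regulatory relationship strength).
    """
    cfg = cfg or FuzzyConfig()
    if len({target, activator, repressor}) != 3:
        raise ValueError("target, activator and repressor must be distinct genes")
    if not ds.normalized:
        raise ValueError("dataset must be normalized")
    if effect_mode not in ("independent", "paired"):
        raise ValueError(f"unknown effect mode: {effect_mode!r}")

    mic_a = m.score(activator, target) if use_rrs else 1.0
    mic_r = m.score(repressor, target) if use_rrs else 1.0
    if effect_mode == "paired":
        scale = max(mic_a, mic_r)
        scale_a = scale_r = scale if scale > 0 else 1.0
    else:
        scale_a = mic_a if mic_a > 0 else 1.0
        scale_r = mic_r if mic_r > 0 else 1.0

    predicted: list[np.ndarray] = []
    actual_all: list[np.ndarray] = []
    firing_all: list[np.ndarray] = []
    no_fire = 0
    a_idx = ds.gene_index(activator)
    r_idx = ds.gene_index(repressor)
    t_idx = ds.gene_index(target)
    for mat in ds.series:
        eff_a = np.clip(mic_a * mat[:-1, a_idx] / scale_a, 0.0, 1.0)
        eff_r = np.clip(mic_r * mat[:-1, r_idx] / scale_r, 0.0, 1.0)
        yhat, firing, nf = _predict_series(eff_a, eff_r, cfg)
        predicted.append(yhat)
        actual_all.append(mat[1:, t_idx])
        firing_all.append(firing)
        no_fire += nf

    mse = trajectory_mse(np.concatenate(actual_all), np.concatenate(predicted))
    firing = np.concatenate(firing_all, axis=0)  # (P, 9)
    counts = (firing > cfg.firing_epsilon).sum(axis=0)
    variance = firing_variance(counts)
    return PairScore(
        target=target,
        activator=activator,
        repressor=repressor,
        predicted=predicted,
        mse=mse,
        firing_counts=counts,
        variance=variance,
        rs=mse * variance,
        no_fire_events=no_fire,
    )


def score_all_pairs(
    ds: ExpressionDataset,
    m: MICMatrix,
    target: str,
    cand: CandidateSet,
    cfg: FuzzyConfig | None = None,
    use_rrs: bool = True,
    effect_mode: str = "independent",
) -> list[PairScore]:
    """Score every ordered (activator, repressor) pair from a candidate set.

    Residual scores are min-max normalized (NRS) within the target's pair
    list; if all RS values are equal every NRS is 0.  A candidate set with
    fewer than two genes cannot form a pair: an empty list is returned and
    the condition is logged (not fatal).
    """
    cfg = cfg or FuzzyConfig()
    genes = cand.genes
    if len(genes) < 2:
        logger.info("target %s: %d candidate(s); no activator-repressor pair inferable",
                    target, len(genes))
        return []
    scores = [
        score_pair(ds, m, target, a, r, cfg, use_rrs=use_rrs, effect_mode=effect_mode)
        for a in genes
        for r in genes
        if a != r
    ]
    rs = np.array([s.rs for s in scores])
    span = rs.max() - rs.min()
    for s, v in zip(scores, rs):
        s.nrs = 0.0 if span == 0 else float((v - rs.min()) / span)
    return scores


def select_regulators(
    scores: list[PairScore],
    mode: str = "nrs_threshold",
    nrs_threshold: float | None = None,
    k: int | None = None,
    gene_order: Sequence[str] | None = None,
    mic_lookup: MICMatrix | None = None,
) -> list[SignedRegulator]:
    """Select signed regulators of one target from its scored pairs.

    ``mode="nrs_threshold"`` keeps pairs with NRS <= threshold;
    ``mode="top_k"`` keeps the k pairs with the smallest RS (ties broken
    by activator then repressor gene order).  Kept pairs emit
    activator -> target (+) and repressor -> target (-) edges; a gene
    appearing in both roles is resolved to the role it plays in its
    lowest-RS kept pair and emitted once.
    """
    if not scores:
        raise ValueError("no scored pairs to select from")
    target = scores[0].target
    if gene_order is None:
        seen: list[str] = []
        for s in scores:
            for g in (s.activator, s.repressor):
                if g not in seen:
                    seen.append(g)
        gene_order = seen
    order = {g: i for i, g in enumerate(gene_order)}

    def sort_key(s: PairScore) -> tuple[float, int, int]:
        return (s.rs, order.get(s.activator, len(order)), order.get(s.repressor, len(order)))

    ranked = sorted(scores, key=sort_key)
    if mode == "nrs_threshold":
        if nrs_threshold is None:
            raise ValueError("nrs_threshold mode requires a threshold value")
        kept = [s for s in ranked if s.nrs is not None and s.nrs <= nrs_threshold]
    elif mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        kept = ranked[:k]
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")

    out: dict[str, SignedRegulator] = {}
    for s in kept:  # ascending rs: first role seen wins
        for gene, sign in ((s.activator, "+"), (s.repressor, "-")):
            if gene not in out:
                mic_score = float("nan")
                if mic_lookup is not None:
                    mic_score = mic_lookup.score(gene, target)
                out[gene] = SignedRegulator(
                    regulator=gene, target=target, sign=sign,
                    rs=s.rs, nrs=s.nrs if s.nrs is not None else 0.0, mic=mic_score,
                )
    return sorted(out.values(), key=lambda e: order.get(e.regulator, len(order)))
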