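"""End-to-end inference: screening, pair scoring, selection, assembly.

This is the programmatic surface the command-line tool wraps: normalize
the data, compute the lagged MIC matrix, screen candidates per target,
score every activator-repressor pair from each candidate set, select the
lowest-residual pairs and assemble the signed network.  The run log
records per-target candidate sizes, pair counts, thresholds, the fuzzy
configuration hash and the combinatorial-reduction percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evaluate import InferredNetwork, assemble_network, combinatorial_reduction
from .fuzzy import FuzzyConfig, PairScore, SignedRegulator, score_all_pairs, select_regulators
from .io import ExpressionDataset, minmax_normalize
from .mic import CandidateSet, MICMatrix, candidate_set, mic_matrix

__all__ = ["InferenceResult", "infer_network"]


@dataclass
class InferenceResult:
    """Inferred network plus the intermediate state of the run."""

    network: InferredNetwork
    mic: MICMatrix
    candidates: dict[str, CandidateSet]
    pair_scores: dict[str, list[PairScore]]
    selections: dict[str, list[SignedRegulator]]
    reduction_percent: float
    config_digest: str
    log_lines: list[str] = field(default_factory=list)

    def log_text(self) -> str:
        return "\n".join(self.log_lines) + "\n"


def infer_network(
    ds: ExpressionDataset,
    mic_mode: str = "mean",
    mic_threshold: float | None = None,
    selection_mode: str = "nrs_threshold",
    nrs_threshold: float | None = 0.05,
    top_k: int | None = None,
    cfg: FuzzyConfig | None = None,
    use_rrs: bool = True,
    effect_mode: str = "independent",
    alpha: float = 0.6,
    clump_factor: int = 15,
    strict_grid: bool = False,
) -> InferenceResult:
    """Run the full two-stage inference on a dataset.

    ``mic_mode`` is "mean" (per-target average MIC threshold) or "fixed"
    (``mic_threshold`` required); ``selection_mode`` is "nrs_threshold"
    (``nrs_threshold`` required) or "top_k" (``top_k`` required).
    """
    cfg = cfg or FuzzyConfig()
    if selection_mode == "nrs_threshold" and nrs_threshold is None:
        raise ValueError("nrs_threshold selection requires a threshold")
    if selection_mode == "top_k" and top_k is None:
        raise ValueError("top_k selection requires k")

    ds = minmax_normalize(ds)
    m = mic_matrix(ds, alpha=alpha, c=clump_factor, strict=strict_grid)

    log: list[str] = [
        f"genes={ds.n_genes} series={ds.n_series} timepoints={ds.total_timepoints}",
        f"fuzzy_config_sha256={cfg.digest()}",
        f"mic_mode={mic_mode} mic_threshold={mic_threshold}"
        f" selection_mode={selection_mode} nrs_threshold={nrs_threshold} top_k={top_k}"
        f" use_rrs={use_rrs} effect_mode={effect_mode}",
    ]

    candidates: dict[str, CandidateSet] = {}
    pair_scores: dict[str, list[PairScore]] = {}
    selections: dict[str, list[SignedRegulator]] = {}
    for target in ds.gene_ids:
        cand = candidate_set(m, target, mode=mic_mode, fixed_value=mic_threshold)
        candidates[target] = cand
        scores = score_all_pairs(ds, m, target, cand, cfg, use_rrs=use_rrs,
                                 effect_mode=effect_mode)
        pair_scores[target] = scores
        if scores:
            selections[target] = select_regulators(
                scores, mode=selection_mode, nrs_threshold=nrs_threshold, k=top_k,
                gene_order=ds.gene_ids, mic_lookup=m,
            )
        else:
            selections[target] = []
        log.append(
            f"target={target} mic_threshold_used={cand.threshold_used:.6g}"
            f" candidates={len(cand)} pairs={len(scores)}"
            f" selected={len(selections[target])}"
        )

    reduction = combinatorial_reduction([len(c) for c in candidates.values()], ds.n_genes)
    log.append(f"combinatorial_reduction_percent={reduction:.4f}")
    net = assemble_network(selections, ds.gene_ids)
    log.append(f"edges={len(net.edges)}")
    return InferenceResult(
        network=net,
        mic=m,
        candidates=candidates,
        pair_scores=pair_scores,
        selections=selections,
        reduction_percent=reduction,
        config_digest=cfg.digest(),
        log_lines=log,
    )
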