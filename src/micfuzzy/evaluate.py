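"""Network assembly, topology evaluation and combinatorial-cost accounting.

Evaluation compares the inferred directed network against a gold standard
over all n(n-1) ordered non-self gene pairs.  Edge signs are ignored in
the confusion counts (DREAM gold standards are unsigned); a separate sign
accuracy is available when a signed truth is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fuzzy import SignedRegulator
from .io import GoldStandard

__all__ = [
    "InferredNetwork",
    "EvaluationReport",
    "assemble_network",
    "confusion",
    "metrics",
    "sign_accuracy",
    "combinatorial_reduction",
    "write_network",
    "read_network",
]


@dataclass
class InferredNetwork:
    """Signed directed network: at most one edge per (regulator, target)."""

    gene_universe: list[str]
    edges: dict[tuple[str, str], SignedRegulator] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for (reg, tgt), e in self.edges.items():
            if reg == tgt:
                raise ValueError(f"self-loop ({reg}, {tgt}) in inferred network")
            if reg not in universe or tgt not in universe:
                raise ValueError(f"edge ({reg}, {tgt}) outside the gene universe")
            if (e.regulator, e.target) != (reg, tgt):
                raise ValueError("edge key does not match edge record")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


@dataclass
class EvaluationReport:
    """Confusion counts and derived topology metrics.

    Ratio metrics with a zero denominator are reported as 0 and the metric
    name is listed in ``degenerate``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    tpr: float
    fpr: float
    specificity: float
    f_score: float
    ss_mean: float
    mcc: float
    structural_accuracy: float
    ss_mean_kind: str = "harmonic"
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "tpr": self.tpr, "fpr": self.fpr,
            "specificity": self.specificity, "f_score": self.f_score,
            "ss_mean": self.ss_mean, "mcc": self.mcc,
            "structural_accuracy": self.structural_accuracy,
        }

    def summary(self) -> str:
        d = self.as_dict()
        counts = "  ".join(f"{k.upper()}={int(d[k])}" for k in ("tp", "fp", "tn", "fn"))
        rates = "  ".join(
            f"{k}={d[k]:.4f}"
            for k in ("precision", "tpr", "fpr", "specificity", "f_score",
                      "ss_mean", "mcc", "structural_accuracy")
        )
        return counts + "\n" + rates


def assemble_network(
    selections: Iterable[SignedRegulator] | Mapping[str, Sequence[SignedRegulator]],
    gene_universe: Sequence[str],
) -> InferredNetwork:
    """Union of per-target selections into one network.

    Duplicate (regulator, target) edges with conflicting signs are
    resolved to the occurrence with the lower residual score (logged via
    a warning); equal-sign duplicates keep the minimum-RS record.
    """
    if isinstance(selections, Mapping):
        flat: list[SignedRegulator] = [e for sel in selections.values() for e in sel]
    else:
        flat = list(selections)
    edges: dict[tuple[str, str], SignedRegulator] = {}
    for e in flat:
        key = (e.regulator, e.target)
        prev = edges.get(key)
        if prev is None:
            edges[key] = e
            continue
        winner = e if e.rs < prev.rs else prev
        if prev.sign != e.sign:
            warnings.warn(
                f"conflicting signs for edge {key}; keeping lower-RS sign {winner.sign!r}",
                UserWarning, stacklevel=2,
            )
        edges[key] = winner
    return InferredNetwork(gene_universe=list(gene_universe), edges=edges)


def confusion(net: InferredNetwork, gold: GoldStandard) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) over all ordered non-self pairs; signs ignored."""
    if set(net.gene_universe) != set(gold.gene_universe):
        raise ValueError("inferred network and gold standard have different gene universes")
    genes = net.gene_universe
    predicted = net.edge_set
    true = gold.edges
    tp = fp = tn = fn = 0
    for reg in genes:
        for tgt in genes:
            if reg == tgt:
                continue
            p = (reg, tgt) in predicted
            t = (reg, tgt) in true
            if p and t:
                tp += 1
            elif p:
                fp += 1
            elif t:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def metrics(
    counts: tuple[int, int, int, int], ss_mean_kind: str = "harmonic"
) -> EvaluationReport:
    """Topology metrics from (tp, fp, tn, fn) confusion counts.

    ``ss_mean_kind`` selects how sensitivity and specificity are combined
    into SS_mean: "harmonic" (default), "geometric" or "arithmetic".
    """
    tp, fp, tn, fn = counts
    if min(counts) < 0:
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all confusion counts are zero")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    tpr = ratio(tp, tp + fn, "tpr")
    fpr = ratio(fp, fp + tn, "fpr")
    specificity = 1.0 - fpr
    f_score = ratio(2 * precision * tpr, precision + tpr, "f_score")
    if ss_mean_kind == "harmonic":
        ss_mean = ratio(2 * tpr * specificity, tpr + specificity, "ss_mean")
    elif ss_mean_kind == "geometric":
        ss_mean = float(np.sqrt(tpr * specificity))
    elif ss_mean_kind == "arithmetic":
        ss_mean = (tpr + specificity) / 2.0
    else:
        raise ValueError(f"unknown ss_mean kind: {ss_mean_kind!r}")
    mcc_den = float(np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    structural_accuracy = (tp + tn) / sum(counts)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, tpr=tpr, fpr=fpr, specificity=specificity,
        f_score=f_score, ss_mean=ss_mean, mcc=mcc,
        structural_accuracy=structural_accuracy,
        ss_mean_kind=ss_mean_kind, degenerate=degenerate,
    )


def sign_accuracy(
    net: InferredNetwork, signed_truth: Mapping[tuple[str, str], str]
) -> float:
    """Fraction of correctly signed edges among recovered true edges.

    ``signed_truth`` maps (regulator, target) to "+" or "-".  Returns NaN
    if the network recovers no true edge.
    """
    hits = [key for key in net.edges if key in signed_truth]
    if not hits:
        return float("nan")
    correct = sum(1 for key in hits if net.edges[key].sign == signed_truth[key])
    return correct / len(hits)


def combinatorial_reduction(candidate_sizes: Sequence[int], n: int) -> float:
    """Percentage reduction in scored pairs versus the unfiltered model.

    Without screening, every target would be scored against all ordered
    activator-repressor pairs from the remaining genes: n(n-1)(n-2)
    evaluations.  With per-target candidate sets of sizes m_g the fuzzy
    stage scores sum of m_g(m_g - 1) pairs.
    """
    if n < 3:
        raise ValueError("reduction is defined for n >= 3 genes")
    classical = n * (n - 1) * (n - 2)
    filtered = sum(m * (m - 1) for m in candidate_sizes)
    return 100.0 * (1.0 - filtered / classical)


# ---------------------------------------------------------------------------
# network files


def write_network(net: InferredNetwork, path: str | Path) -> None:
    """TSV: regulator, target, sign, rs, nrs, mic (one row per edge)."""
    lines = ["regulator\ttarget\tsign\trs\tnrs\tmic"]
    for (reg, tgt) in sorted(net.edges, key=lambda k: (net.gene_universe.index(k[1]),
                                                       net.gene_universe.index(k[0]))):
        e = net.edges[(reg, tgt)]
        lines.append(f"{reg}\t{tgt}\t{e.sign}\t{e.rs:.12g}\t{e.nrs:.12g}\t{e.mic:.12g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network(path: str | Path, gene_universe: Sequence[str] | None = None) -> InferredNetwork:
    """Read a network TSV written by :func:`write_network`.

    If no universe is given, it is taken to be the genes mentioned by the
    edges, in order of appearance.
    """
    edges: dict[tuple[str, str], SignedRegulator] = {}
    seen: list[str] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("regulator\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns")
        reg, tgt, sign, rs, nrs, mic_s = fields
        edges[(reg, tgt)] = SignedRegulator(
            regulator=reg, target=tgt, sign=sign,
            rs=float(rs), nrs=float(nrs), mic=float(mic_s),
        )
        for g in (reg, tgt):
            if g not in seen:
                seen.append(g)
    return InferredNetwork(gene_universe=list(gene_universe or seen), edges=edges)
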