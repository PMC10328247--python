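"""Score a predicted network against a known edge list, file to file.

Writes a small gold standard and a predicted network to disk in the TSV
formats the tool exchanges, reads them back, and prints the full metric
report — the same computation as `micfuzzy eval`.
"""

import tempfile
from pathlib import Path

from micfuzzy import confusion, metrics
from micfuzzy.evaluate import assemble_network, read_network, write_network
from micfuzzy.fuzzy import SignedRegulator
from micfuzzy.io import read_goldstandard

genes = [f"g{i}" for i in range(8)]
# 9 known regulations in an 8-gene module
gold_edges = [("g0", f"g{i}") for i in range(1, 8)] + [("g1", "g0"), ("g2", "g0")]
# a prediction recovering 6 of them plus 8 spurious edges
predicted = [("g0", f"g{i}") for i in range(1, 6)] + [("g1", "g0")]
predicted += [("g3", "g4"), ("g4", "g3"), ("g5", "g6"), ("g6", "g5"),
              ("g7", "g1"), ("g1", "g7"), ("g2", "g3"), ("g3", "g2")]

with tempfile.TemporaryDirectory() as tmp:
    gold_path = Path(tmp) / "gold.tsv"
    net_path = Path(tmp) / "net.tsv"
    gold_path.write_text("".join(f"{r}\t{t}\t1\n" for r, t in gold_edges))
    net = assemble_network(
        [SignedRegulator(r, t, "+", 0.0, 0.0) for r, t in predicted], genes)
    write_network(net, net_path)

    gold = read_goldstandard(gold_path, genes)
    pred = read_network(net_path, gene_universe=genes)
    report = metrics(confusion(pred, gold))

print(report.summary())
# Precision counts how many predicted edges are real; TPR (recall) how many
# real edges were found.  The F-score balances the two, and MCC/structural
# accuracy additionally reward the (many) correctly absent edges.
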