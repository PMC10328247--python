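"""Step through the fuzzy stage by hand on a single timepoint.

Shows fuzzification of a regulatory effect, rule firing for an
(activator, repressor) input pair, bounded-sum aggregation and centroid
defuzzification — the computation the pair scorer repeats at every
timepoint of every candidate triplet.
"""

from micfuzzy import FuzzyConfig, defuzzify, infer_target_level, input_membership

cfg = FuzzyConfig()

# 1. fuzzification: a normalized regulatory effect of 0.4
low, med, high = input_membership(0.4, cfg)
print(f"effect 0.4 fuzzifies to Low={low:.1f}, Medium={med:.1f}, High={high:.1f}")

# 2. a saturated activator with a silent repressor fires only (High, Low)
agg, firing = infer_target_level(1.0, 0.0, cfg)
print("firing strengths (rows=activator level, cols=repressor level):")
for row in firing:
    print("   ", "  ".join(f"{v:.2f}" for v in row))
print(f"defuzzified target level: {defuzzify(agg, cfg):.4f}"
      "  (centroid of the Very High output triangle)")

# 3. a mixed input engages several rules at once
agg, firing = infer_target_level(0.4, 0.4, cfg)
fired = int((firing > cfg.firing_epsilon).sum())
print(f"effects (0.4, 0.4) fire {fired} rules; "
      f"defuzzified target level: {defuzzify(agg, cfg):.4f}")
# The first output sits at the top of the scale because a strong activator
# with no repression predicts maximal expression; the mixed case lands near
# the middle because opposing rules pull the centroid toward 0.5.
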