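"""Why the cyclic (reglucosylating) architecture wins at low production.

Computes the folding efficiency f*max (maximum folding fraction at total
unfolded protein = 1) for the physiological cycle and the three variants
that cannot restore the glucose tag, at a low production rate.
"""

from glycoqc import Conditions, OptimizationProblem, VARIANTS, folding_efficiency

conditions = Conditions(kpt=0.3, mf=0.001, kf=1.0, Pb=1.0)
results = {}
for name in ("PHYS", "WB", "WBSV", "OS"):
    problem = OptimizationProblem(VARIANTS[name], conditions, starts=8, seed=0)
    results[name] = folding_efficiency(problem).objective
    print(f"{name:5s} f*max = {results[name]:.4f}")

for name in ("WB", "WBSV", "OS"):
    print(f"PHYS / {name} = {results['PHYS'] / results[name]:.3f}")
# The non-recycling variants are capped near kf/(kf+kr) = 0.5 (one
# chaperone visit per protein), so the physiological cycle folds roughly
# twice as many proteins per unit of production.
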