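"""The four Fisher-exact constructions used by the pipeline, on tiny tables.

Every statistical gate is a 2x2 Fisher test; only the table construction
differs: junction background expression, variant-vs-error significance,
ALT-frequency consistency and variant-junction association.
"""

from svase.assoc import AssocParams, association_test, consistency_check
from svase.junctions import Junction, JunctionParams, background_test
from svase.variants import VariantCandidate, VariantParams, variant_significance

# 1. background expression: is this junction's read share above a 1% floor?
j = Junction("chr1", 100, 200, supporting={f"r{i}" for i in range(10)})
rel = Junction("chr1", 150, 200, supporting={f"s{i}" for i in range(10)})
p = background_test(j, [rel], JunctionParams())
print(f"background: depth 10 of 20 related reads -> p={p:.3g} "
      "(well above a 1% background share, junction kept)")

# 2. variant significance: 5 ALT in depth 30 vs the Q30 error expectation
cand = VariantCandidate("chr1", 110, "G", "A", j.key, "left", 30, 5)
p = variant_significance(cand, VariantParams())
print(f"variant: 5/30 ALT vs error rate 0.001 -> p={p:.3g} "
      "(far more ALT than sequencing error explains)")

# 3. consistency: target 3/6 ALT vs related 3/6 ALT -> same frequency
ok = consistency_check((3, 3), (3, 3), AssocParams())
print(f"consistency of equal ALT fractions: {ok} "
      "(association will use target-junction reads only)")

# 4. association: 2 ALT in junction reads, 0 of 5 elsewhere
p, no_contrast = association_test((2, 0), (0, 5), AssocParams())
print(f"association: ALT confined to junction reads -> p={p:.4f} "
      f"(= 1/21; kept at alpha 0.05, no_contrast={no_contrast})")
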