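"""Generate a synthetic spliced-RNA-seq dataset and run the full caller.

Plants 10 junction-private variants at ALT fraction 0.9 across 40 GT-AG
junctions, runs QC -> junction discovery -> per-side variant calling ->
association, and scores the emitted associations against the truth table.
"""

from svase.pipeline import call_svase
from svase.simdata import SimConfig, evaluate, simulate, to_aligned_reads

cfg = SimConfig(seed=7, chrom_len=250_000, n_junctions=40, n_variants=10)
sim = simulate(cfg)
print(f"simulated {len(sim.reads)} reads over {len(sim.truth.junctions)} junctions, "
      f"{len(sim.truth.variants)} planted variants")

result = call_svase(sim.genome, to_aligned_reads(sim))
print(f"stage counts: {result.stage_counts}")

for r in result.records[:3]:
    print(f"  {r.chrom}:{r.pos + 1} {r.ref}>{r.alt}  junction "
          f"{r.junction[1]}-{r.junction[2]} ({r.side} part)  "
          f"ALT {r.alt_count}/{r.depth}  p_var={r.p_variant:.2e}  "
          f"p_assoc={r.p_association:.2e}")
print("  ... each line is one variant whose ALT allele is confined to the"
      " reads supporting one splicing junction")

m = evaluate(result.records, sim.truth)
print(f"recall {m['recall']:.2f}, precision {m['precision']:.2f} "
      f"against the planted truth — both should be 1.00 at these settings")
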