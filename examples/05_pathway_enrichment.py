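"""Over-representation analysis of a differential-metabolite hit list.

Tests each pathway of the packaged demo collection for excess overlap
with the hits (hypergeometric upper tail, BH-adjusted).  An adjusted
p < 0.05 marks a pathway as over-represented among the changed
metabolites relative to the quantified background.
"""

from gestox import enrich, synth

background = synth.build_default_library("plasma").names
hits = ["Citrate", "cis-Aconitate", "Fumarate", "Pyruvate", "Acetoacetate"]

pathways = enrich.load_demo_pathways()
results = enrich.ora(hits, background, pathways)

print(f"{len(hits)} hits against a background of {len(background)} "
      f"quantified metabolites, {len(results)} pathways tested\n")
print(f"{'pathway':<28s} {'overlap':>7s} {'size':>4s} {'p':>9s} {'adj p':>9s}")
for r in results:
    print(f"{r.name[:28]:<28s} {r.overlap:>7d} {r.pathway_size:>4d} "
          f"{r.p_value:>9.2e} {r.adjusted_p:>9.2e}")
print("\n'overlap' = hits inside the pathway; 'size' = pathway members "
      "present in the background")
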