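"""Gene-set over-representation of a DEG list.

Builds a small universe and gene-set library, tests each set with a
one-sided Fisher exact test and BH-adjusts within the library.  The
union of query genes inside significant sets seeds the PPI stage.
"""

from fflpipe import GeneSetLibrary, enriched_union, fisher_enrich

universe = [f"G{i:03d}" for i in range(100)]
query = universe[:10]  # the DEG list
library = GeneSetLibrary("pathways", {
    "protease_inhibition": frozenset(universe[:5]),       # 5/5 in query
    "mucin_production": frozenset(universe[5:9] + universe[40:48]),
    "unrelated_process": frozenset(universe[60:75]),
})

results = fisher_enrich(query, library, universe, enrich_alpha=0.05)
print(results[["set_name", "a", "p", "bh_p", "significant"]].to_string(index=False))
# a = overlap size; p is the hypergeometric upper tail P(X >= a); sets
# with bh_p < 0.05 are called enriched.

union = enriched_union([results], query)
print(f"union of DEGs in enriched sets (PPI seeds): {sorted(union)}")
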