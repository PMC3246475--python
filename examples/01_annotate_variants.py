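"""Annotate a handful of coding variants against the bundled gene model.

Each HGVS-c description is parsed and classified into a strand-normalized
base-pair category (G>A and C>T both count as G:C>A:T), with G:C>A:T
transitions split by CpG context, a predicted protein effect, and
hotspot / PAH-adduct-site flags from the codon sets.
"""

from tp53spectrum import annotate_mutation, parse_variant, toy_gene_model

model = toy_gene_model()

variants = [
    "c.524G>A",    # codon 175 (hotspot), CpG transition
    "c.733C>A",    # codon 245 (hotspot + PAH site), transversion
    "c.469C>A",    # codon 157 (PAH site), transversion
    "c.375+1G>T",  # splice-junction change
    "c.386_387delCT",
]

print(f"{'variant':>16} {'category':>10} {'effect':>9} codon exon hotspot PAH")
for desc in variants:
    rec = annotate_mutation(model, parse_variant(desc, sample_id="demo"))
    print(f"{desc:>16} {rec.category:>10} {rec.effect:>9} "
          f"{str(rec.codon):>5} {str(rec.exon):>4} {str(rec.is_hotspot):>7} "
          f"{rec.is_pah_site}")

# The category is what the spectrum analysis counts; the effect is what
# the IHC analysis uses (missense protein accumulates and stains positive,
# nonsense/frameshift/splice predict absent protein).
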