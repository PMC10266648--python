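"""Intron typing and the intron-B vs codon-1534 mutation association.

Uses the bundled 2020 Shanghai survey counts (638 intron-typed
mosquitoes) to build the 2x2 table of intron A/B against 1534
wild-homozygous vs mutant-carrying individuals (among 1532 I/I), and
tests independence with Pearson's chi-square.
"""

from kdrsurv import chi_square
from kdrsurv.popstats import intron_mutation_2x2
from kdrsurv.surveys import load_intron_genotype_counts

counts = load_intron_genotype_counts()
print("individuals per intron type x genotype class:")
print(counts.to_string())

table = intron_mutation_2x2(counts)
res = chi_square(table)
print(f"\n2x2 (rows A/B, cols 1534 wild-hom/mutant): {table.astype(int).tolist()}")
print(f"chi-square = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.3g}")
print(
    "\nMosquitoes carrying the 68 bp intron B are overwhelmingly 1534\n"
    "mutants, while the 83 bp intron A travels with the wild-type codon —\n"
    "a p-value this small rejects independence at any conventional level."
)
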