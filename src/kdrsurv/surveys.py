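"""Bundled summary tables from a 2020 Aedes albopictus kdr survey in Shanghai.

Sixteen field populations (658 genotyped mosquitoes) were surveyed for
VGSC mutations at codons 1016, 1532 and 1534; 638 of them were typed for
the Domain III intron, and 2021 district-level pyrethroid usage was
recorded for 14 districts.  These published per-population frequencies
and counts serve two purposes here: they parameterise the "paperlike"
simulator preset, and they are the inputs from which the headline
population statistics are recomputed through the same operations the
pipeline applies to fresh genotype calls.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

_DATA = files("kdrsurv.data")

#: aa-genotype column labels per site, in reporting order.
GENOTYPE_CLASSES = {
    1016: ["V/V", "V/G", "G/G"],
    1532: ["I/I", "I/T", "T/T"],
    1534: ["F/F", "F/S", "S/C", "S/I", "S/S", "C/C"],
}

#: codon-allele column labels per site, in reporting order.
ALLELE_CLASSES = {
    1016: ["GTA", "GGA"],
    1532: ["ATC", "ACC"],
    1534: ["TTC", "TTT", "TCC", "TGC", "ATC"],
}


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mutation_frequency() -> pd.DataFrame:
    """Per-population sample size and kdr mutant-carrier frequency (%)."""
    return _read("mutation_frequency.tsv")


def load_codon_genotypes(site: int) -> pd.DataFrame:
    """Per-population allele and genotype frequencies (%) at one codon.

    Includes the published pooled ``Total`` row.
    """
    if site not in GENOTYPE_CLASSES:
        raise KeyError(f"no bundled genotype table for codon {site}")
    return _read(f"genotypes_{site}.tsv")


def load_intron_genotype_counts() -> pd.DataFrame:
    """Individuals per intron type x (1532, 1534) genotype class (n=638)."""
    return _read("intron_genotype_counts.tsv").set_index("intron")


def load_district_usage() -> pd.DataFrame:
    """District area, pyrethroid grams, and observed mutation frequencies."""
    return _read("district_usage.tsv")
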