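"""Shared fixtures: catalog, references, simulated cohorts, decode oracle."""

from __future__ import annotations

import itertools

import pytest

from kdrsurv import default_catalog, default_references
from kdrsurv import synth
from kdrsurv._iupac import IUPAC_TO_BASES


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def references(catalog):
    return default_references(catalog)


#: a mixed-frequency test population touching every catalogued 1534 allele
MIXED_FREQS = {
    1016: {"GTA": 0.85, "GGA": 0.15},
    1532: {"ATC": 0.93, "ACC": 0.07},
    1534: {"TTC": 0.30, "TTT": 0.02, "TCC": 0.60, "TGC": 0.06, "ATC": 0.02},
}


def make_config(code="SIM", n=50, seed=11, noise_rate=0.0, freqs=None, intron_cond=None):
    return synth.PopulationSimConfig(
        population_code=code,
        n_individuals=n,
        allele_freqs=freqs or {s: dict(f) for s, f in MIXED_FREQS.items()},
        intron_given_1534=intron_cond,
        noise_rate=noise_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def simulated_cohort(catalog, references):
    """Truth records + rendered sequences for a 120-mosquito population."""
    cfg = make_config(n=120, seed=23)
    records, sequences = synth.simulate_population(cfg, catalog, references)
    return cfg, records, sequences


# ---------------------------------------------------------------------------
# independent diploid-decoding oracle

ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
_UNORDERED = [
    (x, y) for i, x in enumerate(ALL_CODONS) for y in ALL_CODONS[i:]
]
_PAIRSET = {
    (a, b): frozenset((a, b)) for a in "ACGT" for b in "ACGT"
}


def oracle_window_pairs(window: str) -> set[tuple[str, str]]:
    """Exhaustive enumeration: all unordered codon pairs whose per-position
    base sets equal the window's IUPAC base sets (64 x 64 filter)."""
    sets = [frozenset(IUPAC_TO_BASES[b]) for b in window]
    out = set()
    for x, y in _UNORDERED:
        if (
            _PAIRSET[x[0], y[0]] == sets[0]
            and _PAIRSET[x[1], y[1]] == sets[1]
            and _PAIRSET[x[2], y[2]] == sets[2]
        ):
            out.add((x, y))
    return out


ALL_WINDOWS = ["".join(w) for w in itertools.product(IUPAC_TO_BASES, repeat=3)]


@pytest.fixture(scope="session")
def window_oracle():
    """Pair enumeration for every one of the 3375 IUPAC codon windows."""
    return {w: oracle_window_pairs(w) for w in ALL_WINDOWS}
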