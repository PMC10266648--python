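"""Frequency tables, pooled statistics, chi-square and Pearson correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kdrsurv import genotype, popstats, surveys, synth
from kdrsurv.popstats import (
    allele_freq_from_genotype_classes,
    allele_frequencies,
    chi_square,
    combination_table,
    genotype_frequencies,
    intron_mutation_2x2,
    mutation_frequency,
    pearson_correlation,
    pooled_rate,
    usage_density,
)

from conftest import make_config


def _calls_frame(rows):
    """Minimal calls table from (pop, aa1016, aa1532, aa1534, zyg..., carrier)."""
    out = []
    for i, (pop, g16, g32, g34, carrier) in enumerate(rows):
        rec = {"population": pop, "individual": f"{pop}{i}", "mutant_carrier": carrier}
        for site, aa in ((1016, g16), (1532, g32), (1534, g34)):
            rec[f"{site}_aa"] = aa or ""
            rec[f"{site}_resolution"] = "unique" if aa else "failed"
            wild = {1016: "V", 1532: "I", 1534: "F"}[site]
            pair = (aa or "/").split("/")
            zyg = ""
            if aa:
                muts = [p != wild for p in pair]
                if not any(muts):
                    zyg = "wild_hom"
                elif all(muts):
                    zyg = "mut_hom" if pair[0] == pair[1] else "mut_het"
                else:
                    zyg = "het_wild_mut"
            rec[f"{site}_zygosity"] = zyg
            codon = {
                "V": "GTA", "G": "GGA", "I": "ATC", "T": "ACC",
                "F": "TTC", "S": "TCC", "C": "TGC",
            }
            rec[f"{site}_alleles"] = (
                "/".join(codon.get(p, "NNN") for p in pair) if aa else ""
            )
        out.append(rec)
    return pd.DataFrame(out)


def test_genotype_frequencies_arithmetic():
    rows = (
        [("JD", "V/V", "I/I", "S/S", True)] * 19
        + [("JD", "V/V", "I/I", "F/S", True)] * 19
        + [("JD", "V/V", "I/I", "F/F", False)] * 2
    )
    table = genotype_frequencies(_calls_frame(rows), 1534)
    jd = table[table.population == "JD"].set_index("genotype")["pct"]
    assert jd["S/S"] == pytest.approx(47.50)
    assert jd["F/S"] == pytest.approx(47.50)
    assert jd["F/F"] == pytest.approx(5.00)


def test_all_wild_cohort_is_all_ff():
    rows = [("FX", "V/V", "I/I", "F/F", False)] * 37
    table = genotype_frequencies(_calls_frame(rows), 1534)
    fx = table[table.population == "FX"]
    assert list(fx.genotype) == ["F/F"]
    assert fx.pct.iloc[0] == pytest.approx(100.0)


def test_empty_cohort_gives_empty_table():
    table = genotype_frequencies(_calls_frame([]).reindex(
        columns=["population", "1534_aa", "1534_resolution"]), 1534)
    assert table.empty or (table["n"] == 0).all()


def test_single_mutant_homozygote_allele_frequency():
    rows = [("XX", "G/G", "I/I", "F/F", True)]
    table = allele_frequencies(_calls_frame(rows), 1016)
    xx = table[table.population == "XX"].set_index("allele")
    assert xx.loc["GGA", "pct"] == pytest.approx(100.0)


def test_allele_from_genotype_algebra_on_published_total_rows():
    t4 = {"V/V": 86.63, "V/G": 12.46, "G/G": 0.91}
    assert allele_freq_from_genotype_classes(t4)["G"] == pytest.approx(7.14)
    t6 = {"F/F": 22.04, "F/S": 27.96, "S/C": 1.52, "S/I": 0.30, "S/S": 47.87, "C/C": 0.30}
    freqs = allele_freq_from_genotype_classes(t6)
    assert freqs["S"] == pytest.approx(62.76)
    assert freqs["C"] == pytest.approx(1.06)
    assert freqs["I"] == pytest.approx(0.15)


def test_mutation_frequency_per_population_and_pooled():
    rows = [("QP", "V/V", "I/I", "F/S", True)] * 22 + [
        ("QP", "V/V", "I/I", "F/F", False)
    ] * 25
    mf = mutation_frequency(_calls_frame(rows))
    qp = mf[mf.population == "QP"].iloc[0]
    assert qp["n"] == 47 and qp["carriers"] == 22
    assert qp["pct"] == pytest.approx(46.81, abs=0.01)


def test_pooled_is_count_pooling_not_mean_of_percentages():
    rows = [("A", "V/G", "I/I", "F/F", True)] * 10 + [
        ("B", "V/V", "I/I", "F/F", False)
    ] * 90
    mf = mutation_frequency(_calls_frame(rows))
    total = mf[mf.population == "Total"].iloc[0]
    assert total["pct"] == pytest.approx(10.0)  # 10/100, not mean(100, 0) = 50


def test_pooled_rate_reconstructs_survey_total():
    df = surveys.load_mutation_frequency()
    carriers, pct = pooled_rate(df["n"], df["mutation_frequency_pct"])
    assert carriers == 557
    assert pct == pytest.approx(84.65, abs=0.01)


def test_count_conservation_on_simulated_population(catalog, references):
    cfg = make_config(n=100, seed=8)
    records, sequences = synth.simulate_population(cfg, catalog, references)
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    calls = genotype.records_to_frame(
        genotype.call_dataset(
            [SeqRecord(Seq(s), id=h, description="") for h, s in sequences],
            references,
            catalog,
        )
    )
    for site in (1016, 1532, 1534):
        g = genotype_frequencies(calls, site)
        a = allele_frequencies(calls, site)
        g_tot = g[g.population == "Total"]
        a_tot = a[a.population == "Total"]
        n = g_tot["n"].iloc[0]
        assert g_tot["count"].sum() == n
        assert a_tot["count"].sum() == 2 * n
        # allele-from-genotype identity, exactly on counts
        derived = allele_freq_from_genotype_classes(
            dict(zip(g_tot.genotype, g_tot["count"]))
        )
        allele_counts = dict(zip(a_tot.allele, a_tot["count"]))
        for aa, cnt in derived.items():
            direct = sum(
                c
                for al, c in allele_counts.items()
                if catalog.classify(site, al).amino_acid == aa
            ) / 2
            assert cnt == pytest.approx(direct)


def test_combination_table_counts_multi_site_patterns():
    rows = (
        [("CN", "V/G", "I/I", "F/S", True)] * 7
        + [("CN", "V/V", "I/I", "F/S", True)] * 3
        + [("CN", "V/V", "I/I", "F/F", False)] * 30
    )
    patterns, wild_hom = combination_table(_calls_frame(rows))
    assert len(patterns) == 1
    row = patterns.iloc[0]
    assert (row["1016"], row["1534"], row["count"]) == ("V/G", "F/S", 7)
    assert wild_hom["CN"] == 30


def test_all_wild_cohort_has_no_combinations():
    rows = [("AA", "V/V", "I/I", "F/F", False)] * 12
    patterns, wild_hom = combination_table(_calls_frame(rows))
    assert patterns.empty
    assert wild_hom["AA"] == 12


# ---------------------------------------------------------------------------
# statistics

def test_homogeneous_table_gives_zero_statistic():
    res = chi_square([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_survey_intron_2x2_and_its_chi_square():
    counts = surveys.load_intron_genotype_counts()
    table = intron_mutation_2x2(counts)
    assert table.tolist() == [[67.0, 9.0], [53.0, 465.0]]
    res = chi_square(table)
    assert res.p_value < 1e-4
    assert res.df == 1


def _brute_chi2(obs):
    obs = np.asarray(obs, float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.lists(st.integers(min_value=1, max_value=80), min_size=2, max_size=4),
        min_size=2,
        max_size=3,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_chi_square_matches_textbook_formula(rows):
    res = chi_square(rows)
    assert res.statistic == pytest.approx(_brute_chi2(rows), rel=1e-10)
    r, c = len(rows), len(rows[0])
    assert res.df == (r - 1) * (c - 1)
    assert res.p_value == pytest.approx(
        stats.chi2.sf(res.statistic, res.df), rel=1e-12
    )


def test_chi_square_rejects_degenerate_input():
    with pytest.raises(ValueError):
        chi_square([[1, 2]])
    with pytest.raises(ValueError):
        chi_square([[0, 0], [1, 2]])


def test_perfect_linear_relation():
    x = np.arange(10.0)
    res = pearson_correlation(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.p_value < 1e-30


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=4,
        max_size=20,
    ),
    st.randoms(use_true_random=False),
)
def test_pearson_matches_reference_implementation(xs, rnd):
    ys = [rnd.uniform(-100, 100) for _ in xs]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return
    res = pearson_correlation(xs, ys)
    ref_r, ref_p = stats.pearsonr(xs, ys)
    assert res.r == pytest.approx(ref_r, abs=1e-12)
    assert res.p_value == pytest.approx(ref_p, abs=1e-9)
    # p symmetric under negating one variable
    neg = pearson_correlation(xs, [-y for y in ys])
    assert neg.p_value == pytest.approx(res.p_value, abs=1e-12)
    assert neg.r == pytest.approx(-res.r, abs=1e-12)


def test_pearson_rejects_zero_variance():
    with pytest.raises(ValueError):
        pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])


def test_usage_density_published_examples():
    df = usage_density(surveys.load_district_usage())
    dens = df.set_index("district")["density_g_per_km2"]
    assert dens["Hongkou"] == pytest.approx(6006.24, abs=0.01)
    assert dens["Songjiang"] == pytest.approx(26.83, abs=0.01)


def test_usage_density_zero_grams_and_missing_area():
    df = pd.DataFrame(
        {
            "district": ["a", "b"],
            "area_km2": [10.0, 0.0],
            "pyrethroid_g": [0.0, 5.0],
        }
    )
    out = usage_density(df)
    assert list(out.district) == ["a"]  # zero-area row dropped
    assert out.density_g_per_km2.iloc[0] == 0.0
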