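"""Alignment, codon-window extraction and IUPAC diploid decoding."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdrsurv import genotype, intron, synth
from kdrsurv.genotype import (
    AmpliconRead,
    align_to_reference,
    call_dataset,
    call_individual,
    decode_diploid_codon,
    enumerate_window_pairs,
    extract_codon_window,
    records_to_frame,
)
from kdrsurv.intron import INTRON_SEQUENCES
from kdrsurv.refcat import UNCATALOGUED

from conftest import make_config


# ---------------------------------------------------------------------------
# alignment

def test_identity_read_maps_one_to_one(references):
    frag = references["DomainIII"]
    res = align_to_reference(frag.sequence, frag)
    assert res.ok and res.identity == 1.0
    assert all(res.position_map[p] == p for p in range(1, len(frag.sequence) + 1))


def test_ambiguity_code_matches_without_penalty(references):
    frag = references["DomainII"]
    read = list(frag.sequence)
    read[49] = "Y" if frag.sequence[49] in "CT" else "R"
    res = align_to_reference("".join(read), frag)
    assert res.ok and res.identity == 1.0


def test_intron_length_swap_keeps_exon_positions_mapped(references):
    """Replacing the 83 bp reference intron with the 68 bp type-B intron
    leaves every exon base 1:1 aligned and both codon windows recoverable."""
    frag = references["DomainIII"]
    seg = next(s for s in frag.segments if s.kind == "intron")
    read = (
        frag.sequence[: seg.start - 1]
        + INTRON_SEQUENCES["B"]
        + frag.sequence[seg.end :]
    )
    res = align_to_reference(read, frag)
    assert res.ok
    for s in (1532, 1534):
        window = extract_codon_window(res, frag, s, read)
        assert window in ("ATC", "TTC")
    # all exon positions are mapped, consecutively within each exon block
    for s in frag.segments:
        if s.kind != "exon":
            continue
        mapped = [res.position_map.get(p) for p in range(s.start, s.end + 1)]
        assert None not in mapped
        assert mapped == list(range(mapped[0], mapped[0] + len(mapped)))


def test_low_identity_read_fails_threshold(references):
    frag = references["DomainII"]
    res = align_to_reference("ACGT" * 60, frag)
    assert not res.ok


def test_truncated_read_fails_codon_extraction(references):
    frag = references["DomainII"]
    read = frag.sequence[:80]  # ends before codon 1016 at 100..102
    res = align_to_reference(read, frag, identity_threshold=0.2)
    assert extract_codon_window(res, frag, 1016, read) is None


# ---------------------------------------------------------------------------
# diploid decoding

@pytest.mark.parametrize(
    "site,window,pair,aa,zygosity",
    [
        (1534, "TYC", ("TTC", "TCC"), "F/S", "het_wild_mut"),
        (1534, "WYC", ("TCC", "ATC"), "S/I", "mut_het"),
        (1016, "GKA", ("GTA", "GGA"), "V/G", "het_wild_mut"),
        (1534, "TTY", ("TTC", "TTT"), "F/F", "wild_hom"),
        (1534, "TCC", ("TCC", "TCC"), "S/S", "mut_hom"),
        (1532, "AYC", ("ATC", "ACC"), "I/T", "het_wild_mut"),
    ],
)
def test_decode_known_windows(catalog, site, window, pair, aa, zygosity):
    call = decode_diploid_codon(window, catalog, site)
    assert call.resolution == "unique"
    assert call.allele_pair == pair
    assert call.aa_genotype == aa
    assert call.zygosity == zygosity


def test_synonymous_wild_het_is_noted(catalog):
    call = decode_diploid_codon("TTY", catalog, 1534)
    assert any("synonymous" in n for n in call.notes)


def test_n_in_window_fails(catalog):
    assert decode_diploid_codon("TNC", catalog, 1534).resolution == "failed"


def test_novel_allele_channel_single_explanation(catalog):
    # homozygous uncatalogued codon: one explanation, flagged
    call = decode_diploid_codon("ACC", catalog, 1534)
    assert call.resolution == "unique"
    assert call.allele_pair == ("ACC", "ACC")
    assert any("uncatalogued" in n for n in call.notes)


def test_decode_matches_exhaustive_oracle_on_all_windows(catalog, window_oracle):
    """Against brute force over all 64x64 codon pairs, on every IUPAC window.

    The expected outcome is derived here independently: unique iff exactly
    one fully catalogued pair survives, or no catalogued pair survives and
    the window has a single explanation at all; ambiguous otherwise;
    failed when no pair can explain the window.
    """
    site = 1534
    for window, pairs in window_oracle.items():
        catalogued = {
            p
            for p in pairs
            if catalog.classify(site, p[0]).status != UNCATALOGUED
            and catalog.classify(site, p[1]).status != UNCATALOGUED
        }
        call = decode_diploid_codon(window, catalog, site)
        if not pairs:
            assert call.resolution == "failed", window
        elif len(catalogued) == 1:
            assert call.resolution == "unique", window
            assert tuple(sorted(call.allele_pair)) in pairs
            assert set(call.allele_pair) == set(next(iter(catalogued)))
        elif len(catalogued) > 1:
            assert call.resolution == "ambiguous", window
            assert set(map(frozenset, call.candidates)) == set(
                map(frozenset, catalogued)
            )
        elif len(pairs) == 1:
            assert call.resolution == "unique", window
            assert set(call.allele_pair) == set(next(iter(pairs)))
        else:
            assert call.resolution == "ambiguous", window


def test_enumerate_window_pairs_equals_oracle(window_oracle):
    for window, pairs in window_oracle.items():
        if any(len(genotype.bases_of(b)) > 2 for b in window):
            with pytest.raises(ValueError):
                enumerate_window_pairs(window)
        else:
            assert set(enumerate_window_pairs(window)) == pairs


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=3, max_size=3))
def test_plain_window_always_homozygous(window):
    from kdrsurv import default_catalog

    call = decode_diploid_codon(window, default_catalog(), 1534)
    assert call.resolution == "unique"
    assert call.allele_pair[0] == call.allele_pair[1] == window


# ---------------------------------------------------------------------------
# per-individual and dataset calling

def _reads_for(records, sequences, individual_id):
    by_frag = {}
    for header, seq in sequences:
        r = AmpliconRead.from_header(header, seq)
        if r.individual == individual_id:
            by_frag.setdefault(r.fragment, []).append(r)
    return by_frag


def test_missing_fragment_fails_those_sites(catalog, references, simulated_cohort):
    _, records, sequences = simulated_cohort
    reads = _reads_for(records, sequences, records[0].individual_id)
    reads.pop("DomainIII")
    rec = call_individual(reads, references, catalog)
    assert rec.calls[1532].resolution == "failed"
    assert rec.calls[1534].resolution == "failed"
    assert rec.calls[1016].resolution == "unique"


def test_only_wild_domain_ii_read_is_not_a_carrier(catalog, references):
    frag = references["DomainII"]
    reads = {"DomainII": [AmpliconRead("P", "i1", "DomainII", frag.sequence)]}
    rec = call_individual(reads, references, catalog)
    assert rec.mutant_carrier is False
    assert rec.calls[1016].aa_genotype == "V/V"
    assert rec.calls[1534].resolution == "failed"


def test_duplicate_fragment_without_hap_flags_is_an_error(catalog, references):
    frag = references["DomainII"]
    r = AmpliconRead("P", "i1", "DomainII", frag.sequence)
    with pytest.raises(ValueError, match="hap"):
        call_individual({"DomainII": [r, r]}, references, catalog)


def test_end_to_end_truth_recovery_at_zero_noise(catalog, references, simulated_cohort):
    """Genotyping the rendered cohort reproduces every truth record exactly:
    all three codon pairs, the intron type pair, and the carrier flag."""
    _, records, sequences = simulated_cohort
    from Bio.SeqRecord import SeqRecord
    from Bio.Seq import Seq

    seq_records = [SeqRecord(Seq(s), id=h, description="") for h, s in sequences]
    called = call_dataset(seq_records, references, catalog)
    assert len(called) == len(records)
    by_id = {c.individual_id: c for c in called}
    for truth in records:
        c = by_id[truth.individual_id]
        for site in (1016, 1532, 1534):
            assert c.calls[site].resolution == "unique", (truth.individual_id, site)
            assert c.calls[site].allele_pair == truth.genotypes[site]
        assert intron.resolved_type_pair(c.intron_observations) == truth.introns
        assert c.mutant_carrier == truth.mutant_carrier


def test_raising_identity_threshold_never_genotypes_more(catalog, references):
    cfg = make_config(n=40, seed=31, noise_rate=0.03)
    records, sequences = synth.simulate_population(cfg, catalog, references)
    from Bio.SeqRecord import SeqRecord
    from Bio.Seq import Seq

    seq_records = [SeqRecord(Seq(s), id=h, description="") for h, s in sequences]

    def n_called(threshold):
        called = call_dataset(
            seq_records, references, catalog, identity_threshold=threshold
        )
        return sum(
            1
            for c in called
            if all(c.calls[s].resolution == "unique" for s in (1016, 1532, 1534))
        )

    counts = [n_called(t) for t in (0.80, 0.95, 0.985, 0.999)]
    assert counts == sorted(counts, reverse=True)


def test_records_to_frame_round_trips_key_columns(catalog, references, simulated_cohort):
    _, records, sequences = simulated_cohort
    from Bio.SeqRecord import SeqRecord
    from Bio.Seq import Seq

    called = call_dataset(
        [SeqRecord(Seq(s), id=h, description="") for h, s in sequences],
        references,
        catalog,
    )
    frame = records_to_frame(called)
    assert len(frame) == len(records)
    assert set(frame["population"]) == {"SIM"}
    assert frame["mutant_carrier"].dtype == bool
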