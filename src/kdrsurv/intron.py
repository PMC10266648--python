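"""Domain III intron typing for the Aedes albopictus VGSC gene.

The amplicon spanning codons 1532/1534 contains a single spliceosomal
intron whose length is polymorphic in field populations.  Introns are
classified into types by exact length — A (83 bp), B (68 bp), C (80 bp),
D (72 bp), E (70 bp) and F (67 bp) — and into sequence subtypes within a
length class.  Intron type co-segregates with the codon-1534 kdr
genotype, which is what the intron-by-genotype contingency table below
measures.

The subtype library shipped here is synthetic (same lengths, GT...AG
boundaries, fixed deterministic sequences); a real library can be
substituted wherever a ``{name: sequence}`` mapping is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .refcat import ReferenceFragment

#: Intron type -> exact length in bp.  Type A is the reference-length class.
INTRON_LENGTHS: dict[str, int] = {"A": 83, "B": 68, "C": 80, "D": 72, "E": 70, "F": 67}

_LENGTH_TO_TYPE = {v: k for k, v in INTRON_LENGTHS.items()}

#: Number of sequence subtypes per length class in the shipped library.
SUBTYPE_COUNTS: dict[str, int] = {"A": 6, "B": 6, "C": 1, "D": 1, "E": 2, "F": 1}

_BASES = np.array(list("ACGT"))


def _make_base_sequence(rng: np.random.Generator, length: int) -> str:
    inner = rng.choice(_BASES, size=length - 4)
    return "GT" + "".join(inner) + "AG"


def _variant(seq: str, index: int) -> str:
    """Derive subtype ``index`` (1-based) from the canonical sequence.

    Subtype 1 is the canonical sequence itself; higher subtypes differ by
    ``index - 1`` interior point substitutions, so subtypes of one type are
    always far closer to each other than to any other length class.
    """
    if index == 1:
        return seq
    s = list(seq)
    for k in range(index - 1):
        pos = 4 + 7 * k  # interior, clear of the GT...AG boundary
        order = "ACGT"
        s[pos] = order[(order.index(s[pos]) + 1 + k % 3) % 4]
    return "".join(s)


def _build_library() -> tuple[dict[str, str], dict[str, str]]:
    rng = np.random.default_rng(1789)
    canonical: dict[str, str] = {}
    library: dict[str, str] = {}
    for t in "ABCDEF":
        canonical[t] = _make_base_sequence(rng, INTRON_LENGTHS[t])
        for i in range(1, SUBTYPE_COUNTS[t] + 1):
            library[f"{t}{i}"] = _variant(canonical[t], i)
    return canonical, library


#: Canonical sequence per intron type (subtype 1 of each class).
INTRON_SEQUENCES, _SUBTYPE_LIBRARY = _build_library()


def subtype_library() -> dict[str, str]:
    """The shipped synthetic subtype library as ``{subtype_name: sequence}``."""
    return dict(_SUBTYPE_LIBRARY)


@dataclass
class IntronObservation:
    """One intron observed in one read (consensus or single haplotype)."""

    length: int
    type_label: str
    sequence: str
    subtype: str
    haplotype_resolved: bool = False
    individual_id: str | None = None
    warnings: list[str] = field(default_factory=list)


class IntronExtractionError(ValueError):
    """Raised when the intron cannot be cut out of an aligned read."""


def extract_intron(
    read: str,
    frag: "ReferenceFragment",
    position_map: Mapping[int, int | None],
) -> tuple[str, list[str]]:
    """Cut the intron out of an aligned read.

    ``position_map`` maps 1-based reference positions to 1-based read
    positions (``None`` where the read has a gap), as produced by
    :func:`kdrsurv.genotype.align_to_reference`.  The returned sequence is
    the read material strictly between the last base of the upstream exon
    and the first base of the downstream exon, whatever its length.

    Non-canonical (non GT...AG) boundaries produce a warning, not a
    failure: classification is by length alone.
    """
    introns = [s for s in frag.segments if s.kind == "intron"]
    if len(introns) != 1:
        raise IntronExtractionError(
            f"{frag.fragment_id} carries {len(introns)} introns; expected exactly 1"
        )
    seg = introns[0]
    up, down = seg.start - 1, seg.end + 1  # flanking exon bases on the reference
    q_up = position_map.get(up)
    q_down = position_map.get(down)
    if q_up is None or q_down is None:
        raise IntronExtractionError("intron flank not covered by the alignment")
    if q_down <= q_up:
        raise IntronExtractionError("intron flanks align out of order")
    seq = read[q_up : q_down - 1]  # 1-based positions -> slice between flanks
    warnings = []
    if not (seq[:2] == "GT" and seq[-2:] == "AG"):
        warnings.append("non-canonical splice boundaries (expected GT...AG)")
    return seq, warnings


def classify_intron(
    sequence: str,
    *,
    individual_id: str | None = None,
    haplotype_resolved: bool = False,
    library: Mapping[str, str] | None = None,
    warnings: Iterable[str] = (),
) -> IntronObservation:
    """Type an intron by exact length and subtype it by exact sequence.

    Length not in the catalogue -> type ``unknown``; a catalogued length
    with a sequence absent from the library -> subtype ``novel``.
    """
    lib = _SUBTYPE_LIBRARY if library is None else library
    length = len(sequence)
    type_label = _LENGTH_TO_TYPE.get(length, "unknown")
    subtype = "novel"
    for name, seq in lib.items():
        if seq == sequence:
            subtype = name
            break
    return IntronObservation(
        length=length,
        type_label=type_label,
        sequence=sequence,
        subtype=subtype,
        haplotype_resolved=haplotype_resolved,
        individual_id=individual_id,
        warnings=list(warnings),
    )


def resolved_type_pair(observations: list[IntronObservation]) -> tuple[str, str] | None:
    """The individual's two chromosomal intron types, when determinable.

    One consensus observation implies a length-homozygote (both
    chromosomes share the type); two haplotype observations give the pair
    directly.  Anything else is unresolvable.
    """
    if len(observations) == 1 and not observations[0].haplotype_resolved:
        t = observations[0].type_label
        return (t, t)
    if len(observations) == 2:
        return tuple(sorted(o.type_label for o in observations))  # type: ignore[return-value]
    return None


_CLASS_1532_ORDER = {c: i for i, c in enumerate(["I/I", "I/T", "T/T"])}
_CLASS_1534_ORDER = {
    c: i for i, c in enumerate(["F/F", "F/S", "S/S", "S/C", "S/I", "C/C"])
}


def _class_sort_key(label: str) -> tuple[int, int, str]:
    g1532, g1534 = label.split("+")
    return (
        _CLASS_1532_ORDER.get(g1532, 99),
        _CLASS_1534_ORDER.get(g1534, 99),
        label,
    )


def _build_genotype_table(rows: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Pivot (intron, g1532, g1534) tuples into a margined count table.

    Columns are ``"g1532+g1534"`` class labels in reporting order.
    """
    if not rows:
        table = pd.DataFrame(index=pd.Index([], name="intron"), dtype=int)
    else:
        df = pd.DataFrame(rows, columns=["intron", "g1532", "g1534"])
        df["class"] = df["g1532"] + "+" + df["g1534"]
        table = df.pivot_table(
            index="intron", columns="class", aggfunc="size", fill_value=0
        )
        table = table[sorted(table.columns, key=_class_sort_key)]
        table.columns.name = None
    table = table.sort_index()
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table.astype(int)


def intron_genotype_table(records) -> tuple[pd.DataFrame, int]:
    """Cross-tabulate intron type against the (1532, 1534) genotype class.

    ``records`` are :class:`kdrsurv.genotype.IndividualRecord`.  An
    individual enters the table with one intron type when both Domain III
    codon calls resolved uniquely and its intron type is unambiguous (a
    single consensus type, or two concordant haplotype types); all others
    — including individuals carrying two different intron types — are
    excluded and tallied, mirroring how a survey tabulates one intron per
    mosquito.  Returns ``(table, n_excluded)`` where the table carries a
    ``Total`` row and column margin.
    """
    rows: list[tuple[str, str, str]] = []
    excluded = 0
    for rec in records:
        c1532 = rec.calls.get(1532)
        c1534 = rec.calls.get(1534)
        ok_calls = (
            c1532 is not None
            and c1534 is not None
            and c1532.resolution == "unique"
            and c1534.resolution == "unique"
        )
        pair = resolved_type_pair(rec.intron_observations)
        if not ok_calls or pair is None or pair[0] != pair[1] or pair[0] == "unknown":
            excluded += 1
            continue
        rows.append((pair[0], c1532.aa_genotype, c1534.aa_genotype))
    return _build_genotype_table(rows), excluded


def intron_genotype_table_from_frame(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Same cross-tabulation, built from a flattened calls table."""
    rows: list[tuple[str, str, str]] = []
    excluded = 0
    for _, row in calls.iterrows():
        ok = (
            row.get("1532_resolution") == "unique"
            and row.get("1534_resolution") == "unique"
        )
        pair = str(row.get("intron_types", "") or "").split("/")
        concordant = (
            len(pair) == 2 and pair[0] == pair[1] and pair[0] not in ("", "unknown")
        )
        if not ok or not concordant:
            excluded += 1
            continue
        rows.append((pair[0], row["1532_aa"], row["1534_aa"]))
    return _build_genotype_table(rows), excluded


def intron_distance_matrix(library: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise Levenshtein distances between intron sequences."""
    names = list(library)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(library[names[i]], library[names[j]], task="distance")["editDistance"]
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)
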