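"""ITIM detection, binding-loop residue extraction, conservation summaries.

The canonical immunoreceptor tyrosine-based inhibition motif (ITIM) is the
6-mer (I/L/V/S)-x-Y-x-x-(L/V).  Inhibitory KIR carry two ITIMs in the
cytoplasmic tail, separated by ~25 residues; this module classifies each
slot as intact, substituted, truncated by a premature stop, or absent.

Binding-loop analysis projects a set of reference-numbered positions (the
ligand-contact loops characterised crystallographically for KIR3DL1)
through a protein alignment onto each taxon, then summarises per-position
conservation across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

ITIM_FIRST = {"I", "L", "V", "S"}
ITIM_LAST = {"L", "V"}


def is_canonical_itim(six: str) -> bool:
    """True iff the 6-mer matches (I/L/V/S)-x-Y-x-x-(L/V)."""
    return (
        len(six) == 6
        and six[0] in ITIM_FIRST
        and six[2] == "Y"
        and six[5] in ITIM_LAST
    )


@dataclass
class ItimCall:
    allele: str
    ordinal: int  # 1 = first ITIM, 2 = second
    start: int  # mature numbering, 1-based
    observed: str
    conforms: bool
    disruption: str  # none | substitution | premature_stop | absent


def scan_itims(
    protein: str,
    expected_positions: Sequence[int] | None = None,
    allele: str = "",
) -> list[ItimCall]:
    """Classify ITIM slots in a (mature-numbered) translated protein.

    With ``expected_positions`` (1-based starts of each ITIM slot), one
    call is emitted per slot, including ``premature_stop`` when a stop
    codon truncates the sequence at or before the slot and ``absent``
    when the protein simply ends early.  Without expected positions, all
    pattern matches in the sequence are reported.
    """
    stop_at = protein.find("*")  # index of first stop, -1 if none
    effective = protein if stop_at < 0 else protein[:stop_at]

    calls: list[ItimCall] = []
    if expected_positions is None:
        for i in range(len(effective) - 5):
            six = effective[i : i + 6]
            if is_canonical_itim(six):
                calls.append(ItimCall(allele, len(calls) + 1, i + 1, six, True, "none"))
        return calls

    for ordinal, pos in enumerate(expected_positions, start=1):
        i = pos - 1
        window = effective[i : i + 6]
        if len(window) == 6:
            conforms = is_canonical_itim(window)
            calls.append(
                ItimCall(allele, ordinal, pos, window, conforms,
                         "none" if conforms else "substitution")
            )
        elif stop_at >= 0 and stop_at <= i + 5:
            observed = protein[i : i + 6].replace("*", "x")
            calls.append(ItimCall(allele, ordinal, pos, observed, False, "premature_stop"))
        else:
            calls.append(ItimCall(allele, ordinal, pos, window, False, "absent"))
    return calls


@dataclass
class LoopResidueSet:
    """Named binding loops as lists of reference-mature positions."""

    loops: dict[str, list[int]]

    def __post_init__(self) -> None:
        for name, positions in self.loops.items():
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"loop {name}: positions not strictly increasing")

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.loops.values())

    @property
    def all_positions(self) -> list[int]:
        return [p for v in self.loops.values() for p in v]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LoopResidueSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(loops={k: list(map(int, v)) for k, v in cfg["loops"].items()})


def default_loop_set() -> LoopResidueSet:
    path = Path(__file__).parent / "data" / "kir3dl1_binding_loops.yaml"
    return LoopResidueSet.from_yaml(path)


def extract_loop_residues(
    alignment: Mapping[str, str],
    reference: str,
    loops: LoopResidueSet,
) -> dict[str, str]:
    """Project reference loop positions through the alignment onto each taxon.

    Positions are 1-based in the reference's ungapped (mature) sequence;
    a gap in a query at a projected column is reported as ``-``.
    """
    if reference not in alignment:
        raise ValueError(f"reference {reference!r} not in alignment")
    ref_row = alignment[reference]
    # reference residue index -> alignment column
    col_of: dict[int, int] = {}
    r = 0
    for col, aa in enumerate(ref_row):
        if aa != "-":
            r += 1
            col_of[r] = col
    ref_len = r
    cols = []
    for pos in loops.all_positions:
        if pos > ref_len:
            raise ValueError(f"loop position {pos} beyond reference length {ref_len}")
        cols.append(col_of[pos])
    return {name: "".join(row[c] for c in cols) for name, row in alignment.items()}


@dataclass
class ConservationSummary:
    positions: list[dict]
    n_conserved: int
    n_single_taxon_variant: int
    n_positions: int
    n_taxa: int


def conservation_count(
    residues: Mapping[str, str], ignore_gap_only_taxa: bool = False
) -> ConservationSummary:
    """Per-position conservation flags across taxa and aggregate counts.

    A position is fully conserved iff exactly one residue state is present
    (a gap counts as a distinct, non-conserved state unless
    ``ignore_gap_only_taxa``).  Positions where all taxa but one share a
    state are tallied separately as single-taxon variants.
    """
    lengths = {len(v) for v in residues.values()}
    if len(lengths) != 1:
        raise ValueError(f"residue string lengths differ: {sorted(lengths)}")
    (n,) = lengths
    taxa = list(residues)
    rows = []
    conserved = single = 0
    for i in range(n):
        column = [residues[t][i] for t in taxa]
        if ignore_gap_only_taxa:
            column = [c for c in column if c != "-"] or ["-"]
        states = set(column)
        is_cons = len(states) == 1
        is_single = False
        if not is_cons and len(column) > 2:
            from collections import Counter

            counts = Counter(column)
            top, top_n = counts.most_common(1)[0]
            is_single = top_n == len(column) - 1
        conserved += is_cons
        single += is_single
        rows.append(
            {
                "column": i + 1,
                "residues": "".join(column),
                "fully_conserved": is_cons,
                "single_taxon_variant": is_single,
                "n_taxa": len(column),
            }
        )
    return ConservationSummary(
        positions=rows,
        n_conserved=conserved,
        n_single_taxon_variant=single,
        n_positions=n,
        n_taxa=len(taxa),
    )


def per_position_variation(
    alignment: Mapping[str, str],
    domain_map=None,
    reference: str | None = None,
) -> list[dict]:
    """Polymorphic-position table over a mature-numbered protein alignment.

    For each polymorphic position: the domain label, the number of alleles
    differing from the majority residue ("diffs"), and whether more than
    one alternative residue exists.  Majority ties break toward the
    reference allele's residue when one is supplied.
    """
    from collections import Counter

    names = list(alignment)
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    (n,) = lengths
    rows = []
    for i in range(n):
        column = [alignment[t][i] for t in names if alignment[t][i] not in "-X*"]
        if len(set(column)) <= 1:
            continue
        counts = Counter(column)
        best = max(counts.values())
        tied = sorted(r for r, c in counts.items() if c == best)
        majority = tied[0]
        if reference is not None and len(tied) > 1:
            ref_res = alignment[reference][i]
            if ref_res in tied:
                majority = ref_res
        diffs = sum(c for r, c in counts.items() if r != majority)
        domain = domain_map.domain_of_mature(i + 1) if domain_map else ""
        rows.append(
            {
                "position": i + 1,
                "domain": domain,
                "majority": majority,
                "diffs": diffs,
                "multi_alternative": len(counts) > 2,
            }
        )
    return rows


def conservation_report(summary: ConservationSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tresidues\tfully_conserved\tsingle_taxon_variant\tn_taxa\n")
        for row in summary.positions:
            fh.write(
                f"{row['column']}\t{row['residues']}\t{int(row['fully_conserved'])}\t"
                f"{int(row['single_taxon_variant'])}\t{row['n_taxa']}\n"
            )
        fh.write(
            f"# conserved {summary.n_conserved}/{summary.n_positions}"
            f" across {summary.n_taxa} taxa;"
            f" single-taxon variants {summary.n_single_taxon_variant}\n"
        )


def itim_report(calls: Sequence[ItimCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tordinal\tstart\tobserved\tconforms\tdisruption\n")
        for c in calls:
            fh.write(
                f"{c.allele}\t{c.ordinal}\t{c.start}\t{c.observed}\t"
                f"{int(c.conforms)}\t{c.disruption}\n"
            )
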