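"""Reading, validation, translation and domain partitioning of allele CDS sets.

Allele nomenclature follows the IPD convention used for KIR: an allele name
is ``GENE*DDDDD`` where the first three digits after the ``*`` identify the
allotype (the protein-level group) and the first five digits identify the
synonymous (coding-identical protein) variant.  Non-human alleles carry a
species prefix, e.g. ``Patr-KIR3DL3*001``.

Sequences are codon-aligned CDS: length divisible by three, with alignment
gaps (``-``) permitted only in whole-codon triples.  Gap codons translate to
``-``; codons containing ``N`` translate to ``X`` and are excluded from codon
statistics downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
_VALID_CHARS = set("ACGTN-")

_NAME_RE = re.compile(r"^(?:(?P<species>[A-Za-z]{4})-)?(?P<gene>[A-Za-z0-9]+)\*(?P<digits>\d{3,})$")


def translate_codon(codon: str) -> str:
    """Translate one codon; gap triple -> '-', ambiguous -> 'X', stop -> '*'."""
    codon = codon.upper()
    if codon == "---":
        return "-"
    if "N" in codon or "-" in codon:
        return "X"
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


def translate_cds(cds: str) -> str:
    """Standard-genetic-code translation of a codon-aligned CDS."""
    if len(cds) % 3:
        raise ValueError(f"length not multiple of 3: {len(cds)}")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def parse_allele_name(name: str) -> tuple[str, str, str]:
    """Split an allele name into (gene, allotype_id, synonymous_id).

    >>> parse_allele_name("KIR3DL3*00101")
    ('KIR3DL3', '001', '00101')
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"cannot parse allele name {name!r}: expected GENE*<digits> with >=3 digits"
        )
    digits = m.group("digits")
    allotype = digits[:3]
    synonymous = digits[:5] if len(digits) >= 5 else allotype
    return m.group("gene"), allotype, synonymous


@dataclass
class AlleleRecord:
    """One named allele: codon-aligned CDS plus derived annotation."""

    name: str
    cds: str
    species: str = "Homo"
    gene: str = ""
    allotype_id: str = ""
    synonymous_id: str = ""
    protein: str = ""
    is_null: bool = False

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3:
            raise ValueError(f"{self.name}: length not multiple of 3 ({len(self.cds)})")
        bad = [
            (i + 1, c) for i, c in enumerate(self.cds) if c not in _VALID_CHARS
        ]
        if bad:
            pos, c = bad[0]
            raise ValueError(f"{self.name}: non-nucleotide character {c!r} at position {pos}")
        if not self.gene:
            m = _NAME_RE.match(self.name)
            if m:
                self.gene, self.allotype_id, self.synonymous_id = parse_allele_name(self.name)
                if m.group("species"):
                    self.species = m.group("species")
        if not self.protein:
            self.protein = translate_cds(self.cds)
        # premature stop: any stop before the final codon
        self.is_null = "*" in self.protein[:-1]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]


@dataclass
class DomainMap:
    """Codon-coordinate partition of a CDS into functional domains.

    Segments are (label, start_codon, end_codon) in 1-based inclusive
    full-CDS codon coordinates and must tile the CDS contiguously.  The
    leader length links mature-protein numbering to CDS numbering: mature
    residue ``r`` sits at CDS codon ``r + leader_length_codons``.
    """

    segments: list[tuple[str, int, int]]
    leader_length_codons: int = 21

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty domain map")
        labels = [s[0] for s in self.segments]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate domain labels")
        prev_end = 0
        for label, start, end in self.segments:
            if start != prev_end + 1:
                raise ValueError(
                    f"segments not contiguous at {label}: starts at {start}, expected {prev_end + 1}"
                )
            if end < start:
                raise ValueError(f"{label}: end {end} < start {start}")
            prev_end = end

    @property
    def n_codons(self) -> int:
        return self.segments[-1][2]

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]

    def mature_to_codon(self, residue: int) -> int:
        """CDS codon (1-based) holding mature residue ``residue``."""
        return residue + self.leader_length_codons

    def codon_to_mature(self, codon: int) -> int:
        return codon - self.leader_length_codons

    def domain_of_codon(self, codon: int) -> str:
        for label, start, end in self.segments:
            if start <= codon <= end:
                return label
        raise ValueError(f"codon {codon} outside map (1..{self.n_codons})")

    def domain_of_mature(self, residue: int) -> str:
        return self.domain_of_codon(self.mature_to_codon(residue))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        segs = [(d["label"], int(d["start_codon"]), int(d["end_codon"])) for d in cfg["segments"]]
        return cls(segments=segs, leader_length_codons=int(cfg.get("leader_length_codons", 21)))

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "leader_length_codons": self.leader_length_codons,
            "segments": [
                {"label": l, "start_codon": s, "end_codon": e} for l, s, e in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def default_domain_map() -> DomainMap:
    """The default KIR3DL3*00101 domain map shipped with the package."""
    path = Path(__file__).parent / "data" / "kir3dl3_domains.yaml"
    return DomainMap.from_yaml(path)


def read_allele_fasta(path: str | Path, species_default: str = "Homo") -> list[AlleleRecord]:
    """Read codon-aligned allele CDS records from FASTA.

    Every record is translated and null-flagged on load.  Names must be
    unique and all aligned lengths equal.
    """
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate allele name: {name}")
        seen.add(name)
        records.append(AlleleRecord(name=name, cds=str(rec.seq), species=species_default))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(r.cds) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unequal aligned lengths in {path}: {sorted(lengths)}")
    return records


def write_allele_fasta(records: Iterable[AlleleRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.cds), 60):
                fh.write(rec.cds[i : i + 60] + "\n")


def partition_domains(
    records: Sequence[AlleleRecord], domain_map: DomainMap
) -> dict[str, dict[str, str]]:
    """Slice each aligned CDS into per-domain codon blocks.

    Returns ``{domain_label: {allele_name: cds_block}}`` in map order; the
    concatenation of a record's blocks reconstructs its CDS exactly.
    """
    lengths = {r.n_codons for r in records}
    if len(lengths) > 1:
        raise ValueError(f"records have unequal codon lengths: {sorted(lengths)}")
    (n_codons,) = lengths
    if domain_map.n_codons != n_codons:
        raise ValueError(
            f"domain map covers {domain_map.n_codons} codons but alignment has {n_codons}"
        )
    blocks: dict[str, dict[str, str]] = {}
    for label, start, end in domain_map.segments:
        blocks[label] = {r.name: r.cds[(start - 1) * 3 : end * 3] for r in records}
    return blocks


@dataclass
class NovelAlleleClass:
    """Classification of one novel allele against the known reference set."""

    name: str
    category: str  # new_allotype | synonymous_variant | null_allele
    closest_known: str
    nt_diffs: list[tuple[int, str, str]] = field(default_factory=list)
    aa_diffs: list[tuple[int, str, str, str]] = field(default_factory=list)


def _nt_differences(a: str, b: str) -> list[tuple[int, str, str]]:
    return [
        (i + 1, x, y)
        for i, (x, y) in enumerate(zip(a, b))
        if x != y and x in "ACGT" and y in "ACGT"
    ]


def classify_novel_alleles(
    novel: Sequence[AlleleRecord],
    known: Sequence[AlleleRecord],
    domain_map: DomainMap | None = None,
) -> list[NovelAlleleClass]:
    """Assign each novel allele its nearest known allele and a category.

    Nearest = smallest nucleotide-difference count, ties broken by
    lexicographically smallest known-allele name.  Categories follow the
    convention used when naming new immune-receptor alleles: a premature
    stop makes a ``null_allele``; a coding-identical protein makes a
    ``synonymous_variant``; anything else is a ``new_allotype``.
    """
    if not known:
        raise ValueError("empty known allele set")
    out: list[NovelAlleleClass] = []
    for q in novel:
        best = min(known, key=lambda k: (len(_nt_differences(k.cds, q.cds)), k.name))
        nt = _nt_differences(best.cds, q.cds)
        aa: list[tuple[int, str, str, str]] = []
        for i, (x, y) in enumerate(zip(best.protein, q.protein)):
            if x != y and x not in "-X" and y not in "-X":
                codon = i + 1
                mature = domain_map.codon_to_mature(codon) if domain_map else codon
                domain = domain_map.domain_of_codon(codon) if domain_map else ""
                aa.append((mature, x, y, domain))
        if q.is_null and not best.is_null:
            category = "null_allele"
        elif not [d for d in aa if d[2] != "*"] and not q.is_null:
            category = "synonymous_variant"
        else:
            category = "new_allotype"
        out.append(
            NovelAlleleClass(
                name=q.name, category=category, closest_known=best.name, nt_diffs=nt, aa_diffs=aa
            )
        )
    return out


def novel_allele_report(classes: Sequence[NovelAlleleClass], path: str | Path) -> None:
    """TSV report: name, category, closest_known, nt_diffs, aa_diffs, domains."""
    with open(path, "w") as fh:
        fh.write("name\tcategory\tclosest_known\tnt_diffs\taa_diffs\tdomains\n")
        for c in classes:
            nt = ",".join(f"{p}{r}>{a}" for p, r, a in c.nt_diffs)
            aa = ",".join(f"{r}{x}>{y}" for r, x, y, _ in c.aa_diffs)
            doms = ",".join(sorted({d for *_, d in c.aa_diffs if d}))
            fh.write(f"{c.name}\t{c.category}\t{c.closest_known}\t{nt}\t{aa}\t{doms}\n")
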