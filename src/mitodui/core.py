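"""Core domain types for annotated circular mitogenomes.

Bivalve mitochondrial genomes are circular molecules of ~15-25 kb carrying
13 protein-coding genes, 2 rRNAs and a variable complement of tRNAs, usually
all on one strand.  This module provides the containers used by every other
stage of the package (:class:`CircularSequence`, :class:`GeneFeature`,
:class:`AnnotatedMitogenome`), the invertebrate mitochondrial genetic code
with per-position degeneracy (:class:`GeneticCode`), GenBank/FASTA I/O and
per-position site classification (:func:`classify_sites`).

Coordinate convention
---------------------
All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive coordinates are converted at the I/O boundary.  A feature that
wraps the origin of the circle is stored *unwrapped*, i.e. with
``end > genome length``; consumers index the sequence modulo its length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "GeneFeature",
    "AnnotatedMitogenome",
    "GeneticCode",
    "SiteClassMask",
    "SITE_LABELS",
    "parse_genbank",
    "write_genbank",
    "extract_feature_sequence",
    "translate",
    "classify_sites",
    "reverse_complement",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_CATEGORIES = (
    "protein",
    "rRNA",
    "tRNA",
    "tRNA_like",
    "noncoding",
    "AT_rich",
    "repeat_region",
)

# site-class labels, index == integer code stored in SiteClassMask.codes
SITE_LABELS = (
    "noncoding",
    "codon_pos1",
    "codon_pos2",
    "codon_pos3_2fold",
    "codon_pos3_4fold",
    "rna_gene",
)
_LABEL_CODE = {name: i for i, name in enumerate(SITE_LABELS)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MitoduiError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MitoduiError):
    pass


class TranslationError(MitoduiError):
    pass


@dataclass(frozen=True)
class CircularSequence:
    """A circular (or linear) nucleotide sequence over ``{A,C,G,T,N}``."""

    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"disallowed residues: {sorted(bad)}")
        if len(self.residues) == 0:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Extract ``[start, end)`` indexing modulo length (wraps the origin)."""
        n = len(self.residues)
        if end <= start:
            raise ValueError(f"empty span [{start}, {end})")
        if not self.circular and end > n:
            raise ValueError("span extends beyond a linear sequence")
        span = end - start
        if span > n:
            raise ValueError("span longer than the sequence")
        start %= n
        end = start + span
        if end <= n:
            return self.residues[start:end]
        return self.residues[start:] + self.residues[: end - n]


@dataclass
class GeneFeature:
    """One annotated feature on a mitogenome.

    ``start``/``end`` are 0-based half-open; a feature wrapping the origin
    has ``end > genome length``.  ``frame_offset`` applies to proteins whose
    annotated span begins mid-codon; ``incomplete_stop`` marks CDSs whose
    stop codon is completed by polyadenylation (span not divisible by 3).
    """

    name: str
    category: str
    start: int
    end: int
    strand: str = "+"
    frame_offset: int = 0
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"feature {self.name}: empty span")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def span(self) -> int:
        return self.end - self.start

    def positions(self, genome_length: int) -> np.ndarray:
        """Genome positions covered, in coding order, modulo genome length."""
        pos = np.arange(self.start, self.end) % genome_length
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class AnnotatedMitogenome:
    """Circular sequence plus typed gene features and an F/M lineage label."""

    sequence: CircularSequence
    features: list[GeneFeature] = field(default_factory=list)
    label: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("F", "M", "other"):
            raise ValueError("label must be 'F', 'M' or 'other'")
        n = len(self.sequence)
        seen: set[tuple[str, str]] = set()
        for f in self.features:
            if not 0 <= f.start < n:
                raise ValueError(f"feature {f.name} start outside genome")
            if f.span > n:
                raise ValueError(f"feature {f.name} longer than genome")
            key = (f.category, f.name)
            if key in seen:
                raise ValueError(f"duplicate feature {f.name} in {f.category}")
            seen.add(key)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get_feature(self, name: str, category: str | None = None) -> GeneFeature:
        for f in self.features:
            if f.name == name and (category is None or f.category == category):
                return f
        raise KeyError(name)

    def proteins(self) -> list[GeneFeature]:
        return [f for f in self.features if f.category == "protein"]


# ---------------------------------------------------------------------------
# genetic code


class GeneticCode:
    """A genetic code with per-codon, per-position degeneracy classes.

    Defaults to NCBI translation table 5 (invertebrate mitochondrial), the
    code used by mytilid mitogenomes (AGA/AGG = Ser, ATA = Met, TGA = Trp).
    Degeneracy of a codon position is the number of bases at that position
    that conserve the encoded amino acid (1-, 2-, 3- or 4-fold).
    """

    BASES = "ACGT"

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.codon_map: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_map[stop] = "*"
        if len(self.codon_map) != 64:
            raise ValueError("incomplete codon table")
        self.stop_codons = frozenset(table.stop_codons)

    def aa(self, codon: str) -> str:
        return self.codon_map[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def degeneracy(self, codon: str, pos: int) -> int:
        """Fold class (1-4) of position ``pos`` of ``codon`` (counts itself)."""
        aa = self.codon_map[codon]
        return sum(
            1
            for b in self.BASES
            if self.codon_map[codon[:pos] + b + codon[pos + 1 :]] == aa
        )

    def synonymous_fraction(self, codon: str, pos: int) -> float:
        """Fraction of possible single-base changes at ``pos`` that are
        synonymous, excluding changes that create a stop codon (Nei-Gojobori
        site counting convention)."""
        aa = self.codon_map[codon]
        syn = tot = 0
        for b in self.BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if self.codon_map[alt] == "*":
                continue
            tot += 1
            if self.codon_map[alt] == aa:
                syn += 1
        return syn / tot if tot else 0.0

    def codon_sites(self, codon: str) -> tuple[float, float]:
        """(synonymous, nonsynonymous) site counts for one codon; total 3."""
        if self.is_stop(codon):
            raise ValueError("site counts undefined for stop codons")
        s = sum(self.synonymous_fraction(codon, p) for p in range(3))
        return s, 3.0 - s

    def pathway_counts(self, codon_a: str, codon_b: str) -> tuple[float, float]:
        """Synonymous/nonsynonymous difference counts between two codons.

        Averages over all minimal mutational pathways, discarding pathways
        that pass through a stop codon.  If every pathway is blocked the
        average over all pathways is returned instead.
        """
        diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
        if not diff:
            return 0.0, 0.0
        results = []
        blocked_ok = []
        for order in permutations(diff):
            cur = codon_a
            sd = nd = 0
            through_stop = False
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if self.codon_map[nxt] == "*":
                    through_stop = True
                if self.codon_map[nxt] == self.codon_map[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            blocked_ok.append((sd, nd))
            if not through_stop:
                results.append((sd, nd))
        use = results if results else blocked_ok
        sd = sum(r[0] for r in use) / len(use)
        nd = sum(r[1] for r in use) / len(use)
        return sd, nd


@lru_cache(maxsize=4)
def default_code(table_id: int = 5) -> GeneticCode:
    return GeneticCode(table_id)


# ---------------------------------------------------------------------------
# operations


def translate(
    cds: str | CircularSequence,
    code: GeneticCode | None = None,
    frame_offset: int = 0,
    allow_internal_stop: bool = False,
) -> str:
    """Translate a CDS in coding orientation.

    Trailing incomplete codons are dropped, as is a single terminal stop.
    An internal stop raises :class:`TranslationError` naming the codon index
    unless ``allow_internal_stop`` is set.
    """
    code = code or default_code()
    seq = cds.residues if isinstance(cds, CircularSequence) else cds
    seq = seq[frame_offset:]
    if len(seq) < 3:
        raise TranslationError("fewer than one full codon after frame offset")
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            aas.append("X")
            continue
        aa = code.aa(codon)
        if aa == "*":
            if i == n_codons - 1:
                break  # terminal stop dropped
            if not allow_internal_stop:
                raise TranslationError(f"internal stop at codon index {i}")
        aas.append(aa)
    return "".join(aas)


def extract_feature_sequence(
    genome: AnnotatedMitogenome, feature: GeneFeature
) -> CircularSequence:
    """Feature span in coding orientation; wrapping spans concatenate
    suffix + prefix; minus-strand features are reverse-complemented."""
    n = genome.length
    if feature.start >= n or feature.span > n:
        raise ValueError(f"feature {feature.name} outside genome")
    seq = genome.sequence
    if feature.end <= n:
        s = seq.residues[feature.start : feature.end]
    else:
        s = seq.residues[feature.start :] + seq.residues[: feature.end - n]
    if feature.strand == "-":
        s = reverse_complement(s)
    return CircularSequence(s, circular=False)


@dataclass
class SiteClassMask:
    """Per-position site-class labels over a whole genome.

    ``codes[i]`` indexes into :data:`SITE_LABELS`.  Positions in protein
    features carry codon-position labels (third positions split by
    degeneracy: 4-fold vs everything else), positions in RNA genes carry
    ``rna_gene`` and all remaining positions are ``noncoding``.
    """

    codes: np.ndarray  # int8, len == genome length

    def __len__(self) -> int:
        return len(self.codes)

    def labels(self) -> list[str]:
        return [SITE_LABELS[c] for c in self.codes]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.codes == i)) for i, name in enumerate(SITE_LABELS)
        }

    def selector(self, labels: Iterable[str]) -> np.ndarray:
        """Boolean eligibility vector for a set of label names."""
        want = {_LABEL_CODE[l] for l in labels}
        return np.isin(self.codes, list(want))


def classify_sites(
    genome: AnnotatedMitogenome, code: GeneticCode | None = None
) -> SiteClassMask:
    """Label every genome position by its mutational context.

    Priority on overlap is protein > RNA gene > noncoding.  Third-codon-
    position degeneracy is computed from the actual codon at that site.
    Protein features overlapping in incompatible frames raise an error.
    """
    code = code or default_code()
    n = genome.length
    codes = np.zeros(n, dtype=np.int8)  # noncoding

    for f in genome.features:
        if f.category in ("rRNA", "tRNA", "tRNA_like"):
            codes[f.positions(n)] = _LABEL_CODE["rna_gene"]

    claimed = np.full(n, -1, dtype=np.int8)  # per-position codon label, proteins only
    for f in genome.proteins():
        cds = extract_feature_sequence(genome, f).residues[f.frame_offset :]
        pos = f.positions(n)[f.frame_offset :]
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci : 3 * ci + 3]
            if "N" in codon:
                lab3 = _LABEL_CODE["codon_pos3_2fold"]
            elif code.degeneracy(codon, 2) == 4:
                lab3 = _LABEL_CODE["codon_pos3_4fold"]
            else:
                lab3 = _LABEL_CODE["codon_pos3_2fold"]
            labs = (_LABEL_CODE["codon_pos1"], _LABEL_CODE["codon_pos2"], lab3)
            for k in range(3):
                p = pos[3 * ci + k]
                if claimed[p] != -1 and claimed[p] != labs[k]:
                    raise MitoduiError(
                        f"protein features overlap in different frames at position {p}"
                        f" (feature {f.name})"
                    )
                claimed[p] = labs[k]
                codes[p] = labs[k]
    return SiteClassMask(codes)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O

_GB_CATEGORY = {
    "CDS": "protein",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "repeat_region": "repeat_region",
}


def _feature_name(sf: SeqFeature, default: str) -> str:
    for key in ("gene", "product", "note", "rpt_type"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return default


def parse_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Read a single-record GenBank flat file into an AnnotatedMitogenome.

    ``join()`` locations across the origin are unwrapped into wrapping
    coordinates (``end > length``).  Records without features produce a
    warning and an empty feature list.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = CircularSequence(str(record.seq).upper())
    n = len(seq)
    features: list[GeneFeature] = []
    counter: dict[str, int] = {}
    for sf in record.features:
        if sf.type not in _GB_CATEGORY and sf.type != "misc_feature":
            continue
        if sf.type == "misc_feature":
            note = " ".join(str(v) for v in sf.qualifiers.get("note", [])).lower()
            if "trna-like" in note or "trna_like" in note:
                category = "tRNA_like"
            elif "at-rich" in note or "at_rich" in note:
                category = "AT_rich"
            elif "repeat" in note:
                category = "repeat_region"
            else:
                category = "noncoding"
        else:
            category = _GB_CATEGORY[sf.type]
        counter[category] = counter.get(category, 0) + 1
        name = _feature_name(sf, f"{category}_{counter[category]}")
        loc = sf.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin wrap: a part ending at the sequence end + one starting at 0
            first = next((p for p in parts if int(p.end) == n), None)
            second = next((p for p in parts if int(p.start) == 0), None)
            if first is None or second is None:
                raise ParseError(
                    f"{path}: unsupported compound location for {name}: {loc}"
                )
            start, end = int(first.start), n + int(second.end)
        else:
            start, end = int(loc.start), int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        frame = 0
        if sf.type == "CDS" and "codon_start" in sf.qualifiers:
            frame = int(sf.qualifiers["codon_start"][0]) - 1
        incomplete = category == "protein" and (end - start - frame) % 3 != 0
        features.append(
            GeneFeature(
                name=name,
                category=category,
                start=start,
                end=end,
                strand=strand,
                frame_offset=frame,
                incomplete_stop=incomplete,
            )
        )
    if not features:
        warnings.warn(f"{path}: record has no usable features", stacklevel=2)
    label = "other"
    src = str(record.description) + " " + str(record.annotations.get("comment", ""))
    for tag in ("F", "M"):
        if f"{tag}-type" in src or f"type {tag}" in src:
            label = tag
    return AnnotatedMitogenome(seq, features, label=label, name=record.id or path.stem)


_GB_TYPE = {
    "protein": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "repeat_region": "repeat_region",
}


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    """Write an AnnotatedMitogenome back to a GenBank flat file, re-wrapping
    origin-spanning features into ``join()`` locations."""
    n = genome.length
    record = SeqRecord(
        Seq(genome.sequence.residues),
        id=genome.name or "mitogenome",
        name=(genome.name or "mitogenome")[:16].replace(" ", "_"),
        description=f"synthetic mitogenome ({genome.label}-type)"
        if genome.label in "FM"
        else "mitogenome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.end <= n:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, n, strand=strand),
                    SimpleLocation(0, f.end - n, strand=strand),
                ]
            )
        ftype = _GB_TYPE.get(f.category, "misc_feature")
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.category == "protein" and f.frame_offset:
            quals["codon_start"] = [str(f.frame_offset + 1)]
        if f.category not in _GB_TYPE:
            quals["note"] = [f.category.replace("_", "-")]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def write_feature_table(genome: AnnotatedMitogenome, path: str | Path) -> None:
    """TSV feature table: name, category, start, end, strand, span."""
    with open(path, "w") as fh:
        fh.write("name\tcategory\tstart\tend\tstrand\tspan\n")
        for f in genome.features:
            fh.write(
                f"{f.name}\t{f.category}\t{f.start}\t{f.end}\t{f.strand}\t{f.span}\n"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
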