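import textwrap

import pytest

from mitodui.core import (
    AnnotatedMitogenome,
    CircularSequence,
    GeneFeature,
)


def make_genome(seq: str, features=None, label: str = "other") -> AnnotatedMitogenome:
    return AnnotatedMitogenome(CircularSequence(seq), list(features or []), label=label)


@pytest.fixture
def tiny_genome():
    """6 bp genome with one CDS covering it all (codons ATG GTA)."""
    return make_genome(
        "ATGGTA", [GeneFeature("orf1", "protein", 0, 6)]
    )


def write_minimal_genbank(path, length=100, cds_loc="1..30"):
    """Hand-written single-record GenBank flat file for parser tests."""
    seq = ("ATGAAAGGGCCCTTTAACGTA" * 10)[:length]
    lines = [
        f"LOCUS       TESTREC    {length} bp    DNA     circular INV 01-JAN-2020",
        "DEFINITION  synthetic test record.",
        "ACCESSION   TESTREC",
        "FEATURES             Location/Qualifiers",
        f"     CDS             {cds_loc}",
        '                     /gene="orfA"',
        "ORIGIN",
    ]
    for i in range(0, length, 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts.lower()}")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
    return seq
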