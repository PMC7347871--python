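"""Between-lineage divergence: p-distances with bootstrap standard errors.

In a DUI species the maternally (F) and paternally (M) transmitted
mitogenomes diverge gene by gene; the standard summary is the per-gene
p-distance (proportion of differing sites) between the two lineages —
amino-acid distance for protein genes, nucleotide distance for RNA genes —
plus an overall nucleotide distance over the concatenated genes.  Standard
errors come from resampling alignment columns with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotatedMitogenome, GeneticCode, default_code, translate

__all__ = [
    "MultiAlignment",
    "DivergenceRow",
    "p_distance",
    "between_group_p_distance",
    "per_gene_divergence",
]

_NT = set("ACGT")
_GAPLIKE_NT = set("-NRYSWKMBDHV?")  # ambiguity codes treated as gaps


@dataclass
class MultiAlignment:
    """Equal-length aligned sequences with per-row group labels."""

    names: list[str]
    groups: list[str]
    rows: list[str]
    molecule: str = "nt"  # or "aa"

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.groups) == len(self.rows)):
            raise ValueError("names, groups and rows must align")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")
        if self.molecule not in ("nt", "aa"):
            raise ValueError("molecule must be 'nt' or 'aa'")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def group(self, label: str) -> list[str]:
        return [r for g, r in zip(self.groups, self.rows) if g == label]

    @classmethod
    def from_fasta(cls, path: str | Path, molecule: str = "nt") -> "MultiAlignment":
        """Read aligned FASTA with group labels encoded as ``>name|GROUP``."""
        from .core import read_fasta

        names, groups, rows = [], [], []
        for header, seq in read_fasta(path):
            name, _, group = header.partition("|")
            names.append(name)
            groups.append(group or "other")
            rows.append(seq)
        return cls(names, groups, rows, molecule)

    def to_fasta(self, path: str | Path) -> None:
        from .core import write_fasta

        write_fasta(
            [(f"{n}|{g}", r) for n, g, r in zip(self.names, self.groups, self.rows)],
            path,
        )


@dataclass
class DivergenceRow:
    gene: str
    molecule: str
    p_distance: float
    bootstrap_se: float
    n_sites_used: int


def _usable(ch: str, molecule: str) -> bool:
    if molecule == "nt":
        return ch in _NT
    return ch.isalpha() and ch not in ("X",)


def _usable_matrix(rows: Sequence[str], molecule: str) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    if molecule == "nt":
        ok = np.isin(arr, list(_NT))
    else:
        ok = (arr != "-") & (arr != "X") & (arr != "?") & (arr != "*")
    return ok


def p_distance(
    a: str, b: str, deletion: str = "complete", molecule: str = "nt"
) -> tuple[float, int]:
    """Proportion of differing sites between two aligned sequences.

    ``complete`` deletion drops columns where either sequence has a gap or
    ambiguity (for a pair, complete and pairwise deletion coincide).
    Returns ``(nan, 0)`` when no usable column remains.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if deletion not in ("complete", "pairwise"):
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    used = mism = 0
    for x, y in zip(a, b):
        if _usable(x, molecule) and _usable(y, molecule):
            used += 1
            if x != y:
                mism += 1
    if used == 0:
        return float("nan"), 0
    return mism / used, used


def between_group_p_distance(
    aln: MultiAlignment,
    group_a: str,
    group_b: str,
    bootstrap_reps: int = 10_000,
    seed: int | None = None,
    deletion: str = "complete",
) -> tuple[float, float, int]:
    """Mean p-distance over all cross-group pairs, with a site-resampling
    bootstrap SE.

    Under complete deletion, columns containing a gap or ambiguity in *any*
    row are removed before computing; the bootstrap resamples the remaining
    columns with replacement and the SE is the standard deviation of the
    replicate means.  Returns ``(mean_p, se, n_sites_used)``; ``se`` is NaN
    when fewer than two usable columns exist.
    """
    rows_a = aln.group(group_a)
    rows_b = aln.group(group_b)
    if not rows_a or not rows_b:
        raise ValueError("both groups must be non-empty")
    arr_a = np.array([list(r) for r in rows_a])
    arr_b = np.array([list(r) for r in rows_b])
    ok_a = _usable_matrix(rows_a, aln.molecule)
    ok_b = _usable_matrix(rows_b, aln.molecule)
    if deletion == "complete":
        keep = ok_a.all(axis=0) & ok_b.all(axis=0)
    else:
        keep = ok_a.any(axis=0) & ok_b.any(axis=0)
    arr_a, arr_b = arr_a[:, keep], arr_b[:, keep]
    n_sites = arr_a.shape[1]
    if n_sites == 0:
        return float("nan"), float("nan"), 0

    # per-column mean mismatch fraction across all cross pairs: the overall
    # mean p is linear in columns, which makes the site bootstrap cheap
    col_mismatch = np.zeros(n_sites)
    for ra in arr_a:
        col_mismatch += (arr_b != ra).mean(axis=0)
    col_mismatch /= len(arr_a)
    mean_p = float(col_mismatch.mean())

    if n_sites < 2:
        return mean_p, float("nan"), n_sites
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    chunk = max(1, int(2e6) // n_sites)
    done = 0
    while done < bootstrap_reps:
        k = min(chunk, bootstrap_reps - done)
        idx = rng.integers(0, n_sites, size=(k, n_sites))
        reps[done : done + k] = col_mismatch[idx].mean(axis=1)
        done += k
    return mean_p, float(reps.std(ddof=1)), n_sites


def per_gene_divergence(
    genome_f: AnnotatedMitogenome | None,
    genome_m: AnnotatedMitogenome | None,
    per_gene_alignments: Mapping[str, MultiAlignment],
    bootstrap_reps: int = 10_000,
    seed: int | None = None,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-gene F/M divergence rows plus an overall concatenated row.

    Inputs are nucleotide alignments per gene with rows labelled ``F``/``M``.
    Genes present as protein features in the genomes (or named like one of
    the 13 metazoan mitochondrial proteins, when genomes are not supplied)
    are translated and reported as amino-acid distances; RNA genes stay at
    the nucleotide level.  The overall row is the nucleotide p-distance of
    the concatenation of all per-gene nucleotide alignments.
    """
    code = code or default_code()
    protein_names: set[str] = set()
    for g in (genome_f, genome_m):
        if g is not None:
            protein_names |= {f.name for f in g.proteins()}
    if not protein_names:
        protein_names = {
            "cox1", "cox2", "cox3", "cob", "cytb", "atp6", "atp8",
            "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
        }
    if genome_f is not None and genome_m is not None:
        shared = {f.name for f in genome_f.features} & {
            f.name for f in genome_m.features
        }
        for gene in per_gene_alignments:
            if gene not in shared:
                warnings.warn(f"gene {gene} missing from one genome", stacklevel=2)

    rows: list[DivergenceRow] = []
    concat_f: list[str] = []
    concat_m: list[str] = []
    rng = np.random.default_rng(seed)
    for gene in sorted(per_gene_alignments):
        aln = per_gene_alignments[gene]
        is_protein = gene.lower() in {n.lower() for n in protein_names}
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if is_protein:
            aa = MultiAlignment(
                aln.names,
                aln.groups,
                [
                    translate(r.replace("-", ""), code, allow_internal_stop=True)
                    for r in aln.rows
                ],
                molecule="aa",
            )
            if len({len(r) for r in aa.rows}) > 1:
                # gapped codon alignments translate unevenly; fall back to nt
                aa = aln
            p, se, n = between_group_p_distance(
                aa, "F", "M", bootstrap_reps, seed=sub_seed
            )
            rows.append(DivergenceRow(gene, aa.molecule, p, se, n))
        else:
            p, se, n = between_group_p_distance(
                aln, "F", "M", bootstrap_reps, seed=sub_seed
            )
            rows.append(DivergenceRow(gene, "nt", p, se, n))
        concat_f.append(aln.group("F")[0])
        concat_m.append(aln.group("M")[0])

    overall = MultiAlignment(
        ["F_concat", "M_concat"],
        ["F", "M"],
        ["".join(concat_f), "".join(concat_m)],
        molecule="nt",
    )
    p, se, n = between_group_p_distance(
        overall, "F", "M", bootstrap_reps, seed=int(rng.integers(0, 2**31 - 1))
    )
    rows.append(DivergenceRow("overall", "nt", p, se, n))
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "molecule": r.molecule,
                "p_distance": r.p_distance,
                "bootstrap_se": r.bootstrap_se,
                "n_sites_used": r.n_sites_used,
            }
            for r in rows
        ]
    )
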