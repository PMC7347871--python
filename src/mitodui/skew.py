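"""Sliding-window compositional indices on circular genomes.

AT-skew ``(A-T)/(A+T)`` and GC-skew ``(G-C)/(G+C)`` measure strand
compositional asymmetry; in mitogenomes they track replication- and
transcription-associated mutational pressure.  Windows tile the whole
circle (one window per step, wrapping the origin) and can be restricted to
a set of site classes from :func:`mitodui.core.classify_sites` — e.g.
4-fold degenerate third codon positions plus noncoding sites as a proxy
for neutrally evolving positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import AnnotatedMitogenome, GeneticCode, SiteClassMask, classify_sites

__all__ = ["WindowTrack", "windowed_index", "genome_wide_index", "INDEX_NAMES"]

INDEX_NAMES = ("AT_skew", "GC_skew", "GC_content")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class WindowTrack:
    """Per-window values of one compositional index around a circle.

    ``values`` holds NaN where a window contains no eligible site; skews are
    additionally NaN where the relevant base pair is absent from the window.
    """

    index_name: str
    window_size: int
    step: int
    centers: np.ndarray
    values: np.ndarray
    eligible_counts: np.ndarray
    relative_scale: bool = False
    site_filter: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.values) == len(self.eligible_counts)):
            raise ValueError("track arrays must have equal length")

    def __len__(self) -> int:
        return len(self.centers)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("center\tvalue\teligible\tindex_name\n")
            for c, v, e in zip(self.centers, self.values, self.eligible_counts):
                val = "NA" if math.isnan(v) else f"{v:.6g}"
                fh.write(f"{c:.1f}\t{val}\t{int(e)}\t{self.index_name}\n")

    def to_bed(self, path: str | Path, chrom: str = "mitogenome") -> None:
        """BED-like interval export (start/end clipped to the circle)."""
        half = self.window_size / 2
        with open(path, "w") as fh:
            for c, v in zip(self.centers, self.values):
                if math.isnan(v):
                    continue
                fh.write(f"{chrom}\t{int(c - half)}\t{int(c + half)}\t{v:.6g}\n")

    def plot(self, ax=None, **kwargs):
        """Basic line plot of the track (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        ax.plot(self.centers, self.values, **kwargs)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel(self.index_name)
        return ax


def _sequence_codes(genome: AnnotatedMitogenome) -> np.ndarray:
    return np.frombuffer(
        genome.sequence.residues.translate(
            str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")
        ).encode("latin1"),
        dtype=np.uint8,
    )


def _resolve_eligibility(
    genome: AnnotatedMitogenome,
    site_filter: Iterable[str] | None,
    mask: SiteClassMask | None,
    code: GeneticCode | None,
) -> tuple[np.ndarray, tuple[str, ...] | None]:
    n = genome.length
    if site_filter is None:
        return np.ones(n, dtype=bool), None
    labels = tuple(site_filter)
    if mask is None:
        mask = classify_sites(genome, code)
    return mask.selector(labels), labels


def _index_from_counts(index_name: str, counts: np.ndarray) -> np.ndarray:
    """counts: (..., 4) base counts in ACGT order; returns index values."""
    a, c, g, t = (counts[..., i].astype(float) for i in range(4))
    with np.errstate(invalid="ignore", divide="ignore"):
        if index_name == "AT_skew":
            return np.where(a + t > 0, (a - t) / (a + t), np.nan)
        if index_name == "GC_skew":
            return np.where(g + c > 0, (g - c) / (g + c), np.nan)
        if index_name == "GC_content":
            tot = a + c + g + t
            return np.where(tot > 0, (g + c) / tot, np.nan)
    raise ValueError(f"unknown index {index_name!r}")


def windowed_index(
    genome: AnnotatedMitogenome,
    index_name: str,
    window_size: int,
    step: int,
    site_filter: Iterable[str] | None = None,
    relative: bool = False,
    mask: SiteClassMask | None = None,
    code: GeneticCode | None = None,
    complement_strand: bool = False,
) -> WindowTrack:
    """Compute one compositional index in sliding windows around the circle.

    One window starts at every multiple of ``step`` (``ceil(L/step)``
    windows), wrapping the origin.  Only positions whose site-class label is
    in ``site_filter`` contribute; windows with no eligible position get NaN.
    With ``relative=True`` (GC content only, matching the convention of
    plotting local GC relative to the genome average) values are divided by
    the genome-wide index over the same filter.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}")
    n = genome.length
    if window_size > n:
        raise ValueError("window_size exceeds genome length")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")

    codes = _sequence_codes(genome)
    eligible, labels = _resolve_eligibility(genome, site_filter, mask, code)

    # doubled arrays avoid modular indexing for wrapping windows
    ext_codes = np.concatenate([codes, codes[:window_size]])
    ext_elig = np.concatenate([eligible, eligible[:window_size]])

    # prefix sums of eligible base counts, one column per base (N excluded)
    onehot = np.zeros((len(ext_codes), 4), dtype=np.int64)
    for b in range(4):
        onehot[:, b] = (ext_codes == b) & ext_elig
    cum = np.vstack([np.zeros((1, 4), dtype=np.int64), np.cumsum(onehot, axis=0)])
    cum_elig = np.concatenate([[0], np.cumsum(ext_elig.astype(np.int64))])

    n_windows = math.ceil(n / step)
    starts = np.arange(n_windows) * step
    counts = cum[starts + window_size] - cum[starts]
    elig_counts = cum_elig[starts + window_size] - cum_elig[starts]

    if complement_strand:
        counts = counts[:, [3, 2, 1, 0]]  # A<->T, C<->G

    values = _index_from_counts(index_name, counts)
    values[elig_counts == 0] = np.nan
    if relative:
        denom = genome_wide_index(
            genome, index_name, site_filter=labels, mask=mask, code=code,
            complement_strand=complement_strand,
        )
        values = values / denom
    centers = (starts + window_size / 2) % n
    return WindowTrack(
        index_name=index_name,
        window_size=window_size,
        step=step,
        centers=centers.astype(float),
        values=values,
        eligible_counts=elig_counts,
        relative_scale=relative,
        site_filter=labels,
    )


def genome_wide_index(
    genome: AnnotatedMitogenome,
    index_name: str,
    site_filter: Iterable[str] | None = None,
    mask: SiteClassMask | None = None,
    code: GeneticCode | None = None,
    complement_strand: bool = False,
) -> float:
    """Whole-genome value of an index: a single window covering the circle.

    This aggregates base counts over all eligible positions (it is not the
    mean of per-window skews).
    """
    codes = _sequence_codes(genome)
    eligible, _ = _resolve_eligibility(genome, site_filter, mask, code)
    counts = np.array(
        [int(np.sum((codes == b) & eligible)) for b in range(4)], dtype=np.int64
    )
    if complement_strand:
        counts = counts[[3, 2, 1, 0]]
    return float(_index_from_counts(index_name, counts[np.newaxis, :])[0])
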