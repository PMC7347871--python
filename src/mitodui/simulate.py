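"""Synthetic-data generators with known ground truth.

Every analysis stage in this package has a matching generator here that
produces inputs with the statistical structure the stage assumes, plus a
truth record, so estimator-recovery tests run entirely offline:

* :func:`simulate_mitogenome_pair` — a divergent F/M mitogenome pair with a
  realistic mytilid gene complement (13 proteins, 2 rRNAs, 23 tRNAs, the
  F genome 18,113 bp and the M genome 24,347 bp by default, including the
  M-specific atp8 extension, relocated small-subunit rRNA and long repeat
  region), controlled per-gene divergence and optional compositional-skew
  profiles.
* :func:`simulate_haplotypes` — standard neutral coalescent samples under
  the infinite-sites model at a chosen theta, or codon sequences evolved
  with a chosen nonsynonymous/synonymous rate ratio omega.
* :func:`simulate_qpcr_dataset` — dilution series and tissue Cq tables
  generated from log-linear standard curves on top of the linear
  soma/sperm mixture structure with a known intercept.
* :func:`simulate_ngs_counts` — binomial read splits at a known M/F ratio.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotatedMitogenome,
    CircularSequence,
    GeneFeature,
    GeneticCode,
    default_code,
)
from .divergence import MultiAlignment
from .popgen import HaplotypeSet

__all__ = [
    "MitoPairConfig",
    "CoalescentConfig",
    "QpcrSimConfig",
    "simulate_mitogenome_pair",
    "simulate_haplotypes",
    "simulate_qpcr_dataset",
    "simulate_ngs_counts",
    "default_gene_table",
]

BASES = np.array(list("ACGT"))


def _composition(at_skew: float = 0.0, gc_skew: float = 0.0, gc: float = 0.5):
    """Base probabilities (ACGT order) realising target skews and GC content."""
    pa = (1 - gc) * (1 + at_skew) / 2
    pt = (1 - gc) * (1 - at_skew) / 2
    pg = gc * (1 + gc_skew) / 2
    pc = gc * (1 - gc_skew) / 2
    return np.array([pa, pc, pg, pt])


def _random_seq(rng: np.random.Generator, length: int, probs=None) -> str:
    if probs is None:
        probs = np.full(4, 0.25)
    return "".join(rng.choice(BASES, size=length, p=probs))


# ---------------------------------------------------------------------------
# mitogenome pair


# shared gene complement (bp); protein lengths include the stop codon
_PROTEIN_LENGTHS = {
    "cox1": 1536, "cox2": 690, "cox3": 783, "atp6": 708, "atp8": 369,
    "nad1": 936, "nad2": 978, "nad3": 354, "nad4": 1341, "nad4l": 282,
    "nad5": 1716, "nad6": 480, "cytb": 1161,
}
_RRNA_LENGTHS = {"rrnS": 950, "rrnL": 1250}
_TRNA_NAMES = [
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM1", "trnM2", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
]
_TRNA_LEN = 66

F_GENOME_LENGTH = 18_113
M_GENOME_LENGTH = 24_347
M_ATP8_LENGTH = 885


def default_gene_table() -> list[tuple[str, str, int]]:
    """(name, category, length) for the shared gene complement."""
    table = [(n, "protein", l) for n, l in _PROTEIN_LENGTHS.items()]
    table += [(n, "rRNA", l) for n, l in _RRNA_LENGTHS.items()]
    table += [(n, "tRNA", _TRNA_LEN) for n in _TRNA_NAMES]
    return table


@dataclass
class MitoPairConfig:
    """Configuration for a synthetic divergent F/M mitogenome pair.

    ``divergence`` is the target per-site p-distance, either one value for
    every gene or a per-gene mapping; values must stay below 0.75 (the
    Jukes-Cantor saturation bound).  ``skew_profile`` maps region names to
    ``(at_skew, gc_skew, gc_content)`` triples used when generating that
    region's sequence.
    """

    divergence: float | Mapping[str, float] = 0.347
    gene_table: list[tuple[str, str, int]] = field(default_factory=default_gene_table)
    skew_profile: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    extend_atp8: bool = True
    relocate_srRNA: bool = True
    add_repeat_region: bool = True
    f_length: int = F_GENOME_LENGTH
    m_length: int = M_GENOME_LENGTH
    seed: int | None = None

    def target_for(self, gene: str) -> float:
        d = (
            self.divergence.get(gene, 0.0)
            if isinstance(self.divergence, Mapping)
            else self.divergence
        )
        if not 0.0 <= d <= 0.75:
            raise ValueError(f"divergence target {d} outside [0, 0.75]")
        return d


def _random_cds(rng: np.random.Generator, length: int, code: GeneticCode) -> str:
    """Random CDS: ATG start, non-stop internal codons, TAA stop."""
    ncod = length // 3
    codons = ["ATG"]
    while len(codons) < ncod - 1:
        c = "".join(rng.choice(BASES, size=3))
        if not code.is_stop(c):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate_nt(rng: np.random.Generator, seq: str, d: float) -> str:
    """Per-site substitution with probability d, always to a different base."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < d
    for i in np.where(hit)[0]:
        alts = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alts[rng.integers(0, 3)]
    return "".join(arr)


def _mutate_cds(rng: np.random.Generator, seq: str, d: float, code: GeneticCode) -> str:
    """Codon-wise mutation at per-site probability d avoiding stop codons."""
    ncod = len(seq) // 3
    out = []
    for i in range(ncod):
        codon = seq[3 * i : 3 * i + 3]
        if i == ncod - 1 and code.is_stop(codon):
            out.append(codon)  # keep the terminal stop intact
            continue
        hit = rng.random(3) < d
        if not hit.any():
            out.append(codon)
            continue
        for _ in range(50):
            cand = list(codon)
            for k in np.where(hit)[0]:
                alts = [b for b in "ACGT" if b != codon[k]]
                cand[k] = alts[rng.integers(0, 3)]
            cand = "".join(cand)
            if not code.is_stop(cand):
                out.append(cand)
                break
        else:
            out.append(codon)
    return "".join(out)


def _build_genome(
    rng: np.random.Generator,
    order: Sequence[tuple[str, str, str]],
    label: str,
    name: str,
) -> AnnotatedMitogenome:
    """Assemble features laid end to end on the + strand."""
    pos = 0
    feats: list[GeneFeature] = []
    chunks: list[str] = []
    for gname, category, seq in order:
        if category not in ("noncoding", "AT_rich", "repeat_region", "spacer"):
            feats.append(
                GeneFeature(gname, category, pos, pos + len(seq), strand="+")
            )
        elif category != "spacer":
            feats.append(
                GeneFeature(gname, category, pos, pos + len(seq), strand="+")
            )
        chunks.append(seq)
        pos += len(seq)
    return AnnotatedMitogenome(
        CircularSequence("".join(chunks)), feats, label=label, name=name
    )


def simulate_mitogenome_pair(
    cfg: MitoPairConfig | None = None,
) -> tuple[AnnotatedMitogenome, AnnotatedMitogenome, dict[str, MultiAlignment]]:
    """Generate a divergent F/M mitogenome pair plus truth alignments.

    The M genome differs from F by per-gene substitutions at the configured
    target p-distance (codon-aware for proteins, so CDSs stay stop-free),
    the structural differences of a DUI mitotype pair (extended atp8,
    relocated small-subunit rRNA, long repeat region) and freshly drawn
    noncoding regions with no between-genome similarity.  Returned truth
    alignments are gap-free nucleotide alignments of the shared gene cores.
    """
    cfg = cfg or MitoPairConfig()
    rng = np.random.default_rng(cfg.seed)
    code = default_code()

    f_genes: dict[str, tuple[str, str]] = {}  # name -> (category, seq)
    for gname, category, length in cfg.gene_table:
        probs = None
        if gname in cfg.skew_profile:
            probs = _composition(*cfg.skew_profile[gname])
        if category == "protein":
            seq = _random_cds(rng, length, code)
        else:
            seq = _random_seq(rng, length, probs)
        f_genes[gname] = (category, seq)

    # M versions of the shared genes, mutated to the per-gene target
    m_genes: dict[str, tuple[str, str]] = {}
    alignments: dict[str, MultiAlignment] = {}
    for gname, (category, fseq) in f_genes.items():
        d = cfg.target_for(gname)
        if category == "protein":
            mseq = _mutate_cds(rng, fseq, d, code)
        else:
            mseq = _mutate_nt(rng, fseq, d)
        core_m = mseq
        if gname == "atp8" and cfg.extend_atp8:
            ext = _random_cds(rng, M_ATP8_LENGTH - len(mseq) + 6, code)
            # splice the extension before the stop codon
            mseq = mseq[:-3] + ext[3:-3] + "TAA"
            core_m = mseq[: len(fseq) - 3] + "TAA"
        m_genes[gname] = (category, mseq)
        alignments[gname] = MultiAlignment(
            ["F", "M"], ["F", "M"], [fseq, core_m], molecule="nt"
        )

    def _nc(length: int, name: str) -> str:
        probs = _composition(*cfg.skew_profile.get(name, (0.0, 0.0, 0.35)))
        return _random_seq(rng, length, probs)

    coding_f = sum(len(s) for _, s in f_genes.values())
    at_rich_len = 150
    f_ncr_len = cfg.f_length - coding_f - at_rich_len
    if f_ncr_len < 0:
        raise ValueError("gene table longer than requested F genome length")

    gene_names = list(f_genes)
    base = [g for g in gene_names if g not in ("rrnS", "rrnL")]

    def _insert_after(names: list[str], anchor: str, new: str) -> list[str]:
        i = names.index(anchor)
        return names[:i + 1] + [new] + names[i + 1 :]

    # F order: small-subunit rRNA sits between nad1 and cox1 (here: right
    # after nad1); large-subunit rRNA after cytb
    f_order_names = _insert_after(base, "nad1", "rrnS") if "nad1" in base else base
    if "cytb" in base:
        f_order_names = _insert_after(f_order_names, "cytb", "rrnL")
    f_order = [(g, f_genes[g][0], f_genes[g][1]) for g in f_order_names]
    f_order.append(("AT_rich", "AT_rich", _nc(at_rich_len, "AT_rich")))
    f_order.append(("NCR", "noncoding", _nc(f_ncr_len, "NCR")))
    genome_f = _build_genome(rng, f_order, "F", "synthetic_F")

    coding_m = sum(len(s) for _, s in m_genes.values())
    m_rest = cfg.m_length - coding_m - at_rich_len
    repeat_len = 6000 if cfg.add_repeat_region else 0
    m_ncr_len = m_rest - repeat_len
    if m_ncr_len < 0:
        raise ValueError("gene table longer than requested M genome length")
    if repeat_len:
        unit = _nc(120, "repeat_region")
        repeat_seq = (unit * (repeat_len // len(unit) + 1))[:repeat_len]
    if cfg.relocate_srRNA and "nad4l" in base:
        # M layout: the small-subunit rRNA moves next to the large rRNA,
        # with the repeat-rich region between the two rRNA genes, the whole
        # block sitting just upstream of nad4l
        i = base.index("nad4l")
        pre, post = base[:i], base[i:]
        m_order = [(g, m_genes[g][0], m_genes[g][1]) for g in pre]
        m_order.append(("rrnL", "rRNA", m_genes["rrnL"][1]))
        if repeat_len:
            m_order.append(("repeat_region", "repeat_region", repeat_seq))
        m_order.append(("rrnS", "rRNA", m_genes["rrnS"][1]))
        m_order += [(g, m_genes[g][0], m_genes[g][1]) for g in post]
    else:
        m_order = [(g, m_genes[g][0], m_genes[g][1]) for g in f_order_names]
        if repeat_len:
            m_order.append(("repeat_region", "repeat_region", repeat_seq))
    m_order.append(("AT_rich", "AT_rich", _nc(at_rich_len, "AT_rich_M")))
    m_order.append(("NCR", "noncoding", _nc(m_ncr_len, "NCR_M")))
    genome_m = _build_genome(rng, m_order, "M", "synthetic_M")

    return genome_f, genome_m, alignments


# ---------------------------------------------------------------------------
# neutral coalescent


@dataclass
class CoalescentConfig:
    """Neutral-coalescent sample configuration.

    ``theta_per_site`` is the population-scaled mutation rate per site
    (4*Ne*mu); in nucleotide mode mutations follow the infinite-sites
    model, in codon mode (``omega`` set) substitutions are accepted with
    probability ``omega`` when nonsynonymous.
    """

    n_samples: int = 18
    sequence_length: int = 1317
    theta_per_site: float = 0.02
    frame_offset: int = 0
    omega: float | None = None
    region: str = "sim"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.theta_per_site <= 0:
            raise ValueError("theta must be positive")


def _coalescent_branches(n: int, rng: np.random.Generator):
    """Hudson coalescent: returns (children, node_times, root).

    Leaves are nodes 0..n-1 at time 0; waiting time while k lineages remain
    is exponential with rate k(k-1)/2 (time in units of 2N generations).
    """
    children: dict[int, tuple[int, int]] = {}
    times = {i: 0.0 for i in range(n)}
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        children[nxt] = (a, b)
        times[nxt] = t
        active.append(nxt)
        nxt += 1
    return children, times, active[0]


def _leaves_below(node: int, children: dict, n: int, cache: dict) -> list[int]:
    if node in cache:
        return cache[node]
    if node < n:
        res = [node]
    else:
        a, b = children[node]
        res = _leaves_below(a, children, n, cache) + _leaves_below(b, children, n, cache)
    cache[node] = res
    return res


def simulate_haplotypes(cfg: CoalescentConfig) -> tuple[HaplotypeSet, dict]:
    """Sample haplotypes under the standard neutral coalescent.

    Nucleotide mode: mutations are Poisson on branches at theta/2 per site
    (so E[S] = theta_per_site * L * a1) and each lands on a fresh site
    (infinite sites).  Codon mode: an ancestral stop-free codon sequence is
    evolved along the tree; each attempted substitution is rejected if it
    creates a stop and accepted with probability omega when nonsynonymous.
    Returns the haplotype set and a truth record.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_samples, cfg.sequence_length
    children, times, root = _coalescent_branches(n, rng)
    cache: dict = {}
    code = default_code()

    if cfg.omega is None:
        theta_total = cfg.theta_per_site * L
        mutations: list[list[int]] = []  # carriers per mutation
        total_branch = 0.0
        for node in list(times):
            if node == root:
                continue
            parent = next(p for p, (a, b) in children.items() if node in (a, b))
            blen = times[parent] - times[node]
            total_branch += blen
            n_mut = rng.poisson(theta_total / 2 * blen)
            for _ in range(n_mut):
                mutations.append(_leaves_below(node, children, n, cache))
        S = len(mutations)
        if S > L:
            raise ValueError(
                f"{S} mutations exceed {L} sites; lower theta or lengthen the region"
            )
        sites = rng.choice(L, size=S, replace=False)
        anc = rng.integers(0, 4, size=L)
        mat = np.tile(anc, (n, 1))
        for site, carriers in zip(sites, mutations):
            derived = (anc[site] + rng.integers(1, 4)) % 4
            mat[carriers, site] = derived
        rows = ["".join(BASES[r]) for r in mat]
        truth = {
            "theta_per_site": cfg.theta_per_site,
            "S": S,
            "total_branch_length": total_branch,
            "mode": "infinite_sites",
        }
    else:
        ncod = L // 3
        anc_codons = []
        while len(anc_codons) < ncod:
            c = "".join(rng.choice(BASES, size=3))
            if not code.is_stop(c):
                anc_codons.append(c)
        rate_total = cfg.theta_per_site / 2 * 3 * ncod  # attempts per branch-time

        seqs: dict[int, list[str]] = {root: anc_codons}

        def _evolve(node: int) -> None:
            if node < n:
                return
            a, b = children[node]
            for child in (a, b):
                blen = times[node] - times[child]
                cs = list(seqs[node])
                for _ in range(rng.poisson(rate_total * blen)):
                    ci = rng.integers(0, ncod)
                    pos = rng.integers(0, 3)
                    codon = cs[ci]
                    alts = [x for x in "ACGT" if x != codon[pos]]
                    cand = codon[:pos] + alts[rng.integers(0, 3)] + codon[pos + 1 :]
                    if code.is_stop(cand):
                        continue
                    if code.aa(cand) != code.aa(codon) and rng.random() >= cfg.omega:
                        continue
                    cs[ci] = cand
                seqs[child] = cs
                _evolve(child)

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * n + 100))
        _evolve(root)
        sys.setrecursionlimit(old)
        rows = ["".join(seqs[i]) for i in range(n)]
        truth = {
            "theta_per_site": cfg.theta_per_site,
            "omega": cfg.omega,
            "mode": "codon",
        }
    hs = HaplotypeSet(cfg.region, rows, frame_offset=cfg.frame_offset, code=code)
    return hs, truth


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrSimConfig:
    """Synthetic qPCR experiment emulating a DUI tissue panel.

    Defaults describe the male-mantle mixture: every sample has a somatic
    F-mtDNA load per nuclear genome drawn log-uniformly from
    ``somatic_f_range`` and an M load ``true_intercept + true_slope * F``
    (the sperm contribution plus the soma-correlated trend); female-mantle
    samples carry only trace M at a planted F/M ratio in
    ``female_fm_ratio_range``.  Cq values come from per-target log-linear
    standard curves with Gaussian replicate noise ``sigma_cq``.
    """

    true_intercept: float = 15.06
    true_slope: float = 0.8
    n_samples: int = 18
    somatic_f_range: tuple[float, float] = (1.0, 80.0)
    somatic_f_levels: Sequence[float] | None = None
    female_f_range: tuple[float, float] = (200.0, 3000.0)
    female_fm_ratio_range: tuple[float, float] = (300.0, 10_000.0)
    nuclear_copies: float = 5000.0
    sigma_cq: float = 0.1
    biological_sd: float = 0.0  # sample-level scatter of M/nDNA around the line
    n_replicates: int = 3
    n_experiments: int = 3
    dilution_decades: int = 7
    curve_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "F_cox1": (-3.3219, 37.0),
            "M_nad1": (-3.3219, 37.5),
            "nuclear_atpa": (-3.3219, 36.5),
        }
    )
    include_female: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_cq < 0:
            raise ValueError("sigma_cq must be non-negative")
        for t, (slope, _) in self.curve_params.items():
            if slope >= 0:
                raise ValueError(f"{t}: curve slope must be negative")
        if self.true_intercept < 0 or self.true_slope < 0:
            raise ValueError("planted copy parameters must be non-negative")


@dataclass
class QpcrTruth:
    intercept: float
    slope: float
    somatic_f: np.ndarray
    male_m: np.ndarray
    female_f: np.ndarray
    female_fm_ratio: np.ndarray
    nuclear_copies: float
    curve_params: dict


def _cq_for(copies: float, slope: float, icq: float, rng, sigma: float, k: int):
    if copies <= 0:
        return [np.nan] * k
    base = icq + slope * math.log10(copies)
    return list(base + rng.normal(0.0, sigma, size=k)) if sigma > 0 else [base] * k


def simulate_qpcr_dataset(
    cfg: QpcrSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, QpcrTruth]:
    """Generate dilution-series and tissue-sample Cq tables plus truth.

    Returns ``(dilutions, samples, truth)``; ``dilutions`` has columns
    target/experiment/copies/cq, ``samples`` has columns
    sample_id/tissue/target/replicate/cq.
    """
    cfg = cfg or QpcrSimConfig()
    rng = np.random.default_rng(cfg.seed)

    dil_rows = []
    for target, (slope, icq) in cfg.curve_params.items():
        for exp in range(1, cfg.n_experiments + 1):
            for dec in range(1, cfg.dilution_decades + 1):
                copies = 10.0**dec
                for cq in _cq_for(copies, slope, icq, rng, cfg.sigma_cq, 3):
                    dil_rows.append(
                        {"target": target, "experiment": exp, "copies": copies,
                         "cq": cq}
                    )
    dilutions = pd.DataFrame(dil_rows)

    if cfg.somatic_f_levels is not None:
        somatic = np.asarray(list(cfg.somatic_f_levels), dtype=float)
        n = len(somatic)
    else:
        n = cfg.n_samples
        lo, hi = cfg.somatic_f_range
        somatic = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    male_m = cfg.true_intercept + cfg.true_slope * somatic
    if cfg.biological_sd > 0:
        male_m = np.clip(
            male_m + rng.normal(0.0, cfg.biological_sd, size=n), 0.01, None
        )
    lo, hi = cfg.female_f_range
    female_f = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    rlo, rhi = cfg.female_fm_ratio_range
    female_ratio = np.exp(rng.uniform(math.log(rlo), math.log(rhi), size=n))

    sample_rows = []

    def _emit(sid: str, tissue: str, target: str, copies: float) -> None:
        slope, icq = cfg.curve_params[target]
        for r, cq in enumerate(
            _cq_for(copies, slope, icq, rng, cfg.sigma_cq, cfg.n_replicates), 1
        ):
            sample_rows.append(
                {"sample_id": sid, "tissue": tissue, "target": target,
                 "replicate": r, "cq": cq}
            )

    nuc = cfg.nuclear_copies
    for i in range(n):
        sid = f"S{i + 1:02d}"
        _emit(sid, "male_mantle", "nuclear_atpa", nuc)
        _emit(sid, "male_mantle", "F_cox1", somatic[i] * nuc)
        _emit(sid, "male_mantle", "M_nad1", male_m[i] * nuc)
        if cfg.include_female:
            _emit(sid, "female_mantle", "nuclear_atpa", nuc)
            _emit(sid, "female_mantle", "F_cox1", female_f[i] * nuc)
            _emit(sid, "female_mantle", "M_nad1", female_f[i] / female_ratio[i] * nuc)
    samples = pd.DataFrame(sample_rows)
    truth = QpcrTruth(
        intercept=cfg.true_intercept,
        slope=cfg.true_slope,
        somatic_f=somatic,
        male_m=male_m,
        female_f=female_f,
        female_fm_ratio=female_ratio,
        nuclear_copies=nuc,
        curve_params=dict(cfg.curve_params),
    )
    return dilutions, samples, truth


def simulate_ngs_counts(
    true_ratio: float,
    len_m: float,
    len_f: float,
    total_reads: int,
    seed: int | None = None,
) -> tuple[int, int]:
    """Binomial read split between two mitogenomes at a known copy ratio.

    A molecule ratio r (M copies per F copy) and genome lengths translate
    into a per-read probability ``p = r*len_M / (r*len_M + len_F)`` of
    mapping to M; :func:`mitodui.quantify.ngs_ratio` inverts this mapping
    in expectation.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if true_ratio < 0 or len_m <= 0 or len_f <= 0:
        raise ValueError("invalid ratio or lengths")
    rng = np.random.default_rng(seed)
    p = true_ratio * len_m / (true_ratio * len_m + len_f)
    reads_m = int(rng.binomial(total_reads, p))
    return reads_m, total_reads - reads_m
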