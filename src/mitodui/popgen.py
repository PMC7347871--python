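"""Population-genetic summaries of mitotype haplotype sets.

For each sequenced region (e.g. fragments of ND5, ND6, CYTB from the F and
M mitogenomes of many individuals) this module computes the standard row of
diversity indices: sample size N, haplotype number h, segregating sites S,
haplotype diversity hd, Watterson's theta, nucleotide diversity pi,
Tajima's D with its beta-distribution significance test, and Nei-Gojobori
Ka/Ks (Jukes-Cantor corrected) with codon-bootstrap standard errors.

Columns containing gaps or N are excluded from all site-based statistics
(complete deletion).  Watterson's theta is reported both per site and per
sequence, since published tables are often ambiguous about the scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneticCode, default_code

__all__ = [
    "HaplotypeSet",
    "PopGenSummary",
    "diversity_stats",
    "tajimas_d",
    "tajima_constants",
    "nei_gojobori_kaks",
    "region_summary",
    "concatenate",
]

_NT = np.array(list("ACGT"))


@dataclass
class HaplotypeSet:
    """Equal-length coding-frame nucleotide sequences from one region."""

    region: str
    rows: list[str]
    frame_offset: int = 0
    code: GeneticCode | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("haplotypes differ in length")
        if self.code is None:
            self.code = default_code()
        if self.names is None:
            self.names = [f"{self.region}_{i + 1}" for i in range(len(self.rows))]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def codon_rows(self) -> list[str]:
        """Rows trimmed to complete codons from the frame offset."""
        ncod = (self.length - self.frame_offset) // 3
        lo = self.frame_offset
        return [r[lo : lo + 3 * ncod] for r in self.rows]


@dataclass
class PopGenSummary:
    """One summary row for a region (or a concatenation of regions)."""

    region: str
    N: int
    h: int
    S: int
    hd: float
    theta_per_site: float
    theta_per_sequence: float
    pi: float
    tajima_D: float
    D_significant: bool
    Ka: float
    Ka_SE: float
    Ks: float
    Ks_SE: float
    Ka_over_Ks: float
    L_used: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _clean_columns(mat: np.ndarray) -> np.ndarray:
    """Columns free of gaps/ambiguity in every row (complete deletion)."""
    ok = np.isin(mat, _NT).all(axis=0)
    return mat[:, ok]


def diversity_stats(hs: HaplotypeSet) -> tuple[int, int, int, float, float, float]:
    """(N, h, S, hd, theta_per_site, pi) for one haplotype set.

    hd is the unbiased haplotype diversity ``N/(N-1) * (1 - sum p_i^2)``;
    Watterson's theta is ``S / (a1 * L)`` with ``a1 = sum_{i<N} 1/i``; pi is
    the mean number of pairwise differences per usable site over all
    ``C(N,2)`` pairs.
    """
    if hs.n < 2:
        raise ValueError("need at least two sequences")
    mat = _clean_columns(hs.matrix())
    n, L = mat.shape
    if L == 0:
        raise ValueError("no gap-free columns")
    S = int(np.sum((mat != mat[0]).any(axis=0)))
    haplos = ["".join(row) for row in mat]
    counts = pd.Series(haplos).value_counts().to_numpy()
    h = len(counts)
    freqs = counts / n
    hd = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    a1 = sum(1.0 / i for i in range(1, n))
    theta_site = S / (a1 * L)
    # pi: mean pairwise differences per site; column-wise heterozygosity sum
    diffs = 0
    for i, j in combinations(range(n), 2):
        diffs += int(np.sum(mat[i] != mat[j]))
    pi = diffs / math.comb(n, 2) / L
    return n, h, S, hd, theta_site, pi


def tajima_constants(n: int) -> dict[str, float]:
    """The sample-size constants of Tajima's neutrality test."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _tajima_beta_limits(n: int, cst: dict[str, float]) -> tuple[float, float]:
    """Smallest and largest attainable D in the large-S limit."""
    a1, e2 = cst["a1"], cst["e2"]
    d_min = (2 / n - 1 / a1) / math.sqrt(e2)
    if n % 2 == 0:
        d_max = (n / (2 * (n - 1)) - 1 / a1) / math.sqrt(e2)
    else:
        d_max = ((n + 1) / (2 * n) - 1 / a1) / math.sqrt(e2)
    return d_min, d_max


def tajimas_d(hs: HaplotypeSet) -> tuple[float, bool, float]:
    """Tajima's D and its significance at p < 0.05.

    D standardises the difference between the pairwise-difference estimator
    of theta and the segregating-sites estimator.  Significance follows the
    beta-distribution approximation over the attainable range of D, scaled
    to mean 0 and variance 1.  Returns ``(D, significant, p_value)``;
    D is NaN (and not significant) when S == 0.
    """
    if hs.n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    n, _, S, _, _, pi = diversity_stats(hs)
    if S == 0:
        return float("nan"), False, float("nan")
    mat = _clean_columns(hs.matrix())
    L = mat.shape[1]
    cst = tajima_constants(n)
    num = pi * L - S / cst["a1"]
    den = math.sqrt(cst["e1"] * S + cst["e2"] * S * (S - 1))
    D = num / den
    a, b = _tajima_beta_limits(n, cst)
    # beta density over [a, b] with mean 0 and variance 1
    alpha = -(1 + a * b) * b / (b - a)
    beta = (1 + a * b) * a / (b - a)
    x = (D - a) / (b - a)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    p = 2 * min(cdf, 1 - cdf)
    return D, bool(p < 0.05), float(p)


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _jc_correct(p: float) -> float:
    """Jukes-Cantor correction of a proportion of differences; NaN when
    saturated (p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _codon_arrays(rows: Sequence[str], code: GeneticCode):
    """Split rows into codon lists, masking codons with gaps/N or stops."""
    ncod = len(rows[0]) // 3
    codons = []
    valid = np.ones((len(rows), ncod), dtype=bool)
    for i, r in enumerate(rows):
        cl = [r[3 * j : 3 * j + 3] for j in range(ncod)]
        codons.append(cl)
        for j, c in enumerate(cl):
            if any(ch not in "ACGT" for ch in c) or code.is_stop(c):
                valid[i, j] = False
    return codons, valid


def nei_gojobori_kaks(
    hs: HaplotypeSet,
    groups: tuple[Sequence[int], Sequence[int]] | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Nei-Gojobori Ka and Ks with Jukes-Cantor correction.

    Site counts use per-position synonymous fractions (changes to stop
    codons excluded); differences between codons average the synonymous and
    nonsynonymous steps over all minimal mutational pathways that avoid
    stop codons.  With ``groups`` given as two index lists, distances are
    averaged over between-group pairs (divergence mode); otherwise over all
    pairs (within-sample polymorphism mode).  Standard errors come from a
    codon-resampling bootstrap of the mean-over-pairs statistic.

    Returns a dict with Ka, Ka_SE, Ks, Ks_SE, Ka_over_Ks, n_pairs.
    """
    code = hs.code or default_code()
    rows = hs.codon_rows()
    if len(rows[0]) < 3:
        raise ValueError("no complete codon")
    codons, valid = _codon_arrays(rows, code)
    ncod = valid.shape[1]
    if groups is None:
        pairs = list(combinations(range(hs.n), 2))
    else:
        ga, gb = groups
        pairs = [(i, j) for i in ga for j in gb]
    if not pairs:
        raise ValueError("no sequence pairs")

    # per-pair per-codon arrays so the codon bootstrap is a reindexing
    npairs = len(pairs)
    sd_arr = np.zeros((npairs, ncod))
    nd_arr = np.zeros((npairs, ncod))
    s_sites = np.zeros((npairs, ncod))
    n_sites = np.zeros((npairs, ncod))
    use = np.zeros((npairs, ncod), dtype=bool)
    site_cache: dict[str, tuple[float, float]] = {}
    path_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for k, (i, j) in enumerate(pairs):
        for c in range(ncod):
            if not (valid[i, c] and valid[j, c]):
                continue
            ca, cb = codons[i][c], codons[j][c]
            for cd in (ca, cb):
                if cd not in site_cache:
                    site_cache[cd] = code.codon_sites(cd)
            key = (ca, cb) if ca <= cb else (cb, ca)
            if key not in path_cache:
                path_cache[key] = code.pathway_counts(*key)
            sd, nd = path_cache[key]
            sa, na = site_cache[ca]
            sb, nb = site_cache[cb]
            use[k, c] = True
            sd_arr[k, c] = sd
            nd_arr[k, c] = nd
            s_sites[k, c] = (sa + sb) / 2
            n_sites[k, c] = (na + nb) / 2

    def _jc_vec(p: np.ndarray) -> np.ndarray:
        out = np.full_like(p, np.nan)
        ok = p < 0.75
        out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
        return out

    def _stat(cols: np.ndarray) -> tuple[float, float]:
        # unused codons hold zeros, so plain column sums are correct
        Ssite = s_sites[:, cols].sum(axis=1)
        Nsite = n_sites[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = np.where(Ssite > 0, sd_arr[:, cols].sum(axis=1) / Ssite, 0.0)
            pn = np.where(Nsite > 0, nd_arr[:, cols].sum(axis=1) / Nsite, 0.0)
        alive = use[:, cols].any(axis=1)
        ps[~alive] = np.nan
        pn[~alive] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(_jc_vec(pn))), float(np.nanmean(_jc_vec(ps)))

    all_cols = np.arange(ncod)
    ka, ks = _stat(all_cols)
    if bootstrap_reps > 1:
        rng = np.random.default_rng(seed)
        ka_reps = np.empty(bootstrap_reps)
        ks_reps = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            cols = rng.integers(0, ncod, size=ncod)
            ka_reps[r], ks_reps[r] = _stat(cols)
        with np.errstate(invalid="ignore"):
            ka_se = float(np.nanstd(ka_reps, ddof=1))
            ks_se = float(np.nanstd(ks_reps, ddof=1))
    else:
        ka_se = ks_se = float("nan")
    ratio = ka / ks if ks and not math.isnan(ks) and ks > 0 else float("nan")
    return {
        "Ka": ka,
        "Ka_SE": ka_se,
        "Ks": ks,
        "Ks_SE": ks_se,
        "Ka_over_Ks": ratio,
        "n_pairs": npairs,
    }


def pairwise_kaks(a: str, b: str, code: GeneticCode | None = None) -> dict[str, float]:
    """Ka/Ks for a single pair of in-frame sequences (no bootstrap)."""
    hs = HaplotypeSet("pair", [a, b], code=code)
    return nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)


def concatenate(sets: Sequence[HaplotypeSet], region: str = "concat") -> HaplotypeSet:
    """Join regions row-wise; all regions must share N and codon frame."""
    ns = {s.n for s in sets}
    if len(ns) != 1:
        raise ValueError("regions differ in sample size")
    rows = ["".join(s.codon_rows()[i] for s in sets) for i in range(sets[0].n)]
    return HaplotypeSet(region, rows, frame_offset=0, code=sets[0].code)


def region_summary(
    hs: HaplotypeSet,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> PopGenSummary:
    """Assemble the full summary row for one region (or concatenation)."""
    n, h, S, hd, theta_site, pi = diversity_stats(hs)
    mat = _clean_columns(hs.matrix())
    L = mat.shape[1]
    if n >= 4 and S >= 1:
        D, signif, _ = tajimas_d(hs)
    else:
        D, signif = float("nan"), False
    kaks = nei_gojobori_kaks(hs, bootstrap_reps=bootstrap_reps, seed=seed)
    return PopGenSummary(
        region=hs.region,
        N=n,
        h=h,
        S=S,
        hd=hd,
        theta_per_site=theta_site,
        theta_per_sequence=theta_site * L,
        pi=pi,
        tajima_D=D,
        D_significant=signif,
        Ka=kaks["Ka"],
        Ka_SE=kaks["Ka_SE"],
        Ks=kaks["Ks"],
        Ks_SE=kaks["Ks_SE"],
        Ka_over_Ks=kaks["Ka_over_Ks"],
        L_used=L,
    )


def summary_table(summaries: Sequence[PopGenSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
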