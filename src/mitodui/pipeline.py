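"""End-to-end report assembly: run every stage on one input bundle.

The pipeline reads a plain YAML key-value config (or a RunConfig built in
code), executes the requested stages in dependency order and writes one
TSV per stage output plus a run log.  With ``simulate: true`` all inputs
are generated by :mod:`mitodui.simulate` from the config seed, so a full
report is reproducible offline; identical seeds give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import core, divergence, popgen, quantify, simulate, skew, sperm

logger = logging.getLogger("mitodui")

__all__ = ["RunConfig", "run_pipeline"]

NEUTRAL_FILTER = ("codon_pos3_4fold", "noncoding")
POS2_FILTER = ("codon_pos2", "noncoding")

FILTER_ALIASES = {
    "neutral": "codon_pos3_4fold",
    "second": "codon_pos2",
    "noncoding": "noncoding",
    "rna": "rna_gene",
}


def resolve_filter(spec: str | None) -> tuple[str, ...] | None:
    """Translate a comma-separated filter spec (aliases allowed) to labels."""
    if not spec:
        return None
    labels = []
    for token in spec.split(","):
        token = token.strip()
        labels.append(FILTER_ALIASES.get(token, token))
    return tuple(labels)


@dataclass
class RunConfig:
    """Parameters and input paths for one pipeline run."""

    outdir: str = "mitodui_report"
    seed: int = 0
    simulate: bool = True
    # stage parameters; defaults follow the conventional analysis settings
    window: int = 200
    step: int = 25
    neutral_window: int = 1000
    bootstrap_reps: int = 10_000
    kaks_bootstrap_reps: int = 1000
    code_table: int = 5
    cq_cutoff: float = 35.0
    n_mito: int = 5
    ci_level: float = 0.95
    divergence_target: float = 0.347
    theta_per_site: float = 0.02
    popgen_regions: Mapping[str, int] = field(
        default_factory=lambda: {"ND5": 1317, "ND6": 417, "CYTB": 663}
    )
    popgen_n: int = 18
    # real-data inputs (used when simulate is false)
    genome_f: str | None = None
    genome_m: str | None = None
    alignment_dir: str | None = None
    haplotype_fastas: Mapping[str, str] = field(default_factory=dict)
    dilutions_tsv: str | None = None
    samples_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mitodui config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _skew_stage(cfg: RunConfig, genomes, outdir: Path) -> None:
    for genome in genomes:
        mask = core.classify_sites(genome)
        tag = genome.label if genome.label in "FM" else genome.name
        tracks = {
            f"at_skew_{tag}": skew.windowed_index(
                genome, "AT_skew", cfg.window, cfg.step, mask=mask
            ),
            f"at_skew_pos2nc_{tag}": skew.windowed_index(
                genome, "AT_skew", cfg.window, cfg.step,
                site_filter=POS2_FILTER, mask=mask,
            ),
            f"at_skew_neutral_{tag}": skew.windowed_index(
                genome, "AT_skew", cfg.neutral_window, cfg.step,
                site_filter=NEUTRAL_FILTER, mask=mask,
            ),
            f"gc_skew_{tag}": skew.windowed_index(
                genome, "GC_skew", cfg.window, cfg.step, mask=mask
            ),
            f"gc_skew_neutral_{tag}": skew.windowed_index(
                genome, "GC_skew", cfg.neutral_window, cfg.step,
                site_filter=NEUTRAL_FILTER, mask=mask,
            ),
            f"gc_content_rel_{tag}": skew.windowed_index(
                genome, "GC_content", cfg.window, cfg.step, relative=True, mask=mask
            ),
        }
        for name, track in tracks.items():
            track.to_tsv(outdir / f"skew_{name}.tsv")
        core.write_feature_table(genome, outdir / f"features_{tag}.tsv")
    logger.info("skew stage: %d genomes scanned", len(genomes))


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Execute all stages and write the report bundle under ``cfg.outdir``.

    Returns a dict of the main in-memory results (divergence table, popgen
    table, quantification tables, sperm-model results).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    rng = np.random.default_rng(cfg.seed)
    results: dict[str, object] = {}
    logger.info("config %s seed %d", cfg.digest(), cfg.seed)

    try:
        # --- genomes + alignments -------------------------------------
        if cfg.simulate:
            pair_cfg = simulate.MitoPairConfig(
                divergence=cfg.divergence_target,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            genome_f, genome_m, alignments = simulate.simulate_mitogenome_pair(pair_cfg)
        else:
            if not (cfg.genome_f and cfg.genome_m):
                raise FileNotFoundError("genome_f and genome_m paths are required")
            genome_f = core.parse_genbank(cfg.genome_f)
            genome_m = core.parse_genbank(cfg.genome_m)
            alignments = {}
            if cfg.alignment_dir:
                for p in sorted(Path(cfg.alignment_dir).glob("*.fasta")):
                    alignments[p.stem] = divergence.MultiAlignment.from_fasta(p)

        _skew_stage(cfg, [genome_f, genome_m], outdir)

        if alignments:
            div = divergence.per_gene_divergence(
                genome_f, genome_m, alignments,
                bootstrap_reps=cfg.bootstrap_reps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _write_tsv(div, outdir / "divergence.tsv", cfg)
            results["divergence"] = div
            logger.info(
                "divergence stage: overall p = %.4f",
                float(div.loc[div.gene == "overall", "p_distance"].iloc[0]),
            )

        # --- popgen ----------------------------------------------------
        hap_sets = []
        if cfg.simulate:
            for region, length in cfg.popgen_regions.items():
                hs, _ = simulate.simulate_haplotypes(
                    simulate.CoalescentConfig(
                        n_samples=cfg.popgen_n,
                        sequence_length=length,
                        theta_per_site=cfg.theta_per_site,
                        region=region,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
                hap_sets.append(hs)
        else:
            for region, path in cfg.haplotype_fastas.items():
                rows = [s for _, s in core.read_fasta(path)]
                hap_sets.append(popgen.HaplotypeSet(region, rows))
        if hap_sets:
            summaries = [
                popgen.region_summary(
                    hs, bootstrap_reps=cfg.kaks_bootstrap_reps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for hs in hap_sets
            ]
            if len(hap_sets) > 1:
                summaries.append(
                    popgen.region_summary(
                        popgen.concatenate(hap_sets),
                        bootstrap_reps=cfg.kaks_bootstrap_reps,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
            pop_table = popgen.summary_table(summaries)
            _write_tsv(pop_table, outdir / "popgen.tsv", cfg)
            results["popgen"] = pop_table
            logger.info("popgen stage: %d regions", len(summaries))

        # --- quantification ---------------------------------------------
        if cfg.simulate:
            dil, samp, truth = simulate.simulate_qpcr_dataset(
                simulate.QpcrSimConfig(seed=int(rng.integers(0, 2**31 - 1)))
            )
            results["qpcr_truth"] = truth
        else:
            if not (cfg.dilutions_tsv and cfg.samples_tsv):
                dil = samp = None
            else:
                dil = pd.read_csv(cfg.dilutions_tsv, sep="\t", comment="#")
                samp = pd.read_csv(cfg.samples_tsv, sep="\t", comment="#")
        if dil is not None:
            curves, quant = quantify.quantify_table(
                dil, samp, detection_cutoff=cfg.cq_cutoff
            )
            curve_df = pd.DataFrame(
                [
                    {"target": c.target, "slope": c.slope,
                     "intercept_cq": c.intercept_cq, "r_squared": c.r_squared,
                     "efficiency": c.efficiency, "qc_pass": c.qc_pass}
                    for c in curves.values()
                ]
            )
            _write_tsv(curve_df, outdir / "standard_curves.tsv", cfg)
            _write_tsv(quant, outdir / "sample_quant.tsv", cfg)
            loads, ratios = per_ndna_loads(quant, curves, cq_cutoff=cfg.cq_cutoff)
            _write_tsv(loads, outdir / "per_ndna_loads.tsv", cfg)
            _write_tsv(ratios, outdir / "mf_ratios.tsv", cfg)
            results.update(curves=curves, quant=quant, loads=loads, ratios=ratios)
            for c in curves.values():
                if not c.qc_pass:
                    logger.warning("curve %s fails efficiency QC", c.target)

            # --- sperm model -------------------------------------------
            male = loads[loads.tissue == "male_mantle"]
            usable = male[~male.M_below_detection]
            n_excl = len(male) - len(usable)
            if n_excl:
                logger.warning("sperm model: %d below-detection points excluded",
                               n_excl)
            if len(usable) >= 3:
                model = sperm.SpermCopyModel(
                    [
                        sperm.TissuePoint(r.sample_id, r.F_per_nDNA, r.M_per_nDNA)
                        for r in usable.itertuples()
                    ]
                )
                fit = model.fit(ci_level=cfg.ci_level)
                fit.copies_per_mitochondrion(cfg.n_mito)
                fit_df = pd.DataFrame(
                    [
                        {"slope": fit.slope, "intercept": fit.intercept,
                         "intercept_se": fit.intercept_se,
                         "intercept_ci_low": fit.intercept_ci[0],
                         "intercept_ci_high": fit.intercept_ci[1],
                         "r_squared": fit.r_squared, "n_points": fit.n_points,
                         "n_mitochondria_assumed": cfg.n_mito,
                         "copies_per_mitochondrion":
                             fit.copies_per_mitochondrion(cfg.n_mito)}
                    ]
                )
                _write_tsv(fit_df, outdir / "sperm_model.tsv", cfg)
                (outdir / "sperm_model_summary.txt").write_text(fit.summary() + "\n")
                results["sperm_fit"] = fit
                logger.info("sperm model: intercept %.2f copies/sperm", fit.intercept)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return results


def per_ndna_loads(
    quant: pd.DataFrame,
    curves: Mapping[str, quantify.StandardCurve],
    nuclear_target: str = "nuclear_atpa",
    f_target: str = "F_cox1",
    m_target: str = "M_nad1",
    cq_cutoff: float = 35.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mtDNA loads per nuclear genome and M/F (or F/M) ratios.

    Takes the tidy quantification table from
    :func:`mitodui.quantify.quantify_table` and pivots it into one row per
    sample x tissue with F and M copies per nuclear copy, plus a ratio
    table with delta-method intervals.
    """
    wide = quant.pivot_table(
        index=["sample_id", "tissue"], columns="target",
        values=["copies", "mean_cq", "below_detection"], aggfunc="first",
    )
    rows, ratio_rows = [], []
    for (sid, tissue), r in wide.iterrows():
        nuc = r[("copies", nuclear_target)]
        f_cop = r[("copies", f_target)]
        m_cop = r[("copies", m_target)]
        m_bd = bool(r[("below_detection", m_target)])
        f_bd = bool(r[("below_detection", f_target)])
        rows.append(
            {"sample_id": sid, "tissue": tissue,
             "F_per_nDNA": f_cop / nuc, "M_per_nDNA": m_cop / nuc,
             "F_below_detection": f_bd, "M_below_detection": m_bd}
        )
        num_t, den_t = (m_target, f_target)
        if tissue == "female_mantle":
            num_t, den_t = f_target, m_target
        sub = quant[(quant.sample_id == sid) & (quant.tissue == tissue)]

        def _sq(t):
            row = sub[sub.target == t].iloc[0]
            return quantify.SampleQuant(
                sample_id=sid, tissue=tissue, target=t, mean_cq=row.mean_cq,
                copies=row.copies, ci_low=row.ci_low, ci_high=row.ci_high,
                n_replicates=int(row.n_replicates), cq_se=float(row.cq_se),
                curve=curves[t], below_detection=bool(row.below_detection),
            )

        est = quantify.ratio_with_ci(_sq(num_t), _sq(den_t))
        ratio_rows.append(
            {"sample_id": sid, "tissue": tissue,
             "numerator": num_t, "denominator": den_t,
             "ratio": est.ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
             "below_detection": est.below_detection}
        )
    return pd.DataFrame(rows), pd.DataFrame(ratio_rows)
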