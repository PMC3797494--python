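"""End-to-end orchestration: validate -> diversity -> SGS -> sigma -> meta.

A :class:`RunConfig` fully determines a run; it is serialized into the
output directory so any run can be reproduced bit-for-bit from its saved
config (the run log carries a wall-clock stamp, the result files do not).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .datamodel import DensityInfo, ValidationError, validate_dataset
from .diversity import (
    fis_inference,
    locus_summary_table,
    multilocus_fis_excluding_null,
    wc_f_statistics,
)
from .io import (
    read_coordinates,
    read_genotype_table,
    read_summary,
    write_summary,
)
from .meta import anova_log_sp, group_summary, load_sp_table, sp_ratio_range
from .sgs import sgs_analysis

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

NULL_FLAG_THRESHOLD = 0.05  # loci with estimated null freq above this are excluded
                            # from the modified multilocus F_IS


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genotype_path: str
    coords_path: str
    output_dir: str
    genotype_format: str = "genepop"
    density_per_ha: Optional[float] = None
    ne_over_n: float = 0.25
    n_distance_classes: int = 7
    min_pairs_per_class: int = 100
    n_permutations: int = 10_000
    seed: int = 0
    null_method: str = "brookfield1"
    min_cluster_n: int = 45  # SGS floor for per-cluster analyses
    min_individuals: int = 10
    meta_table_path: Optional[str] = None
    run_meta: bool = False

    def to_file(self, path) -> None:
        write_summary(
            {k: "" if v is None else v for k, v in dataclasses.asdict(self).items()},
            path,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = read_summary(path)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if text == "":
                kwargs[f.name] = None
            elif f.type in ("int", int):
                kwargs[f.name] = int(text)
            elif f.type in ("float", float) or f.name in ("density_per_ha",):
                kwargs[f.name] = float(text)
            elif f.type in ("bool", bool):
                kwargs[f.name] = text in ("True", "true", "1")
            elif f.name in ("ne_over_n",):
                kwargs[f.name] = float(text)
            else:
                kwargs[f.name] = text
        # dataclasses stores annotations as strings; coerce the numerics
        for name in ("n_distance_classes", "min_pairs_per_class", "n_permutations",
                     "seed", "min_cluster_n", "min_individuals"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = int(kwargs[name])
        for name in ("density_per_ha", "ne_over_n"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = float(kwargs[name])
        if "run_meta" in kwargs and isinstance(kwargs["run_meta"], str):
            kwargs["run_meta"] = kwargs["run_meta"] in ("True", "true", "1")
        return cls(**kwargs)


def _sgs_block(g, coords, density, cfg, seed, log, label, summary):
    res = sgs_analysis(
        g,
        coords,
        density=density,
        n_classes=cfg.n_distance_classes,
        min_pairs=cfg.min_pairs_per_class,
        n_perm=cfg.n_permutations,
        seed=seed,
    )
    out = Path(cfg.output_dir)
    res.correlogram.to_csv(out / f"correlogram_{label}.tsv", sep="\t", index=False)
    summary[f"sgs.{label}.b_log"] = f"{res.b_log:.6g}"
    summary[f"sgs.{label}.r2"] = f"{res.r2:.6g}"
    summary[f"sgs.{label}.F1"] = f"{res.f1:.6g}"
    summary[f"sgs.{label}.first_class_upper_m"] = f"{res.first_class_upper:.6g}"
    summary[f"sgs.{label}.Sp"] = f"{res.sp:.6g}"
    summary[f"sgs.{label}.Nb"] = f"{res.nb:.6g}" if res.nb else "NA"
    summary[f"sgs.{label}.p_slope"] = f"{res.p_value:.6g}"
    summary[f"sgs.{label}.n_pairs"] = res.n_pairs
    summary[f"sgs.{label}.n_zero_distance_excluded"] = res.n_zero_excluded
    if res.sigma is not None:
        summary[f"sgs.{label}.sigma_m"] = (
            f"{res.sigma.sigma:.6g}" if np.isfinite(res.sigma.sigma) else "NA"
        )
        summary[f"sgs.{label}.sigma_converged"] = res.sigma.converged
    log.append(f"sgs[{label}]: b_log={res.b_log:.6g} Sp={res.sp:.6g}")
    return res


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary key-value dict.

    Stages: validate -> diversity -> SGS (per population, and per cluster
    with at least ``min_cluster_n`` individuals) -> sigma (inside SGS when a
    density is configured) -> optional meta-analysis. A stage failure raises
    :class:`PipelineError` naming the stage; partial outputs are preserved.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "config.txt")
    summary: dict = {"version": __version__, "seed": cfg.seed}
    log: list[str] = [f"sgskit {__version__}", f"config: {dataclasses.asdict(cfg)}"]

    stage = "validate"
    try:
        g = read_genotype_table(cfg.genotype_path, cfg.genotype_format)
        coords = read_coordinates(cfg.coords_path)
        g, coords, report = validate_dataset(g, coords, cfg.min_individuals)
        summary["n_individuals"] = g.n_individuals
        summary["n_loci"] = g.n_loci
        summary["n_dropped_genotypes"] = len(report.dropped_genotype_ids)
        summary["n_dropped_coordinates"] = len(report.dropped_coordinate_ids)
        if report.dropped_genotype_ids:
            log.append(f"dropped genotype ids: {report.dropped_genotype_ids}")
        if report.dropped_coordinate_ids:
            log.append(f"dropped coordinate ids: {report.dropped_coordinate_ids}")

        stage = "diversity"
        div = locus_summary_table(g, null_method=cfg.null_method)
        div.to_csv(out / "locus_summary.tsv", sep="\t", index=False)
        fis, fis_p = fis_inference(g, n_perm=cfg.n_permutations, seed=cfg.seed)
        summary["diversity.F_IS"] = f"{fis:.6g}"
        summary["diversity.F_IS_p"] = f"{fis_p:.6g}"
        flagged = div.loc[div["null_freq"] > NULL_FLAG_THRESHOLD, "locus"].tolist() \
            if "null_freq" in div else []
        summary["diversity.loci_flagged_null"] = ",".join(flagged) or "none"
        if flagged and g.n_loci - len(flagged) >= 2:
            fis_mod, se, p_mod = multilocus_fis_excluding_null(g, flagged)
            summary["diversity.F_IS_excl_null"] = f"{fis_mod:.6g}"
            summary["diversity.F_IS_excl_null_se"] = f"{se:.6g}"
            summary["diversity.F_IS_excl_null_p"] = f"{p_mod:.6g}"
        pops = set(g.population_labels or [])
        if len(pops) >= 2:
            fst = wc_f_statistics(g)
            summary["diversity.F_ST"] = f"{fst.theta:.6g}"
            if "theta" in fst.jackknife_se:
                summary["diversity.F_ST_jackknife_se"] = (
                    f"{fst.jackknife_se['theta']:.6g}"
                )

        stage = "sgs"
        density = (
            DensityInfo(cfg.density_per_ha, cfg.ne_over_n)
            if cfg.density_per_ha
            else None
        )
        pops = g.population_labels or ["all"] * g.n_individuals
        for pop in sorted(set(pops)):
            idx = [i for i, p in enumerate(pops) if p == pop]
            if len(idx) < cfg.min_individuals:
                log.append(f"sgs[{pop}]: skipped, n={len(idx)} < {cfg.min_individuals}")
                continue
            _sgs_block(
                g.subset_individuals(idx), coords.subset(idx), density, cfg,
                cfg.seed, log, pop, summary,
            )
        if g.cluster_labels is not None:
            for cl in sorted(set(g.cluster_labels)):
                idx = [i for i, c in enumerate(g.cluster_labels) if c == cl]
                if len(idx) < cfg.min_cluster_n:
                    log.append(
                        f"sgs[cluster {cl}]: skipped, n={len(idx)} < "
                        f"min_cluster_n={cfg.min_cluster_n}"
                    )
                    summary[f"sgs.cluster_{cl}.skipped"] = (
                        f"n={len(idx)}<{cfg.min_cluster_n}"
                    )
                    continue
                _sgs_block(
                    g.subset_individuals(idx), coords.subset(idx), density, cfg,
                    cfg.seed, log, f"cluster_{cl}", summary,
                )

        if cfg.run_meta:
            stage = "meta"
            table = load_sp_table(cfg.meta_table_path)
            group_summary(table).to_csv(
                out / "meta_group_summary.tsv", sep="\t", index=False
            )
            contrast = anova_log_sp(table)
            summary["meta.anova_F"] = f"{contrast.f_statistic:.6g}"
            summary["meta.anova_df"] = f"{contrast.df[0]},{contrast.df[1]}"
            summary["meta.anova_p"] = f"{contrast.p_value:.6g}"
            ratio_table = (
                table[table["is_ficus"]] if table["is_ficus"].any() else table
            )
            lo, hi, rom = sp_ratio_range(ratio_table, "dioecy", "monoecy")
            summary["meta.ratio_min"] = f"{lo:.6g}"
            summary["meta.ratio_max"] = f"{hi:.6g}"
            summary["meta.ratio_of_means"] = f"{rom:.6g}"
    except PipelineError:
        raise
    except Exception as exc:
        (out / "run.log").write_text("\n".join(log) + f"\nFAILED at {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    write_summary(summary, out / "summary.txt")
    import datetime

    log.append(f"finished {datetime.datetime.now().isoformat()}")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary
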