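"""Orchestration of the full factorial study:
replicates x missingness levels x imputation methods x GS models.

One :class:`ExperimentConfig` drives everything; per-cell seeds derive
deterministically from the base seed, so any cell can be re-run independently
and the whole bundle is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from . import factors as fct
from . import gs as gsmod
from . import imputers as imp
from . import simulate as sim
from .matrix import GenotypeMatrix


def cell_seed(base_seed: int, *parts) -> int:
    """Deterministic per-cell seed below 2^31 from the base seed and labels."""
    h = hashlib.sha256(repr((int(base_seed),) + tuple(map(str, parts))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    # synthetic panel (the data source; file-based input can replace it)
    n_founders: int = 20
    n_families: int = 20
    lines_per_family: int = 10
    n_markers: int = 500
    n_chromosomes: int = 10
    recomb_rate: float = 0.1
    selfing_generations: int = 8
    maf_floor: float = 0.05
    founder_ld: float = 0.9
    founder_ld_flip: float = 0.05
    n_qtl: int = 40
    heritability: float = 0.5
    # study design
    levels: Sequence[str] = ("NA20", "NA50", "NA70")
    n_replicates: int = 10
    methods: Sequence[str] = ("MNI", "kNNI", "SVDI", "EMI", "RFI")
    gs_models: Sequence[str] = ("RR",)
    # method hyperparameters
    knni_k: int = 5
    svdi_k: Optional[int] = None
    rfi_trees: int = 100
    rfi_max_iter: int = 10
    emi_tol: float = 0.02
    bl_n_iter: int = 2000
    bl_burn_in: int = 500
    n_folds: int = 10
    # bookkeeping
    base_seed: int = 1
    out_dir: Optional[str] = None
    run_factors: bool = True
    run_gs: bool = True
    pev_mode: str = "auto"
    dataset_name: str = "synthetic"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @classmethod
    def desk_scale(cls, base_seed: int = 1, **overrides) -> "ExperimentConfig":
        """The reduced reference study: a 100 x 200 high-LD panel, 2 replicates.

        A 10-family x 10-line panel from 16 founders with 200 markers on 5
        chromosomes — the same design as the full defaults, scaled so the
        complete factorial (3 levels x 5 methods x 2 replicates, RFI at 100
        trees) finishes in minutes on one CPU.
        """
        cfg = cls(
            n_founders=16, n_families=10, lines_per_family=10,
            n_markers=200, n_chromosomes=5, n_replicates=2,
            base_seed=base_seed,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    population: sim.SimulatedPopulation
    accuracy_long: pd.DataFrame  # level, replicate, method, median rm2/ri2
    median_table: pd.DataFrame  # method x level median Rm2-bar (Table-2 style)
    rm2_bar: dict  # (method, level) -> per-marker replicate-mean accuracy
    ri2_bar: dict
    rm2_doublebar: dict  # method -> per-marker mean across levels
    ri2_doublebar: dict
    gs_table: Optional[pd.DataFrame] = None
    gs_summary: Optional[pd.DataFrame] = None
    factor_tables: Optional[pd.DataFrame] = None
    ld_summary: Optional[fct.LDSummary] = None
    ld_ratios: Optional[pd.DataFrame] = None
    failures: list = field(default_factory=list)


def _impute_cell(gm: GenotypeMatrix, method: str, cfg: ExperimentConfig, seed: int):
    if method == "MNI":
        return imp.impute_mni(gm)
    if method == "kNNI":
        return imp.impute_knni(gm, k=cfg.knni_k)
    if method == "SVDI":
        return imp.impute_svdi(gm, k=cfg.svdi_k)
    if method == "EMI":
        return imp.impute_emi(gm, tol=cfg.emi_tol)
    if method == "RFI":
        return imp.impute_rfi(
            gm, n_trees=cfg.rfi_trees, max_iter=cfg.rfi_max_iter, seed=seed
        )
    raise ValueError(f"unknown imputation method {method!r}")


def _gs_accuracy(values, y, model, cfg, seed):
    if model == "RR":
        return gsmod.cross_validate(values, y, "rr", n_folds=cfg.n_folds, seed=seed)
    if model == "BL":
        return gsmod.cross_validate(
            values, y, "bl", n_folds=cfg.n_folds, seed=seed,
            n_iter=cfg.bl_n_iter, burn_in=cfg.bl_burn_in,
        )
    raise ValueError(f"unknown GS model {model!r}")


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the factorial study defined by ``cfg`` and assemble the report bundle.

    Per-cell failures are recorded in ``result.failures`` without aborting
    sibling cells.
    """
    pop = sim.simulate_population(
        n_founders=cfg.n_founders,
        n_families=cfg.n_families,
        lines_per_family=cfg.lines_per_family,
        n_markers=cfg.n_markers,
        n_chromosomes=cfg.n_chromosomes,
        recomb_rate=cfg.recomb_rate,
        selfing_generations=cfg.selfing_generations,
        maf_floor=cfg.maf_floor,
        founder_ld=cfg.founder_ld,
        founder_ld_flip=cfg.founder_ld_flip,
        seed=cell_seed(cfg.base_seed, "population"),
    )
    pop = sim.simulate_phenotypes(
        pop, n_qtl=cfg.n_qtl, h2=cfg.heritability,
        seed=cell_seed(cfg.base_seed, "phenotypes"),
    )
    truth = pop.genotypes
    y = pop.phenotypes.values

    rm2_reports: dict = {}
    ri2_reports: dict = {}
    acc_rows = []
    gs_rows = []
    failures = []
    nonmiss_counts: dict = {}

    sim_levels = [lv for lv in cfg.levels if lv != "NA0"]
    for level in sim_levels:
        for rep in range(cfg.n_replicates):
            spec = sim.default_missingness_distribution(
                level, seed=cell_seed(cfg.base_seed, "mask", level, rep)
            )
            md = sim.mask_missing(truth, spec)
            nonmiss_counts[(level, rep)] = (~md.observed.missing_mask).sum(axis=0)
            for method in cfg.methods:
                key = (method, level)
                try:
                    res = _impute_cell(
                        md.observed, method, cfg,
                        seed=cell_seed(cfg.base_seed, "impute", level, rep, method),
                    )
                    rm = acc.per_marker_accuracy(
                        md, res, replicate_id=rep, method=method,
                        level=level, dataset=cfg.dataset_name,
                    )
                    ri = acc.per_individual_accuracy(
                        md, res, replicate_id=rep, method=method,
                        level=level, dataset=cfg.dataset_name,
                    )
                    rm2_reports.setdefault(key, []).append(rm)
                    ri2_reports.setdefault(key, []).append(ri)
                    acc_rows.append(
                        dict(
                            level=level, replicate=rep, method=method,
                            median_rm2=acc.median_accuracy(rm.rm2),
                            median_ri2=acc.median_accuracy(ri.ri2),
                        )
                    )
                    if cfg.run_gs:
                        for model in cfg.gs_models:
                            cv = _gs_accuracy(
                                res.completed.values, y, model, cfg,
                                seed=cell_seed(cfg.base_seed, "cv", level, rep,
                                               method, model),
                            )
                            gs_rows.append(
                                dict(
                                    level=level, replicate=rep, method=method,
                                    model=model, mean_accuracy=cv.mean_accuracy,
                                )
                            )
                except Exception as e:  # record, keep sibling cells running
                    failures.append(dict(level=level, replicate=rep,
                                         method=method, error=repr(e)))

    # NA0 baseline: GS on the complete truth matrix
    if cfg.run_gs and "NA0" in cfg.levels:
        for model in cfg.gs_models:
            cv = _gs_accuracy(
                truth.values, y, model, cfg,
                seed=cell_seed(cfg.base_seed, "cv", "NA0", 0, "none", model),
            )
            gs_rows.append(dict(level="NA0", replicate=0, method="none",
                                model=model, mean_accuracy=cv.mean_accuracy))

    rm2_bar = {k: acc.mean_across_replicates(v, "rm2") for k, v in rm2_reports.items()}
    ri2_bar = {k: acc.mean_across_replicates(v, "ri2") for k, v in ri2_reports.items()}
    rm2_doublebar = {}
    ri2_doublebar = {}
    for method in cfg.methods:
        bars = [rm2_bar[(method, lv)] for lv in sim_levels if (method, lv) in rm2_bar]
        if bars:
            rm2_doublebar[method] = acc.mean_across_levels(bars)
        ibars = [ri2_bar[(method, lv)] for lv in sim_levels if (method, lv) in ri2_bar]
        if ibars:
            ri2_doublebar[method] = acc.mean_across_levels(ibars)

    med_rows = []
    for (method, level), bar in rm2_bar.items():
        med_rows.append(
            dict(method=method, level=level,
                 median_rm2_bar=acc.median_accuracy(bar),
                 median_ri2_bar=acc.median_accuracy(ri2_bar[(method, level)]))
        )
    median_table = pd.DataFrame(med_rows)

    gs_table = pd.DataFrame(gs_rows) if gs_rows else None
    gs_summary = None
    if gs_table is not None and len(gs_table):
        gs_summary = (
            gs_table.groupby(["level", "method", "model"])["mean_accuracy"]
            .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s))
                 if len(s) > 1 else 0.0)
            .reset_index()
        )

    factor_tables = None
    ld_summary = None
    ld_ratios = None
    if cfg.run_factors:
        maf = truth.minor_allele_frequency()
        ld_summary = fct.ld_classify(truth)
        dist = fct.closest_relative_distance(truth)
        pev = fct.pev_per_individual(truth, mode=cfg.pev_mode)
        ftabs = []
        ratio_rows = []
        for method in cfg.methods:
            if method not in rm2_doublebar:
                continue
            dbar = rm2_doublebar[method]
            idbar = ri2_doublebar[method]
            for factor, vals, accs in [
                (fct.Factor.MAF, maf, dbar),
                (fct.Factor.DISTANCE, dist, idbar),
                (fct.Factor.PEV, pev, idbar),
            ]:
                t = fct.bin_accuracy_by(factor, vals, accs)
                t.insert(0, "method", method)
                ftabs.append(t)
            try:
                ratio_rows.append(
                    dict(method=method, ld_ratio=fct.ld_ratio(ld_summary, dbar))
                )
            except ValueError:
                pass
        # nonmissing-count factor pools every replicate and level (per-replicate
        # Rm2 against that replicate's per-marker observed count)
        for method in cfg.methods:
            vals, accs = [], []
            for level in sim_levels:
                for report in rm2_reports.get((method, level), []):
                    vals.append(nonmiss_counts[(level, report.replicate_id)])
                    accs.append(report.rm2)
            if vals:
                t = fct.bin_accuracy_by(
                    fct.Factor.N_NONMISSING, np.concatenate(vals), np.concatenate(accs)
                )
                t.insert(0, "method", method)
                ftabs.append(t)
        factor_tables = pd.concat(ftabs, ignore_index=True) if ftabs else None
        ld_ratios = pd.DataFrame(ratio_rows) if ratio_rows else None

    result = ExperimentResult(
        config=cfg,
        population=pop,
        accuracy_long=pd.DataFrame(acc_rows),
        median_table=median_table,
        rm2_bar=rm2_bar,
        ri2_bar=ri2_bar,
        rm2_doublebar=rm2_doublebar,
        ri2_doublebar=ri2_doublebar,
        gs_table=gs_table,
        gs_summary=gs_summary,
        factor_tables=factor_tables,
        ld_summary=ld_summary,
        ld_ratios=ld_ratios,
        failures=failures,
    )
    if cfg.out_dir:
        write_bundle(result, cfg.out_dir)
    return result


def write_bundle(result: ExperimentResult, out_dir) -> None:
    """Write the report bundle as TSV tables plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.accuracy_long.to_csv(out / "accuracy_by_cell.tsv", sep="\t", index=False)
    result.median_table.to_csv(out / "median_accuracy.tsv", sep="\t", index=False)
    if result.gs_summary is not None:
        result.gs_summary.to_csv(out / "gs_accuracy.tsv", sep="\t", index=False)
    if result.factor_tables is not None:
        result.factor_tables.to_csv(out / "factor_bins.tsv", sep="\t", index=False)
    if result.ld_ratios is not None:
        result.ld_ratios.to_csv(out / "ld_ratios.tsv", sep="\t", index=False)
    manifest = dict(
        config=asdict(result.config),
        n_failures=len(result.failures),
        failures=result.failures,
    )
    manifest["config"]["levels"] = list(result.config.levels)
    manifest["config"]["methods"] = list(result.config.methods)
    manifest["config"]["gs_models"] = list(result.config.gs_models)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
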