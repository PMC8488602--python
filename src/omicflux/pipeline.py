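"""Stage orchestration: fixtures/files -> FBA -> fused matrix -> ML outputs.

Each stage writes CSV artifacts into the output directory using stable
names (``all_atp_flux.csv``, ``all_ATPTF.csv``, ``contrib_*.csv``,
``B_*_nonzero.csv``, ``corr_*_table.csv``, ...) plus a ``manifest.json``
recording parameters, the seed and content hashes, so a run can be
reproduced and compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures as fx
from .fba import ExpressionMapConfig, run_all_conditions, solve_fva, apply_condition_bounds
from .model import (
    MetabolicModel,
    ObjectivePair,
    build_subsystem_index,
    normalize_subsystem_names,
    read_model,
    set_objective_pair,
    split_multi_subsystems,
    write_toy_table,
)
from .mlstats import (
    correlation_distance,
    kmeans_cluster,
    lasso_mpc,
    nonmetric_mds,
    pathway_correlation,
    pathway_pca_aggregate,
    pca_fit,
    pearson_with_ci,
    silhouette_scan,
)
from .omics import build_multiomic, flux_foldchange, rpkm_to_foldchange, subset_growth_conditions

logger = logging.getLogger(__name__)

STAGES = [
    "prepare",
    "fba",
    "multiomic",
    "pca",
    "pathway-pca",
    "cluster",
    "lasso",
    "corr",
    "pathway-corr",
]

#: objective-pair tags -> (secondary reaction name, flux artifact tag)
OBJECTIVE_PAIRS = {
    "atpm": ("ATP maintenance requirment", "atp"),
    "psi": ("Photosystem I Reaction (cytochrome c6)", "p1"),
    "psii": ("photosystem II reaction", "p2"),
}
PRIMARY_OBJECTIVE = "Biomass synthesis (carbon limited)"


@dataclass
class PipelineConfig:
    outdir: str | Path = "omicflux_out"
    model_path: str | Path | None = None  # None -> synthetic toy model
    model_format: str = "toy-table"
    objective_pair: str = "atpm"
    gamma: float = 1.0
    flux_threshold: float = 1e-4
    seed: int = 0
    k_range: tuple[int, int] = (2, 30)
    lasso_cutoff: float = 0.01
    include_control_in_transcript_pca: bool = False
    noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.objective_pair not in OBJECTIVE_PAIRS:
            raise ValueError(
                f"objective_pair must be one of {sorted(OBJECTIVE_PAIRS)}"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.flux_threshold < 0:
            raise ValueError("flux_threshold must be >= 0")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)


class PipelineState:
    """In-memory artifacts shared between stages of one run."""

    def __init__(self) -> None:
        self.model: MetabolicModel | None = None
        self.transcripts: pd.DataFrame | None = None  # conditions x genes
        self.flux: pd.DataFrame | None = None  # conditions x reactions
        self.fused = None  # OmicsMatrix
        self.pca_results: dict[str, object] = {}


def _require(state: PipelineState, attr: str, needed_by: str, produced_by: str):
    value = getattr(state, attr)
    if value is None:
        raise RuntimeError(
            f"stage {needed_by!r} requires the output of stage {produced_by!r}; "
            f"run it first (or include it in --stages)"
        )
    return value


def _prepare(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    if config.model_path is None:
        fconf = fx.FixtureConfig(seed=config.seed, noise_cv=config.noise_cv)
        model = fx.make_toy_model(fconf)
        ds1, ds2 = fx.make_synthetic_transcriptome(model, fconf)
        ds1.to_csv(out / "Dataset1.csv", index=False)
        ds2.to_csv(out / "Dataset2.csv", index=False)
        manifest["outputs"]["Dataset1.csv"] = _sha256(out / "Dataset1.csv")
        manifest["outputs"]["Dataset2.csv"] = _sha256(out / "Dataset2.csv")
    else:
        model = read_model(config.model_path, format=config.model_format)
        ds1 = pd.read_csv(Path(config.model_path).parent / "Dataset1.csv")
        ds2 = pd.read_csv(Path(config.model_path).parent / "Dataset2.csv")

    model = split_multi_subsystems(normalize_subsystem_names(model))
    secondary, _ = OBJECTIVE_PAIRS[config.objective_pair]
    model = set_objective_pair(model, PRIMARY_OBJECTIVE, secondary)
    state.model = model
    write_toy_table(model, out / "model")

    controls = [c for c in ds1.columns if c.startswith("control_")]
    conds1 = [c for c in fx.CONDITIONS if c in ds1.columns]
    conds2 = [c for c in fx.CONDITIONS if c in ds2.columns]
    fc1 = rpkm_to_foldchange(ds1.set_index("gene_id"), controls, conds1)
    fc2 = rpkm_to_foldchange(ds2.set_index("gene_id"), controls, conds2)
    merged = pd.concat([fc1, fc2], axis=1)[fx.CONDITIONS]
    state.transcripts = merged.T  # conditions x genes
    _write(state.transcripts, out / "transcriptsnew.csv", manifest)


def _fba(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    model = _require(state, "model", "fba", "prepare")
    transcripts = _require(state, "transcripts", "fba", "prepare")
    specs = fx.builtin_condition_bounds()
    tag = OBJECTIVE_PAIRS[config.objective_pair][1]
    flux = run_all_conditions(
        model,
        transcripts.T,
        specs,
        config=ExpressionMapConfig(gamma=config.gamma),
        control_name=fx.CONTROL_NAME,
        flux_threshold=config.flux_threshold,
    )
    state.flux = flux
    _write(flux, out / f"all_{tag}_flux.csv", manifest)


def _multiomic(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    flux = _require(state, "flux", "multiomic", "fba")
    transcripts = _require(state, "transcripts", "multiomic", "prepare")
    tag = OBJECTIVE_PAIRS[config.objective_pair][1].upper()
    flux_fc = flux_foldchange(flux, control_row=fx.CONTROL_NAME, threshold=config.flux_threshold)
    fused = build_multiomic(transcripts, flux_fc, control_name=fx.CONTROL_NAME)
    state.fused = fused
    _write(fused.values, out / f"all_{tag}TF.csv", manifest)


def _dataset_views(config: PipelineConfig, state: PipelineState):
    tag = OBJECTIVE_PAIRS[config.objective_pair][1]
    views = {}
    if state.transcripts is not None:
        tr = state.transcripts
        if config.include_control_in_transcript_pca:
            control = pd.DataFrame(
                np.ones((1, tr.shape[1])), index=[fx.CONTROL_NAME], columns=tr.columns
            )
            tr = pd.concat([tr, control])
        views["transcripts"] = tr
    if state.flux is not None:
        views[f"all_{tag}_flux"] = state.flux
    if state.fused is not None:
        views[f"all_{tag.upper()}TF"] = state.fused.values
    return views


def _pca(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    views = _dataset_views(config, state)
    if not views:
        raise RuntimeError("stage 'pca' requires 'prepare' (and 'fba'/'multiomic' for flux data)")
    for name, df in views.items():
        res = pca_fit(df)
        state.pca_results[name] = res
        _write(res.var_contrib, out / f"contrib_{name}.csv", manifest)
        _write(res.ind_coord, out / f"ind_coord_{name}.csv", manifest)
        _write(res.ind_cos2, out / f"ind_cos2_{name}.csv", manifest)


def _pathway_pca(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    model = _require(state, "model", "pathway-pca", "prepare")
    tag = OBJECTIVE_PAIRS[config.objective_pair][1]
    name = f"all_{tag}_flux"
    if name not in state.pca_results:
        raise RuntimeError("stage 'pathway-pca' requires stage 'pca' on the flux dataset")
    res = state.pca_results[name]
    index = build_subsystem_index(model)
    contrib = res.var_contrib.iloc[:, :2]
    table = pathway_pca_aggregate(contrib, index)
    _write(table, out / f"pathway_contrib_{tag.upper()}.csv", manifest)


def _cluster(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    transcripts = _require(state, "transcripts", "cluster", "prepare")
    genes_vs_profiles = transcripts.T.to_numpy()  # features x conditions
    lo, hi = config.k_range
    hi = min(hi, genes_vs_profiles.shape[0] - 1)
    scores, best_k = silhouette_scan(
        genes_vs_profiles, k_range=range(lo, hi + 1), seed=config.seed
    )
    silh = pd.DataFrame(
        {"k": list(scores), "mean_silhouette": list(scores.values())}
    ).set_index("k")
    _write(silh, out / "silh_transcripts.csv", manifest)
    labels, _ = kmeans_cluster(
        genes_vs_profiles, best_k, metric="cityblock", seed=config.seed
    )
    dist = correlation_distance(genes_vs_profiles)
    embedding, stress = nonmetric_mds(dist, seed=config.seed)
    km = pd.DataFrame(
        {
            "cluster": labels,
            "mds_1": embedding[:, 0],
            "mds_2": embedding[:, 1],
        },
        index=transcripts.columns,
    )
    km.attrs["stress"] = stress
    _write(km, out / "kmeans_transcripts.csv", manifest)
    manifest["cluster"] = {"best_k": int(best_k), "stress": float(stress)}


def _subsets(config: PipelineConfig, state: PipelineState):
    names, rates = fx.builtin_growth_rates()
    views = _dataset_views(config, state)
    subsets = {}
    for name, df in views.items():
        if name == "transcripts":
            df = state.transcripts
        sub, y = subset_growth_conditions(
            df, fx.GROWTH_RATE_CONDITIONS, rates, control_name=fx.CONTROL_NAME
        )
        subsets[name] = (sub, y)
    return subsets


def _lasso(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    for name, (sub, y) in _subsets(config, state).items():
        res = lasso_mpc(sub, y, cutoff=config.lasso_cutoff)
        _write(res.retained, out / f"B_{name}_nonzero.csv", manifest)


def _corr(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    state._corr_results = {}
    for name, (sub, y) in _subsets(config, state).items():
        res = pearson_with_ci(sub, y)
        state._corr_results[name] = res
        table = res.table.sort_values("r", ascending=False, kind="stable")
        _write(table, out / f"corr_{name}_table.csv", manifest)


def _pathway_corr(config: PipelineConfig, state: PipelineState, out: Path, manifest: dict):
    model = _require(state, "model", "pathway-corr", "prepare")
    tag = OBJECTIVE_PAIRS[config.objective_pair][1]
    name = f"all_{tag}_flux"
    results = getattr(state, "_corr_results", {})
    if name not in results:
        raise RuntimeError("stage 'pathway-corr' requires stage 'corr' on the flux dataset")
    index = build_subsystem_index(model)
    mean_df, bins_df = pathway_correlation(results[name], index)
    _write(mean_df, out / f"{tag.upper()}_PCC_mean.csv", manifest)
    _write(bins_df, out / f"all_corr_{tag.upper()}.csv", manifest)


_STAGE_FUNCS = {
    "prepare": _prepare,
    "fba": _fba,
    "multiomic": _multiomic,
    "pca": _pca,
    "pathway-pca": _pathway_pca,
    "cluster": _cluster,
    "lasso": _lasso,
    "corr": _corr,
    "pathway-corr": _pathway_corr,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    stages = list(STAGES) if stages is None else stages
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid stages: {STAGES}")
    ordered = [s for s in STAGES if s in stages]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "outdir"},
        },
        "stages": ordered,
        "outputs": {},
    }
    state = PipelineState()
    for stage in ordered:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, state, out, manifest)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    return manifest
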