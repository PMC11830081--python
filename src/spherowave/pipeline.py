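"""End-to-end orchestration: density series -> fits -> waves -> phenotype.

A :class:`RunConfig` (usually loaded from YAML) names the inputs — either
observed density CSVs per cell line or synthetic generation blocks — the
model set and budgets, wave and classification settings, and a single
global seed.  ``run_full_analysis`` fits every replicate independently,
aggregates replicate fits per line by the arithmetic mean of the free
parameters, computes wave parameters on simulations of the aggregated
fits, classifies Go-or-Grow and clusters the lines, and writes CSV
tables plus a provenance record.  The global seed fans out to per-stage
child seeds through ``numpy.random.SeedSequence`` so stages are
individually reproducible; replicate failures are isolated and reported
without aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MODEL_IDS, ModelParams, ParameterBounds, RadialGrid
from .fit import compare_models
from .phenotype import classify_go_or_grow, cluster_cell_lines, normalize_parameters
from .series import read_series_csv
from .synthetic import NoiseSpec, generate_density_series
from .waves import wave_parameters

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger("spherowave.pipeline")


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    force: bool = False
    models: tuple[str, ...] = MODEL_IDS
    budgets: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    solver_grid_n: int = 400
    wave_M: int = 100
    wave_horizon_weeks: float = 5.0
    k: float = 5.0
    n_clusters: int = 2
    inputs: dict = field(default_factory=dict)  # line -> [csv paths]
    synthetic: dict = field(default_factory=dict)  # see validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for m in self.models:
            if m not in MODEL_IDS:
                raise ValueError(f"unknown model name {m!r} in config")
        if not self.inputs and not self.synthetic:
            raise ValueError("empty input set: provide 'inputs' or 'synthetic'")
        for line, paths in self.inputs.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input for line {line!r} missing: {p}")
        if self.synthetic and "lines" not in self.synthetic:
            raise ValueError("synthetic block needs a 'lines' mapping")

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_replicates(config: RunConfig) -> dict[str, list]:
    """line -> list of observed RadialDensitySeries."""
    reps: dict[str, list] = {}
    for line, paths in config.inputs.items():
        reps[line] = [read_series_csv(p) for p in paths]
    if config.synthetic:
        syn = config.synthetic
        times = np.asarray(syn.get("times", np.linspace(0, 1, 8)), dtype=float)
        grid = RadialGrid.uniform(n=syn.get("grid_n", 200))
        sigma = float(syn.get("noise_sigma", 0.01))
        n_rep = int(syn.get("n_replicates", 1))
        children = np.random.SeedSequence(config.seed).spawn(
            len(syn["lines"]) * n_rep
        )
        i = 0
        for line, pdict in syn["lines"].items():
            pdict = dict(pdict)
            params = ModelParams(pdict.pop("model_id", "RD_ARD"), **pdict)
            reps.setdefault(line, [])
            for _ in range(n_rep):
                child_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                obs, _ = generate_density_series(
                    params,
                    times,
                    grid,
                    noise=NoiseSpec(sigma=sigma, seed=child_seed),
                )
                reps[line].append(obs)
    return reps


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``output_dir``.

    Returns a dict with the in-memory tables (fits, line_params, waves,
    gogrow, clusters) and the per-replicate failure report.
    """
    config.validate()
    out = Path(config.output_dir)
    marker = out / "provenance.json"
    if marker.exists() and not config.force:
        raise FileExistsError(
            f"{out} already holds results; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    bounds = ParameterBounds.default(**config.bounds) if config.bounds else None
    grid = RadialGrid.uniform(n=config.solver_grid_n)
    replicates = _load_replicates(config)

    fit_rows, failures = [], []
    line_results: dict[str, list] = {}
    for line, series_list in replicates.items():
        line_results[line] = []
        for k_rep, obs in enumerate(series_list):
            try:
                cmp_res = compare_models(
                    obs,
                    model_ids=config.models,
                    budgets=config.budgets,
                    bounds=bounds,
                    solver_grid=grid,
                )
                for mid, r in cmp_res.results.items():
                    fit_rows.append(
                        {"cell_line": line, "replicate": k_rep, **r.to_dict()["params"],
                         "sse": r.sse, "aic": r.aic, "kappa": r.kappa}
                    )
                line_results[line].append(cmp_res)
                logger.info("line %s rep %d: best %s", line, k_rep,
                            cmp_res.table.iloc[0]["model_id"])
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                failures.append({"cell_line": line, "replicate": k_rep,
                                 "error": str(exc)})
                logger.warning("line %s rep %d FAILED: %s", line, k_rep, exc)

    # per-line aggregation: arithmetic mean of free parameters over replicates
    agg_model = "RD_ARD" if "RD_ARD" in config.models else config.models[-1]
    line_params: dict[str, ModelParams] = {}
    for line, results in line_results.items():
        vecs = [
            c.results[agg_model].params.free_values()
            for c in results
            if agg_model in c.results
        ]
        if vecs:
            line_params[line] = ModelParams.from_free(
                agg_model, np.mean(vecs, axis=0)
            )

    wave_rows = []
    for line, params in line_params.items():
        obs0 = replicates[line][0]
        u0 = np.interp(grid.r, obs0.grid.r, obs0.u[0])
        from .solver import simulate

        times = np.linspace(0.0, config.wave_horizon_weeks, 101)
        sim = simulate(params, u0, grid, times)
        try:
            wp = wave_parameters(sim, M=config.wave_M)
            wave_rows.append(
                {"cell_line": line, "c_max": wp.c_max, "c_min": wp.c_min,
                 "c_diff": wp.c_diff, "c_shape": wp.c_shape}
            )
        except ValueError as exc:
            failures.append({"cell_line": line, "replicate": "waves",
                             "error": str(exc)})

    gogrow_df = clusters = None
    if len(line_params) >= 2:
        try:
            table = classify_go_or_grow(
                normalize_parameters(line_params), k=config.k
            )
            gogrow_df = table.table
        except ValueError as exc:  # e.g. no advection in a single-pop run
            failures.append({"cell_line": "*", "replicate": "gogrow",
                             "error": str(exc)})
        try:
            n_cl = min(config.n_clusters, len(line_params))
            clusters = cluster_cell_lines(
                pd.DataFrame(
                    {ln: p.as_dict() for ln, p in line_params.items()}
                ).T,
                n_clusters=n_cl,
            )
        except ValueError as exc:
            failures.append({"cell_line": "*", "replicate": "cluster",
                             "error": str(exc)})

    fits_df = pd.DataFrame(fit_rows)
    bundle = {
        "fits": fits_df,
        "line_params": pd.DataFrame(
            {ln: p.as_dict() for ln, p in line_params.items()}
        ).T,
        "waves": pd.DataFrame(wave_rows),
        "gogrow": gogrow_df,
        "clusters": clusters,
        "failures": failures,
    }

    fits_df.to_csv(out / "fits.csv", index=False)
    bundle["line_params"].to_csv(out / "line_params.csv")
    bundle["waves"].to_csv(out / "waves.csv", index=False)
    if gogrow_df is not None:
        gogrow_df.to_csv(out / "gogrow.csv")
    if clusters is not None:
        clusters.labels.to_csv(out / "clusters.csv")
    from . import __version__

    provenance = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "spherowave_version": __version__,
        "numpy_version": np.__version__,
        "n_failures": len(failures),
        "failures": failures,
    }
    marker.write_text(json.dumps(provenance, indent=2, default=str))
    logger.removeHandler(handler)
    handler.close()
    return bundle
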