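"""End-to-end benchmark orchestration.

Given a dataset (loaded from files or simulated), a list of predictors and
CV/MCMC settings, runs the full grid — per (trait, model, partition) CV fits
plus per (trait, model) full-data heritability fits — and writes tidy CSV
outputs.  Every cell's RNG is a deterministic substream of the master seed,
so re-running any subset of the grid reproduces the same numbers as the
full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from .data_io import Dataset, load_matrix, align_layers
from .evaluation import (
    EvaluationRecord,
    HeritabilityRecord,
    aggregate_results,
    apc,
    heritability,
    make_partitions,
    nrmse,
    records_to_frame,
)
from .prep import build_base_kernels, required_bases
from .registry import KernelFactory, ModelSpec, resolve_model
from .rkhs import GibbsConfig, MultiKernelRKHS
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


def derive_seed(master: int, *tokens) -> int:
    """Deterministic per-cell substream seed (< 2**31) from the master seed."""
    h = hashlib.sha256(("/".join(map(str, tokens))).encode())
    return (int(master) + int.from_bytes(h.digest()[:4], "big")) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one benchmark run."""

    models: Tuple[str, ...] = ("M1", "M4", "M5")
    traits: Optional[Tuple[str, ...]] = None  # None = all
    cv_fraction: float = 0.5
    cv_partitions: int = 20
    seed: int = 0
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    herit_chains: int = 2
    simulation: Optional[SimulationConfig] = None
    layer_paths: Optional[Dict[str, str]] = None
    delimiter: str = "\t"
    dataset_name: str = "dataset"
    run_cv: bool = True
    run_heritability: bool = True

    def model_specs(self) -> List[ModelSpec]:
        return [resolve_model(m) for m in self.models]


def load_dataset(config: RunConfig) -> Dataset:
    if config.simulation is not None:
        dataset, _ = simulate_dataset(config.simulation)
        return dataset
    if not config.layer_paths:
        raise ValueError("RunConfig needs either simulation settings or layer paths")
    needed = {"genomic", "transcriptomic", "metabolomic", "phenotype"}
    missing = needed - set(config.layer_paths)
    if missing:
        raise ValueError(f"layer path(s) missing: {sorted(missing)}")
    blocks = [
        load_matrix(path, layer=layer, delimiter=config.delimiter)
        for layer, path in config.layer_paths.items()
    ]
    return align_layers(blocks, name=config.dataset_name)


def run_benchmark(config: RunConfig, outdir=None) -> Dict[str, pd.DataFrame]:
    """Run the benchmark grid; optionally write the report bundle to ``outdir``.

    Returns a dict of DataFrames: ``records`` (per-partition long format),
    ``heritability`` (per trait/model), plus the aggregated summaries.
    """
    specs = config.model_specs()
    dataset = load_dataset(config)
    traits = config.traits if config.traits is not None else dataset.traits
    unknown = set(traits) - set(dataset.traits)
    if unknown:
        raise ValueError(f"unknown trait(s): {sorted(unknown)}")

    bases = build_base_kernels(dataset, required_bases(specs))
    factory = KernelFactory(bases)
    kernel_lists = {spec.model_id: factory.materialize(spec) for spec in specs}

    partitions = make_partitions(
        dataset.n_lines,
        seed=derive_seed(config.seed, dataset.name, "partitions"),
        fraction=config.cv_fraction,
        count=config.cv_partitions,
    )

    eval_records: List[EvaluationRecord] = []
    herit_records: List[HeritabilityRecord] = []
    failures: List[dict] = []
    for spec in specs:
        kernels = kernel_lists[spec.model_id]
        labels = spec.term_labels
        for trait in traits:
            y = dataset.trait_vector(trait)
            if config.run_heritability:
                try:
                    cfg = replace(
                        config.gibbs,
                        n_chains=config.herit_chains,
                        seed=derive_seed(config.seed, dataset.name, trait,
                                         spec.model_id, "full"),
                    )
                    fit = MultiKernelRKHS(y, kernels, term_labels=labels).fit(cfg)
                    herit_records.append(
                        heritability(fit, dataset.name, trait, spec.model_id)
                    )
                except Exception as exc:  # record and continue
                    logger.error("full fit failed (%s, %s): %s", trait, spec.model_id, exc)
                    failures.append(
                        {"trait": trait, "model": spec.model_id, "stage": "full",
                         "error": str(exc)}
                    )
            if not config.run_cv:
                continue
            for p_idx, (train, test) in enumerate(partitions.partitions, start=1):
                try:
                    cfg = replace(
                        config.gibbs,
                        n_chains=1,
                        seed=derive_seed(config.seed, dataset.name, trait,
                                         spec.model_id, "cv", p_idx),
                    )
                    fit = MultiKernelRKHS(
                        y, kernels, masked=test, term_labels=labels
                    ).fit(cfg)
                    pred = fit.predict(test)
                    eval_records.append(
                        EvaluationRecord(
                            dataset=dataset.name, trait=trait,
                            model_id=spec.model_id, partition=p_idx,
                            apc=apc(y[test], pred), nrmse=nrmse(y[test], pred),
                        )
                    )
                except Exception as exc:
                    logger.error(
                        "CV fit failed (%s, %s, partition %d): %s",
                        trait, spec.model_id, p_idx, exc,
                    )
                    failures.append(
                        {"trait": trait, "model": spec.model_id,
                         "stage": f"cv:{p_idx}", "error": str(exc)}
                    )

    out: Dict[str, pd.DataFrame] = {}
    if eval_records:
        out["records"] = records_to_frame(eval_records)
    if herit_records:
        out["heritability_records"] = records_to_frame(herit_records)
    summaries = aggregate_results(
        out.get("records"), out.get("heritability_records")
    )
    out.update(summaries)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, frame in out.items():
            frame.to_csv(outdir / f"{key}.csv", index=False, float_format="%.6g")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "models": list(config.models),
            "traits": list(traits),
            "n_lines": dataset.n_lines,
            "cv": {"fraction": config.cv_fraction, "partitions": config.cv_partitions},
            "mcmc": {
                "n_iter": config.gibbs.n_iter,
                "burn_in": config.gibbs.burn_in,
                "thin": config.gibbs.thin,
            },
            "failures": failures,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failures:
        logger.warning("%d grid cell(s) failed; see manifest/log", len(failures))
    return out
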