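"""Cross-validation protocol, prediction metrics and heritability records.

The benchmark protocol: 20 independent random partitions of the lines into
50% training / 50% testing; each model is fitted with the test phenotypes
masked and scored on the test set with the Pearson correlation (APC) and the
normalized root-mean-squared error (NRMSE, normalized by the observed test
range).  Heritability is computed from full-data fits as h2 = VP/(VP+Ve)
where VP sums every kernel-term variance of the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rkhs import RKHSResults

logger = logging.getLogger(__name__)

DEFAULT_TRAIN_FRACTION = 0.5
DEFAULT_N_PARTITIONS = 20


@dataclass(frozen=True)
class PartitionSet:
    """Reproducible random train/test splits over ``n_lines`` lines."""

    n_lines: int
    fraction: float
    seed: int
    partitions: Tuple[Tuple[np.ndarray, np.ndarray], ...]

    @property
    def count(self) -> int:
        return len(self.partitions)


def make_partitions(
    n: int,
    seed: int,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    count: int = DEFAULT_N_PARTITIONS,
) -> PartitionSet:
    """Draw ``count`` independent uniform random splits at ``fraction`` train.

    Index lists are sorted so a PartitionSet is fully determined by
    (n, seed, fraction, count).
    """
    if n < 4:
        raise ValueError(f"need at least 4 lines to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(n * fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("fraction leaves an empty train or test set")
    parts = []
    for _ in range(count):
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        parts.append((train, test))
    return PartitionSet(n_lines=n, fraction=fraction, seed=seed, partitions=tuple(parts))


def apc(observed, predicted) -> float:
    """Pearson correlation between observed and predicted test phenotypes.

    Returns NaN (with a warning) when either vector is constant, in which
    case the correlation is undefined; callers exclude NaNs from averages.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or len(obs) < 3:
        raise ValueError("observed/predicted must be equal-length vectors (>= 3)")
    if np.std(obs) == 0 or np.std(pred) == 0:
        logger.warning("constant vector: Pearson correlation undefined, recording NaN")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def nrmse(observed, predicted, normalizer: str = "range") -> float:
    """RMSE normalized by the observed spread (scale-free prediction error).

    ``normalizer='range'`` divides by max(observed) - min(observed) (the
    default); ``'mean'`` divides by the absolute observed mean.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or len(obs) < 2:
        raise ValueError("observed/predicted must be equal-length vectors (>= 2)")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if normalizer == "range":
        denom = float(obs.max() - obs.min())
    elif normalizer == "mean":
        denom = float(abs(obs.mean()))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0:
        raise ValueError("observed normalizer is zero; NRMSE undefined")
    return rmse / denom


@dataclass(frozen=True)
class EvaluationRecord:
    """APC/NRMSE of one (dataset, trait, model, partition) cell."""

    dataset: str
    trait: str
    model_id: str
    partition: int
    apc: float  # NaN when undefined
    nrmse: float


@dataclass(frozen=True)
class HeritabilityRecord:
    """Full-data variance partition of one (dataset, trait, model) cell."""

    dataset: str
    trait: str
    model_id: str
    vp: float
    ve: float
    h2: float
    max_rhat: Optional[float] = None


def heritability(
    fit: RKHSResults, dataset: str = "", trait: str = "", model_id: str = ""
) -> HeritabilityRecord:
    """Heritability record from a full-data fit: VP sums all kernel-term
    posterior-mean variances, h2 = VP/(VP+Ve)."""
    vp, ve = fit.vp, fit.ve
    rhat = None
    if "rhat" in fit.variance_components:
        rhat = fit.max_rhat
    return HeritabilityRecord(
        dataset=dataset, trait=trait, model_id=model_id,
        vp=vp, ve=ve, h2=vp / (vp + ve), max_rhat=rhat,
    )


def records_to_frame(records: Sequence) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def aggregate_results(
    eval_records: Optional[pd.DataFrame] = None,
    herit_records: Optional[pd.DataFrame] = None,
) -> dict:
    """Aggregate long-format records into per-model summary tables.

    APC/NRMSE: within each (dataset, model), partition metrics are averaged
    over partitions within each trait and then across traits (unweighted);
    the reported sd is taken across partitions of the per-partition
    across-trait mean, matching error bars over the 20 partitions.
    Undefined (NaN) APC cells are excluded with a logged count.

    Heritability: per-trait h2 ratios are averaged across traits
    (mean of ratios, not ratio of means), as are VP and Ve.

    Returns a dict with keys ``prediction`` and/or ``heritability``
    (per-dataset per-model DataFrames) and ``prediction_overall`` /
    ``heritability_overall`` pooling all datasets.
    """
    out: dict = {}
    if eval_records is not None and len(eval_records):
        df = eval_records.copy()
        n_bad = int(df["apc"].isna().sum())
        if n_bad:
            logger.warning("excluding %d undefined APC cell(s) from averages", n_bad)

        def _summary(group: pd.DataFrame) -> pd.Series:
            per_trait_apc = group.groupby("trait")["apc"].mean()
            per_trait_nrmse = group.groupby("trait")["nrmse"].mean()
            per_part_apc = group.groupby("partition")["apc"].mean()
            per_part_nrmse = group.groupby("partition")["nrmse"].mean()
            return pd.Series(
                {
                    "apc_mean": per_trait_apc.mean(),
                    "apc_sd": per_part_apc.std(ddof=1),
                    "nrmse_mean": per_trait_nrmse.mean(),
                    "nrmse_sd": per_part_nrmse.std(ddof=1),
                }
            )

        by = df.groupby(["dataset", "model_id"])[
            ["trait", "partition", "apc", "nrmse"]
        ].apply(_summary)
        out["prediction"] = by.reset_index()
        overall = df.groupby("model_id")[["trait", "partition", "apc", "nrmse"]].apply(
            _summary
        )
        out["prediction_overall"] = overall.reset_index()
    if herit_records is not None and len(herit_records):
        hf = herit_records.copy()
        agg = {
            "vp": ["mean", "std"],
            "ve": ["mean", "std"],
            "h2": ["mean", "std"],
        }
        by = hf.groupby(["dataset", "model_id"]).agg(agg)
        by.columns = [f"{a}_{'sd' if b == 'std' else b}" for a, b in by.columns]
        out["heritability"] = by.reset_index()
        overall = hf.groupby("model_id").agg(agg)
        overall.columns = [f"{a}_{'sd' if b == 'std' else b}" for a, b in overall.columns]
        out["heritability_overall"] = overall.reset_index()
    if not out:
        raise ValueError("no records to aggregate")
    return out
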