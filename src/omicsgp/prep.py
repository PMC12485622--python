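"""Dataset-level preprocessing and base-kernel construction.

Bridges the raw aligned :class:`~omicsgp.data_io.Dataset` and the kernel
registry: transcriptomic/metabolomic layers are mean-imputed and z-scored;
genotype markers stay on 0/1/2 coding for the VanRaden genomic relationship
matrix and are z-scored only when a Gaussian (or generic linear) kernel is
requested for them.
"""

from __future__ import annotations

from typing import Dict, Iterable, Set, Tuple

import numpy as np

from .data_io import Dataset, FeatureMatrix, mean_impute, preprocess_layer
from .kernels import KernelMatrix, gaussian_kernel, linear_kernel, vanraden_kernel
from .registry import ModelSpec

BaseKey = Tuple[str, str]  # (layer letter, kernel kind)

LAYER_BY_LETTER = {"g": "genomic", "t": "transcriptomic", "m": "metabolomic"}


def impute_genotypes(geno: FeatureMatrix) -> FeatureMatrix:
    """Mean-impute markers, then round back to the nearest 0/1/2 code."""
    filled = mean_impute(geno)
    values = np.clip(np.rint(filled.values), 0.0, 2.0)
    return FeatureMatrix(
        line_ids=filled.line_ids,
        feature_ids=filled.feature_ids,
        values=values,
        layer=filled.layer,
    )


def required_bases(specs: Iterable[ModelSpec]) -> Set[BaseKey]:
    """The (layer, kind) base kernels a collection of predictors needs."""
    keys: Set[BaseKey] = set()
    for spec in specs:
        for term in spec.terms:
            for layer in term.layers:
                keys.add((layer, term.base_kind))
    return keys


def build_base_kernels(
    dataset: Dataset, required: Iterable[BaseKey]
) -> Dict[BaseKey, KernelMatrix]:
    """Construct the requested per-layer base kernels from a raw dataset.

    Genomic linear -> VanRaden GRM on 0/1/2 codes; all other combinations
    use imputed + standardized features (linear kernel X Xt / p or Gaussian
    kernel with the median-of-squared-distances bandwidth).
    """
    bases: Dict[BaseKey, KernelMatrix] = {}
    std_cache: Dict[str, FeatureMatrix] = {}

    def standardized(letter: str) -> FeatureMatrix:
        if letter not in std_cache:
            block = dataset.layer(LAYER_BY_LETTER[letter])
            std_cache[letter] = preprocess_layer(block)
        return std_cache[letter]

    for letter, kind in sorted(set(required)):
        recipe = f"{letter}:{kind}"
        if letter == "g" and kind == "linear":
            geno = impute_genotypes(dataset.genomic)
            bases[(letter, kind)] = vanraden_kernel(geno, recipe=recipe)
        elif kind == "linear":
            bases[(letter, kind)] = linear_kernel(standardized(letter), recipe=recipe)
        else:
            bases[(letter, kind)] = gaussian_kernel(standardized(letter), recipe=recipe)
    return bases
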