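"""Registry of the 24 multi-omics predictors and the kernel-term grammar.

Each predictor is a sum of kernel random-effect terms written in a compact
grammar: a main-effect term is a layer letter plus a kernel-kind subscript
(``gL`` = genomic linear, ``tG`` = transcriptomic Gaussian) and an
interaction term is the two layer/kind pairs followed by the triangle tag
(``gLtLCC``, ``tGmGPP``).  Terms are joined with ``+``.  The registered
models M1-M24 range from single-layer baselines through additive
multi-layer predictors to models carrying up to six hybrid interaction
kernels; users can define custom predictors with the same grammar.
Interaction terms combine two same-kind base kernels (linear with linear,
Gaussian with Gaussian).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

from .kernels import KernelMatrix, hybrid_kernels, psd_repair, scale_kernel

LAYER_LETTERS = ("g", "t", "m")
KIND_BY_SUBSCRIPT = {"L": "linear", "G": "gaussian"}
SUBSCRIPT_BY_KIND = {v: k for k, v in KIND_BY_SUBSCRIPT.items()}

_MAIN_RE = re.compile(r"^([gtm])([LG])$")
_INTER_RE = re.compile(r"^([gtm])([LG])([gtm])\2(CC|PP)$")


class ModelGrammarError(ValueError):
    pass


@dataclass(frozen=True)
class KernelTermSpec:
    """One random-effect term of a predictor.

    ``layers``: one layer for a main effect, two distinct layers for an
    interaction.  ``base_kind``: which base kernels the term uses.
    ``combo``: ``main`` or the triangle tag ``CC``/``PP``.
    """

    layers: Tuple[str, ...]
    base_kind: str
    combo: str = "main"

    def __post_init__(self):
        if self.base_kind not in ("linear", "gaussian"):
            raise ModelGrammarError(f"unknown kernel kind {self.base_kind!r}")
        if self.combo == "main":
            if len(self.layers) != 1:
                raise ModelGrammarError("main-effect term takes exactly one layer")
        elif self.combo in ("CC", "PP"):
            if len(self.layers) != 2 or self.layers[0] == self.layers[1]:
                raise ModelGrammarError(
                    "interaction term takes two distinct layers"
                )
        else:
            raise ModelGrammarError(f"unknown combo {self.combo!r}")
        for layer in self.layers:
            if layer not in LAYER_LETTERS:
                raise ModelGrammarError(f"unknown layer {layer!r}")

    @property
    def label(self) -> str:
        sub = SUBSCRIPT_BY_KIND[self.base_kind]
        if self.combo == "main":
            return f"{self.layers[0]}{sub}"
        return f"{self.layers[0]}{sub}{self.layers[1]}{sub}{self.combo}"


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of kernel terms defining one predictor."""

    model_id: str
    terms: Tuple[KernelTermSpec, ...]

    def __post_init__(self):
        if len(set(t.label for t in self.terms)) != len(self.terms):
            raise ModelGrammarError(f"duplicated term in model {self.model_id}")

    @property
    def term_labels(self) -> Tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    @property
    def formula(self) -> str:
        return "+".join(self.term_labels)


def parse_term(token: str) -> KernelTermSpec:
    """Parse one grammar token (``gL``, ``tG``, ``gLtLCC``, ...)."""
    m = _MAIN_RE.match(token)
    if m:
        return KernelTermSpec(layers=(m.group(1),), base_kind=KIND_BY_SUBSCRIPT[m.group(2)])
    m = _INTER_RE.match(token)
    if m:
        return KernelTermSpec(
            layers=(m.group(1), m.group(3)),
            base_kind=KIND_BY_SUBSCRIPT[m.group(2)],
            combo=m.group(4),
        )
    raise ModelGrammarError(
        f"cannot parse term {token!r}: expected e.g. 'gL', 'tG', 'gLtLCC' "
        "(mixed-kind interactions are not supported)"
    )


def parse_formula(formula: str, model_id: str = "custom") -> ModelSpec:
    """Parse a full predictor string, terms joined by '+'."""
    tokens = [t.strip() for t in formula.split("+") if t.strip()]
    if not tokens:
        raise ModelGrammarError("empty predictor formula")
    return ModelSpec(model_id=model_id, terms=tuple(parse_term(t) for t in tokens))


# The 24 registered predictors.  M1-M11 use linear kernels, M12-M22 their
# Gaussian counterparts, M23 combines both additive sets, M24 adds the
# Gaussian interaction set on top of M23.
MODEL_FORMULAS: Dict[str, str] = {
    "M1": "gL",
    "M2": "tL",
    "M3": "mL",
    "M4": "gL+tL+mL",
    "M5": "gL+tL+mL+gLtLCC+gLtLPP",
    "M6": "gL+tL+mL+gLmLCC+gLmLPP",
    "M7": "gL+tL+mL+tLmLCC+tLmLPP",
    "M8": "gL+tL+mL+gLtLCC+gLtLPP+gLmLCC+gLmLPP",
    "M9": "gL+tL+mL+gLtLCC+gLtLPP+tLmLCC+tLmLPP",
    "M10": "gL+tL+mL+gLmLCC+gLmLPP+tLmLCC+tLmLPP",
    "M11": "gL+tL+mL+gLtLCC+gLtLPP+gLmLCC+gLmLPP+tLmLCC+tLmLPP",
    "M12": "gG",
    "M13": "tG",
    "M14": "mG",
    "M15": "gG+tG+mG",
    "M16": "gG+tG+mG+gGtGCC+gGtGPP",
    "M17": "gG+tG+mG+gGmGCC+gGmGPP",
    "M18": "gG+tG+mG+tGmGCC+tGmGPP",
    "M19": "gG+tG+mG+gGtGCC+gGtGPP+gGmGCC+gGmGPP",
    "M20": "gG+tG+mG+gGtGCC+gGtGPP+tGmGCC+tGmGPP",
    "M21": "gG+tG+mG+gGmGCC+gGmGPP+tGmGCC+tGmGPP",
    "M22": "gG+tG+mG+gGtGCC+gGtGPP+gGmGCC+gGmGPP+tGmGCC+tGmGPP",
    "M23": "gL+tL+mL+gG+tG+mG",
    "M24": "gL+tL+mL+gG+tG+mG+gGtGCC+gGtGPP+gGmGCC+gGmGPP+tGmGCC+tGmGPP",
}

MODEL_IDS: Tuple[str, ...] = tuple(MODEL_FORMULAS)


def get_model_spec(model_id: str) -> ModelSpec:
    """Return the canonical term list for one of M1..M24."""
    if model_id not in MODEL_FORMULAS:
        raise ModelGrammarError(
            f"unknown model {model_id!r}; valid IDs: {', '.join(MODEL_IDS)}"
        )
    return parse_formula(MODEL_FORMULAS[model_id], model_id=model_id)


def resolve_model(model: str) -> ModelSpec:
    """Accept either a registered model ID or a raw predictor formula."""
    if model in MODEL_FORMULAS:
        return get_model_spec(model)
    return parse_formula(model, model_id=model)


class KernelFactory:
    """Materializes the kernel list of any predictor from per-layer bases.

    ``base`` maps ``(layer_letter, kind)`` to a :class:`KernelMatrix`, e.g.
    ``("g", "linear") -> VanRaden GRM``.  Hybrid CC/PP pairs are computed
    once per (layer pair, kind) and cached, so every model drawing on the
    same pair reuses bitwise-identical kernels.  All returned kernels are
    PSD-repaired (hybrids only need it) and scaled to mean diagonal 1.
    """

    def __init__(self, base: Mapping[Tuple[str, str], KernelMatrix]):
        self._base: Dict[Tuple[str, str], KernelMatrix] = dict(base)
        self._main_cache: Dict[Tuple[str, str], KernelMatrix] = {}
        self._hybrid_cache: Dict[Tuple[str, str, str], KernelMatrix] = {}

    def _get_base(self, layer: str, kind: str) -> KernelMatrix:
        try:
            return self._base[(layer, kind)]
        except KeyError:
            raise ModelGrammarError(
                f"no base kernel for layer {layer!r}, kind {kind!r}"
            ) from None

    def _main(self, layer: str, kind: str) -> KernelMatrix:
        key = (layer, kind)
        if key not in self._main_cache:
            self._main_cache[key] = scale_kernel(self._get_base(layer, kind))
        return self._main_cache[key]

    def _hybrid(self, layers: Tuple[str, str], kind: str, combo: str) -> KernelMatrix:
        key = (layers[0], layers[1], kind)
        cc_key, pp_key = key + ("CC",), key + ("PP",)
        if (cc_key not in self._hybrid_cache) or (pp_key not in self._hybrid_cache):
            K1 = self._get_base(layers[0], kind)
            K2 = self._get_base(layers[1], kind)
            stem = f"{layers[0]}{layers[1]}:{kind}"
            K_cc, K_pp = hybrid_kernels(K1, K2, recipe_stem=stem)
            self._hybrid_cache[cc_key] = scale_kernel(psd_repair(K_cc))
            self._hybrid_cache[pp_key] = scale_kernel(psd_repair(K_pp))
        return self._hybrid_cache[key + (combo,)]

    def materialize(self, spec: ModelSpec) -> List[KernelMatrix]:
        """Kernel list for ``spec``, in term order."""
        out = []
        for term in spec.terms:
            if term.combo == "main":
                out.append(self._main(term.layers[0], term.base_kind))
            else:
                out.append(self._hybrid(term.layers, term.base_kind, term.combo))
        return out


def materialize_kernels(
    spec: ModelSpec, base: Mapping[Tuple[str, str], KernelMatrix]
) -> List[KernelMatrix]:
    """One-shot convenience wrapper around :class:`KernelFactory`."""
    return KernelFactory(base).materialize(spec)
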