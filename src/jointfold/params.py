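"""Run parameters and the bundled evolutionary parameter set.

``Params`` collects the tunable knobs of the two-step pipeline: the
reliability cutoff ``delta`` (adapted upward from its starting value until
the selected partial structure is probable enough), the ensemble-probability
gate ``gamma``, the single-stranded weight ``alpha`` and the thermodynamic
weight ``beta`` of the combined expected-accuracy score, plus behavioural
flags.

``load_parameter_set`` reads the grammar production probabilities and
substitution models from a YAML asset.  The bundled default asset carries
the standard lightweight structure grammar probabilities and *synthetic*
rate matrices (see the asset header).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .phylo import (
    CANONICAL_PAIRS,
    PAIR_STATES,
    RESIDUES,
    PairSubstModel,
    SingleSubstModel,
    reversible_rate_matrix,
)

DEFAULT_ASSET = "pfold_like_params_synthetic.yaml"


@dataclass
class Params:
    """Pipeline parameters.

    delta       : initial reliability cutoff for Step-1 selection, in [0.5, 1].
    gamma       : ensemble-probability gate in [0, 1].
    alpha       : weight of single-stranded reliabilities (>= 0).
    beta        : weight of the thermodynamic part (>= 0).
    delta_start : hard floor for the adaptive cutoff (>= 0.5 is enforced).
    delta_step  : increment of the cutoff per adaptation round.
    evo         : evolutionary scoring on/off (off allows n = 1).
    eq15_mode   : score constrained pairs as 1 instead of their fixed
                  ensemble probability.
    allow_isolated : keep base pairs without a stacked neighbour in the
                  thermodynamic ensembles (the demo configuration turns
                  this off).
    gamma_agg   : aggregation of per-sequence thermodynamic ensemble
                  probabilities in the gate: 'min' (each sequence must be
                  probable) or 'mean'.
    """

    delta: float = 0.9
    gamma: float = 0.1
    alpha: float = 0.2
    beta: float = 1.0
    delta_start: float = 0.5
    delta_step: float = 0.05
    evo: bool = True
    eq15_mode: bool = False
    allow_isolated: bool = True
    gamma_agg: str = "min"
    extend_stems: bool = True

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.delta < 0.5 or self.delta > 1.0:
            raise ValueError("delta must be in [0.5, 1] (>= 0.5 keeps the "
                             "selected pair set conflict-free)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.delta_step <= 0:
            raise ValueError("delta_step must be > 0")
        if self.gamma_agg not in ("min", "mean"):
            raise ValueError("gamma_agg must be 'min' or 'mean'")

    @property
    def delta_init(self) -> float:
        """Starting cutoff of the adaptation: max(delta, delta_start, 0.5)."""
        return max(self.delta, self.delta_start, 0.5)

    def with_(self, **kw) -> "Params":
        return replace(self, **kw)


@dataclass
class Grammar:
    """Production probabilities of the structure grammar

    S -> LS | L,  L -> s | dFd,  F -> dFd | LS.
    """

    S_LS: float
    S_L: float
    L_s: float
    L_dFd: float
    F_dFd: float
    F_LS: float

    def __post_init__(self):
        for name, total in (
            ("S", self.S_LS + self.S_L),
            ("L", self.L_s + self.L_dFd),
            ("F", self.F_dFd + self.F_LS),
        ):
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"productions of {name} sum to {total}, not 1")
        if min(self.S_LS, self.S_L, self.L_s, self.L_dFd, self.F_dFd, self.F_LS) <= 0:
            raise ValueError("all production probabilities must be > 0")


@dataclass
class ParameterSet:
    grammar: Grammar
    single_model: SingleSubstModel
    pair_model: PairSubstModel


def _hky(pi: np.ndarray, kappa: float) -> np.ndarray:
    S = np.ones((4, 4))
    # transitions: A<->G (0,2), C<->U (1,3)
    S[0, 2] = S[2, 0] = S[1, 3] = S[3, 1] = kappa
    np.fill_diagonal(S, 0.0)
    return reversible_rate_matrix(pi, S)


def _pair_exchangeabilities(single: float, double_can: float, double_other: float):
    k = 16
    S = np.zeros((k, k))
    canon = set(CANONICAL_PAIRS)
    for x in range(k):
        for y in range(k):
            if x == y:
                continue
            sx, sy = PAIR_STATES[x], PAIR_STATES[y]
            ham = (sx[0] != sy[0]) + (sx[1] != sy[1])
            if ham == 1:
                S[x, y] = single
            elif sx in canon and sy in canon:
                S[x, y] = double_can
            else:
                S[x, y] = double_other
    return S


def build_parameter_set(doc: dict) -> ParameterSet:
    grammar = Grammar(**doc["grammar"])
    sm = doc["single_model"]
    pi4 = np.array([sm["frequencies"][r] for r in RESIDUES], dtype=float)
    pi4 = pi4 / pi4.sum()
    single = SingleSubstModel(pi4, _hky(pi4, float(sm["kappa"])))
    pm = doc["pair_model"]
    pi16 = np.zeros(16)
    for p, f in pm["canonical_frequencies"].items():
        pi16[PAIR_STATES.index(p)] = float(f)
    non = [i for i, s in enumerate(PAIR_STATES) if s not in CANONICAL_PAIRS]
    pi16[non] = float(pm["noncanonical_frequency_total"]) / len(non)
    pi16 = pi16 / pi16.sum()
    S16 = _pair_exchangeabilities(
        float(pm["single_change_exchangeability"]),
        float(pm["double_canonical_exchangeability"]),
        float(pm["double_other_exchangeability"]),
    )
    pair = PairSubstModel(pi16, reversible_rate_matrix(pi16, S16))
    return ParameterSet(grammar, single, pair)


def load_parameter_set(path=None) -> ParameterSet:
    """Load a parameter set from YAML; the bundled asset when ``path`` is None."""
    if path is None:
        text = (
            resources.files("jointfold")
            .joinpath("assets")
            .joinpath(DEFAULT_ASSET)
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return build_parameter_set(yaml.safe_load(text))


_default_cache: list[ParameterSet] = []


def default_parameter_set() -> ParameterSet:
    if not _default_cache:
        _default_cache.append(load_parameter_set())
    return _default_cache[0]
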