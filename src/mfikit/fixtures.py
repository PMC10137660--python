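"""Worked-example distributions: noisy logic gates and the dyadic/triadic pair.

Logic gates
-----------
A two-input gate G over inputs A, B and output C defines four legal states
``(a, b, G(a, b))``, each given probability ``p``; the four illegal states
get probability ``ε`` (``4p + 4ε = 1``, ``0 ≤ ε < p``).  Three-input gates
work the same with eight legal and eight illegal states.  At ``ε = 0`` the
table is the uniform distribution over the truth table — the setting for
the entropy/MI results — while ``ε > 0`` keeps every interaction finite;
gate interactions are all multiples of ``I = 4·log(p/ε)``.

Dyadic and triadic distributions
--------------------------------
Two distributions over three four-letter variables that share essentially
all Shannon-type information measures yet differ in construction order.
Each category c ∈ {0,1,2,3} is split into a bit pair via
{0,1,2,3} → {00,01,10,11} (high bit first), giving bits X0,X1,Y0,Y1,Z0,Z1.
The dyadic distribution couples bits pairwise (X0=Y1, Y0=Z1, Z0=X1); the
triadic one uses triplet rules (X0+Y0+Z0 even, X1=Y1=Z1).  The eight legal
states get ``p = (1 − 56ε)/8`` and the 56 illegal ones ``ε``.  Categorical
interactions tell the two apart; entropies do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .distributions import JointTable

__all__ = [
    "GateSpec",
    "GATE_FUNCTIONS",
    "gate_distribution",
    "dyadic_distribution",
    "triadic_distribution",
    "DEFAULT_EPSILON",
]

#: Default illegal-state probability when only symbolic values are given.
DEFAULT_EPSILON = 1e-4

GATE_FUNCTIONS = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "NAND": lambda a, b: 1 - (a & b),
    "NOR": lambda a, b: 1 - (a | b),
    "XOR": lambda a, b: a ^ b,
    "XNOR": lambda a, b: 1 - (a ^ b),
    "XOR3": lambda a, b, c: (a + b + c) % 2,
    "AND3": lambda a, b, c: a & b & c,
    "OR3": lambda a, b, c: a | b | c,
}

TWO_INPUT_GATES = ("AND", "OR", "NAND", "NOR", "XOR", "XNOR")
THREE_INPUT_GATES = ("XOR3", "AND3", "OR3")


@dataclass(frozen=True)
class GateSpec:
    """A noisy logic gate: name plus legal-state and illegal-state probabilities.

    Give ``p``, ``eps``, or both; the missing one is filled in from the
    normalization ``m·p + m·ε = 1`` where m is the number of legal states
    (4 for two-input gates, 8 for three-input).  Requires ``0 ≤ ε < p``.
    """

    name: str
    p: float | None = None
    eps: float | None = None

    def __post_init__(self):
        name = self.name.upper()
        if name not in GATE_FUNCTIONS:
            raise ValueError(
                f"unknown gate {self.name!r}; choose from {sorted(GATE_FUNCTIONS)}"
            )
        object.__setattr__(self, "name", name)
        m = self.n_legal
        p, eps = self.p, self.eps
        if p is None and eps is None:
            eps = DEFAULT_EPSILON
        if p is None:
            p = 1.0 / m - eps
        elif eps is None:
            eps = 1.0 / m - p
        if not np.isclose(m * p + m * eps, 1.0, atol=1e-9):
            raise ValueError(
                f"{m}·p + {m}·ε must equal 1; got p={p}, ε={eps}"
            )
        if not 0 <= eps < p:
            raise ValueError(f"need 0 ≤ ε < p, got p={p}, ε={eps}")
        object.__setattr__(self, "p", float(p))
        object.__setattr__(self, "eps", float(eps))

    @property
    def n_inputs(self) -> int:
        return 3 if self.name in THREE_INPUT_GATES else 2

    @property
    def n_legal(self) -> int:
        return 2 ** self.n_inputs

    @property
    def interaction_scale(self) -> float:
        """``I = 4 log(p/ε)``, the unit all gate interactions are multiples of."""
        if self.eps == 0:
            return float("inf")
        return 4.0 * np.log(self.p / self.eps)


def gate_distribution(spec: GateSpec | str, p: float | None = None,
                      eps: float | None = None) -> JointTable:
    """Joint table of a noisy logic gate.

    Legal truth-table states receive probability ``p`` and every other
    state ``ε``.  Variables are A, B (inputs) and C (output), plus D for
    three-input gates (inputs A, B, C; output D).
    """
    if not isinstance(spec, GateSpec):
        spec = GateSpec(str(spec), p=p, eps=eps)
    fn = GATE_FUNCTIONS[spec.name]
    n = spec.n_inputs
    variables = ("A", "B", "C", "D")[: n + 1]
    probs = np.full((2,) * (n + 1), spec.eps, dtype=float)
    for inputs in product((0, 1), repeat=n):
        probs[(*inputs, fn(*inputs))] = spec.p
    return JointTable(variables, probs)


def _category_bits(c: int) -> tuple[int, int]:
    # {0,1,2,3} → {00,01,10,11}: bit 0 is the high bit of the string
    return c >> 1, c & 1


def _bits_to_category(b0: int, b1: int) -> int:
    return 2 * b0 + b1


def _legal_dyadic() -> set[tuple[int, int, int]]:
    states = set()
    for x1, y1, z1 in product((0, 1), repeat=3):
        x0, y0, z0 = y1, z1, x1
        states.add((
            _bits_to_category(x0, x1),
            _bits_to_category(y0, y1),
            _bits_to_category(z0, z1),
        ))
    return states


def _legal_triadic() -> set[tuple[int, int, int]]:
    states = set()
    for x0, y0 in product((0, 1), repeat=2):
        z0 = (x0 + y0) % 2
        for shared in (0, 1):
            states.add((
                _bits_to_category(x0, shared),
                _bits_to_category(y0, shared),
                _bits_to_category(z0, shared),
            ))
    return states


def _rule_distribution(legal: set[tuple[int, int, int]], eps: float) -> JointTable:
    if not 0 <= eps < 1.0 / 56.0:
        raise ValueError(f"need 0 ≤ ε < 1/56, got {eps}")
    if len(legal) != 8:
        raise AssertionError("rule construction must yield exactly 8 legal states")
    p = (1.0 - 56.0 * eps) / 8.0
    probs = np.full((4, 4, 4), eps, dtype=float)
    for state in legal:
        probs[state] = p
    return JointTable(("X", "Y", "Z"), probs)


def dyadic_distribution(eps: float = DEFAULT_EPSILON) -> JointTable:
    """The pairwise-rule distribution over three four-letter variables."""
    return _rule_distribution(_legal_dyadic(), eps)


def triadic_distribution(eps: float = DEFAULT_EPSILON) -> JointTable:
    """The triplet-rule distribution over three four-letter variables."""
    return _rule_distribution(_legal_triadic(), eps)
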