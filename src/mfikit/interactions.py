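"""Model-free n-point interactions, their duals, and categorical variants.

The model-free interaction (MFI) of a variable set τ is the iterated
Boolean finite-difference of the log joint probability, evaluated with all
other variables held at 0:

    I_τ = ∂^n log p(X) / ∂X_1 … ∂X_n |_{X∖τ = 0}

Equivalently — and this equivalence is enforced by tests, not assumed —
it is the Möbius inversion of the background surprisal
``S_{η;T} = log p(η = 1, T∖η = 0)`` on the subset lattice with top τ:

    I(τ; T) = Σ_{η⊆τ} μ(η, τ) S_{η;T} = Σ_{η⊆τ} (−1)^{|η|−|τ|} S_{η;T}

MFIs are exactly the coupling coefficients of the generalized Ising
(maximum-entropy) model: extracting MFIs from a Boltzmann table returns
the couplings that built it.  All interaction values are in natural-log
("energy") units; divide by ``ln 2`` for bits.

Dual interactions invert surprisal on the order-reversed lattice; the dual
of a singleton X is the interaction among the remaining variables in the
background X = 1 instead of 0.  Categorical interactions replace the
Boolean 0→1 step with an arbitrary increasing transition ``x0 → x1`` per
variable on the chain-product state lattice.

Non-finite policy: interactions touching a zero-probability background
state come back as ±inf/NaN with ``finite=False`` rather than raising, so
whole-table scans complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Callable, Iterable, Mapping

import networkx as nx

from .distributions import JointTable, UnsupportedArityError, background_surprisal
from .lattice import DualView, SubsetLattice, moebius_inversion, zeta_sum

__all__ = [
    "InteractionResult",
    "boolean_derivative",
    "mfi",
    "mfi_moebius",
    "dual_mfi",
    "j_interaction",
    "symmetric_j",
    "surprisal_from_interactions",
    "categorical_mfi",
    "enumerate_categorical_interactions",
    "symmetrized_sum",
    "conditioning_set",
    "InvalidTransitionError",
    "CyclicGraphError",
]


class InvalidTransitionError(ValueError):
    """A categorical transition is not strictly increasing or out of range."""


class CyclicGraphError(ValueError):
    """The supplied conditioning graph is not acyclic."""


@dataclass(frozen=True)
class InteractionResult:
    """An interaction value with its full context.

    Attributes
    ----------
    value
        The interaction in natural-log units.
    variables
        The interacting set τ (order as given; the value is permutation
        invariant).
    background
        The full background set T whose non-τ members are fixed (to 0, or
        to 1 for duals); variables outside T were marginalized over.
    dual
        Whether this is an order-dual interaction.
    transitions
        For categorical interactions, the ``(x0, x1)`` step per variable;
        None for ordinary binary interactions (where the step is 0→1).
    """

    value: float
    variables: tuple[str, ...]
    background: tuple[str, ...]
    dual: bool = False
    transitions: tuple[tuple[int, int], ...] | None = None

    @property
    def order(self) -> int:
        return len(self.variables)

    @property
    def finite(self) -> bool:
        return math.isfinite(self.value)

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# Boolean derivatives and the derivative-route MFI
# ---------------------------------------------------------------------------

def boolean_derivative(f: Callable[[Mapping[str, int]], float],
                       variable: str) -> Callable[[Mapping[str, int]], float]:
    """Finite-difference derivative with respect to a binary variable.

    Returns ``g(X) = f(X_i = 1, rest) − f(X_i = 0, rest)``.  Iterated
    application over several variables commutes, so higher derivatives are
    order-independent.
    """

    def df(assignment: Mapping[str, int]) -> float:
        hi = dict(assignment)
        lo = dict(assignment)
        hi[variable] = 1
        lo[variable] = 0
        return f(hi) - f(lo)

    return df


def _resolve_sets(table: JointTable, tau, T):
    tau = tuple(dict.fromkeys(tau))
    T = tuple(table.variables) if T is None else tuple(dict.fromkeys(T))
    if not set(tau) <= set(T):
        raise ValueError("tau must be a subset of the background set T")
    if not set(T) <= set(table.variables):
        raise KeyError("background set T not within table variables")
    if not table.is_binary(T):
        raise UnsupportedArityError("MFIs are defined on binary variables")
    return tau, T


def mfi(table: JointTable, tau: Iterable[str],
        T: Iterable[str] | None = None) -> InteractionResult:
    """Model-free interaction of τ via iterated Boolean derivatives.

    Differences ``log p`` once per variable of τ and evaluates with the
    remaining variables of the background set ``T`` at 0 (variables outside
    ``T`` are marginalized over first).  Order 1 is the log-odds of
    switching one variable on; order 2 the log odds-ratio; higher orders
    difference those.
    """
    tau, T = _resolve_sets(table, tau, T)
    if not tau:
        raise ValueError("tau must be nonempty (use background_surprisal for I_∅)")
    marg = table if set(T) == set(table.variables) else table.marginalize(T)

    def logp(assignment: Mapping[str, int]) -> float:
        p = marg.p(tuple(assignment[v] for v in marg.variables))
        return math.log(p) if p > 0 else float("-inf")

    f = logp
    for v in tau:
        f = boolean_derivative(f, v)
    value = f({v: 0 for v in T})
    return InteractionResult(value=float(value), variables=tau, background=T)


# ---------------------------------------------------------------------------
# Möbius-route MFI, duals, and derived quantities
# ---------------------------------------------------------------------------

def mfi_moebius(table: JointTable, tau: Iterable[str],
                T: Iterable[str] | None = None) -> InteractionResult:
    """Model-free interaction of τ as a Möbius inversion of surprisal.

    ``I(τ; T) = Σ_{η⊆τ} μ(η, τ) S_{η;T}`` on the subset lattice with top
    τ.  Equals :func:`mfi` for every input (the equivalence theorem); both
    routes are kept so each can check the other.
    """
    tau, T = _resolve_sets(table, tau, T)
    marg = table if set(T) == set(table.variables) else table.marginalize(T)
    lat = SubsetLattice(tau)
    value = moebius_inversion(
        lambda eta: background_surprisal(marg, eta), lat, lat.top
    )
    return InteractionResult(value=float(value), variables=tau, background=T)


def dual_mfi(table: JointTable, tau: Iterable[str],
             T: Iterable[str] | None = None) -> InteractionResult:
    """Order-dual interaction: surprisal inverted on the reversed lattice.

    ``I*(τ; T) = Σ_{σ: τ ⊆ σ ⊆ T} (−1)^{|σ|−|τ|} log p(σ = 1, T∖σ = 0)``.
    For a singleton X in a triple this equals
    ``I(X,Y,Z;T) + I(Y,Z;T) = log[p₁₁₁ p₁₀₀ / (p₁₀₁ p₁₁₀)]`` — the pair
    interaction of the other two variables in the background X = 1.
    """
    tau, T = _resolve_sets(table, tau, T)
    marg = table if set(T) == set(table.variables) else table.marginalize(T)
    dual = DualView(SubsetLattice(T))
    value = moebius_inversion(
        lambda sigma: background_surprisal(marg, sigma), dual, frozenset(tau)
    )
    return InteractionResult(value=float(value), variables=tau, background=T,
                             dual=True)


def j_interaction(table: JointTable, input_var: str,
                  T: Iterable[str] | None = None) -> float:
    """J-interaction ``J*_X = I(T) − I(T∖X)`` on a three-variable background.

    The energy difference between the triplet coupling and the pair
    coupling that omits ``input_var``; unlike the 3-point interaction alone,
    the input-node J-interactions take a distinct value on every two-input
    logic gate.
    """
    T = tuple(table.variables) if T is None else tuple(dict.fromkeys(T))
    if len(T) != 3:
        raise ValueError("J-interactions are defined on a three-variable set")
    if input_var not in T:
        raise KeyError(f"{input_var!r} is not in T")
    rest = tuple(v for v in T if v != input_var)
    return mfi(table, T, T).value - mfi(table, rest, T).value


def symmetric_j(table: JointTable, T: Iterable[str] | None = None) -> float:
    """Symmetric J-interaction: the product of the three per-variable J's."""
    T = tuple(table.variables) if T is None else tuple(dict.fromkeys(T))
    if len(T) != 3:
        raise ValueError("J-interactions are defined on a three-variable set")
    out = 1.0
    for v in T:
        out *= j_interaction(table, v, T)
    return out


def surprisal_from_interactions(table: JointTable, tau: Iterable[str],
                                T: Iterable[str] | None = None) -> float:
    """Zeta-sum of interactions: ``log p(τ=1, T∖τ=0) = Σ_{η⊆τ} I(η; T)``.

    The inversion of the MFI definition — summing every interaction below
    τ (including ``I_∅ = log p(all zeros)``) reconstructs the background
    log-probability.
    """
    tau, T = _resolve_sets(table, tau, T)
    marg = table if set(T) == set(table.variables) else table.marginalize(T)
    lat = SubsetLattice(tau)

    def interaction(eta: frozenset) -> float:
        if not eta:
            return background_surprisal(marg, ())
        return mfi_moebius(marg, tuple(eta)).value

    return zeta_sum(interaction, lat, lat.top)


# ---------------------------------------------------------------------------
# categorical interactions on the chain-product lattice
# ---------------------------------------------------------------------------

def categorical_mfi(table: JointTable,
                    transitions: Mapping[str, tuple[int, int]],
                    T: Iterable[str] | None = None) -> InteractionResult:
    """Interaction of categorical variables along increasing transitions.

    Each participating variable steps ``x0 → x1`` with ``x1 > x0``; the
    value is the alternating sum over corner states of the transition box,

    ``I = Σ_{c ∈ {0,1}^τ} (−1)^{#(c=0)} log p(x_c, rest = 0)``,

    where ``x_c`` picks ``x1`` where ``c = 1`` and ``x0`` where ``c = 0``
    and all non-participating background variables sit at 0.  This is the
    Möbius inversion of surprisal on the sublattice of the chain-product
    state lattice spanned by the transition; for binary variables with the
    transition 0→1 it reduces exactly to :func:`mfi`.  The value is
    antisymmetric under reversing any one transition and additive along
    chained transitions (0→2 equals 0→1 plus 1→2).
    """
    tau = tuple(dict.fromkeys(transitions))
    if not tau:
        raise ValueError("need at least one transition")
    T = tuple(table.variables) if T is None else tuple(dict.fromkeys(T))
    if not set(tau) <= set(T):
        raise ValueError("transition variables must lie in the background set T")
    marg = table if set(T) == set(table.variables) else table.marginalize(T)
    for v in tau:
        x0, x1 = transitions[v]
        k = marg.arities[marg.axis(v)]
        if not (0 <= x0 < k and 0 <= x1 < k):
            raise InvalidTransitionError(
                f"transition {x0}→{x1} out of range for {v!r} (arity {k})"
            )
        if x1 <= x0:
            raise InvalidTransitionError(
                f"transition for {v!r} must increase, got {x0}→{x1}"
            )
    base = {v: 0 for v in T}
    value = 0.0
    for corner in product((0, 1), repeat=len(tau)):
        state = dict(base)
        for v, c in zip(tau, corner):
            state[v] = transitions[v][c]
        p = marg.p(tuple(state[v] for v in marg.variables))
        logp = math.log(p) if p > 0 else float("-inf")
        sign = 1 if (len(tau) - sum(corner)) % 2 == 0 else -1
        value += sign * logp
    return InteractionResult(
        value=float(value),
        variables=tau,
        background=T,
        transitions=tuple(tuple(transitions[v]) for v in tau),
    )


def enumerate_categorical_interactions(table: JointTable):
    """All increasing-transition 3-point interactions of a three-variable table.

    For variables with arities ``k_i`` there are ``Π C(k_i, 2)`` increasing
    transition triples (216 for three four-letter variables).  Returns a
    list of :class:`InteractionResult` in lexicographic transition order.
    """
    if table.n_variables != 3:
        raise ValueError("categorical enumeration is defined for exactly 3 variables")
    per_var = [
        list(combinations(range(k), 2)) for k in table.arities
    ]
    results = []
    for steps in product(*per_var):
        transitions = dict(zip(table.variables, steps))
        results.append(categorical_mfi(table, transitions))
    return results


def symmetrized_sum(table: JointTable) -> float:
    """Additively symmetrised 3-point interaction: the sum over all increasing transitions."""
    return float(sum(r.value for r in enumerate_categorical_interactions(table)))


# ---------------------------------------------------------------------------
# Markov-blanket conditioning sets
# ---------------------------------------------------------------------------

def conditioning_set(graph: nx.DiGraph, tau: Iterable[str]) -> frozenset:
    """Markov-blanket background set for computing the MFI of τ on a DAG.

    Returns τ together with the union of the Markov blankets (parents,
    children and co-parents) of its members.  Holding only these variables
    at 0 gives the same MFI as full conditioning whenever the omitted
    variables are independent of τ given the blanket.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise CyclicGraphError("conditioning graph must be a DAG")
    tau = set(tau)
    missing = tau - set(graph.nodes)
    if missing:
        raise KeyError(f"variables {sorted(missing)!r} not in graph")
    out = set(tau)
    for v in tau:
        parents = set(graph.predecessors(v))
        children = set(graph.successors(v))
        coparents = set()
        for c in children:
            coparents |= set(graph.predecessors(c))
        out |= parents | children | coparents
    return frozenset(out)
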