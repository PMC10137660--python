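"""Entropy, higher-order mutual information, its order-dual, and pointwise MI.

All quantities here are averaged (entropy-based) information measures built
as Möbius inversions on the subset lattice of the variables involved:

* ``MI(τ) = (−1)^{|τ|−1} Σ_{η≤τ} μ(η, τ) H(η) = Σ_{η≤τ} (−1)^{|η|+1} H(η)``
  is the higher-order mutual information (co-information): the alternating
  entropy sum.  For two variables it is the familiar
  ``H(X) + H(Y) − H(X, Y)``; for synergistic systems such as parity gates
  it can be negative.
* The dual mutual information ``MI*`` is the same inversion on the
  order-reversed lattice.  ``MI*(∅)`` is the MI of the whole set, and for a
  singleton ``MI*(X) = MI(T) − MI(T\\X)`` — the differential MI, i.e. the
  change in total mutual information when ``X`` is marginalized out.
* The generalized pointwise mutual information inverts marginal
  log-probabilities of one realization instead of entropies; for two
  variables it reduces to ``log p(x, y) / (p(x) p(y))``.

Logarithms default to base 2 (bits) so gate results are in bits; pass
``base=math.e`` for nats when comparing against interaction values.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .distributions import JointTable
from .lattice import SubsetLattice, moebius_inversion

__all__ = [
    "entropy",
    "mutual_information",
    "entropy_from_mi",
    "dual_mutual_information",
    "conditional_mutual_information",
    "pointwise_mi",
    "info_summary",
]


def entropy(table: JointTable, subset: Iterable[str] | None = None,
            base: float = 2.0) -> float:
    """Marginal Shannon entropy ``H(subset) = −Σ p log p`` (0·log 0 ≡ 0).

    ``subset=None`` means all variables; the empty subset has entropy 0.
    """
    subset = tuple(table.variables if subset is None else subset)
    if not subset:
        return 0.0
    marg = table.marginalize(subset)
    p = marg.probs[marg.probs > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


def _subsets(tau):
    tau = tuple(tau)
    for r in range(len(tau) + 1):
        yield from (frozenset(c) for c in combinations(tau, r))


def mutual_information(table: JointTable, tau: Iterable[str],
                       base: float = 2.0) -> float:
    """Higher-order mutual information among ``tau`` as a Möbius inversion.

    ``MI(τ) = (−1)^{|τ|−1} Σ_{η⊆τ} μ(η, τ) H(η)``, the alternating sum of
    marginal entropies over the subset lattice with top ``τ``.  A singleton
    returns its own entropy; independent variables give 0.
    """
    tau = tuple(dict.fromkeys(tau))
    if not tau:
        raise ValueError("tau must be a nonempty set of variables")
    lat = SubsetLattice(tau)
    h = {eta: entropy(table, eta, base=base) for eta in _subsets(tau)}
    sign = -1 if len(tau) % 2 == 0 else 1
    return sign * moebius_inversion(h.__getitem__, lat, lat.top)


def entropy_from_mi(table: JointTable, tau: Iterable[str],
                    base: float = 2.0) -> float:
    """Reconstruct ``H(τ)`` by inverting MI back: ``Σ_{η⊆τ} (−1)^{|η|−1} MI(η)``.

    Must agree with :func:`entropy`; e.g. for three variables
    ``H = ΣH(singletons) − ΣMI(pairs) + MI(triple)``.
    """
    tau = tuple(dict.fromkeys(tau))
    total = 0.0
    for eta in _subsets(tau):
        if eta:
            sign = -1 if len(eta) % 2 == 0 else 1
            total += sign * mutual_information(table, sorted(eta), base=base)
    return total


def dual_mutual_information(table: JointTable, eta: Iterable[str],
                            T: Iterable[str] | None = None,
                            base: float = 2.0) -> float:
    """Mutual information inverted on the order-reversed subset lattice.

    ``MI*(η) = Σ_{σ: η ⊆ σ ⊆ T} (−1)^{|σ|+1} H(σ)``.  The dual of the
    empty set is the MI of all of ``T``; for a singleton it is the
    differential mutual information ``MI(T) − MI(T\\X)``.
    """
    T = tuple(table.variables if T is None else dict.fromkeys(T))
    eta = frozenset(eta)
    if not eta <= set(T):
        raise ValueError("eta must be a subset of T")
    total = 0.0
    rest = [v for v in T if v not in eta]
    for r in range(len(rest) + 1):
        for extra in combinations(rest, r):
            sigma = eta | set(extra)
            if not sigma:
                continue
            sign = 1 if len(sigma) % 2 == 1 else -1
            total += sign * entropy(table, sorted(sigma, key=T.index), base=base)
    return total


def conditional_mutual_information(table: JointTable, tau: Iterable[str],
                                   given: Iterable[str],
                                   base: float = 2.0) -> float:
    """``MI(τ | Z) = Σ_z p(z) MI(τ)`` under each conditional distribution.

    The standard conditioning-average definition; ``given`` and ``tau``
    must be disjoint.
    """
    tau = tuple(dict.fromkeys(tau))
    given = tuple(dict.fromkeys(given))
    if set(tau) & set(given):
        raise ValueError("tau and conditioning set must be disjoint")
    keep = tau + given
    marg = table.marginalize(keep)
    z_marg = marg.marginalize(given)
    total = 0.0
    for z_state in z_marg.states():
        pz = z_marg.p(z_state)
        if pz <= 0:
            continue
        cond = marg.condition(dict(zip(z_marg.variables, z_state)))
        total += pz * mutual_information(cond, tau, base=base)
    return total


def pointwise_mi(table: JointTable, realization: Mapping[str, int],
                 base: float = 2.0) -> float:
    """Generalized pointwise mutual information of one realization.

    The Möbius inversion of marginal log-probabilities,
    ``pmi(T = τ) = Σ_{η⊆τ} (−1)^{|η|} log p(x_η)`` with ``p(x_∅) ≡ 1``,
    signed so that the two-variable case reduces to
    ``log p(x, y) / (p(x) p(y))``.  Zero marginals yield a non-finite
    result (check ``math.isfinite``).
    """
    tau = tuple(realization)
    if not tau:
        raise ValueError("realization must assign at least one variable")
    total = 0.0
    for eta in _subsets(tau):
        if not eta:
            continue
        marg = table.marginalize(eta)
        p = marg.p(tuple(realization[v] for v in marg.variables))
        logp = math.log(p) if p > 0 else float("-inf")
        sign = 1 if len(eta) % 2 == 0 else -1
        total += sign * logp
    return total / math.log(base)


def info_summary(table: JointTable, max_order: int | None = None,
                 base: float = 2.0) -> pd.DataFrame:
    """Tabulate H, MI and MI* for every variable subset up to ``max_order``.

    Returns a DataFrame with columns ``kind`` (entropy/mi/dual_mi),
    ``variables``, ``order``, ``value`` and ``finite`` — the CLI's `info`
    output.
    """
    max_order = table.n_variables if max_order is None else int(max_order)
    rows = []
    for r in range(1, max_order + 1):
        for combo in combinations(table.variables, r):
            h = entropy(table, combo, base=base)
            mi = mutual_information(table, combo, base=base)
            rows.append(("entropy", combo, r, h))
            rows.append(("mi", combo, r, mi))
    for r in range(0, max_order + 1):
        for combo in combinations(table.variables, r):
            dmi = dual_mutual_information(table, combo, base=base)
            rows.append(("dual_mi", combo, r, dmi))
    df = pd.DataFrame(rows, columns=["kind", "variables", "order", "value"])
    df["variables"] = df["variables"].map(lambda c: ",".join(c))
    df["finite"] = np.isfinite(df["value"])
    return df
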