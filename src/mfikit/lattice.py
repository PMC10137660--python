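"""Finite posets, lattices, Möbius functions, and Möbius inversion.

This module is the algebraic engine of the package.  Every information and
interaction quantity downstream is a Möbius inversion of some set function
(marginal entropy, background surprisal) on one of three lattices:

* :class:`SubsetLattice` — the powerset of a variable set ordered by
  inclusion (a Boolean algebra; an *n*-cube).  Mutual information and the
  model-free interactions live here.
* :class:`ChainProductLattice` — tuples of categorical levels ordered
  componentwise; the stage for categorical interactions.
* :class:`DualView` — any lattice with its order reversed, which carries the
  dual (differential) quantities.

The Möbius function ``μ(x, y)`` is defined recursively: 1 on the diagonal,
``−Σ_{x≤z<y} μ(x, z)`` for ``x < y``, and 0 otherwise.  It is the inverse of
the zeta function of the incidence algebra, so the pair
:func:`moebius_inversion` / :func:`zeta_sum` are mutually inverse —
a poset generalisation of differencing and summing.

Möbius values on the lattices used here are exact integers and are returned
as Python ints.
"""

from __future__ import annotations

from itertools import chain, combinations, product
from typing import Callable, Hashable, Iterable, Mapping


class ElementNotFoundError(LookupError):
    """Raised when an element does not belong to the poset."""


class Poset:
    """A finite partially ordered set.

    Subclasses implement :meth:`elements` (an iterable of hashable
    elements) and :meth:`le` (the order relation).  The generic recursive
    Möbius function is memoised per instance; subclasses may override
    :meth:`moebius` with a closed form (the recursion stays available as
    :meth:`moebius_recursive` so closed forms can be verified against it).
    """

    def elements(self) -> Iterable[Hashable]:
        raise NotImplementedError

    def le(self, x, y) -> bool:
        """Return True iff ``x ≤ y`` in this poset's order."""
        raise NotImplementedError

    # -- derived order predicates -------------------------------------
    def lt(self, x, y) -> bool:
        return x != y and self.le(x, y)

    def __contains__(self, x) -> bool:
        return any(x == e for e in self.elements())

    def _require(self, *xs) -> None:
        for x in xs:
            if x not in self:
                raise ElementNotFoundError(f"{x!r} is not an element of {self!r}")

    def downset(self, y) -> list:
        """All elements ``x`` with ``x ≤ y``."""
        self._require(y)
        return [x for x in self.elements() if self.le(x, y)]

    def interval(self, x, y) -> list:
        """All elements ``z`` with ``x ≤ z ≤ y``."""
        self._require(x, y)
        return [z for z in self.elements() if self.le(x, z) and self.le(z, y)]

    # -- Möbius function ----------------------------------------------
    def moebius_recursive(self, x, y) -> int:
        """Möbius function computed from the defining recursion."""
        self._require(x, y)
        cache = getattr(self, "_mu_cache", None)
        if cache is None:
            cache = self._mu_cache = {}
        return self._mu(x, y, cache)

    def _mu(self, x, y, cache) -> int:
        key = (x, y)
        if key in cache:
            return cache[key]
        if x == y:
            val = 1
        elif not self.le(x, y):
            val = 0
        else:
            val = -sum(
                self._mu(x, z, cache)
                for z in self.elements()
                if self.le(x, z) and self.lt(z, y)
            )
        cache[key] = val
        return val

    moebius = moebius_recursive


class SubsetLattice(Poset):
    """The Boolean algebra of subsets of a ground set, ordered by inclusion.

    Elements are ``frozenset``s over ``ground``.  The lattice is bounded
    (bottom ``∅``, top the full ground set), every pair has a meet
    (intersection) and join (union), and the Möbius function has the closed
    form ``μ(x, y) = (−1)^{|y|−|x|}`` for ``x ⊆ y``.

    The ground ordering supplied by the caller is preserved and used for
    deterministic element enumeration; all quantities computed on the
    lattice are invariant under reordering.
    """

    def __init__(self, ground: Iterable[Hashable]):
        self.ground = tuple(ground)
        if len(set(self.ground)) != len(self.ground):
            raise ValueError("ground set contains duplicate elements")
        self._ground_set = frozenset(self.ground)

    def elements(self):
        for r in range(len(self.ground) + 1):
            for combo in combinations(self.ground, r):
                yield frozenset(combo)

    def le(self, x, y) -> bool:
        return frozenset(x) <= frozenset(y)

    def __contains__(self, x) -> bool:
        try:
            return frozenset(x) <= self._ground_set
        except TypeError:
            return False

    @property
    def bottom(self) -> frozenset:
        return frozenset()

    @property
    def top(self) -> frozenset:
        return self._ground_set

    def meet(self, x, y) -> frozenset:
        return frozenset(x) & frozenset(y)

    def join(self, x, y) -> frozenset:
        return frozenset(x) | frozenset(y)

    def moebius(self, x, y) -> int:
        self._require(x, y)
        x, y = frozenset(x), frozenset(y)
        if not x <= y:
            return 0
        return -1 if (len(y) - len(x)) % 2 else 1

    def __repr__(self):
        return f"SubsetLattice(ground={self.ground!r})"


class ChainProductLattice(Poset):
    """Product of chains: tuples ``a`` with ``0 ≤ a_i < k_i``, ordered componentwise.

    ``a ≤ b ⇔ ∀i: a_i ≤ b_i``.  This is the state lattice of categorical
    variables with arities ``k_i``.  Its Möbius function factorises over
    components; on a single chain ``μ(a, b)`` is 1 if ``b = a``, −1 if
    ``b = a + 1`` and 0 otherwise, so the product vanishes unless every
    component of ``y − x`` is 0 or 1.
    """

    def __init__(self, arities: Iterable[int]):
        self.arities = tuple(int(k) for k in arities)
        if any(k < 2 for k in self.arities):
            raise ValueError("every arity must be at least 2")

    def elements(self):
        return product(*(range(k) for k in self.arities))

    def le(self, x, y) -> bool:
        return all(a <= b for a, b in zip(x, y, strict=True))

    def __contains__(self, x) -> bool:
        try:
            return len(x) == len(self.arities) and all(
                0 <= a < k and int(a) == a for a, k in zip(x, self.arities)
            )
        except TypeError:
            return False

    @property
    def bottom(self) -> tuple:
        return (0,) * len(self.arities)

    @property
    def top(self) -> tuple:
        return tuple(k - 1 for k in self.arities)

    def meet(self, x, y) -> tuple:
        return tuple(min(a, b) for a, b in zip(x, y, strict=True))

    def join(self, x, y) -> tuple:
        return tuple(max(a, b) for a, b in zip(x, y, strict=True))

    def moebius(self, x, y) -> int:
        self._require(x, y)
        sign = 1
        for a, b in zip(x, y, strict=True):
            d = b - a
            if d < 0 or d > 1:
                return 0
            if d == 1:
                sign = -sign
        return sign

    def __repr__(self):
        return f"ChainProductLattice(arities={self.arities!r})"


class DualView(Poset):
    """A poset with the order of ``base`` reversed: ``x ⪯ y ⇔ y ≤ x`` in base.

    The dual of a lattice is a lattice (meets and joins swap); the dual of a
    Boolean algebra is again a Boolean algebra.  The Möbius function of the
    dual is the transpose of the base's: ``μ_op(x, y) = μ(y, x)``.
    """

    def __init__(self, base: Poset):
        self.base = base

    def elements(self):
        return self.base.elements()

    def le(self, x, y) -> bool:
        return self.base.le(y, x)

    def __contains__(self, x) -> bool:
        return x in self.base

    @property
    def bottom(self):
        return self.base.top

    @property
    def top(self):
        return self.base.bottom

    def moebius(self, x, y) -> int:
        return self.base.moebius(y, x)

    def __repr__(self):
        return f"DualView({self.base!r})"


class FinitePoset(Poset):
    """A poset given by explicit elements and covering/order pairs.

    ``relation`` is any set of ``(x, y)`` pairs meaning ``x ≤ y``; the
    reflexive–transitive closure is taken, so supplying only cover
    relations is fine.  Mainly useful for testing the incidence-algebra
    machinery on irregular posets.
    """

    def __init__(self, elements: Iterable[Hashable], relation: Iterable[tuple]):
        self._elements = list(dict.fromkeys(elements))
        idx = {e: i for i, e in enumerate(self._elements)}
        n = len(self._elements)
        closure = [[False] * n for _ in range(n)]
        for i in range(n):
            closure[i][i] = True
        for x, y in relation:
            if x not in idx or y not in idx:
                raise ElementNotFoundError(f"relation pair ({x!r}, {y!r}) off-poset")
            closure[idx[x]][idx[y]] = True
        # Warshall transitive closure
        for k in range(n):
            row_k = closure[k]
            for i in range(n):
                if closure[i][k]:
                    row_i = closure[i]
                    for j in range(n):
                        if row_k[j]:
                            row_i[j] = True
        for i in range(n):
            for j in range(n):
                if i != j and closure[i][j] and closure[j][i]:
                    raise ValueError("relation is not antisymmetric (contains a cycle)")
        self._idx = idx
        self._closure = closure

    def elements(self):
        return iter(self._elements)

    def le(self, x, y) -> bool:
        return self._closure[self._idx[x]][self._idx[y]]

    def __contains__(self, x) -> bool:
        try:
            return x in self._idx
        except TypeError:
            return False


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def moebius(poset: Poset, x, y) -> int:
    """Möbius function ``μ_P(x, y)`` of ``poset``."""
    return poset.moebius(x, y)


def _as_callable(g) -> Callable:
    if callable(g):
        return g
    if isinstance(g, Mapping):
        return g.__getitem__
    raise TypeError("g must be callable or a mapping over poset elements")


def moebius_inversion(g, poset: Poset, y) -> float:
    """Möbius inversion ``f(y) = Σ_{x≤y} μ(x, y) g(x)`` of ``g`` on ``poset``.

    ``g`` may be a callable or a mapping defined on every ``x ≤ y``.
    Non-finite values of ``g`` propagate into the result (possibly as NaN
    when infinities of both signs meet); callers inspect finiteness.
    """
    gf = _as_callable(g)
    return float(sum(poset.moebius(x, y) * gf(x) for x in poset.downset(y)))


def zeta_sum(f, poset: Poset, y) -> float:
    """Order-ideal sum ``g(y) = Σ_{x≤y} f(x)``; the inverse of :func:`moebius_inversion`."""
    ff = _as_callable(f)
    return float(sum(ff(x) for x in poset.downset(y)))


def dualize(poset: Poset) -> Poset:
    """Return the order-reversed poset; dualizing twice restores the original order."""
    if isinstance(poset, DualView):
        return poset.base
    return DualView(poset)


def powerset(iterable) -> Iterable[frozenset]:
    """All subsets of ``iterable`` as frozensets, by increasing size."""
    items = list(iterable)
    return (
        frozenset(c) for c in chain.from_iterable(
            combinations(items, r) for r in range(len(items) + 1)
        )
    )
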