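"""Exact joint probability tables and their sources.

The central object is :class:`JointTable`: a dense, exact joint
distribution over a small set of named discrete variables, stored as an
n-dimensional probability array (one axis per variable).  Tables come from
three places:

* plug-in estimation from a :class:`SampleMatrix` of observations
  (:func:`estimate_joint`),
* exact enumeration of a generalized Ising / Boltzmann model specified by
  subset couplings (:func:`boltzmann`),
* the worked-example constructors in :mod:`mfikit.fixtures`.

The one non-standard evaluation all interaction quantities consume is
:func:`background_surprisal`: the log-probability of the state where a
chosen subset of variables is 1 and the rest of the background set is 0.

Zero-probability states are never smoothed silently: surprisal of an
impossible state is ``−inf`` and downstream quantities carry a finiteness
flag.  Users opt into pseudocounts explicitly via ``estimate_joint``'s
``smoothing`` argument.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JointTable",
    "SampleMatrix",
    "IsingCouplings",
    "estimate_joint",
    "boltzmann",
    "background_surprisal",
    "marginalize",
    "condition",
    "DegenerateConditionError",
    "UnsupportedArityError",
]

_SUM_TOL = 1e-9


class DegenerateConditionError(ValueError):
    """Conditioning on an assignment of zero probability."""


class UnsupportedArityError(ValueError):
    """An operation requiring binary variables met a larger arity."""


class JointTable:
    """Exact joint distribution over named discrete variables.

    Parameters
    ----------
    variables
        Ordered variable identifiers, one per array axis.
    probs
        Array of shape ``(k_1, …, k_n)`` with non-negative entries summing
        to 1; ``k_i`` is the arity of variable ``i``.
    normalize
        If True, rescale ``probs`` to sum to 1 instead of validating.
    """

    def __init__(self, variables: Sequence[str], probs, *, normalize: bool = False):
        self.variables = tuple(str(v) for v in variables)
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != len(self.variables):
            raise ValueError(
                f"probs has {probs.ndim} axes for {len(self.variables)} variables"
            )
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if normalize:
            if total <= 0:
                raise ValueError("cannot normalize a zero table")
            probs = probs / total
        elif not math.isclose(total, 1.0, rel_tol=0, abs_tol=_SUM_TOL):
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        self.probs = probs

    # -- basic introspection ------------------------------------------
    @property
    def arities(self) -> tuple[int, ...]:
        return self.probs.shape

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def axis(self, var: str) -> int:
        try:
            return self.variables.index(var)
        except ValueError:
            raise KeyError(f"unknown variable {var!r}") from None

    def is_binary(self, subset: Iterable[str] | None = None) -> bool:
        vars_ = self.variables if subset is None else subset
        return all(self.arities[self.axis(v)] == 2 for v in vars_)

    def states(self) -> Iterable[tuple[int, ...]]:
        return product(*(range(k) for k in self.arities))

    def p(self, state: Sequence[int]) -> float:
        """Probability of a full state tuple (in variable order)."""
        return float(self.probs[tuple(int(s) for s in state)])

    def p_assignment(self, assignment: Mapping[str, int]) -> float:
        """Probability of a full state given as a {variable: value} mapping."""
        return self.p(tuple(assignment[v] for v in self.variables))

    # -- constructors --------------------------------------------------
    @classmethod
    def from_states(
        cls,
        variables: Sequence[str],
        arities: Sequence[int],
        prob: Mapping[tuple, float],
        *,
        normalize: bool = False,
    ) -> "JointTable":
        """Build a table from a sparse ``{state tuple: probability}`` mapping."""
        arr = np.zeros(tuple(arities), dtype=float)
        for state, pr in prob.items():
            arr[tuple(int(s) for s in state)] = pr
        return cls(variables, arr, normalize=normalize)

    # -- core manipulations -------------------------------------------
    def marginalize(self, keep: Iterable[str]) -> "JointTable":
        """Marginal over ``keep`` (order taken from this table's variable order)."""
        keep = set(keep)
        unknown = keep - set(self.variables)
        if unknown:
            raise KeyError(f"unknown variables {sorted(unknown)!r}")
        kept = tuple(v for v in self.variables if v in keep)
        drop_axes = tuple(i for i, v in enumerate(self.variables) if v not in keep)
        probs = self.probs.sum(axis=drop_axes) if drop_axes else self.probs.copy()
        if not kept:
            raise ValueError("cannot marginalize to the empty variable set")
        return JointTable(kept, probs)

    def condition(self, assignment: Mapping[str, int]) -> "JointTable":
        """Renormalized conditional table given ``assignment`` on a subset of variables."""
        idx: list = [slice(None)] * self.n_variables
        for var, val in assignment.items():
            ax = self.axis(var)
            if not 0 <= int(val) < self.arities[ax]:
                raise ValueError(f"value {val!r} out of range for {var!r}")
            idx[ax] = int(val)
        sub = self.probs[tuple(idx)]
        mass = float(sub.sum())
        if mass <= 0.0:
            raise DegenerateConditionError(
                f"conditioning assignment {dict(assignment)!r} has zero probability"
            )
        kept = tuple(v for v in self.variables if v not in assignment)
        if not kept:
            raise ValueError("conditioning on every variable leaves no table")
        return JointTable(kept, sub / mass)

    # -- I/O ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(*state, self.p(state)) for state in self.states()]
        return pd.DataFrame(rows, columns=[*self.variables, "prob"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "JointTable":
        df = pd.read_csv(path, sep="\t")
        if "prob" not in df.columns:
            raise ValueError("joint-table TSV needs a 'prob' column")
        variables = [c for c in df.columns if c != "prob"]
        states = df[variables].to_numpy(dtype=int)
        arities = tuple(states.max(axis=0) + 1)
        arities = tuple(max(int(k), 2) for k in arities)
        prob = {tuple(row): p for row, p in zip(states.tolist(), df["prob"])}
        return cls.from_states(variables, arities, prob)

    def to_json(self, path=None):
        obj = {
            "variables": list(self.variables),
            "arities": [int(k) for k in self.arities],
            "prob": {
                ",".join(map(str, state)): self.p(state)
                for state in self.states()
                if self.p(state) > 0
            },
        }
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "JointTable":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        prob = {
            tuple(int(s) for s in key.split(",")): float(p)
            for key, p in obj["prob"].items()
        }
        return cls.from_states(obj["variables"], obj["arities"], prob)

    def __repr__(self):
        return f"JointTable(variables={self.variables!r}, arities={self.arities!r})"


@dataclass
class SampleMatrix:
    """Observations × variables integer matrix with declared arities.

    ``data[m, i]`` is the code (``0 … k_i − 1``) of variable ``i`` in
    observation ``m``.  Arities default to ``max(code) + 1`` per column
    (never below 2) when not declared.
    """

    data: np.ndarray
    variables: tuple[str, ...]
    arities: tuple[int, ...] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (observations × variables) array")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one observation")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(int)
            if not np.array_equal(as_int, self.data):
                raise ValueError("sample values must be integers")
            self.data = as_int
        self.variables = tuple(str(v) for v in self.variables)
        if self.data.shape[1] != len(self.variables):
            raise ValueError("number of columns does not match variable names")
        if self.arities is None:
            self.arities = tuple(
                max(2, int(self.data[:, j].max()) + 1) for j in range(self.data.shape[1])
            )
        else:
            self.arities = tuple(int(k) for k in self.arities)
        if np.any(self.data < 0):
            m, j = np.argwhere(self.data < 0)[0]
            raise ValueError(
                f"negative code at row {m}, column {self.variables[j]!r}"
            )
        for j, k in enumerate(self.arities):
            if self.data[:, j].max() >= k:
                m = int(np.argmax(self.data[:, j] >= k))
                raise ValueError(
                    f"code {int(self.data[m, j])} out of range for variable "
                    f"{self.variables[j]!r} (arity {k}) at row {m}"
                )

    @property
    def n_observations(self) -> int:
        return self.data.shape[0]

    @classmethod
    def from_csv(cls, path, *, sep: str | None = None,
                 arities: Sequence[int] | None = None) -> "SampleMatrix":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        if df.empty:
            raise ValueError(f"sample file {path} contains no observations")
        return cls(df.to_numpy(), tuple(df.columns),
                   tuple(arities) if arities is not None else None)

    def to_csv(self, path, *, sep: str = ",") -> None:
        pd.DataFrame(self.data, columns=list(self.variables)).to_csv(
            path, sep=sep, index=False
        )


@dataclass
class IsingCouplings:
    """Subset → real coupling coefficients of a generalized Ising model.

    ``couplings[S] = J_S`` is the energy coefficient of ``Π_{i∈S} s_i`` in
    the Boltzmann exponent; ``constant`` is an (irrelevant after
    normalization) offset.  Keys are frozensets of variable names.
    """

    couplings: dict[frozenset, float] = field(default_factory=dict)
    constant: float = 0.0

    def __post_init__(self):
        clean = {}
        for subset, j in self.couplings.items():
            fs = frozenset(subset)
            if not fs:
                raise ValueError("use `constant` for the empty-set coefficient")
            j = float(j)
            if not math.isfinite(j):
                raise ValueError(f"non-finite coupling for {sorted(fs)!r}")
            clean[fs] = j
        self.couplings = clean

    def variables(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*self.couplings.keys()))) if self.couplings else ()

    def to_json(self, path=None):
        obj = {",".join(sorted(map(str, s))): j for s, j in self.couplings.items()}
        if self.constant:
            obj[""] = self.constant
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "IsingCouplings":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        constant = float(obj.pop("", 0.0))
        return cls(
            {frozenset(k.split(",")): float(v) for k, v in obj.items()},
            constant=constant,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_joint(samples: SampleMatrix, smoothing: float = 0.0) -> JointTable:
    """Plug-in (optionally pseudocount-smoothed) joint estimate from samples.

    ``prob(state) = (count + α) / (M + α·K)`` with ``α = smoothing`` per
    state and ``K`` the number of states; ``α = 0`` is the maximum-
    likelihood estimator.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    counts = np.zeros(samples.arities, dtype=float)
    np.add.at(counts, tuple(samples.data.T), 1.0)
    m = samples.n_observations
    k = counts.size
    probs = (counts + smoothing) / (m + smoothing * k)
    return JointTable(samples.variables, probs)


def boltzmann(couplings: IsingCouplings | Mapping, variables: Sequence[str]) -> JointTable:
    """Exact Boltzmann distribution of a generalized Ising model on binary variables.

    ``p(s) ∝ exp(Σ_S J_S Π_{i∈S} s_i)`` over all ``2^n`` binary strings
    ``s`` (0/1 convention, 1 = "on").  Limited to ``n ≤ 20`` variables so
    the state space stays enumerable.
    """
    if not isinstance(couplings, IsingCouplings):
        couplings = IsingCouplings({frozenset(k): v for k, v in couplings.items()})
    variables = tuple(str(v) for v in variables)
    extra = set().union(*couplings.couplings.keys(), set()) - set(variables)
    if extra:
        raise KeyError(f"couplings refer to unknown variables {sorted(extra)!r}")
    n = len(variables)
    if n > 20:
        raise ValueError("refusing exact enumeration beyond 20 variables")
    axis = {v: i for i, v in enumerate(variables)}
    states = np.array(list(product((0, 1), repeat=n)), dtype=float)
    energy = np.full(len(states), couplings.constant, dtype=float)
    for subset, j in couplings.couplings.items():
        cols = [axis[v] for v in subset]
        energy += j * states[:, cols].prod(axis=1)
    energy -= energy.max()
    w = np.exp(energy)
    probs = (w / w.sum()).reshape((2,) * n)
    return JointTable(variables, probs)


def background_surprisal(
    table: JointTable,
    eta: Iterable[str],
    T: Iterable[str] | None = None,
) -> float:
    """``S_{η;T} = log p(η = 1, T\\η = 0)`` in natural-log units.

    Variables outside ``T`` are marginalized over first.  Requires the
    variables of ``T`` to be binary.  Returns ``−inf`` when the background
    state has zero probability (the caller's finiteness flag picks this up).
    """
    eta = frozenset(eta)
    T = frozenset(table.variables) if T is None else frozenset(T)
    if not eta <= T:
        raise ValueError("eta must be a subset of the background set T")
    if not T <= set(table.variables):
        raise KeyError(f"background set {sorted(T)!r} not within table variables")
    if not table.is_binary(T):
        raise UnsupportedArityError("background surprisal requires binary variables in T")
    marg = table if T == set(table.variables) else table.marginalize(T)
    state = tuple(1 if v in eta else 0 for v in marg.variables)
    p = marg.p(state)
    return math.log(p) if p > 0 else float("-inf")


def marginalize(table: JointTable, keep: Iterable[str]) -> JointTable:
    """Functional alias for :meth:`JointTable.marginalize`."""
    return table.marginalize(keep)


def condition(table: JointTable, assignment: Mapping[str, int]) -> JointTable:
    """Functional alias for :meth:`JointTable.condition`."""
    return table.condition(assignment)
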