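"""Binary data from small causal DAGs, and the association-metric panel.

The generator emulates a simple structural process on a three-node DAG:
orphan (parentless) nodes draw Bernoulli(``root_p``) values; every other
node, visited in topological order, is set to the product (multiplicative
dynamics) or the mean (additive dynamics) of its parents plus zero-mean
Gaussian noise of variance ``sigma2``, then thresholded back to {0, 1}.
For chains and forks the two dynamics coincide (single parents), so the
four preset DAGs × two dynamics give six distinct scenarios.

:func:`association_panel` then summarises one simulated dataset with the
standard association metrics side by side — pairwise Pearson correlations,
pairwise partial correlations (residual correlations after regressing out
the third variable), pairwise and 3-point mutual information, and all MFIs
up to order 3 — each with a sign and a significance label.  Additive
dynamics make the log-odds of the child linear in its parents, so the
3-point MFI vanishes; multiplicative dynamics put the dependence in the
product term and show up as a genuine 3-point interaction.  Conditioning
on a common effect (collider) induces the Berkson negative association
between the parents in both the partial correlation and the pairwise MFI.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .distributions import SampleMatrix, estimate_joint
from .information import conditional_mutual_information, mutual_information
from .interactions import CyclicGraphError, mfi

__all__ = [
    "DAG_PRESETS",
    "DynamicsConfig",
    "make_dag",
    "simulate",
    "association_panel",
    "mfi_sign_pattern",
    "SCENARIOS",
]

#: Edge lists of the preset three-node DAGs.
DAG_PRESETS = {
    "chain": (("A", "B"), ("B", "C")),
    "fork": (("A", "B"), ("A", "C")),
    "collider": (("A", "C"), ("B", "C")),
    "collider_edge": (("A", "B"), ("A", "C"), ("B", "C")),
}

#: The six distinct (DAG, dynamics) scenarios; chains and forks collapse
#: across dynamics because single-parent nodes make product = mean.
SCENARIOS = (
    ("chain", "multiplicative"),
    ("fork", "multiplicative"),
    ("collider", "additive"),
    ("collider", "multiplicative"),
    ("collider_edge", "additive"),
    ("collider_edge", "multiplicative"),
)


@dataclass
class DynamicsConfig:
    """Parameters of the structural simulation.

    mode : "additive" or "multiplicative" parent aggregation.
    root_p : Bernoulli success probability of orphan nodes.
    sigma2 : variance of the Gaussian noise added to child nodes.
    n_samples : number of i.i.d. draws.
    seed : RNG seed (None for nondeterministic).
    """

    mode: str = "multiplicative"
    root_p: float = 0.5
    sigma2: float = 0.1
    n_samples: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown dynamics mode {self.mode!r}")
        if not 0 < self.root_p < 1:
            raise ValueError("root_p must be strictly between 0 and 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def make_dag(preset_or_edges) -> nx.DiGraph:
    """Build a DAG from a preset name or an iterable of directed edges."""
    if isinstance(preset_or_edges, nx.DiGraph):
        g = preset_or_edges
    else:
        if isinstance(preset_or_edges, str):
            try:
                edges = DAG_PRESETS[preset_or_edges]
            except KeyError:
                raise KeyError(
                    f"unknown preset {preset_or_edges!r}; choose from {sorted(DAG_PRESETS)}"
                ) from None
        else:
            edges = list(preset_or_edges)
        g = nx.DiGraph()
        g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise CyclicGraphError("causal graph must be acyclic")
    return g


def simulate(dag, config: DynamicsConfig) -> SampleMatrix:
    """Draw samples from the structural process on ``dag``.

    Orphans are Bernoulli(``root_p``); children are the product or mean of
    their (already binarized) parents plus N(0, σ²), thresholded at 0.5
    (values below 0 clamp to 0, above 1 to 1).  Node update order is
    topological, so each node sees finished parents; reproducible under a
    fixed seed.
    """
    g = make_dag(dag)
    rng = np.random.default_rng(config.seed)
    m = config.n_samples
    values: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if not parents:
            values[node] = rng.binomial(1, config.root_p, size=m)
            continue
        stack = np.stack([values[p] for p in parents], axis=0).astype(float)
        if config.mode == "multiplicative":
            raw = stack.prod(axis=0)
        else:
            raw = stack.mean(axis=0)
        raw = raw + rng.normal(0.0, np.sqrt(config.sigma2), size=m)
        values[node] = (raw >= 0.5).astype(int)  # threshold also clamps
    order = sorted(g.nodes)
    data = np.column_stack([values[v] for v in order])
    return SampleMatrix(data, tuple(order), arities=(2,) * len(order))


# ---------------------------------------------------------------------------
# association panel
# ---------------------------------------------------------------------------

def _bootstrap_ci(counts: np.ndarray, statistic, n_boot: int, rng,
                  alpha: float) -> tuple[float, float]:
    """Percentile bootstrap CI of ``statistic(counts)`` via multinomial resampling."""
    m = int(counts.sum())
    probs = (counts / m).ravel()
    draws = rng.multinomial(m, probs, size=n_boot)
    vals = np.array([statistic(d.reshape(counts.shape)) for d in draws], dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < max(10, n_boot // 10):
        return float("-inf"), float("inf")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _counts_table(counts: np.ndarray, variables) -> "JointTable":
    from .distributions import JointTable

    return JointTable(variables, counts / counts.sum())


def association_panel(samples: SampleMatrix, *, n_boot: int = 500,
                      alpha: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Side-by-side association metrics for three binary variables.

    Returns a DataFrame with one row per (metric, variable set):
    ``metric ∈ {pearson, partial_corr, mi, mfi}``, the value, a
    significance flag, and the resulting sign label ('+', '-', or '0' when
    not significant; 'nan' for undefined).  Pearson and partial-correlation
    significance use their asymptotic tests; MI and MFI significance use a
    seeded multinomial bootstrap (sign stability of the percentile CI).
    """
    if len(samples.variables) != 3:
        raise ValueError("the association panel is defined for 3 variables")
    if samples.n_observations < 100:
        raise ValueError("need at least 100 observations")
    import pingouin as pg

    rng = np.random.default_rng(seed)
    variables = samples.variables
    df = pd.DataFrame(samples.data, columns=list(variables))
    constant = {v: df[v].nunique() < 2 for v in variables}
    counts = np.zeros(samples.arities, dtype=float)
    np.add.at(counts, tuple(samples.data.T), 1.0)
    rows = []

    def add(metric, vars_, value, significant, note=""):
        if value is None or not np.isfinite(value):
            sign = "nan"
        elif not significant:
            sign = "0"
        else:
            sign = "+" if value > 0 else ("-" if value < 0 else "0")
        rows.append({
            "metric": metric,
            "variables": ",".join(vars_),
            "value": np.nan if value is None else float(value),
            "significant": bool(significant),
            "sign": sign,
            "note": note,
        })

    pairs = list(combinations(variables, 2))

    # Pearson correlations
    for a, b in pairs:
        if constant[a] or constant[b]:
            add("pearson", (a, b), None, False, "constant column")
            continue
        r, pval = stats.pearsonr(df[a], df[b])
        add("pearson", (a, b), r, pval < alpha, f"p={pval:.3g}")

    # partial correlations (residual correlations after regressing on the third)
    for a, b in pairs:
        c = next(v for v in variables if v not in (a, b))
        if constant[a] or constant[b] or constant[c]:
            add("partial_corr", (a, b), None, False, "constant column")
            continue
        res = pg.partial_corr(data=df, x=a, y=b, covar=c)
        r = float(res["r"].iloc[0])
        pcol = "p_val" if "p_val" in res.columns else "p-val"
        pval = float(res[pcol].iloc[0])
        add("partial_corr", (a, b), r, pval < alpha, f"p={pval:.3g}")

    # mutual information: pairs and the triple
    def mi_stat(vars_):
        def stat(c):
            return mutual_information(_counts_table(c, variables), vars_)
        return stat

    for a, b in pairs:
        val = mi_stat((a, b))(counts)
        # plug-in MI is non-negative; compare against an independence resample
        null = _independent_mi_quantile(counts, (a, b), variables, n_boot, rng, alpha)
        add("mi", (a, b), val, val > null, f"null_q={null:.4g}")
    val = mi_stat(variables)(counts)
    lo, hi = _bootstrap_ci(counts, mi_stat(variables), n_boot, rng, alpha)
    add("mi", variables, val, not (lo <= 0.0 <= hi), f"ci=({lo:.3g},{hi:.3g})")

    # model-free interactions, order 2 and 3, all-zeros background
    def mfi_stat(vars_):
        def stat(c):
            return mfi(_counts_table(c, variables), vars_).value
        return stat

    for a, b in pairs:
        val = mfi_stat((a, b))(counts)
        lo, hi = _bootstrap_ci(counts, mfi_stat((a, b)), n_boot, rng, alpha)
        add("mfi", (a, b), val, not (lo <= 0.0 <= hi), f"ci=({lo:.3g},{hi:.3g})")
    val = mfi_stat(variables)(counts)
    lo, hi = _bootstrap_ci(counts, mfi_stat(variables), n_boot, rng, alpha)
    add("mfi", variables, val, not (lo <= 0.0 <= hi), f"ci=({lo:.3g},{hi:.3g})")

    return pd.DataFrame(rows)


def _independent_mi_quantile(counts, pair, variables, n_boot, rng, alpha):
    """Upper quantile of plug-in pairwise MI under an independence resample."""
    from .distributions import JointTable

    table = _counts_table(counts, variables).marginalize(pair)
    m = int(counts.sum())
    pa = table.probs.sum(axis=1)
    pb = table.probs.sum(axis=0)
    indep = np.outer(pa, pb)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        c = rng.multinomial(m, indep.ravel()).reshape(indep.shape)
        vals[i] = mutual_information(JointTable(pair, c / m), pair)
    return float(np.quantile(vals, 1 - alpha))


def mfi_sign_pattern(panel: pd.DataFrame) -> tuple[str, ...]:
    """The MFI sign labels of a panel, in lexicographic variable-set order
    (for variables A, B, C: AB, ABC, AC, BC)."""
    sub = panel[panel["metric"] == "mfi"]
    return tuple(sub.sort_values("variables")["sign"])
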