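"""Posterior summaries: direct effects, genus contrasts, and indirect paths.

Effects are summarized by the posterior mean and an equal-tailed 89% credible
interval; an effect is *retained* ("does not greatly overlap zero") when that
interval excludes 0.  Indirect effects along the tier cascade
(climate/geology -> soil -> foliage -> herbivory) are quantified as draw-wise
products of the standardized linear coefficients along the path — computed
per draw, never from summarized means, so the interval of the product
reflects the joint posterior.  Quadratic climate terms are direct-effect-only
and never enter path products.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .draws import PosteriorDraws
from .model import ModelSpec

__all__ = [
    "EffectSummary",
    "PathEffect",
    "summarize",
    "summary_table",
    "genus_contrast",
    "indirect_effect",
    "build_path_graph",
    "coefficient_coverage",
]

ABIOTIC_NODES = ("mat", "map")
QUADRATIC_NODES = ("mat2", "map2")

_SLOPE_RE = re.compile(r"^(?P<resp>[^.]+)\.slope\[(?P<genus>[^\]]+)\]\[(?P<pred>[^\]]+)\]$")


@dataclass(frozen=True)
class EffectSummary:
    """Posterior mean and equal-tailed credible interval for one quantity."""

    parameter: str
    mean: float
    lower: float
    upper: float
    level: float = 0.89
    tier: str | None = None
    genus: str | None = None

    @property
    def excludes_zero(self) -> bool:
        return not (self.lower <= 0.0 <= self.upper)


@dataclass
class PathEffect:
    """A chain of model edges with its draw-wise product effect."""

    nodes: tuple[str, ...]
    edge_parameters: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    summary: EffectSummary = None

    @property
    def label(self) -> str:
        return " -> ".join(self.nodes)


def _hdi(values: np.ndarray, level: float) -> tuple[float, float]:
    """Narrowest interval containing ``level`` of the draws."""
    x = np.sort(values)
    n = len(x)
    k = max(int(np.ceil(level * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def _summarize_values(
    values: np.ndarray, name: str, level: float, interval: str = "equal-tailed"
) -> EffectSummary:
    if interval == "hdi":
        lo, hi = _hdi(values, level)
    elif interval == "equal-tailed":
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    m = _SLOPE_RE.match(name)
    tier = genus = None
    if m:
        genus = m.group("genus") if "-" not in m.group("genus") else None
        tier = m.group("resp")
    elif "." in name:
        tier = name.split(".", 1)[0]
    return EffectSummary(
        parameter=name, mean=float(values.mean()), lower=float(lo),
        upper=float(hi), level=level, tier=tier, genus=genus,
    )


def summarize(
    draws: PosteriorDraws,
    parameter: str,
    level: float = 0.89,
    interval: str = "equal-tailed",
) -> EffectSummary:
    """Posterior mean and credible interval of one parameter.

    The default interval is equal-tailed (quantiles at (1-level)/2 and
    1-(1-level)/2); ``interval='hdi'`` gives the highest-density interval.
    """
    return _summarize_values(draws.stacked(parameter), parameter, level, interval)


def summary_table(draws: PosteriorDraws, parameters=None, level: float = 0.89) -> pd.DataFrame:
    """Effect summaries for many parameters as a tidy table."""
    parameters = list(parameters) if parameters is not None else list(draws.names)
    rows = []
    for p in parameters:
        s = summarize(draws, p, level)
        rows.append(
            {"parameter": p, "tier": s.tier, "genus": s.genus, "mean": s.mean,
             "lower": s.lower, "upper": s.upper, "excludes_zero": s.excludes_zero}
        )
    return pd.DataFrame(rows)


def genus_contrast(
    draws: PosteriorDraws,
    response: str,
    predictor: str,
    genera: tuple[str, str] = ("Alphitonia", "Flindersia"),
    level: float = 0.89,
) -> EffectSummary:
    """Posterior of the slope difference (second genus minus first)."""
    g1, g2 = genera
    d1 = draws.stacked(f"{response}.slope[{g1}][{predictor}]")
    d2 = draws.stacked(f"{response}.slope[{g2}][{predictor}]")
    return _summarize_values(
        d2 - d1, f"{response}.slope[{g2}-{g1}][{predictor}]", level
    )


# ---------------------------------------------------------------------------
# paths through the tier cascade
# ---------------------------------------------------------------------------

def _node_tier(node: str, spec: ModelSpec) -> int:
    base = node.split("[", 1)[0]
    if base in ("mat", "map", "mat2", "map2") or base.startswith("geo_"):
        return 0
    if base.startswith("soil_"):
        return 1
    if base in spec.foliage_responses:
        return 2
    if base == "herbivory":
        return 3
    raise ValueError(f"unknown node {node!r}")


def _parse_node(node: str) -> tuple[str, str | None]:
    m = re.match(r"^([^\[\]]+)(?:\[([^\]]+)\])?$", node)
    if not m:
        raise ValueError(f"malformed node label {node!r}")
    return m.group(1), m.group(2)


def _resolve_edge(src: str, dst: str, spec: ModelSpec) -> str:
    """Coefficient name for the edge src -> dst, validating tier order."""
    s_base, s_genus = _parse_node(src)
    d_base, d_genus = _parse_node(dst)
    st, dt = _node_tier(src, spec), _node_tier(dst, spec)
    if not st < dt:
        raise ValueError(f"edge {src} -> {dst} does not follow the tier ordering")
    if s_genus is not None and d_genus is not None and s_genus != d_genus:
        raise ValueError(f"edge {src} -> {dst} crosses genera")
    if dt == 1:
        if s_base not in spec.soil_predictors:
            raise ValueError(f"{s_base!r} is not a soil-tier predictor")
        return f"{d_base}.{s_base}"
    if dt == 2:
        if d_genus is None:
            raise ValueError(f"foliage node {dst!r} needs a genus, e.g. 'total_n[Flindersia]'")
        if s_base not in spec.foliage_predictors:
            raise ValueError(f"{s_base!r} is not a foliage-tier predictor")
        return f"{d_base}.slope[{d_genus}][{s_base}]"
    if d_genus is None:
        raise ValueError(f"herbivory node {dst!r} needs a genus")
    if s_base not in spec.herbivory_predictors:
        raise ValueError(f"{s_base!r} is not a herbivory-tier predictor")
    return f"herbivory.slope[{d_genus}][{s_base}]"


def indirect_effect(
    draws: PosteriorDraws,
    path,
    spec: ModelSpec | None = None,
    level: float = 0.89,
) -> PathEffect:
    """Draw-wise product of coefficients along a path through the cascade.

    ``path`` is either a sequence of node labels (genus-bearing nodes written
    ``'total_n[Flindersia]'``; requires ``spec`` to resolve coefficients) or,
    when every entry is already a parameter present in ``draws``, a direct
    list of edge coefficients.  Quadratic climate terms are rejected: path
    products are defined over standardized *linear* edges only.
    """
    path = list(path)
    if not path:
        raise ValueError("empty path")
    if all(p in draws for p in path):
        params = path
        nodes = tuple(path)
    else:
        if spec is None:
            spec = ModelSpec()
        if len(path) < 2:
            raise ValueError(f"unknown parameter or single-node path: {path[0]!r}")
        for node in path:
            if node.split("[", 1)[0] in QUADRATIC_NODES:
                raise ValueError(
                    "quadratic climate terms cannot appear in path products"
                )
        params = [_resolve_edge(a, b, spec) for a, b in zip(path[:-1], path[1:])]
        nodes = tuple(path)
    missing = [p for p in params if p not in draws]
    if missing:
        raise KeyError(f"coefficients missing from draws: {missing}")
    values = np.ones_like(draws.stacked(params[0]))
    for p in params:
        values = values * draws.stacked(p)
    label = " * ".join(params)
    return PathEffect(
        nodes=nodes, edge_parameters=tuple(params), values=values,
        summary=_summarize_values(values, label, level),
    )


def build_path_graph(
    draws: PosteriorDraws,
    spec: ModelSpec | None = None,
    level: float = 0.89,
    genera=("Alphitonia", "Flindersia"),
) -> nx.DiGraph:
    """Directed graph of retained effects plus indirect paths to herbivory.

    Nodes are the abiotic drivers (climate terms and geology offsets), soil
    elements, genus-specific foliage responses and genus-specific herbivory.
    An edge is included for every coefficient whose equal-tailed interval at
    ``level`` excludes zero, signed by the posterior-mean sign; quadratic
    climate edges are marked ``order=2`` and excluded from path enumeration.
    All directed paths (up to the full 3-edge cascade) from abiotic nodes to a
    herbivory node along retained linear edges are enumerated and attached as
    :class:`PathEffect` objects in ``graph.graph['paths']``.
    """
    spec = spec or ModelSpec()
    G = nx.DiGraph()

    def maybe_add(src, dst, param, order=1):
        if param not in draws:
            return
        s = summarize(draws, param, level)
        if s.excludes_zero:
            G.add_edge(src, dst, parameter=param, sign=int(np.sign(s.mean)),
                       mean=s.mean, lower=s.lower, upper=s.upper, order=order)

    for e in spec.soil_elements:
        for p in spec.soil_predictors:
            order = 2 if p in QUADRATIC_NODES else 1
            maybe_add(p, f"soil_{e}", f"soil_{e}.{p}", order)
    for r in spec.foliage_responses:
        for g in genera:
            for p in spec.foliage_predictors:
                src = p
                order = 2 if p in QUADRATIC_NODES else 1
                maybe_add(src, f"{r}[{g}]", f"{r}.slope[{g}][{p}]", order)
    for g in genera:
        for p in spec.herbivory_predictors:
            src = f"{p}[{g}]" if p in spec.foliage_responses else p
            order = 2 if p in QUADRATIC_NODES else 1
            maybe_add(src, f"herbivory[{g}]", f"herbivory.slope[{g}][{p}]", order)

    linear = nx.DiGraph(
        (u, v, d) for u, v, d in G.edges(data=True) if d["order"] == 1
    )
    sources = [n for n in linear.nodes
               if n in ABIOTIC_NODES or n.startswith("geo_")]
    targets = [n for n in linear.nodes if n.startswith("herbivory[")]
    paths = []
    for s in sources:
        for t in targets:
            for node_path in nx.all_simple_paths(linear, s, t, cutoff=3):
                params = [
                    linear.edges[a, b]["parameter"]
                    for a, b in zip(node_path[:-1], node_path[1:])
                ]
                pe = indirect_effect(draws, params, spec, level)
                pe.nodes = tuple(node_path)
                paths.append(pe)
    G.graph["paths"] = paths
    G.graph["level"] = level
    return G


def coefficient_coverage(
    draws: PosteriorDraws, truth: dict[str, float], level: float = 0.89
) -> tuple[float, pd.DataFrame]:
    """Fraction of true regression coefficients inside their credible interval.

    Scale parameters (sigmas, site sds, phi) and site effects are excluded:
    coverage is assessed over intercepts, slopes and geology offsets.
    """
    rows = []
    for name, true_val in truth.items():
        if name not in draws:
            continue
        if (".sigma" in name or ".site_sd" in name or ".site[" in name
                or name.endswith(".phi")):
            continue
        s = summarize(draws, name, level)
        rows.append(
            {"parameter": name, "truth": true_val, "mean": s.mean,
             "lower": s.lower, "upper": s.upper,
             "covered": bool(s.lower <= true_val <= s.upper)}
        )
    if not rows:
        raise ValueError("no comparable coefficients between truth and draws")
    table = pd.DataFrame(rows)
    return float(table["covered"].mean()), table
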