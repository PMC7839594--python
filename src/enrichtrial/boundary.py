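"""Decision-boundary mapping by adaptive dyadic subdivision.

Simulating an optimised adaptive enrichment design requires the Bayes
decision at every possible interim outcome x1 = (est1, est2).  Evaluating
the Monte Carlo decision afresh for each simulated trial would be
prohibitively slow, so the optimal decision is precomputed over a region A
of the plane chosen to hold essentially all of the prior-predictive mass of
X1, and looked up during simulation.

Because the enrich region A_E and continue region A_C are geometrically
regular, the plane is not evaluated on a full grid.  A is first split into
four subsquares and the decision evaluated at their vertices; any cell
whose four vertices agree (and are statistically unambiguous) inherits that
decision, while the rest are split into four and the process repeats down
to a minimum cell size.  Vertices are shared between neighbouring cells and
cached, so each is evaluated once.  A vertex is *ambiguous* -- both
decisions look optimal, in the wording of the construction -- when the two
estimated gains differ by less than twice their combined Monte Carlo
standard error; ambiguity forces subdivision just like disagreement.  Leaf
cells still mixed at the minimum size take the majority decision of their
four vertices, ties going to continuation.

Cell bookkeeping uses integer lattice coordinates at the finest dyadic
resolution, so the tiling is exact; a raster of the finest resolution backs
constant-time lookup, with points outside A clamped to the nearest boundary
cell.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import ndtr

from .design import DesignConfig, Stage1Data
from .prior import Prior, posterior_update
from .decision import DecisionEvaluation, decide

__all__ = [
    "DecisionRule",
    "build_boundary",
    "lookup",
    "lookup_bulk",
    "export_rule",
    "import_rule",
    "rasterize",
]

logger = logging.getLogger(__name__)

# Region half-width in prior-predictive SDs per axis.  5.1 keeps the missed
# mass below 1e-6 by a union bound on the two marginal tails.
_REGION_SDS = 5.1
_COVERAGE_TARGET = 1.0 - 1e-6
_AMBIG_SES = 2.0


@dataclass
class DecisionRule:
    """Piecewise-constant enrichment decision over the interim plane.

    ``cells`` tile the region exactly in lattice units: entry (i, j, s, d)
    is the half-open cell [i, i+s) x [j, j+s) at the finest resolution
    ``n`` per axis, with decision d in {1, 2}.  ``raster`` is the n x n
    int8 decision grid backing lookup (first index = est1 axis).
    """

    x0: float
    y0: float
    width: float
    height: float
    n: int
    cells: List[Tuple[int, int, int, int]]
    raster: np.ndarray = field(repr=False)
    vertex_cache: Dict[Tuple[int, int], DecisionEvaluation] = field(
        default_factory=dict, repr=False
    )
    coverage: float = 1.0

    @property
    def min_cell(self) -> Tuple[float, float]:
        """Physical side lengths of the smallest cell (est1, est2 axes)."""
        return self.width / self.n, self.height / self.n

    def vertex_coords(self, i: int, j: int) -> Tuple[float, float]:
        return (
            self.x0 + self.width * i / self.n,
            self.y0 + self.height * j / self.n,
        )


def _predictive_moments(prior: Prior, config: DesignConfig):
    mean = prior.mean
    cov = prior.cov + np.diag([config.var_stage1_s1, config.var_stage1_s2])
    return mean, np.sqrt(np.diag(cov))


def _build_raster(n: int, cells: List[Tuple[int, int, int, int]]) -> np.ndarray:
    raster = np.zeros((n, n), dtype=np.int8)
    for i, j, s, d in cells:
        raster[i : i + s, j : j + s] = d
    if (raster == 0).any():
        raise ValueError("cells do not tile the region")
    return raster


def build_boundary(
    prior: Prior,
    config: DesignConfig,
    m: int = 100_000,
    min_cell: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    z_tie: float = 0.0,
    refine_m: Optional[int] = None,
) -> DecisionRule:
    """Map the Bayes-optimal decision over the interim plane.

    Parameters
    ----------
    m : posterior draws per vertex evaluation.
    min_cell : smallest allowed cell side, in effect units on the est1
        axis; the default is 1/128 of the region width.  The realised cell
        sides are the dyadic fractions of the region no smaller than this.
    refine_m : if given, ambiguous vertices are re-evaluated once with this
        larger number of draws before their decision is recorded.
    z_tie : tie tolerance forwarded to :func:`decide`.
    """
    if rng is None:
        rng = np.random.default_rng()
    base_seed = int(rng.integers(2**31))
    mean, sd = _predictive_moments(prior, config)
    half = _REGION_SDS * sd
    x0, y0 = mean[0] - half[0], mean[1] - half[1]
    width, height = 2 * half[0], 2 * half[1]
    # Union bound on the mass outside the box from the marginal tails.
    miss = 2.0 * float(ndtr(-_REGION_SDS)) * 2.0
    coverage = 1.0 - miss
    if coverage < _COVERAGE_TARGET:
        logger.warning(
            "mapped region covers only %.8f of the prior-predictive mass",
            coverage,
        )
    if min_cell is None:
        kmax = 7  # width / 128
    else:
        if min_cell <= 0:
            raise ValueError("min_cell must be positive")
        kmax = max(1, int(math.floor(math.log2(width / min_cell))))
    n = 2**kmax

    cache: Dict[Tuple[int, int], DecisionEvaluation] = {}

    def vertex(i: int, j: int) -> Tuple[int, bool]:
        ev = cache.get((i, j))
        if ev is None:
            x = Stage1Data(x0 + width * i / n, y0 + height * j / n)
            post = posterior_update(prior, x, config)
            vrng = np.random.default_rng(
                np.random.SeedSequence(base_seed, spawn_key=(i, j))
            )
            ev = decide(x, prior, config, m=m, rng=vrng, z_tie=z_tie, posterior=post)
            if refine_m is not None and _is_ambiguous(ev):
                vrng = np.random.default_rng(
                    np.random.SeedSequence(base_seed, spawn_key=(i, j, 1))
                )
                ev = decide(
                    x, prior, config, m=refine_m, rng=vrng, z_tie=z_tie,
                    posterior=post,
                )
            cache[(i, j)] = ev
        return ev.decision, _is_ambiguous(ev)

    cells: List[Tuple[int, int, int, int]] = []
    s = n // 2
    level = [(0, 0), (s, 0), (0, s), (s, s)]
    while level:
        next_level: List[Tuple[int, int]] = []
        n_ambig = 0
        for i, j in level:
            corners = [vertex(i, j), vertex(i + s, j), vertex(i, j + s),
                       vertex(i + s, j + s)]
            decisions = [d for d, _ in corners]
            ambiguous = any(a for _, a in corners)
            n_ambig += ambiguous
            if len(set(decisions)) == 1 and not ambiguous:
                cells.append((i, j, s, decisions[0]))
            elif s > 1:
                h = s // 2
                next_level.extend(
                    [(i, j), (i + h, j), (i, j + h), (i + h, j + h)]
                )
            else:
                votes = sum(1 for d in decisions if d == 1)
                cells.append((i, j, 1, 1 if votes > 2 else 2))
        logger.info(
            "boundary level s=%d: %d cells examined, %d ambiguous, "
            "%d vertices evaluated so far",
            s, len(level), n_ambig, len(cache),
        )
        level = next_level
        s //= 2
    raster = _build_raster(n, cells)
    return DecisionRule(
        x0=x0, y0=y0, width=width, height=height, n=n, cells=cells,
        raster=raster, vertex_cache=cache, coverage=coverage,
    )


def _is_ambiguous(ev: DecisionEvaluation) -> bool:
    se = math.hypot(ev.se_enrich, ev.se_continue)
    return abs(ev.gain_enrich - ev.gain_continue) <= _AMBIG_SES * se


def lookup(rule: DecisionRule, x1: Stage1Data) -> int:
    """Decision of the cell containing x1 (lower-left-inclusive cells).

    Points outside the mapped region take the decision of the nearest
    boundary cell, found by clamping each coordinate to the region.
    """
    return int(lookup_bulk(rule, np.array([x1.est1]), np.array([x1.est2]))[0])


def lookup_bulk(
    rule: DecisionRule, est1: np.ndarray, est2: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`lookup` over arrays of interim estimates."""
    ix = np.floor(
        (np.asarray(est1, dtype=float) - rule.x0) / rule.width * rule.n
    ).astype(np.int64)
    iy = np.floor(
        (np.asarray(est2, dtype=float) - rule.y0) / rule.height * rule.n
    ).astype(np.int64)
    np.clip(ix, 0, rule.n - 1, out=ix)
    np.clip(iy, 0, rule.n - 1, out=iy)
    return rule.raster[ix, iy]


def rasterize(rule: DecisionRule, nx: int, ny: int) -> np.ndarray:
    """Decisions sampled at the centres of an nx x ny grid over the region."""
    if not rule.cells:
        raise ValueError("empty rule")
    xc = rule.x0 + rule.width * (np.arange(nx) + 0.5) / nx
    yc = rule.y0 + rule.height * (np.arange(ny) + 0.5) / ny
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    return lookup_bulk(rule, X.ravel(), Y.ravel()).reshape(nx, ny)


def export_rule(rule: DecisionRule, path=None) -> str:
    """Serialise the rule to JSON (region, resolution and cell list).

    The cell list plus region bounds reproduce the rule exactly on import;
    the per-vertex Monte Carlo evaluations are working data and are not
    persisted.
    """
    if not rule.cells:
        raise ValueError("empty rule")
    doc = {
        "region": {
            "x0": rule.x0, "y0": rule.y0,
            "width": rule.width, "height": rule.height,
        },
        "n": rule.n,
        "coverage": rule.coverage,
        "cells": [list(c) for c in rule.cells],
    }
    text = json.dumps(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def import_rule(source: str) -> DecisionRule:
    """Rebuild a rule from :func:`export_rule` output (text or file path)."""
    if "\n" not in source and not source.lstrip().startswith("{"):
        with open(source) as fh:
            source = fh.read()
    try:
        doc = json.loads(source)
        region = doc["region"]
        n = int(doc["n"])
        cells = [tuple(int(v) for v in c) for c in doc["cells"]]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed rule file: {exc}") from exc
    raster = _build_raster(n, cells)
    return DecisionRule(
        x0=float(region["x0"]), y0=float(region["y0"]),
        width=float(region["width"]), height=float(region["height"]),
        n=n, cells=cells, raster=raster,
        coverage=float(doc.get("coverage", 1.0)),
    )
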