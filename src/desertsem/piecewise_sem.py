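"""Assembly of local fits into the piecewise SEM.

Because the nine local models differ in dataset length and include random
effects, no global covariance fit is attempted; the SEM is the collection
of local estimates.  Effect sizes are put on a common scale as
*standardized path coefficients*: the change in the predicted response
(natural scale, random effect at zero) as the predictor moves from its
observed minimum to its observed maximum with all other predictors held
at their observed means, divided by the observed range of the response.
For Poisson nodes predictions and responses are effort-standardised rates
so the ratio is unit-free.  Paths with two-sided Wald p < 0.05 are
flagged significant; the rendered network shows only those, with each
node's percentage deviance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm_engine import FittedNode, deviance_explained
from .model_graph import ModelGraph, TERM_SOURCES

__all__ = [
    "PathEstimate",
    "SemResult",
    "standardized_coefficient",
    "assemble",
    "render_network",
    "render_network_from_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PathEstimate:
    source: str
    target: str
    term: str
    raw_coefficient: float
    standardized_coefficient: float
    p_value: float
    significant: bool


@dataclass
class SemResult:
    paths: list[PathEstimate]
    deviance_explained_pct: dict[str, float]
    fits: dict[str, FittedNode] = field(default_factory=dict)

    def path_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": p.source,
                    "target": p.target,
                    "term": p.term,
                    "raw_coefficient": p.raw_coefficient,
                    "standardized_coefficient": p.standardized_coefficient,
                    "p_value": p.p_value,
                    "significant": p.significant,
                }
                for p in self.paths
            ]
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "SemResult":
        paths = [
            PathEstimate(
                source=r.source, target=r.target, term=r.term,
                raw_coefficient=float(r.raw_coefficient),
                standardized_coefficient=float(r.standardized_coefficient),
                p_value=float(r.p_value), significant=bool(r.significant),
            )
            for r in df.itertuples()
        ]
        return cls(paths=paths, deviance_explained_pct={})

    def n_significant(self) -> int:
        return sum(p.significant for p in self.paths)


def _design_row(fit: FittedNode, assignments: dict[str, float]) -> np.ndarray:
    """A design-scale row: assigned terms at given raw values, all other
    columns at their observed means (z-transform applied where the fit
    used one)."""
    row = fit.col_means.copy()
    for term, val in assignments.items():
        j = fit.term_columns[term][0]
        if fit.z_scale and term in fit.z_scale:
            m, s = fit.z_scale[term]
            val = (val - m) / s
        row[j] = val
    return row


def _raw_term_stats(fit: FittedNode, term: str) -> tuple[float, float, float]:
    """(min, mean, max) of a single-column term on its raw scale."""
    j = fit.term_columns[term][0]
    lo, mid, hi = fit.col_mins[j], fit.col_means[j], fit.col_maxs[j]
    if fit.z_scale and term in fit.z_scale:
        m, s = fit.z_scale[term]
        lo, mid, hi = lo * s + m, mid * s + m, hi * s + m
    return float(lo), float(mid), float(hi)


def standardized_coefficient(fit: FittedNode, term: str) -> float:
    """Min-to-max prediction sweep for one predictor term.

    Categorical terms (the dasyurid site effect) are swept across their
    levels instead, returning the spread between the most extreme level
    predictions (always non-negative).  Interaction terms are swept over
    the observed range of the product column, main effects held at their
    means.
    """
    if term not in fit.term_columns:
        raise KeyError(f"{term!r} is not a term of node {fit.name!r}")
    resp_range = float(fit.response_obs.max() - fit.response_obs.min())
    if resp_range == 0:
        raise ValueError(f"node {fit.name!r}: zero observed response range")

    idxs = fit.term_columns[term]
    if fit.spec and term in fit.spec.categorical:
        base = fit.col_means.copy()
        preds = []
        for level_cols in [[]] + [[j] for j in idxs]:  # reference + each level
            row = base.copy()
            for j in idxs:
                row[j] = 0.0
            for j in level_cols:
                row[j] = 1.0
            preds.append(float(fit.predict_response(row)[0]))
        return (max(preds) - min(preds)) / resp_range

    lo, _, hi = _raw_term_stats(fit, term)
    if lo == hi:
        warnings.warn(f"constant predictor {term!r}; standardized coefficient 0",
                      stacklevel=2)
        return 0.0
    row_lo = _design_row(fit, {term: lo})
    row_hi = _design_row(fit, {term: hi})
    pred_lo = float(fit.predict_response(row_lo)[0])
    pred_hi = float(fit.predict_response(row_hi)[0])
    return (pred_hi - pred_lo) / resp_range


def _term_p_value(fit: FittedNode, term: str) -> float:
    idxs = fit.term_columns[term]
    if len(idxs) == 1:
        return float(fit.p_values[idxs[0]])
    # joint Wald test for a multi-column (categorical) term
    b = fit.coefficients[idxs]
    V = fit.cov[np.ix_(idxs, idxs)]
    try:
        w = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        w = float(b @ np.linalg.pinv(V) @ b)
    return float(stats.chi2.sf(w, df=len(idxs)))


def _term_raw_coefficient(fit: FittedNode, term: str) -> float:
    idxs = fit.term_columns[term]
    if len(idxs) == 1:
        return float(fit.coefficients[idxs[0]])
    effects = np.concatenate([[0.0], fit.coefficients[idxs]])  # reference level 0
    return float(effects.max() - effects.min())


def assemble(
    fits: dict[str, FittedNode], graph: ModelGraph, data=None
) -> SemResult:
    """Estimate every path of the graph from the node fits.

    Raises if a node fit is missing; the assembled edge set equals the
    canonical edge set exactly (one estimate per directed effect, the
    phase x dingo interaction counted once).
    """
    missing = [s.name for s in graph.nodes if s.name not in fits]
    if missing:
        raise ValueError(f"missing fits for nodes: {missing}")
    paths = []
    for spec in graph.nodes:
        fit = fits[spec.name]
        for term in spec.predictors:
            raw = _term_raw_coefficient(fit, term)
            std = standardized_coefficient(fit, term)
            p = _term_p_value(fit, term)
            paths.append(
                PathEstimate(
                    source=TERM_SOURCES.get(term, term),
                    target=spec.name,
                    term=term,
                    raw_coefficient=raw,
                    standardized_coefficient=std,
                    p_value=p,
                    significant=bool(p < ALPHA),
                )
            )
    dev = {name: 100.0 * deviance_explained(f) for name, f in fits.items()}
    return SemResult(paths=paths, deviance_explained_pct=dev, fits=dict(fits))


def render_network(result: SemResult) -> str:
    """Textual analogue of the quantified interaction network: significant
    paths with standardized coefficients, per-node deviance explained;
    non-significant paths are suppressed here but kept in the full path
    table."""
    lines = ["Significant paths (p < 0.05):"]
    any_sig = False
    for p in sorted(result.paths, key=lambda q: (q.target, -abs(q.standardized_coefficient))):
        if not p.significant:
            continue
        any_sig = True
        lines.append(
            f"  {p.source:>22s} -> {p.target:<14s} "
            f"std={p.standardized_coefficient:+.3f}  p={p.p_value:.3g}"
        )
    if not any_sig:
        lines.append("  (none)")
    if result.deviance_explained_pct:
        lines.append("Deviance explained:")
        for node, pct in result.deviance_explained_pct.items():
            lines.append(f"  {node:<14s} {pct:5.1f}%")
    return "\n".join(lines)


def render_network_from_table(df: pd.DataFrame) -> str:
    return render_network(SemResult.from_table(df))
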