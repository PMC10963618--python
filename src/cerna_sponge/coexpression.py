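"""Pearson correlation machinery and the anti-correlation edge filter.

The sponge model predicts that a miRNA is negatively co-expressed with both
the lncRNA that sequesters it and the mRNA it represses; edges are retained
when r < -0.85 (strictly more negative, configurable). Correlation is only
evaluated for pairs that already carry targeting evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix
from .targets import TargetPair

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance or too few samples)."""


@dataclass(frozen=True)
class CorrelationEdge:
    """A retained miRNA -> target anti-correlation edge."""

    source_id: str  # miRNA
    target_id: str  # lncRNA or mRNA
    pearson_r: float
    n_samples: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")
        if self.n_samples < 3:
            raise ValueError("correlation needs >= 3 samples")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance vector")
    r = stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def anticorrelated_edges(
    mirna_expr: ExpressionMatrix,
    other_expr: ExpressionMatrix,
    candidate_pairs: Iterable[TargetPair],
    r_cut: float = -0.85,
    samples: Sequence[str] | None = None,
) -> list[CorrelationEdge]:
    """Anti-correlation edges over targeting-supported candidate pairs.

    An edge is retained iff r < ``r_cut`` (strictly). ``samples`` restricts
    the computation (e.g. to the two groups of a contrast); default is the
    shared sample set. Zero-variance pairs are dropped with a logged
    warning.
    """
    if samples is None:
        other = set(other_expr.sample_ids)
        samples = [s for s in mirna_expr.sample_ids if s in other]
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for correlation")
    mi_df = mirna_expr.values[samples]
    ot_df = other_expr.values[samples]
    edges = []
    for pair in candidate_pairs:
        if pair.mirna_id not in mi_df.index or pair.transcript_id not in ot_df.index:
            continue
        x = mi_df.loc[pair.mirna_id].to_numpy(float)
        y = ot_df.loc[pair.transcript_id].to_numpy(float)
        try:
            r = pearson_r(x, y)
        except UndefinedCorrelationError:
            logger.warning(
                "dropping pair (%s, %s): undefined correlation",
                pair.mirna_id,
                pair.transcript_id,
            )
            continue
        if r < r_cut:
            edges.append(
                CorrelationEdge(
                    source_id=pair.mirna_id,
                    target_id=pair.transcript_id,
                    pearson_r=r,
                    n_samples=len(samples),
                )
            )
    return edges


def sample_correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Samples x samples Pearson correlation (repeatability check)."""
    mat = expr.values.to_numpy(float)
    r = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(r, index=expr.sample_ids, columns=expr.sample_ids)
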