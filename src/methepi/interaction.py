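"""Multiplicative-model genetic-interaction scoring of phenotype measurements.

Fitness W of a genotype is its phenotype metric (thymopoietic index =
rag1 signal area / gh signal area, or eye size) normalized to the
wild-type mean, so wild type has W = 1 by construction.  Under the
multiplicative null the expected double-mutant fitness is
E(W_xy) = W_x * W_y; the interaction score is the log2 fold change
I = log2(W_xy / E), positive for alleviating interactions (phenotype
less severe than expected) and negative for synthetic ones.  The error
propagated onto E from the single-mutant estimates is the first-order
expression for a product, E * sqrt((d_x/W_x)^2 + (d_y/W_y)^2).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("thymopoietic_index", "eye_size")


@dataclasses.dataclass(frozen=True)
class FitnessEstimate:
    """Normalized fitness of one genotype: mean W, dispersion delta, n fish."""

    genotype: str
    W: float
    delta: float
    n: int
    metric: str


@dataclasses.dataclass(frozen=True)
class InteractionResult:
    """Observed vs expected double-mutant fitness and its classification."""

    W_x: float
    W_y: float
    W_xy_observed: float
    E_expected: float
    epsilon_prop: float
    I: float
    p_value: float
    classification: str
    degenerate: bool = False


def thymopoietic_index(rag1_area: float, gh_area: float) -> float:
    """rag1 signal area over gh (internal control) signal area."""
    if gh_area <= 0:
        raise ValueError("gh_area must be positive (internal-control failure)")
    if rag1_area < 0:
        raise ValueError("rag1_area must be non-negative")
    return rag1_area / gh_area


def per_fish_metric(table: pd.DataFrame, metric: str) -> pd.Series:
    """Per-fish metric values; fish with failed gh control are dropped.

    For the thymopoietic index, fish with ``gh_area <= 0`` are excluded
    with a warning rather than imputed.
    """
    if metric == "thymopoietic_index":
        ok = table["gh_area"] > 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} fish with non-positive gh_area "
                "(control-channel failure)",
                stacklevel=2,
            )
        t = table.loc[ok]
        return t["rag1_area"] / t["gh_area"]
    if metric == "eye_size":
        return table["eye_size"].copy()
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def normalized_values(
    table: pd.DataFrame,
    genotype: str,
    wildtype: str = "wt",
    metric: str = "thymopoietic_index",
) -> np.ndarray:
    """Per-fish metric values of ``genotype`` divided by the wild-type mean."""
    wt_values = per_fish_metric(table.loc[table["genotype"] == wildtype], metric)
    if len(wt_values) < 2:
        raise ValueError("need at least two wild-type fish")
    wt_mean = float(wt_values.mean())
    if wt_mean <= 0:
        raise ValueError("wild-type mean metric is not positive")
    values = per_fish_metric(table.loc[table["genotype"] == genotype], metric)
    if len(values) < 2:
        raise ValueError(f"need at least two fish for genotype {genotype!r}")
    return values.to_numpy() / wt_mean


def estimate_fitness(
    table: pd.DataFrame,
    genotype: str,
    wildtype: str = "wt",
    metric: str = "thymopoietic_index",
) -> FitnessEstimate:
    """Mean and dispersion of the wild-type-normalized metric for a genotype.

    W is the arithmetic mean of the normalized per-fish values and delta
    their sample standard deviation (ddof 1).  The wild type's own W is
    exactly 1.
    """
    values = normalized_values(table, genotype, wildtype, metric)
    w = float(values.mean())
    if genotype == wildtype:
        w = 1.0
    return FitnessEstimate(
        genotype=genotype,
        W=w,
        delta=float(values.std(ddof=1)),
        n=len(values),
        metric=metric,
    )


def expected_fitness(w_x: float, w_y: float) -> float:
    """Multiplicative-model expectation E(W_xy) = W_x * W_y."""
    if w_x <= 0 or w_y <= 0:
        raise ValueError("fitness values must be positive")
    return w_x * w_y


def propagate_error(
    w_x: float,
    delta_x: float,
    w_y: float,
    delta_y: float,
    mode: str = "standard",
) -> float:
    """Propagated error of the expected fitness E = W_x * W_y.

    ``standard`` (default) is the first-order propagation for a product,
    E * sqrt((delta_x/W_x)^2 + (delta_y/W_y)^2).  ``as_printed``
    evaluates the literal expression
    [(delta_x/W_x)^2 + (delta_y/W_y)^2]^(-2), retained for auditability
    only: an inverse square of a small relative variance yields absurd
    magnitudes, which is why it is not the default.
    """
    if w_x <= 0 or w_y <= 0:
        raise ValueError("fitness values must be positive")
    if delta_x < 0 or delta_y < 0:
        raise ValueError("dispersions must be non-negative")
    rel2 = (delta_x / w_x) ** 2 + (delta_y / w_y) ** 2
    if mode == "standard":
        return w_x * w_y * math.sqrt(rel2)
    if mode == "as_printed":
        if rel2 == 0:
            raise ValueError("as_printed mode undefined when both dispersions are zero")
        return rel2**-2
    raise ValueError(f"unknown mode {mode!r}; expected 'standard' or 'as_printed'")


def interaction_score(w_xy_observed: float, e_expected: float) -> float:
    """log2 fold change of observed over expected double-mutant fitness."""
    if w_xy_observed <= 0 or e_expected <= 0:
        raise ValueError("fitness values must be positive")
    return math.log2(w_xy_observed / e_expected)


def classify_interaction(
    values_xy: np.ndarray,
    e_expected: float,
    epsilon_prop: float,
    alpha: float = 0.05,
    w_x: float = float("nan"),
    w_y: float = float("nan"),
) -> InteractionResult:
    """Classify the interaction as alleviating, synthetic or non-interacting.

    ``values_xy`` are the double mutant's wild-type-normalized per-fish
    values.  A z statistic compares observed and expected fitness, with
    the double mutant's standard error of the mean and the propagated
    error of the expectation combined in quadrature; the two-sided p
    comes from the normal reference.  p <= alpha with positive score is
    alleviating, with negative score synthetic, anything else
    non-interacting.  If both variance components are zero the p-value
    degenerates to an exact-equality rule and the result is flagged.
    """
    values_xy = np.asarray(values_xy, dtype=float)
    if values_xy.size < 2:
        raise ValueError("need at least two double-mutant fish")
    if epsilon_prop < 0:
        raise ValueError("epsilon_prop must be non-negative")
    w_xy = float(values_xy.mean())
    delta_xy = float(values_xy.std(ddof=1))
    n = values_xy.size
    score = interaction_score(w_xy, e_expected)
    se = math.sqrt(delta_xy**2 / n + epsilon_prop**2)
    degenerate = se == 0
    if degenerate:
        p = 0.0 if w_xy != e_expected else 1.0
        warnings.warn(
            "degenerate variance: identical values and zero propagated error",
            stacklevel=2,
        )
    else:
        z = (w_xy - e_expected) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    if p <= alpha and score > 0:
        label = "alleviating"
    elif p <= alpha and score < 0:
        label = "synthetic"
    else:
        label = "non_interacting"
    return InteractionResult(
        W_x=w_x,
        W_y=w_y,
        W_xy_observed=w_xy,
        E_expected=e_expected,
        epsilon_prop=epsilon_prop,
        I=score,
        p_value=p,
        classification=label,
        degenerate=degenerate,
    )


def analyze_pair(
    table: pd.DataFrame,
    x: str = "x",
    y: str = "y",
    xy: str = "xy",
    wildtype: str = "wt",
    metric: str = "thymopoietic_index",
    alpha: float = 0.05,
    error_mode: str = "standard",
) -> tuple[InteractionResult, list[FitnessEstimate]]:
    """End-to-end interaction analysis for one mutant pair and one metric."""
    estimates = [
        estimate_fitness(table, g, wildtype, metric) for g in (wildtype, x, y, xy)
    ]
    _, fx, fy, fxy = estimates
    e = expected_fitness(fx.W, fy.W)
    eps = propagate_error(fx.W, fx.delta, fy.W, fy.delta, mode=error_mode)
    values_xy = normalized_values(table, xy, wildtype, metric)
    result = classify_interaction(
        values_xy, e, eps, alpha=alpha, w_x=fx.W, w_y=fy.W
    )
    return result, estimates
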