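"""Negative-binomial background model, significance filter and sigmoid scaling.

Per mark, the genome-wide coverage vector is modelled as a Poisson-Gamma
mixture: the local Poisson rate is Gamma-distributed with shape beta and scale
alpha, which marginally gives a negative binomial with

    P(N = n) = C(n + beta - 1, n) * (alpha/(alpha+1))**n * (1/(alpha+1))**beta

and mean alpha * beta. beta is the gamma-shape maximum-likelihood estimate on
the strictly positive coverage values (the gamma support excludes zero); the
mixture mean is anchored to the mean coverage over *all* bins by setting
alpha = mu / beta. A bin is significant for a mark when the upper-tail
probability of its coverage under this null is at most the chosen threshold
(1% by default); a bin enters the analysis matrix when at least one mark is
significant there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coverage import ConfigurationError, CoverageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkBackgroundModel",
    "PValueMatrix",
    "TransformParams",
    "fit_mark_background",
    "nb_tail_pvalue",
    "filter_significant_bins",
    "compute_transform_params",
    "sigmoid_transform",
]


class ModelUnfitError(ValueError):
    """Raised when a background model cannot be fitted to a coverage vector."""


@dataclass
class MarkBackgroundModel:
    """Fitted Poisson-Gamma null for one mark.

    ``mu`` is the mean coverage over all bins, ``beta`` the gamma shape and
    ``alpha`` the gamma scale; the implied NB mean ``alpha * beta`` equals
    ``mu`` by construction.
    """

    mark: str
    mu: float
    beta: float
    alpha: float
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.beta > 0 and self.alpha > 0):
            raise ModelUnfitError(
                f"invalid background parameters for {self.mark!r}: "
                f"mu={self.mu}, beta={self.beta}, alpha={self.alpha}"
            )
        if abs(self.alpha * self.beta - self.mu) > 1e-6 * max(self.mu, 1.0):
            raise ModelUnfitError(
                f"NB mean {self.alpha * self.beta} inconsistent with mu={self.mu}"
            )

    @property
    def p_success(self) -> float:
        """scipy's NB success probability: 1/(1 + alpha)."""
        return 1.0 / (1.0 + self.alpha)


@dataclass
class PValueMatrix:
    """Upper-tail probabilities Q(j,k), aligned with a coverage matrix."""

    values: np.ndarray
    marks: list[str]
    bin_chroms: np.ndarray
    bin_starts: np.ndarray
    bin_ends: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        self.values = v


@dataclass
class TransformParams:
    """Per-mark scale for the sigmoid transform.

    ``y`` is the chosen percentile (default 95th) of each mark's coverage
    distribution, zeros included, with linear interpolation.
    """

    y: dict[str, float]
    percentile: float = 95.0


def fit_mark_background(
    z: np.ndarray,
    mark: str = "",
    min_bins: int = 100,
    min_positive: int = 10,
) -> MarkBackgroundModel:
    """Fit the per-mark negative-binomial null to a coverage vector.

    The gamma shape is the MLE on strictly positive values; if the MLE is
    degenerate or fails to converge the method-of-moments shape mean^2/var is
    used instead (with a warning). ``mu`` is the mean over the full vector.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < min_bins:
        raise ModelUnfitError(f"need >= {min_bins} bins, got {len(z)}")
    pos = z[z > 0]
    if len(pos) < min_positive or z.sum() == 0:
        raise ModelUnfitError(f"mark {mark!r}: too few positive coverage values")

    mu = float(z.mean())
    beta = None
    method = "gamma-mle"
    var = float(pos.var())
    if var > 0:
        try:
            with np.errstate(all="ignore"):
                shape, _, scale = stats.gamma.fit(pos, floc=0)
            if np.isfinite(shape) and shape > 0:
                beta = float(shape)
        except Exception:  # scipy raises a mix of FitError/RuntimeError
            beta = None
    if beta is None:
        method = "moments"
        if var <= 0:
            # constant positive coverage: no overdispersion measurable; use a
            # large shape so the NB is close to Poisson
            beta = 1e6
            logger.warning(
                "mark %r: zero-variance coverage, falling back to near-Poisson shape",
                mark,
            )
        else:
            beta = float(pos.mean() ** 2 / var)
            logger.warning("mark %r: gamma MLE failed, using method of moments", mark)

    alpha = mu / beta
    loglik = float(np.sum(stats.gamma.logpdf(pos, beta, scale=pos.mean() / beta)))
    return MarkBackgroundModel(
        mark=mark,
        mu=mu,
        beta=beta,
        alpha=alpha,
        fit_info={"method": method, "n_bins": len(z), "n_positive": len(pos), "loglik": loglik},
    )


def nb_tail_pvalue(model: MarkBackgroundModel, x) -> np.ndarray | float:
    """P(N >= x) under the fitted null, inclusive of the observed value.

    Continuous coverage is ceiled to the next integer before evaluating the
    discrete tail; x = 0 gives exactly 1.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("coverage values must be non-negative")
    n = np.ceil(arr).astype(np.int64)
    p = stats.nbinom.sf(n - 1, model.beta, model.p_success)
    if np.isscalar(x) or arr.ndim == 0:
        return float(p)
    return p


def filter_significant_bins(
    V: CoverageMatrix,
    models: dict[str, MarkBackgroundModel] | None = None,
    tail: float = 0.01,
) -> tuple[CoverageMatrix, PValueMatrix]:
    """Keep bins where at least one mark beats the tail threshold.

    Returns the filtered matrix (stage ``filtered``) together with the full
    p-value matrix Q(j,k) over all input bins. Models are fitted from V's own
    columns when not supplied.
    """
    if not (0 < tail < 1):
        raise ConfigurationError(f"tail probability must be in (0, 1), got {tail}")
    if models is None:
        models = {m: fit_mark_background(V.values[:, k], mark=m) for k, m in enumerate(V.marks)}
    missing = [m for m in V.marks if m not in models]
    if missing:
        raise ConfigurationError(f"no background model for marks: {missing}")

    Q = np.empty_like(V.values)
    for k, mark in enumerate(V.marks):
        Q[:, k] = nb_tail_pvalue(models[mark], V.values[:, k])
    keep = (Q <= tail).any(axis=1)
    pvals = PValueMatrix(
        values=Q,
        marks=list(V.marks),
        bin_chroms=V.bin_chroms,
        bin_starts=V.bin_starts,
        bin_ends=V.bin_ends,
    )
    return V.select_rows(keep, stage="filtered"), pvals


def compute_transform_params(V: CoverageMatrix, percentile: float = 95.0) -> TransformParams:
    """Per-mark percentile scale for the sigmoid, zeros included."""
    if not (0 < percentile <= 100):
        raise ConfigurationError(f"percentile must be in (0, 100], got {percentile}")
    y = {
        mark: float(np.percentile(V.values[:, k], percentile))
        for k, mark in enumerate(V.marks)
    }
    return TransformParams(y=y, percentile=percentile)


def sigmoid_transform(
    V: CoverageMatrix,
    params: TransformParams | None = None,
    percentile: float = 95.0,
) -> CoverageMatrix:
    """Compress each mark into [0, 1) with X' = 2/(1 + exp(-2x/y)) - 1.

    y is the mark's 95th percentile, so the transform is close to linear
    (X' ~ x/y) below it and saturates above; X'(y) = tanh(1). A mark whose
    percentile is zero is passed through unchanged (its values are zeros).
    """
    if (V.values < 0).any():
        raise ValueError("sigmoid transform requires non-negative input")
    if params is None:
        params = compute_transform_params(V, percentile=percentile)
    out = np.zeros_like(V.values)
    for k, mark in enumerate(V.marks):
        y = params.y[mark]
        if y <= 0:
            logger.warning("mark %r: zero scale percentile, passing zeros through", mark)
            out[:, k] = V.values[:, k]
            continue
        out[:, k] = 2.0 / (1.0 + np.exp(-2.0 * V.values[:, k] / y)) - 1.0
    return CoverageMatrix(
        values=out,
        marks=list(V.marks),
        bin_chroms=V.bin_chroms,
        bin_starts=V.bin_starts,
        bin_ends=V.bin_ends,
        stage="transformed",
        unmappable=V.unmappable,
    )
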