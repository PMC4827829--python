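"""Row-deletion outlier diagnostics for the Downs-Mardia regression.

The residual summary is the mean circular error

    MCEs = (1/n) * sum_j sin(d_j / 2),

where ``d_j`` is the circular distance between observed and fitted
response; it lives in [0, 1], with 0 a perfect fit and 1 the worst possible
(every residual antipodal).  Deleting observation j and recomputing the
summary on the remaining n-1 points gives MCEs_(-j); the detection
statistic is the largest absolute change

    DMCEs = max_j | MCEs - MCEs_(-j) |.

An observation is flagged as an outlier (an influential observation, since
this is a row-deletion diagnostic) when DMCEs strictly exceeds a cut-off
point obtained by clean-data simulation.

Two conventions are supported for the half-angle sine:

* ``signed=False`` (the definition above): s_j = sin(d_j/2) with the
  unsigned circular distance d_j in [0, pi].
* ``signed=True``: s_j = sin(z_j/2) with the signed wrapped residual
  z_j in (-pi, pi], so s_j keeps the residual's direction.  This is the
  convention under which the published simulated cut-off tables are
  reproducible (see docs/methods.md); the simulation engine uses it by
  default.

By default each deletion triggers a refit of the model on the reduced data
(``refit=True``), warm-started at the full-data estimates; ``refit=False``
keeps the full-data parameters fixed and merely recomputes the summary,
which is cheaper and has the closed form
``|MCEs - MCEs_(-j)| = |s_j - mean(s)| / (n - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import wrap_signed
from .exceptions import (
    DmregError,
    InvalidInputError,
    InvalidParameterError,
    LeaveOneOutFitError,
)
from .model import AnglePairs, DMFit, fit as fit_model

__all__ = ["OutlierReport", "mces", "dmces", "detect"]


@dataclass(frozen=True)
class OutlierReport:
    """Per-observation row-deletion diagnostics.

    Observation numbering is 1-based throughout (``argmax_index``,
    ``flagged``), matching how observations are labelled in reports.
    ``mces_full`` lies in [0, 1] under the unsigned convention and in
    [-1, 1] under the signed one.  ``cutoff`` is None until a detection
    threshold has been applied.
    """

    mces_full: float
    mces_loo: np.ndarray = field(repr=False)
    dmces_per_obs: np.ndarray = field(repr=False)
    dmces: float
    argmax_index: int
    fit: DMFit = field(repr=False)
    refit: bool
    signed: bool = False
    cutoff: float | None = None
    flagged: tuple = ()

    def with_cutoff(self, cutoff: float) -> "OutlierReport":
        """Apply a detection threshold: flag the argmax iff DMCEs > cutoff."""
        if not np.isfinite(cutoff) or cutoff < 0:
            raise InvalidParameterError(f"cutoff must be non-negative, got {cutoff}")
        flagged = (self.argmax_index,) if self.dmces > cutoff else ()
        return OutlierReport(
            mces_full=self.mces_full,
            mces_loo=self.mces_loo,
            dmces_per_obs=self.dmces_per_obs,
            dmces=self.dmces,
            argmax_index=self.argmax_index,
            fit=self.fit,
            refit=self.refit,
            signed=self.signed,
            cutoff=float(cutoff),
            flagged=flagged,
        )


def mces(residuals) -> float:
    """Mean circular error ``(1/n) * sum sin(d_j / 2)`` of circular residuals.

    Each residual must lie in [0, pi]; the result lies in [0, 1].
    """
    d = np.atleast_1d(np.asarray(residuals, dtype=float))
    if d.size == 0:
        raise InvalidInputError("need at least one residual")
    if not np.all(np.isfinite(d)) or np.any(d < -1e-12) or np.any(d > np.pi + 1e-12):
        raise InvalidInputError("residuals must lie in [0, pi]")
    return float(np.mean(np.sin(0.5 * np.clip(d, 0.0, np.pi))))


def _half_sines(data: AnglePairs, fit: DMFit, signed: bool) -> np.ndarray:
    """Per-observation half-angle sines s_j under either convention."""
    z = wrap_signed(data.v - fit.fitted)
    if signed:
        return np.sin(0.5 * z)
    return np.sin(0.5 * np.abs(z))


def dmces(
    data: AnglePairs,
    refit: bool = True,
    signed: bool = False,
    seed=None,
    full_fit: DMFit | None = None,
) -> OutlierReport:
    """Row-deletion statistic DMCEs and its per-observation components.

    Fits the full data, then for each observation j computes the residual
    summary with j deleted — refitting the model on the n-1 remaining
    pairs when ``refit`` is true (warm-started at the full-data estimates),
    or reusing the full-data parameters when false — and records
    ``|MCEs - MCEs_(-j)|``.  Ties at the maximum are broken by the smallest
    observation number.  ``full_fit`` may supply an existing full-data fit
    to avoid recomputation.

    Requires n >= 5 so each leave-one-out fit keeps n-1 >= 4 observations.
    """
    n = len(data)
    if n < 5:
        raise InvalidInputError(
            f"need at least 5 observations for leave-one-out diagnostics, got {n}"
        )
    full = full_fit if full_fit is not None else fit_model(data, seed=seed)
    s = _half_sines(data, full, signed)
    mces_full = float(np.mean(s))
    if refit:
        loo = np.empty(n)
        for j in range(n):
            reduced = data.drop(j)
            try:
                sub = fit_model(reduced, init=full.params, seed=seed)
            except DmregError as exc:
                raise LeaveOneOutFitError(j + 1, exc) from exc
            loo[j] = float(np.mean(_half_sines(reduced, sub, signed)))
    else:
        loo = (np.sum(s) - s) / (n - 1)
    diffs = np.abs(mces_full - loo)
    argmax = int(np.argmax(diffs))  # first index wins ties
    return OutlierReport(
        mces_full=mces_full,
        mces_loo=loo,
        dmces_per_obs=diffs,
        dmces=float(diffs[argmax]),
        argmax_index=argmax + 1,
        fit=full,
        refit=refit,
        signed=signed,
    )


def detect(
    data: AnglePairs,
    cutoff: float,
    refit: bool = True,
    signed: bool = False,
    seed=None,
    full_fit: DMFit | None = None,
) -> OutlierReport:
    """Single-pass outlier detection at a pre-specified cut-off point.

    Runs :func:`dmces` and flags the observation attaining the maximum iff
    DMCEs strictly exceeds ``cutoff``.  At most one observation is flagged
    per pass.  The cut-off must come from a simulation run under the same
    ``refit``/``signed`` convention.
    """
    if not np.isfinite(cutoff) or cutoff < 0:
        raise InvalidParameterError(f"cutoff must be non-negative, got {cutoff}")
    report = dmces(data, refit=refit, signed=signed, seed=seed, full_fit=full_fit)
    return report.with_cutoff(cutoff)
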