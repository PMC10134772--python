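"""Profile-sampling confidence intervals for fitted rate-matrix elements.

Around the best-fit matrix M, a large number of trial matrices M* are
drawn by scaling every element independently and multiplicatively:

    M*_ij = M_ij * b^{a_ij},   a_ij ~ U(-1, 1)

(b = 2 by default; structurally-zero elements are untouched, since zero
scales to zero).  For each sample the cost excess d = chi2(M*) - chi2(M)
is recorded.  For a chosen element (k, l) the a_kl values are binned over
[-1, 1]; the smallest d in each bin traces an approximate profile of the
cost along that element with the others roughly re-optimized by the
sampling.  Scanning outward from a_kl = 0, the first bin whose minimum d
reaches the threshold (2.71 by default) marks the upper (or lower)
confidence bound; a direction that never crosses is reported open-ended.

The scheme suffers the curse of dimensionality: the more elements are
perturbed jointly, the more samples are needed for per-bin minima to
approach the true profile.  A warning is emitted when the sample budget
looks thin for the number of free slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, _CostEvaluator
from .kinetics import ValidationError
from .moments import MomentSummary

__all__ = ["CISettings", "IntervalEstimate", "estimate_intervals"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CISettings:
    """Sampling settings: base b, sample count, binning, threshold, seed."""

    base: float = 2.0
    n_samples: int = 100_000
    n_bins: int = 40
    d_threshold: float = 2.71
    seed: int = 0

    def __post_init__(self):
        if self.base <= 1.0:
            raise ValidationError(f"base must be > 1, got {self.base}")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_bins < 2 or self.n_bins % 2:
            # even bin count keeps the two central bins symmetric about 0
            raise ValidationError(f"n_bins must be even and >= 2, got {self.n_bins}")
        if self.d_threshold < 0:
            raise ValidationError("d_threshold must be >= 0")


@dataclass(frozen=True)
class IntervalEstimate:
    """Confidence bounds on one rate-matrix element.

    Multipliers live in [1/b, b] in the identified case; an open flag
    means the threshold was never crossed in that direction and the bound
    is the edge of the sampled range.
    """

    slot: tuple[str, str]
    point: float
    lower_multiplier: float
    upper_multiplier: float
    lower: float
    upper: float
    open_lower: bool = False
    open_upper: bool = False
    degenerate: bool = False  # zero point estimate: multiplicative CI collapses

    @property
    def non_identifiable(self) -> bool:
        return self.open_lower and self.open_upper


def _free_elements(fit_result: FitResult) -> list[tuple[int, int]]:
    """Matrix positions whose element is free under the architecture."""
    arch = fit_result.architecture
    out = [(i, j) for i, j in zip(*np.nonzero(arch.allowed))]
    out += [(i, i) for i in np.nonzero(arch.self_allowed)[0]]
    # the diagonal also moves with off-diagonal outflow even without a
    # self-rate; intervals are reported only for architecture-free slots
    return out


def estimate_intervals(
    fit_result: FitResult,
    m1: MomentSummary,
    m2: MomentSummary,
    settings: CISettings | None = None,
    conservation_scale: float | None = None,
    epsilon_rel: float = 1e-12,
    pair_mode: str = "all",
) -> list[IntervalEstimate]:
    """Confidence intervals for every architecture-free element of M."""
    if settings is None:
        settings = CISettings()
    ev = _CostEvaluator(m1, m2, conservation_scale, epsilon_rel, pair_mode)
    M = fit_result.M.M
    p = fit_result.M.p
    names = fit_result.M.panel.names
    chi2_best = ev.total(M)
    if not np.isfinite(chi2_best):
        raise ValidationError("best-fit cost is not finite")
    slots = _free_elements(fit_result)
    if settings.n_samples < 1000 * max(1, len(slots)):
        logger.warning(
            "only %d samples for %d jointly perturbed slots; per-bin profile "
            "minima may be far above the true profile (curse of dimensionality)",
            settings.n_samples, len(slots),
        )

    rng = np.random.default_rng(settings.seed)
    n = settings.n_samples
    b = settings.base
    A = rng.uniform(-1.0, 1.0, size=(n, p, p))
    d = np.empty(n)
    scale = np.power(b, A)
    for s in range(n):
        d[s] = ev.total(M * scale[s]) - chi2_best

    edges = np.linspace(-1.0, 1.0, settings.n_bins + 1)
    half = settings.n_bins // 2
    out: list[IntervalEstimate] = []
    for (i, j) in slots:
        point = float(M[i, j])
        slot_name = (names[j], names[i]) if i != j else (names[i], names[i])
        if point == 0.0:
            out.append(
                IntervalEstimate(
                    slot=slot_name, point=0.0,
                    lower_multiplier=1.0 / b, upper_multiplier=b,
                    lower=0.0, upper=0.0,
                    open_lower=True, open_upper=True, degenerate=True,
                )
            )
            continue
        a = A[:, i, j]
        bins = np.clip(np.digitize(a, edges) - 1, 0, settings.n_bins - 1)
        min_d = np.full(settings.n_bins, np.inf)
        np.minimum.at(min_d, bins, d)
        if np.any(np.isinf(min_d)):
            empty = int(np.isinf(min_d).sum())
            raise ValidationError(
                f"{empty} bin(s) received no samples for slot {slot_name}; "
                "increase n_samples or decrease n_bins"
            )
        # scan outward from the two central bins
        a_upper, open_upper = 1.0, True
        for k in range(half, settings.n_bins):
            if min_d[k] >= settings.d_threshold:
                a_upper = 0.5 * (edges[k] + edges[k + 1])
                open_upper = False
                break
        a_lower, open_lower = -1.0, True
        for k in range(half - 1, -1, -1):
            if min_d[k] >= settings.d_threshold:
                a_lower = 0.5 * (edges[k] + edges[k + 1])
                open_lower = False
                break
        lo_mult, up_mult = b ** a_lower, b ** a_upper
        v_lo, v_up = point * lo_mult, point * up_mult
        out.append(
            IntervalEstimate(
                slot=slot_name, point=point,
                lower_multiplier=lo_mult, upper_multiplier=up_mult,
                lower=min(v_lo, v_up), upper=max(v_lo, v_up),
                open_lower=open_lower, open_upper=open_upper,
            )
        )
    return out
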