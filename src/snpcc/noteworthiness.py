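"""False-positive report probability (FPRP) and Bayesian false discovery
probability (BFDP) screens for single-SNP association findings.

FPRP is the posterior probability that a "significant" association is a false
positive, given the observed two-sided p-value (alpha), the power of the test
to detect a stated target odds ratio at that significance level, and a prior
probability pi of true association:

    FPRP = alpha (1 - pi) / (alpha (1 - pi) + power * pi)

BFDP is the posterior probability of the null from an approximate Bayes
factor (ABF) comparing a point null on the log odds ratio against a normal
alternative with prior variance W chosen so that the target odds ratio is the
97.5th percentile of the prior:

    V   = SE(log OR)^2,   W = (ln OR_target / z_0.975)^2,   z = log OR / SE
    ABF = sqrt((V + W) / V) * exp(-z^2 W / (2 (V + W)))      (null / alternative)
    BFDP = ABF * PO / (1 + ABF * PO),   PO = (1 - pi) / pi   (prior odds of null)

Both screens depend on the estimate only through |z| and SE, so they are
invariant to the orientation of the 2x2 table. The ABF is reported alongside
BFDP so the convention is auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .association import AssociationResult
from .models import ModelKind

__all__ = [
    "NoteworthinessConfig",
    "NoteworthinessResult",
    "power_at_threshold",
    "fprp",
    "bfdp",
    "evaluate",
]

logger = logging.getLogger(__name__)

_DEFAULT_FPRP_PRIORS = (0.25, 0.1, 0.01, 0.001, 0.0001)
_DEFAULT_BFDP_PRIORS = (0.01, 0.001, 0.00001)


@dataclass(frozen=True)
class NoteworthinessConfig:
    """Target effect size, prior grids and noteworthiness cutoffs.

    The defaults are the conventional screen for candidate-gene studies: a
    target OR of 1.5, FPRP priors from 0.25 down to 1e-4 with findings below
    0.2 noteworthy, and BFDP priors 0.01/0.001/1e-5 with findings below 0.8
    noteworthy. :meth:`published_screen` relaxes the FPRP cutoff to the 0.5
    value many reports use for their bolded entries.
    """

    or_threshold: float = 1.5
    priors: Sequence[float] = _DEFAULT_FPRP_PRIORS
    bfdp_priors: Sequence[float] = _DEFAULT_BFDP_PRIORS
    fprp_noteworthy_cutoff: float = 0.2
    bfdp_noteworthy_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if self.or_threshold <= 1:
            raise ValueError("or_threshold must exceed 1")
        for prior in list(self.priors) + list(self.bfdp_priors):
            if not 0 < prior < 1:
                raise ValueError(f"prior {prior} not in (0,1)")

    @classmethod
    def published_screen(cls, **overrides) -> "NoteworthinessConfig":
        """The permissive FPRP < 0.5 screen (otherwise identical defaults)."""
        overrides.setdefault("fprp_noteworthy_cutoff", 0.5)
        return cls(**overrides)


@dataclass(frozen=True)
class NoteworthinessResult:
    """FPRP and BFDP of one model across the prior grids."""

    model: ModelKind
    alpha_observed: float  # exact (unrounded) two-sided p
    power: float
    fprp_by_prior: Mapping[float, float]
    abf: float
    bfdp_by_prior: Mapping[float, float]
    noteworthy_fprp: Mapping[float, bool] = field(default_factory=dict)
    noteworthy_bfdp: Mapping[float, bool] = field(default_factory=dict)


def power_at_threshold(
    se_log_or: float,
    alpha: float,
    or_threshold: float = 1.5,
    direction: str = "risk",
) -> float:
    """Power of the two-sided Wald z-test against the target odds ratio.

    The alternative places the log OR at ln(or_threshold) (risk) or
    -ln(or_threshold) (protective); the estimate is normal with the observed
    SE. Both rejection tails are included; the discordant tail is negligible
    in practice but keeps the expression exact.

    ``alpha`` must be the exact observed p-value, not a rounded display value
    (rounding alpha visibly shifts the power at small p).
    """
    if se_log_or <= 0:
        raise ValueError("se_log_or must be positive")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0,1], got {alpha}")
    if direction not in ("risk", "protective"):
        raise ValueError(f"direction must be 'risk' or 'protective', got {direction!r}")
    theta = abs(math.log(or_threshold))
    z_alpha = float(stats.norm.isf(alpha / 2))
    shift = theta / se_log_or
    return float(stats.norm.cdf(shift - z_alpha) + stats.norm.cdf(-shift - z_alpha))


def fprp(alpha: float, power: float, prior: float) -> float:
    """False-positive report probability for one prior.

    Returns 1 (with a warning) when power is 0: a test that cannot detect
    the alternative cannot vindicate a positive report.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0,1], got {alpha}")
    if not 0 <= power <= 1:
        raise ValueError(f"power must be in [0,1], got {power}")
    if not 0 < prior <= 1:
        raise ValueError(f"prior must be in (0,1], got {prior}")
    if power == 0:
        logger.warning("fprp: zero power, returning 1")
        return 1.0
    numerator = alpha * (1 - prior)
    return numerator / (numerator + power * prior)


def bfdp(
    log_or: float,
    se_log_or: float,
    or_threshold: float = 1.5,
    prior: float = 0.01,
) -> tuple[float, float]:
    """Approximate Bayes factor (null/alternative) and BFDP for one prior."""
    if se_log_or <= 0:
        raise ValueError("se_log_or must be positive")
    if not 0 < prior < 1:
        raise ValueError(f"prior must be in (0,1), got {prior}")
    v = se_log_or**2
    w = (math.log(or_threshold) / float(stats.norm.ppf(0.975))) ** 2
    z = log_or / se_log_or
    abf = math.sqrt((v + w) / v) * math.exp(-(z**2) * w / (2 * (v + w)))
    prior_odds_null = (1 - prior) / prior
    posterior_odds = abf * prior_odds_null
    return abf, posterior_odds / (1 + posterior_odds)


def evaluate(
    assoc: AssociationResult, config: NoteworthinessConfig | None = None
) -> NoteworthinessResult:
    """Run both screens on one association result.

    The direction of the power alternative follows the sign of the estimated
    OR (protective iff OR < 1; an OR of exactly 1 is treated as risk).
    """
    config = config or NoteworthinessConfig()
    direction = "protective" if assoc.or_estimate < 1 else "risk"
    power = power_at_threshold(
        assoc.se_log_or, assoc.p_value, config.or_threshold, direction
    )
    fprp_by_prior = {
        prior: fprp(assoc.p_value, power, prior) for prior in config.priors
    }
    abf = None
    bfdp_by_prior = {}
    for prior in config.bfdp_priors:
        abf, value = bfdp(assoc.log_or, assoc.se_log_or, config.or_threshold, prior)
        bfdp_by_prior[prior] = value
    return NoteworthinessResult(
        model=assoc.model,
        alpha_observed=assoc.p_value,
        power=power,
        fprp_by_prior=fprp_by_prior,
        abf=abf,
        bfdp_by_prior=bfdp_by_prior,
        noteworthy_fprp={
            prior: value < config.fprp_noteworthy_cutoff
            for prior, value in fprp_by_prior.items()
        },
        noteworthy_bfdp={
            prior: value < config.bfdp_noteworthy_cutoff
            for prior, value in bfdp_by_prior.items()
        },
    )
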