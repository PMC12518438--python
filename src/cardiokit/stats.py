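"""Group statistics: Welch tests, Holm–Bonferroni, TOST equivalence.

The equivalence layer implements the two one-sided tests (TOST) at α = 0.05
with relevance bounds of ±30% of the control-group mean.  Two variants are
provided:

* :func:`tost_relative` — the primary test.  Each one-sided hypothesis is a
  Welch test of the treated group against the *scaled* control group
  (factors 1−b and 1+b).  Scaling the control inside the test propagates the
  sampling uncertainty of the anchor mean, so the test holds its nominal
  size at the equivalence boundary; treating 0.3·x̄_control as a known
  constant does not (the anchored contrast x̄_b − 1.3·x̄_a has variance
  σ_b²/n_b + 1.69·σ_a²/n_a, which a plain TOST underestimates).
* :func:`tost_fixed` — TOST against fixed bounds in metric units, with the
  exact duality: equivalent ⇔ max(p) < α ⇔ (1−2α) CI within (Δ_L, Δ_U).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, SpecError

__all__ = [
    "GroupSample",
    "EquivalenceResult",
    "TroponinEstimate",
    "welch_test",
    "holm_bonferroni",
    "tost_relative",
    "tost_fixed",
    "tost_equivalence",
    "summarize_replicates",
    "correlate",
    "troponin_release_bound",
]

DEFAULT_RELATIVE_BOUND = 0.30
DEFAULT_ALPHA = 0.05


@dataclass
class GroupSample:
    """Per-cell values for one experimental group."""

    label: str
    values: np.ndarray
    n_hearts: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SpecError("group values must be a 1-D array")

    @property
    def n_cells(self) -> int:
        return self.values.size


@dataclass
class EquivalenceResult:
    """TOST outcome for one parameter and one group pair."""

    delta_lower: float
    delta_upper: float
    effect: float
    ci: tuple[float, float]
    p_lower: float
    p_upper: float
    alpha: float
    equivalent: bool
    bound_mode: str = "relative"
    relative_bound: float | None = None

    @property
    def p_tost(self) -> float:
        return max(self.p_lower, self.p_upper)


@dataclass
class TroponinEstimate:
    detection_limit_ug_l: float
    volume_l: float
    released_upper_bound_ug: float
    total_content_ug: float | None = None
    damage_fraction_upper_bound: float | None = None


def _as_values(g) -> np.ndarray:
    if isinstance(g, GroupSample):
        return g.values
    return np.asarray(g, dtype=float)


def _welch_parts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(mean difference b−a, standard error, Welch–Satterthwaite df)."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return float(b.mean() - a.mean()), float(se), float(df)


def welch_test(a, b) -> tuple[float, float, float]:
    """Two-sided Welch's t test; returns (t, df, p)."""
    av, bv = _as_values(a), _as_values(b)
    if av.size < 2 or bv.size < 2:
        raise SpecError("Welch's test needs at least two values per group")
    res = sps.ttest_ind(av, bv, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def holm_bonferroni(p_values, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and reject verdicts at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, adj, *_ = multipletests(p, alpha=alpha, method="holm")
    return adj, reject


def tost_fixed(
    a,
    b,
    delta_lower: float,
    delta_upper: float,
    alpha: float = DEFAULT_ALPHA,
) -> EquivalenceResult:
    """Welch TOST of the mean difference against fixed bounds (metric units).

    H0₁: μ_b−μ_a ≤ Δ_L and H0₂: μ_b−μ_a ≥ Δ_U; equivalence is declared when
    both are rejected, identically: when the (1−2α) Welch CI of the
    difference lies inside (Δ_L, Δ_U).
    """
    av, bv = _as_values(a), _as_values(b)
    if av.size < 2 or bv.size < 2:
        raise SpecError("TOST needs at least two values per group")
    if delta_lower >= delta_upper:
        raise SpecError("delta_lower must be below delta_upper")
    diff, se, df = _welch_parts(av, bv)
    t_lo = (diff - delta_lower) / se
    t_hi = (diff - delta_upper) / se
    p_lower = float(sps.t.sf(t_lo, df))
    p_upper = float(sps.t.cdf(t_hi, df))
    tcrit = float(sps.t.ppf(1.0 - alpha, df))
    ci = (diff - tcrit * se, diff + tcrit * se)
    return EquivalenceResult(
        delta_lower=delta_lower,
        delta_upper=delta_upper,
        effect=diff,
        ci=ci,
        p_lower=p_lower,
        p_upper=p_upper,
        alpha=alpha,
        equivalent=max(p_lower, p_upper) < alpha,
        bound_mode="fixed",
    )


def _scaled_welch_onesided(
    a: np.ndarray, b: np.ndarray, factor: float, alternative: str
) -> float:
    """One-sided Welch p for H1: μ_b >/< factor·μ_a."""
    na, nb = a.size, b.size
    va = factor**2 * a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    t = (b.mean() - factor * a.mean()) / se
    return float(sps.t.sf(t, df) if alternative == "greater" else sps.t.cdf(t, df))


def tost_relative(
    control,
    treated,
    relative_bound: float = DEFAULT_RELATIVE_BOUND,
    alpha: float = DEFAULT_ALPHA,
) -> EquivalenceResult:
    """TOST with relevance bounds of ±``relative_bound`` of the control mean.

    Equivalence means the treated mean lies between (1−b)·μ_control and
    (1+b)·μ_control.  Each one-sided hypothesis is tested as a Welch
    comparison of the treated group against the correspondingly scaled
    control group (see module docstring for why the scaling happens inside
    the test).  Works for control means of either sign; a control mean of
    zero leaves relative bounds undefined.
    """
    av, bv = _as_values(control), _as_values(treated)
    if av.size < 2 or bv.size < 2:
        raise SpecError("TOST needs at least two values per group")
    if not 0 < relative_bound:
        raise SpecError("relative_bound must be positive")
    m_a = av.mean()
    if m_a == 0:
        raise AnalysisError("control mean is zero: relative bounds are undefined")
    f_lo, f_hi = 1.0 - relative_bound, 1.0 + relative_bound
    b_lo, b_hi = sorted((f_lo * m_a, f_hi * m_a))
    # which factor realises the lower bound depends on the sign of the mean
    fac_lo, fac_hi = (f_lo, f_hi) if m_a > 0 else (f_hi, f_lo)
    p_lower = _scaled_welch_onesided(av, bv, fac_lo, "greater")
    p_upper = _scaled_welch_onesided(av, bv, fac_hi, "less")
    diff, se, df = _welch_parts(av, bv)
    tcrit = float(sps.t.ppf(1.0 - alpha, df))
    return EquivalenceResult(
        delta_lower=float(b_lo - m_a),
        delta_upper=float(b_hi - m_a),
        effect=diff,
        ci=(diff - tcrit * se, diff + tcrit * se),
        p_lower=p_lower,
        p_upper=p_upper,
        alpha=alpha,
        equivalent=max(p_lower, p_upper) < alpha,
        bound_mode="relative",
        relative_bound=relative_bound,
    )


# the primary entry point used by the study driver
tost_equivalence = tost_relative


def summarize_replicates(values) -> float:
    """Mean of technical replicates (the per-sample representative value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise SpecError("no replicate values given")
    return float(v.mean())


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation of paired per-cell metrics; returns (r, p)."""
    xv, yv = np.asarray(x, float), np.asarray(y, float)
    if xv.size != yv.size or xv.size < 3:
        raise SpecError("paired arrays of at least 3 values are required")
    res = sps.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def troponin_release_bound(
    detection_limit_ug_l: float,
    volume_l: float,
    total_content_ug: float | None = None,
) -> TroponinEstimate:
    """Upper bound on troponin released into a storage solution.

    When no sample reaches the assay's detection limit, the released amount
    is at most detection_limit × solution volume; dividing by the total
    cellular troponin content bounds the damaged-cell fraction.
    """
    if detection_limit_ug_l < 0 or volume_l <= 0:
        raise SpecError("detection limit must be >= 0 and volume positive")
    released = detection_limit_ug_l * volume_l
    frac = None
    if total_content_ug is not None:
        if total_content_ug <= 0:
            raise SpecError("total troponin content must be positive")
        frac = released / total_content_ug
    return TroponinEstimate(
        detection_limit_ug_l=detection_limit_ug_l,
        volume_l=volume_l,
        released_upper_bound_ug=released,
        total_content_ug=total_content_ug,
        damage_fraction_upper_bound=frac,
    )
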