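"""Single-component cosinor rhythmometry and between-genotype comparison.

The cosinor model regresses a time series on a cosine of fixed period tau
(24 h throughout this package):

    y(t) = M + A*cos(2*pi*(t - phi)/tau) + e,   e ~ N(0, sigma^2)

which is linear in the reparametrisation y = M + beta*cos(w t) + gamma*sin(w t)
with w = 2*pi/tau, beta = A*cos(w*phi), gamma = A*sin(w*phi).  M is the MESOR
(rhythm-adjusted mean), A >= 0 the amplitude, and phi in [0, tau) the
acrophase — the clock time of the fitted peak.

Rhythmicity is declared by the zero-amplitude test: an F test of the cosinor
fit against the intercept-only model,

    F = ((RSS0 - RSS)/2) / (RSS/(n - 3)) ~ F(2, n-3) under A = 0.

Confidence intervals for A and phi come from the delta method on the
(beta, gamma) least-squares covariance; phase intervals are circular.
Between-genotype phase and amplitude differences are Wald tests on the
fitted quantities, with CI-overlap flags reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PERIOD = 24.0

#: Ratio A / se(A) below which the acrophase CI is considered unreliable
#: (the phase of a vanishing vector is undefined); the CI is then reported
#: as the full circle.
PHASE_CI_MIN_AMP_SNR = 2.0


class InvalidDesignError(ValueError):
    """Raised when a series cannot support a cosinor fit."""


@dataclass
class ExpressionSeries:
    """Replicated time course for one gene x tissue x genotype x light."""

    gene: str
    tissue: str
    genotype: str
    light: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidDesignError("times and values must have equal length")
        if not (np.isfinite(self.times).all() and np.isfinite(self.values).all()):
            raise InvalidDesignError("times and values must be finite")

    @property
    def n_timepoints(self) -> int:
        return np.unique(self.times).size


@dataclass
class CosinorFit:
    """Fitted cosinor parameters and inference for one series."""

    gene: str
    tissue: str
    genotype: str
    light: str
    mesor: float
    amplitude: float
    acrophase: float
    period: float
    rss: float
    n_obs: int
    p_rhythm: float
    amp_se: float
    phase_se: float
    amp_ci: tuple[float, float]
    phase_ci: tuple[float, float]
    phase_ci_reliable: bool
    degenerate: bool = False
    # (beta, gamma) estimates and their 2x2 covariance, kept for Wald tests.
    beta: float = 0.0
    gamma: float = 0.0
    coef_cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def is_rhythmic(self, alpha: float = 0.01) -> bool:
        return (not self.degenerate) and self.p_rhythm < alpha


@dataclass
class RhythmComparison:
    """Phase/amplitude comparison of one gene between two genotypes."""

    gene: str
    tissue: str
    light: str
    genotype_a: str
    genotype_b: str
    comparable: bool
    reason: str
    delta_phase: float = float("nan")
    amp_ratio: float = float("nan")
    p_phase: float = float("nan")
    p_amp: float = float("nan")
    differential_phase: bool = False
    differential_amp: bool = False
    phase_ci_overlap: bool | None = None
    amp_ci_overlap: bool | None = None


def circular_phase_difference(phase_a: float, phase_b: float,
                              period: float = DEFAULT_PERIOD) -> float:
    """Signed circular difference phase_b - phase_a in [-period/2, period/2).

    Positive values mean the second phase is delayed (peaks later).  The
    boundary convention maps +period/2 to -period/2.
    """
    half = period / 2.0
    return (phase_b - phase_a + half) % period - half


def fit_cosinor(series: ExpressionSeries, period: float = DEFAULT_PERIOD,
                ci_level: float = 0.95) -> CosinorFit:
    """Least-squares cosinor fit with rhythmicity test and delta-method CIs.

    Requires at least four distinct timepoints.  An all-constant series is
    returned as a degenerate fit (A = 0, p_rhythm = 1) rather than an error,
    so batch runs over gene panels complete.
    """
    if period <= 0:
        raise InvalidDesignError(f"period must be positive, got {period}")
    t, y = series.times, series.values
    n = y.size
    if series.n_timepoints < 4:
        raise InvalidDesignError(
            f"cosinor needs >=4 distinct timepoints, got {series.n_timepoints}"
        )

    if np.ptp(y) == 0.0:
        return CosinorFit(
            gene=series.gene, tissue=series.tissue, genotype=series.genotype,
            light=series.light, mesor=float(y[0]), amplitude=0.0, acrophase=0.0,
            period=period, rss=0.0, n_obs=n, p_rhythm=1.0,
            amp_se=0.0, phase_se=float("inf"), amp_ci=(0.0, 0.0),
            phase_ci=(0.0, period), phase_ci_reliable=False, degenerate=True,
        )

    w = 2.0 * math.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    rss = float(resid @ resid)
    amplitude = math.hypot(beta, gamma)
    acrophase = (math.atan2(gamma, beta) / w) % period

    df = n - 3
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if df > 0 and rss > 0:
        f_stat = ((rss0 - rss) / 2.0) / (rss / df)
        p_rhythm = float(stats.f.sf(f_stat, 2, df))
    else:
        # A perfect fit: the zero-amplitude hypothesis is rejected outright.
        p_rhythm = 0.0 if amplitude > 0 else 1.0

    sigma2 = rss / df if df > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    cov_bg = sigma2 * xtx_inv[1:, 1:]

    amp_se, phase_se = _delta_method_se(beta, gamma, cov_bg, period)
    amp_ci, phase_ci, reliable = _cosinor_cis(
        amplitude, acrophase, amp_se, phase_se, period, df, ci_level
    )

    return CosinorFit(
        gene=series.gene, tissue=series.tissue, genotype=series.genotype,
        light=series.light, mesor=mesor, amplitude=amplitude,
        acrophase=acrophase, period=period, rss=rss, n_obs=n,
        p_rhythm=p_rhythm, amp_se=amp_se, phase_se=phase_se,
        amp_ci=amp_ci, phase_ci=phase_ci, phase_ci_reliable=reliable,
        beta=beta, gamma=gamma, coef_cov=cov_bg,
    )


def _delta_method_se(beta: float, gamma: float, cov: np.ndarray,
                     period: float) -> tuple[float, float]:
    """Standard errors of amplitude and acrophase (hours) from (beta, gamma)."""
    amp2 = beta * beta + gamma * gamma
    if amp2 == 0.0:
        return float(np.sqrt(max(cov[0, 0], cov[1, 1]))), float("inf")
    amp = math.sqrt(amp2)
    g_amp = np.array([beta / amp, gamma / amp])
    amp_var = float(g_amp @ cov @ g_amp)
    # d(atan2)/d(beta,gamma) = (-gamma, beta)/A^2, converted to hours.
    g_phi = np.array([-gamma / amp2, beta / amp2]) * (period / (2.0 * math.pi))
    phase_var = float(g_phi @ cov @ g_phi)
    return math.sqrt(max(amp_var, 0.0)), math.sqrt(max(phase_var, 0.0))


def _cosinor_cis(amplitude: float, acrophase: float, amp_se: float,
                 phase_se: float, period: float, df: int,
                 level: float) -> tuple[tuple[float, float], tuple[float, float], bool]:
    if df > 0:
        q = float(stats.t.ppf(0.5 + level / 2.0, df))
    else:
        q = 0.0
    amp_ci = (amplitude - q * amp_se, amplitude + q * amp_se)
    half_width = q * phase_se
    snr = amplitude / amp_se if amp_se > 0 else float("inf")
    reliable = math.isfinite(half_width) and half_width < period / 2.0 \
        and snr >= PHASE_CI_MIN_AMP_SNR
    if reliable:
        phase_ci = ((acrophase - half_width) % period,
                    (acrophase + half_width) % period)
    else:
        phase_ci = (0.0, period)
    return amp_ci, phase_ci, reliable


def test_rhythmicity(fit: CosinorFit) -> float:
    """P-value of the zero-amplitude F test stored on the fit."""
    if fit.n_obs <= 3:
        raise InvalidDesignError("zero-amplitude test needs n > 3 observations")
    return fit.p_rhythm


def confidence_intervals(fit: CosinorFit, level: float = 0.95
                         ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Delta-method CIs for amplitude and (circular) acrophase at `level`."""
    if fit.degenerate:
        return (0.0, 0.0), (0.0, fit.period)
    amp_ci, phase_ci, _ = _cosinor_cis(
        fit.amplitude, fit.acrophase, fit.amp_se, fit.phase_se,
        fit.period, fit.n_obs - 3, level,
    )
    return amp_ci, phase_ci


def _circular_intervals_overlap(ci_a: tuple[float, float],
                                ci_b: tuple[float, float],
                                period: float) -> bool:
    """Whether two circular arcs (lo going clockwise to hi) intersect."""

    def arc_contains(lo: float, hi: float, x: float) -> bool:
        span = (hi - lo) % period
        return (x - lo) % period <= span

    a_lo, a_hi = ci_a
    b_lo, b_hi = ci_b
    return (arc_contains(a_lo, a_hi, b_lo) or arc_contains(a_lo, a_hi, b_hi)
            or arc_contains(b_lo, b_hi, a_lo) or arc_contains(b_lo, b_hi, a_hi))


def compare_rhythms(fit_a: CosinorFit, fit_b: CosinorFit,
                    cutoff: float = 0.01,
                    rhythm_alpha: float = 0.01) -> RhythmComparison:
    """Wald tests of amplitude and circular phase difference between fits.

    Both fits must be rhythmic at `rhythm_alpha`; otherwise an explicit
    not-comparable result is returned (never a silent omission).  The sign
    convention is delta_phase = phase(b) - phase(a) wrapped to [-12, 12):
    positive means the second genotype peaks later (is phase delayed).
    """
    base = dict(gene=fit_a.gene, tissue=fit_a.tissue, light=fit_a.light,
                genotype_a=fit_a.genotype, genotype_b=fit_b.genotype)
    for fit, tag in ((fit_a, "first"), (fit_b, "second")):
        if not fit.is_rhythmic(rhythm_alpha):
            return RhythmComparison(
                comparable=False,
                reason=f"{tag} genotype not rhythmic "
                       f"(p={fit.p_rhythm:.3g} >= {rhythm_alpha})",
                **base,
            )

    period = fit_a.period
    delta = circular_phase_difference(fit_a.acrophase, fit_b.acrophase, period)
    amp_ratio = fit_b.amplitude / fit_a.amplitude if fit_a.amplitude > 0 else math.inf

    # Reference t distribution uses the smaller per-fit residual df: the
    # combined Wald statistic has heavier-than-normal tails at this design's
    # n, and the summed-df reference is anti-conservative.
    df = min(fit_a.n_obs, fit_b.n_obs) - 3
    se_phase = math.hypot(fit_a.phase_se, fit_b.phase_se)
    se_amp = math.hypot(fit_a.amp_se, fit_b.amp_se)
    p_phase = _wald_p(delta, se_phase, df)
    p_amp = _wald_p(fit_b.amplitude - fit_a.amplitude, se_amp, df)

    return RhythmComparison(
        comparable=True, reason="",
        delta_phase=delta, amp_ratio=amp_ratio,
        p_phase=p_phase, p_amp=p_amp,
        differential_phase=p_phase < cutoff,
        differential_amp=p_amp < cutoff,
        phase_ci_overlap=_circular_intervals_overlap(
            fit_a.phase_ci, fit_b.phase_ci, period),
        amp_ci_overlap=not (fit_a.amp_ci[1] < fit_b.amp_ci[0]
                            or fit_b.amp_ci[1] < fit_a.amp_ci[0]),
        **base,
    )


def _wald_p(estimate: float, se: float, df: int) -> float:
    if se == 0.0:
        return 1.0 if estimate == 0.0 else 0.0
    if not math.isfinite(se):
        return 1.0
    z = estimate / se
    return float(2.0 * stats.t.sf(abs(z), df)) if df > 0 else float("nan")


def summarize_phase_delays(comparisons: Iterable[RhythmComparison],
                           gene_class_map: Mapping[str, str]) -> pd.DataFrame:
    """Mean signed phase delay per gene class over comparable gene pairs.

    Genes missing from `gene_class_map` are excluded with a logged warning.
    Returns a frame with columns gene_class, n, mean_delay_h, sd_delay_h.
    """
    rows = []
    for comp in comparisons:
        if not comp.comparable:
            continue
        cls = gene_class_map.get(comp.gene)
        if cls is None:
            logger.warning("gene %s has no class assignment; excluded", comp.gene)
            continue
        rows.append({"gene_class": cls, "gene": comp.gene,
                     "delta_phase": comp.delta_phase})
    if not rows:
        return pd.DataFrame(columns=["gene_class", "n", "mean_delay_h", "sd_delay_h"])
    df = pd.DataFrame(rows)
    out = (df.groupby("gene_class")["delta_phase"]
             .agg(n="size", mean_delay_h="mean", sd_delay_h="std")
             .reset_index())
    return out


def rhythmicity_table(fits: Iterable[CosinorFit], cutoff: float = 0.01,
                      gene_class_map: Mapping[str, str] | None = None
                      ) -> pd.DataFrame:
    """Counts and percentages of rhythmic genes per stratum.

    One row per genotype x tissue x light (x gene class when a class map is
    given), plus 'all'-class and per-genotype marginal rows.  Duplicate
    gene x tissue x genotype x light cells raise a ValueError.
    """
    fits = list(fits)
    keys = [(f.gene, f.tissue, f.genotype, f.light) for f in fits]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate fit cells: {dupes[:5]}")

    records = [{
        "gene": f.gene, "tissue": f.tissue, "genotype": f.genotype,
        "light": f.light,
        "gene_class": (gene_class_map or {}).get(f.gene, "unclassified"),
        "rhythmic": f.is_rhythmic(cutoff),
    } for f in fits]
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=["genotype", "tissue", "light", "gene_class",
                                     "n_genes", "n_rhythmic", "pct_rhythmic"])

    def agg(frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
        g = (frame.groupby(by, sort=True)["rhythmic"]
                  .agg(n_genes="size", n_rhythmic="sum").reset_index())
        g["pct_rhythmic"] = 100.0 * g["n_rhythmic"] / g["n_genes"]
        return g

    per_cell = agg(df, ["genotype", "tissue", "light", "gene_class"])
    per_stratum = agg(df, ["genotype", "tissue", "light"])
    per_stratum["gene_class"] = "all"
    per_genotype = agg(df, ["genotype"])
    per_genotype["tissue"] = "all"
    per_genotype["light"] = "all"
    per_genotype["gene_class"] = "all"
    out = pd.concat([per_cell, per_stratum, per_genotype], ignore_index=True)
    cols = ["genotype", "tissue", "light", "gene_class",
            "n_genes", "n_rhythmic", "pct_rhythmic"]
    return out[cols].sort_values(cols[:4]).reset_index(drop=True)


EXPRESSION_COLUMNS = ["gene", "tissue", "genotype", "light", "time_h", "value"]


def read_expression_csv(path) -> pd.DataFrame:
    """Read a long-format expression table; header with the standard columns."""
    df = pd.read_csv(path)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression CSV missing columns: {missing}")
    return df


def series_from_frame(df: pd.DataFrame) -> list[ExpressionSeries]:
    """Split a long-format table into one ExpressionSeries per cell."""
    out = []
    for (gene, tissue, genotype, light), grp in df.groupby(
            ["gene", "tissue", "genotype", "light"], sort=True):
        out.append(ExpressionSeries(
            gene=gene, tissue=tissue, genotype=genotype, light=light,
            times=grp["time_h"].to_numpy(), values=grp["value"].to_numpy(),
        ))
    return out


def fits_to_frame(fits: Iterable[CosinorFit]) -> pd.DataFrame:
    """Tabulate fits, one row per gene x tissue x genotype x light."""
    rows = [{
        "gene": f.gene, "tissue": f.tissue, "genotype": f.genotype,
        "light": f.light, "mesor": f.mesor, "amplitude": f.amplitude,
        "acrophase_h": f.acrophase, "period_h": f.period, "n_obs": f.n_obs,
        "rss": f.rss, "p_rhythm": f.p_rhythm,
        "amp_ci_lo": f.amp_ci[0], "amp_ci_hi": f.amp_ci[1],
        "phase_ci_lo": f.phase_ci[0], "phase_ci_hi": f.phase_ci[1],
        "phase_ci_reliable": f.phase_ci_reliable, "degenerate": f.degenerate,
    } for f in fits]
    return pd.DataFrame(rows)


def comparisons_to_frame(comps: Sequence[RhythmComparison]) -> pd.DataFrame:
    rows = [{
        "gene": c.gene, "tissue": c.tissue, "light": c.light,
        "genotype_a": c.genotype_a, "genotype_b": c.genotype_b,
        "comparable": c.comparable, "reason": c.reason,
        "delta_phase_h": c.delta_phase, "amp_ratio": c.amp_ratio,
        "p_phase": c.p_phase, "p_amp": c.p_amp,
        "differential_phase": c.differential_phase,
        "differential_amp": c.differential_amp,
        "phase_ci_overlap": c.phase_ci_overlap,
        "amp_ci_overlap": c.amp_ci_overlap,
    } for c in comps]
    return pd.DataFrame(rows)
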