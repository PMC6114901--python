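"""Concentration-response analysis for thyroid-reporter induction assays.

Normalizes per-embryo gland fluorescence to plate controls, fits the
Hill (log-logistic) induction model with the lower asymptote fixed at the
control level, and derives the potency metrics used to rank goitrogens:

* ``EC50`` — concentration of half-maximal reporter induction,
* ``BMD20`` — benchmark dose at which fold induction reaches 1.2
  (a 20% increase over controls),
* ``LC50`` — median lethal concentration from binomial mortality counts,
* ``TDI`` — thyroid disruption index, ``LC50 / EC50``,
* toxic ratio — hydrophobicity-predicted baseline ``LC50`` over observed
  ``LC50``; ratios below 10 indicate unspecific baseline toxicity.

The induction model is

    y(x) = Min + (Max - Min) / (1 + (x / EC50)^(-p))

with ``Min`` fixed (default 1, the normalized control level), so only the
upper asymptote ``Max``, the midpoint ``EC50`` and the Hill slope ``p``
are estimated. ``EC50`` is parameterized as ``log10(EC50)`` during
optimization; at ``x = 0`` the model evaluates to ``Min`` (its limit for
``p > 0``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "HillParameters",
    "MortalityFit",
    "PotencyReport",
    "hill_curve",
    "normalize_to_control",
    "exclude_declining_top",
    "fit_hill",
    "compute_bmd",
    "fit_mortality",
    "compute_tdi",
    "baseline_toxicity",
    "toxic_ratio",
    "rank_compounds",
    "round_half_up",
    "ec50_confidence_interval",
]

#: columns expected in a per-embryo measurement table
MEASUREMENT_COLUMNS = ("compound", "concentration_uM", "replicate", "pixel_sum")

# threshold on the fitted induction amplitude below which a compound is
# reported as non-inducing and EC50 left undefined
NO_INDUCTION_DELTA = 0.05


@dataclass
class HillParameters:
    """Parameters of the Hill induction curve.

    ``Min`` is the lower asymptote (fixed at 1 for induction fits, the
    normalized control level). ``Max`` is the upper asymptote in fold
    induction, ``EC50`` the midpoint in μM and ``slope`` the
    dimensionless Hill coefficient ``p``. Fitted instances additionally
    carry standard errors and the covariance of the free parameters
    ``(Max, log10 EC50, p)``.
    """

    Min: float
    Max: float
    EC50: float
    slope: float
    EC50_SE: float = float("nan")
    Max_SE: float = float("nan")
    slope_SE: float = float("nan")
    cov: np.ndarray | None = None  # covariance of (Max, log10 EC50, p)
    n_points: int = 0
    converged: bool = True
    no_induction: bool = False

    def __call__(self, x):
        return hill_curve(x, self.Min, self.Max, self.EC50, self.slope)


@dataclass
class MortalityFit:
    """Result of a two-parameter log-logistic mortality fit.

    ``method`` is ``"ml"`` for a binomial maximum-likelihood fit,
    ``"interval"`` when all-or-nothing data only allowed a geometric-mean
    interval estimate, and ``"censored"`` when no mortality was observed
    up to the highest tested concentration (``lc50`` is then a lower
    bound equal to that concentration).
    """

    lc50: float
    slope: float = float("nan")
    lc50_se: float = float("nan")
    slope_se: float = float("nan")
    method: str = "ml"

    @property
    def censored(self) -> bool:
        return self.method == "censored"


@dataclass
class PotencyReport:
    """Per-compound potency summary (one row of the final report table)."""

    compound: str
    cas: str | None = None
    log_d: float = float("nan")
    ec50: float = float("nan")
    ec50_se: float = float("nan")
    slope: float = float("nan")
    max_fold: float = float("nan")
    bmd20: float = float("nan")
    lc50: float = float("nan")
    lc50_flag: str = ""
    tdi: float = float("nan")
    baseline_lc50: float = float("nan")
    toxic_ratio: float = float("nan")
    baseline_like: bool | None = None
    no_induction: bool = False
    excluded_top_concentration: float | None = None
    warnings: list[str] = field(default_factory=list)
    hill: HillParameters | None = None

    @property
    def tdi_display(self) -> float:
        """TDI rounded half-up to the integer, as printed in reports."""
        return round_half_up(self.tdi) if np.isfinite(self.tdi) else float("nan")


def round_half_up(x: float) -> float:
    """Round to the nearest integer with ties going away from zero."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def hill_curve(x, min_, max_, ec50, p):
    """Evaluate the Hill induction model; ``x = 0`` maps to ``min_``.

    Written so that the zero-concentration control is the exact lower
    asymptote rather than relying on ``0 ** negative`` arithmetic.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(min_))
    pos = x > 0
    u = (x[pos] / ec50) ** (-p)
    out[pos] = min_ + (max_ - min_) / (1.0 + u)
    return out if out.shape else float(out)


def normalize_to_control(measurements: pd.DataFrame) -> pd.DataFrame:
    """Fold induction per concentration, controls set exactly to 1.

    ``measurements`` holds per-embryo rows with at least the columns
    ``compound, concentration_uM, replicate, pixel_sum`` and optionally a
    boolean ``flagged`` column; flagged embryos (no gland detected) are
    excluded before averaging. Within each (compound, replicate) group
    the mean pixel sum per concentration is divided by the mean pixel sum
    of that replicate's zero-concentration controls.

    Returns a table with columns ``compound, replicate,
    concentration_uM, fold_induction, n_embryos, low_n`` where ``low_n``
    marks concentrations with fewer than 10 usable embryos (the assay's
    minimum images-per-concentration design rule).

    Raises ``ValueError`` if a replicate lacks controls or its control
    mean is zero.
    """
    df = measurements.copy()
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if "flagged" in df.columns:
        df = df[~df["flagged"].astype(bool)]

    rows = []
    for (compound, replicate), grp in df.groupby(["compound", "replicate"], sort=True):
        controls = grp.loc[grp["concentration_uM"] == 0, "pixel_sum"]
        if controls.empty:
            raise ValueError(
                f"no control (concentration 0) for compound={compound!r} "
                f"replicate={replicate!r}"
            )
        control_mean = float(controls.mean())
        if control_mean == 0:
            raise ValueError(
                f"control mean is zero for compound={compound!r} "
                f"replicate={replicate!r}; fold induction undefined"
            )
        for conc, sub in grp.groupby("concentration_uM", sort=True):
            mean = float(sub["pixel_sum"].mean())
            rows.append(
                {
                    "compound": compound,
                    "replicate": replicate,
                    "concentration_uM": float(conc),
                    "fold_induction": mean / control_mean,
                    "n_embryos": int(len(sub)),
                    "low_n": len(sub) < 10,
                }
            )
    return pd.DataFrame(rows)


def exclude_declining_top(
    normalized: pd.DataFrame, margin: float = 0.10
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Drop a compound's highest concentration if its response collapses.

    At cytotoxic top concentrations the reporter signal can fall off
    instead of plateauing; such points distort an induction fit. For
    each compound the replicate-pooled mean fold induction of the highest
    concentration is compared with that of the next-highest: the top is
    removed iff it is lower by more than ``margin`` (relative). At most
    one concentration is ever removed per compound.

    Returns the filtered table and a map of compound -> removed
    concentration for the run manifest.
    """
    excluded: dict[str, float] = {}
    keep = np.ones(len(normalized), dtype=bool)
    for compound, grp in normalized.groupby("compound"):
        nz = grp[grp["concentration_uM"] > 0]
        concs = np.sort(nz["concentration_uM"].unique())
        if len(concs) < 3:
            continue
        top, second = concs[-1], concs[-2]
        mean_top = nz.loc[nz["concentration_uM"] == top, "fold_induction"].mean()
        mean_second = nz.loc[nz["concentration_uM"] == second, "fold_induction"].mean()
        if mean_top < mean_second * (1.0 - margin):
            excluded[compound] = float(top)
            keep &= ~(
                (normalized["compound"] == compound)
                & (normalized["concentration_uM"] == top)
            )
    return normalized[keep].reset_index(drop=True), excluded


def _hill_model_factory(fix_min: float):
    def model(x, max_, log_ec50, p):
        return hill_curve(x, fix_min, max_, 10.0**log_ec50, p)

    return model


def fit_hill(
    normalized: pd.DataFrame,
    fix_min: float = 1.0,
    per_embryo: bool = False,
) -> HillParameters:
    """Least-squares Hill fit to replicate-level fold-induction points.

    The free parameters are ``(Max, log10 EC50, p)``; ``Min`` is held at
    ``fix_min``. Points are the per-(replicate, concentration) means
    pooled across replicates, including the controls at concentration 0.
    Starting values follow screening practice: ``Max`` from the largest
    observed fold, ``EC50`` from the geometric mean of the tested nonzero
    concentrations, ``p = 1``, with a multi-start over
    ``p ∈ {0.5, 1, 2, 4}`` if the first attempt fails. ``EC50_SE`` is
    obtained from the asymptotic covariance by the delta method.

    A fitted amplitude of at most ``fix_min + 0.05`` is reported as "no
    induction" (EC50 undefined); non-convergence is reported via
    ``converged=False``. Requires at least 4 distinct nonzero
    concentrations.
    """
    if "fold_induction" not in normalized.columns:
        raise ValueError("expected a normalized response table (fold_induction column)")
    x = normalized["concentration_uM"].to_numpy(dtype=float)
    y = normalized["fold_induction"].to_numpy(dtype=float)
    if per_embryo and "n_embryos" in normalized.columns:
        # weight each mean by the number of embryos behind it
        w = normalized["n_embryos"].to_numpy(dtype=float)
        sigma = 1.0 / np.sqrt(np.maximum(w, 1.0))
    else:
        sigma = None
    nz = np.unique(x[x > 0])
    if len(nz) < 4:
        raise ValueError(
            f"need >= 4 distinct nonzero concentrations to fit, got {len(nz)}"
        )
    if np.any(y <= 0):
        raise ValueError("fold inductions must be positive")

    model = _hill_model_factory(fix_min)
    log_gm = float(np.mean(np.log10(nz)))
    max0 = float(np.max(y))
    lo = [-np.inf, np.log10(nz.min()) - 3.0, 1e-3]
    hi = [np.inf, np.log10(nz.max()) + 3.0, 50.0]

    popt = pcov = None
    for p0_slope in (1.0, 0.5, 2.0, 4.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model,
                    x,
                    y,
                    p0=[max0, log_gm, p0_slope],
                    sigma=sigma,
                    bounds=(lo, hi),
                    maxfev=20000,
                )
            break
        except RuntimeError:
            continue
    if popt is None:
        return HillParameters(
            Min=fix_min,
            Max=float("nan"),
            EC50=float("nan"),
            slope=float("nan"),
            n_points=len(x),
            converged=False,
        )

    max_, log_ec50, p = (float(v) for v in popt)
    ec50 = 10.0**log_ec50
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ec50_se = ec50 * math.log(10.0) * float(se[1])  # delta method
    params = HillParameters(
        Min=fix_min,
        Max=max_,
        EC50=ec50,
        slope=p,
        EC50_SE=ec50_se,
        Max_SE=float(se[0]),
        slope_SE=float(se[2]),
        cov=np.asarray(pcov),
        n_points=len(x),
    )
    if max_ <= fix_min + NO_INDUCTION_DELTA:
        params = replace(
            params, no_induction=True, EC50=float("nan"), EC50_SE=float("nan")
        )
    return params


def ec50_confidence_interval(
    params: HillParameters, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for EC50 on the log10 scale.

    Uses a Student-t quantile with ``n_points - 3`` degrees of freedom
    (three free parameters), matching the residual-variance scaling of
    the least-squares covariance.
    """
    if params.cov is None or not np.isfinite(params.EC50):
        raise ValueError("fit covariance unavailable; cannot form an interval")
    df = max(params.n_points - 3, 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    se_log = math.sqrt(max(params.cov[1, 1], 0.0))
    log_ec50 = math.log10(params.EC50)
    return 10.0 ** (log_ec50 - tq * se_log), 10.0 ** (log_ec50 + tq * se_log)


def compute_bmd(params: HillParameters, target_y: float = 1.2) -> float:
    """Benchmark dose: concentration at which the fitted curve reaches
    ``target_y`` (default 1.2, i.e. a 20% increase over controls).

    Closed-form inversion of the Hill model:

        x = EC50 * ((Max - Min)/(target_y - Min) - 1) ** (-1/p)

    Raises ``ValueError`` when ``target_y`` lies outside the open
    interval (Min, Max), where the curve never attains the target.
    """
    if not np.isfinite(params.EC50):
        raise ValueError("EC50 undefined; cannot compute a benchmark dose")
    if target_y >= params.Max:
        raise ValueError(
            f"target {target_y} at or above the upper asymptote Max={params.Max}; "
            "curve never reaches the target"
        )
    if target_y <= params.Min:
        raise ValueError(
            f"target {target_y} at or below the lower asymptote Min={params.Min}"
        )
    if target_y == (params.Min + params.Max) / 2.0:
        # half-maximal response: the midpoint parameter itself, returned
        # directly so the identity holds exactly rather than to an ulp
        return params.EC50
    ratio = (params.Max - params.Min) / (target_y - params.Min) - 1.0
    return params.EC50 * ratio ** (-1.0 / params.slope)


def _loglogistic_cdf(c, lc50, slope):
    c = np.asarray(c, dtype=float)
    out = np.zeros(c.shape)
    pos = c > 0
    out[pos] = 1.0 / (1.0 + (c[pos] / lc50) ** (-slope))
    return out if out.shape else float(out)


def fit_mortality(mortality: pd.DataFrame) -> MortalityFit:
    """LC50 from mortality counts by binomial maximum likelihood.

    The survival model is a two-parameter log-logistic with asymptotes
    fixed at 0 and 1, which on the log-concentration scale is exactly a
    binomial GLM with logit link:

        logit P(death | c) = slope * (ln c - ln LC50)

    so the fit is delegated to a statsmodels GLM on ``ln c`` and LC50
    recovered as ``exp(-intercept / slope)`` with a delta-method SE.
    Zero-concentration rows carry no information under this model and
    are dropped (the model's control mortality is 0).

    Degenerate tables are handled explicitly: with no deaths anywhere the
    LC50 is censored at the highest tested concentration; with strictly
    all-or-nothing kills the LC50 is the geometric mean of the bracketing
    concentrations, flagged as an interval estimate.
    """
    df = mortality[mortality["concentration_uM"] > 0].copy()
    if (df["n_dead"] > df["n_exposed"]).any() or (df["n_dead"] < 0).any():
        raise ValueError("n_dead must lie in [0, n_exposed]")
    nz = df["concentration_uM"].unique()
    if len(nz) < 3:
        raise ValueError("need >= 3 nonzero concentrations for a mortality fit")

    frac = df["n_dead"] / df["n_exposed"]
    if (df["n_dead"] == 0).all():
        return MortalityFit(lc50=float(df["concentration_uM"].max()), method="censored")
    all_or_nothing = ((frac == 0) | (frac == 1)).all()
    if all_or_nothing:
        by_conc = df.groupby("concentration_uM").apply(
            lambda g: g["n_dead"].sum() / g["n_exposed"].sum(), include_groups=False
        )
        alive = by_conc[by_conc == 0]
        dead = by_conc[by_conc == 1]
        if len(dead) == 0:
            return MortalityFit(
                lc50=float(df["concentration_uM"].max()), method="censored"
            )
        if len(alive) == 0:
            # everything died: LC50 below the lowest tested concentration
            return MortalityFit(
                lc50=float(df["concentration_uM"].min()), method="interval"
            )
        low, high = alive.index.max(), dead.index.min()
        return MortalityFit(lc50=float(np.sqrt(low * high)), method="interval")

    endog = df[["n_dead"]].assign(n_alive=df["n_exposed"] - df["n_dead"]).to_numpy()
    exog = sm.add_constant(np.log(df["concentration_uM"].to_numpy(dtype=float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
    b0, b1 = res.params
    if b1 <= 0:
        return MortalityFit(lc50=float("nan"), method="ml")
    lc50 = math.exp(-b0 / b1)
    # delta method on g(b) = exp(-b0/b1)
    grad = np.array([-lc50 / b1, lc50 * b0 / b1**2])
    var = float(grad @ res.cov_params() @ grad)
    return MortalityFit(
        lc50=lc50,
        slope=float(b1),
        lc50_se=math.sqrt(max(var, 0.0)),
        slope_se=float(res.bse[1]),
        method="ml",
    )


def compute_tdi(lc50: float, ec50: float) -> float:
    """Thyroid disruption index, LC50 / EC50.

    Large values mean reporter induction occurs far below lethal
    concentrations — the hallmark of a specific goitrogenic mode of
    action. Undefined (NaN) when either input is missing, e.g. for a
    non-inducing compound. Full precision is returned; reports display
    the half-up-rounded integer.
    """
    if not (np.isfinite(lc50) and np.isfinite(ec50)):
        return float("nan")
    if lc50 <= 0 or ec50 <= 0:
        raise ValueError("LC50 and EC50 must be positive")
    return lc50 / ec50


def baseline_toxicity(log_d: float, qsar: tuple[float, float]) -> float:
    """Baseline (narcosis) LC50 in μM predicted from hydrophobicity.

    ``qsar`` supplies ``(slope, intercept)`` of a linear-in-log-D QSAR,
    ``log10 LC50_baseline = slope * log_d + intercept``; the coefficients
    are configuration, so any published fish-embryo baseline model can be
    plugged in.
    """
    slope, intercept = qsar
    if not np.isfinite(log_d):
        raise ValueError("log D must be finite")
    return 10.0 ** (slope * log_d + intercept)


def toxic_ratio(baseline_lc50: float, observed_lc50: float) -> tuple[float, bool]:
    """Ratio of predicted baseline LC50 to observed LC50.

    Returns ``(ratio, baseline_like)`` where ``baseline_like`` is True
    for ratios strictly below 10 — the conventional cutoff under which
    mortality is attributed to unspecific baseline toxicity rather than a
    specific mode of action.
    """
    if baseline_lc50 <= 0 or observed_lc50 <= 0:
        raise ValueError("LC50 values must be positive")
    ratio = baseline_lc50 / observed_lc50
    return ratio, ratio < 10.0


_RANK_KEYS = {"EC50": ("ec50", True), "BMD20": ("bmd20", True), "TDI": ("tdi", False)}


def rank_compounds(reports: list[PotencyReport], key: str = "EC50") -> list[PotencyReport]:
    """Order compounds by potency.

    Ascending for EC50/BMD20 (most potent first), descending for TDI.
    Compounds with the key undefined sort last; ties break on the
    compound name.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"key must be one of {sorted(_RANK_KEYS)}")
    attr, ascending = _RANK_KEYS[key]

    def sort_key(rep: PotencyReport):
        v = getattr(rep, attr)
        if v is None or not np.isfinite(v):
            return (1, 0.0, rep.compound)
        return (0, v if ascending else -v, rep.compound)

    return sorted(reports, key=sort_key)
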