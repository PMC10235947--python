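"""Bayesian meta-analysis of group-level reproductive skew.

Group-level skew values on the signed-square-root scale (M*) are modeled
hierarchically: each observation is its class mean plus a group-level
deviation,

    y_g ~ Normal(theta_{c(g)}, sqrt(sigma^2 + se_g^2)),

with weakly informative priors theta_c ~ Normal(0, 1) and
sigma ~ HalfNormal(1).  The optional known measurement SD ``se_g``
(bootstrap SE of each group's M*, zero when unused) gives a classical
measurement-error meta-analysis.  Class comparisons are posterior
contrasts theta_A − theta_B, summarized by their mean and equal-tailed
89% credible interval — the package's interval convention; the
polygyny-intensity regression uses a 95% band for its fitted line.

Sampling is Metropolis-within-Gibbs: the class means (and regression
coefficients) have exact conjugate normal updates given sigma, and
log(sigma) takes an adaptive random-walk step.  Chains are vectorized,
seeded, and checked with split-chain R-hat and bulk effective sample
size (via arviz); fits failing the gates (R-hat <= 1.01, ESS >= 400) are
flagged, not silently returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ValidationError

logger = logging.getLogger("repskew")

__all__ = [
    "SamplerSettings",
    "MetaSpec",
    "PosteriorSummary",
    "MetaFit",
    "RegressionFit",
    "fit_group_model",
    "contrast",
    "fit_polygyny_regression",
    "robustness_subset",
]

OUTCOMES = ("M_star_male", "M_star_female", "M_star_sexdiff")
GROUPINGS = (
    "taxon",
    "primate_taxon",
    "nonhuman_mating_system",
    "human_marriage_system",
    "human_subsistence",
    "polygynous_taxon",
)

RHAT_GATE = 1.01
ESS_GATE = 400.0


def _rhat_ess(draws: np.ndarray) -> tuple[float, float]:
    """Split-chain R-hat and bulk ESS for a (chains, draws) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws)), float(az.ess(draws))


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    seed: int = 0


@dataclass(frozen=True)
class MetaSpec:
    """What to fit: outcome, grouping of the groups into classes, options.

    ``grouping`` choices: ``taxon`` (human vs all nonhuman mammals),
    ``primate_taxon`` (human vs nonhuman primates only),
    ``nonhuman_mating_system``, ``human_marriage_system``,
    ``human_subsistence``, and ``polygynous_taxon`` (normatively
    polygynous human populations vs polygynous nonhuman mammals).
    """

    outcome: str
    grouping: str
    use_measurement_error: bool = False
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}; allowed: {OUTCOMES}")
        if self.grouping not in GROUPINGS:
            raise ValidationError(f"unknown grouping {self.grouping!r}; allowed: {GROUPINGS}")


@dataclass
class PosteriorSummary:
    """Posterior draws and equal-tailed summary for one parameter."""

    label: str
    draws: np.ndarray  # (chains, draws)
    mean: float
    ci89_low: float
    ci89_high: float
    rhat: float
    ess_bulk: float

    @property
    def converged(self) -> bool:
        return self.rhat <= RHAT_GATE and self.ess_bulk >= ESS_GATE

    @classmethod
    def from_draws(cls, label: str, draws: np.ndarray) -> "PosteriorSummary":
        lo, hi = np.quantile(draws, [0.055, 0.945])
        rhat, ess = _rhat_ess(draws)
        return cls(label, draws, float(draws.mean()), float(lo), float(hi), rhat, ess)

    def __repr__(self) -> str:
        return (f"PosteriorSummary({self.label}: mean={self.mean:.3f}, "
                f"89% CI [{self.ci89_low:.3f}, {self.ci89_high:.3f}], "
                f"rhat={self.rhat:.3f}, ess={self.ess_bulk:.0f})")


@dataclass
class MetaFit:
    """A fitted hierarchical group-comparison model."""

    spec: MetaSpec
    class_labels: list[str]
    summaries: dict[str, PosteriorSummary]
    n_groups: dict[str, int]
    subset: str = "all"

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.summaries.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"parameter": s.label, "mean": s.mean, "ci89_low": s.ci89_low,
             "ci89_high": s.ci89_high, "rhat": s.rhat, "ess_bulk": s.ess_bulk}
            for s in self.summaries.values()
        ])


# ---------------------------------------------------------------------------
# Outcome and class assembly
# ---------------------------------------------------------------------------


def _mstar_table(estimates: pd.DataFrame) -> pd.DataFrame:
    df = estimates.copy()
    if "M_star" not in df.columns:
        df["M_star"] = np.sign(df["M"]) * np.sqrt(np.abs(df["M"]))
    if "se" not in df.columns:
        df["se"] = np.nan
    # delta-method SE on the signed-sqrt scale, |M| floored to avoid blowup
    df["se_star"] = df["se"] / (2.0 * np.sqrt(np.clip(np.abs(df["M"]), 1e-6, None)))
    return df


def assemble_outcome(estimates: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """One row per group: the requested M* outcome and its measurement SD.

    For the per-group sex difference, only groups with both sexes observed
    contribute; its measurement SD combines the two sexes' in quadrature.
    """
    df = _mstar_table(estimates)
    if df.duplicated(subset=["group_id", "sex"]).any():
        raise ValidationError("each group contributes at most one estimate per sex")
    wide_y = df.pivot(index="group_id", columns="sex", values="M_star")
    wide_se = df.pivot(index="group_id", columns="sex", values="se_star")
    for col in ("male", "female"):
        if col not in wide_y.columns:
            wide_y[col] = np.nan
            wide_se[col] = np.nan
    if outcome == "M_star_male":
        y, se = wide_y["male"], wide_se["male"]
    elif outcome == "M_star_female":
        y, se = wide_y["female"], wide_se["female"]
    else:
        y = wide_y["male"] - wide_y["female"]
        se = np.sqrt(wide_se["male"] ** 2 + wide_se["female"] ** 2)
    out = pd.DataFrame({"y": y, "se": se}).dropna(subset=["y"])
    if not np.isfinite(out["y"]).all():
        raise ValidationError("outcome values must be finite")
    return out


def class_assignment(metadata: pd.DataFrame, grouping: str) -> pd.Series:
    """Map group_id -> class label for a grouping; excluded groups get NA."""
    meta = metadata.set_index("group_id")
    human = meta["taxon"] == "human"
    if grouping == "taxon":
        cls = meta["taxon"].astype("string")
    elif grouping == "primate_taxon":
        cls = pd.Series(pd.NA, index=meta.index, dtype="string")
        cls[human] = "human"
        primate = (~human) & (meta["is_primate"] == True)  # noqa: E712
        cls[primate] = "nonhuman_primate"
    elif grouping == "nonhuman_mating_system":
        cls = meta["mating_system"].where(~human).astype("string")
    elif grouping == "human_marriage_system":
        cls = meta["marriage_system"].where(human).astype("string")
    elif grouping == "human_subsistence":
        cls = meta["subsistence"].where(human).astype("string")
    elif grouping == "polygynous_taxon":
        cls = pd.Series(pd.NA, index=meta.index, dtype="string")
        cls[human & (meta["marriage_system"] == "normative_polygyny")] = "polygynous_human"
        cls[~human & (meta["mating_system"] == "polygynous")] = "polygynous_nonhuman"
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    return cls


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def _sample_hierarchical(
    y: np.ndarray, cls_idx: np.ndarray, se2: np.ndarray, n_classes: int,
    settings: SamplerSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis-within-Gibbs for the class-means model.

    Returns (theta_draws (chains, draws, C), sigma_draws (chains, draws)).
    """
    rng = np.random.default_rng(settings.seed)
    chains, draws, warmup = settings.chains, settings.draws, settings.warmup
    N = y.size
    Z = np.zeros((N, n_classes))
    Z[np.arange(N), cls_idx] = 1.0
    theta = rng.normal(0.0, 0.5, size=(chains, n_classes))
    log_sigma = rng.normal(-1.0, 0.3, size=chains)
    step = np.full(chains, 0.5)
    accepts = np.zeros(chains)
    theta_out = np.empty((chains, draws, n_classes))
    sigma_out = np.empty((chains, draws))

    def sigma_logpost(log_sig: np.ndarray, theta: np.ndarray) -> np.ndarray:
        sig2 = np.exp(2.0 * log_sig)[:, None] + se2[None, :]
        resid = y[None, :] - theta @ Z.T
        ll = -0.5 * np.sum(np.log(2 * np.pi * sig2) + resid**2 / sig2, axis=1)
        sig = np.exp(log_sig)
        return ll - 0.5 * sig**2 + log_sig  # half-normal prior + log-Jacobian

    for it in range(warmup + draws):
        sig2 = np.exp(2.0 * log_sigma)[:, None] + se2[None, :]  # (chains, N)
        prec = 1.0 / sig2
        post_prec = 1.0 + prec @ Z                      # prior Normal(0, 1)
        post_mean = ((prec * y[None, :]) @ Z) / post_prec
        theta = post_mean + rng.standard_normal((chains, n_classes)) / np.sqrt(post_prec)

        prop = log_sigma + step * rng.standard_normal(chains)
        lp_cur = sigma_logpost(log_sigma, theta)
        lp_prop = sigma_logpost(prop, theta)
        accept = np.log(rng.random(chains)) < lp_prop - lp_cur
        log_sigma = np.where(accept, prop, log_sigma)
        accepts += accept

        if it < warmup and (it + 1) % 50 == 0:
            rate = accepts / 50.0
            step *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            accepts[:] = 0.0
        if it >= warmup:
            theta_out[:, it - warmup] = theta
            sigma_out[:, it - warmup] = np.exp(log_sigma)
    return theta_out, sigma_out


def fit_group_model(
    estimates: pd.DataFrame, metadata: pd.DataFrame, spec: MetaSpec
) -> MetaFit:
    """Fit the hierarchical class-means model for one outcome and grouping.

    Returns posterior summaries for every class mean (labelled
    ``mean[<class>]``) plus the residual SD ``sigma``.  Every class must
    contain at least 2 groups.  Non-convergence is flagged on the result,
    with a logged warning, rather than raised.
    """
    outcome = assemble_outcome(estimates, spec.outcome)
    cls = class_assignment(metadata, spec.grouping)
    joined = outcome.join(cls.rename("cls"), how="inner").dropna(subset=["cls"])
    if joined.empty:
        raise ValidationError("no groups left after joining outcome with grouping")
    labels = sorted(joined["cls"].unique())
    counts = joined["cls"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"class {thin.index[0]!r} has {int(thin.iloc[0])} group(s); need >= 2"
        )
    y = joined["y"].to_numpy(dtype=float)
    if spec.use_measurement_error:
        se2 = np.nan_to_num(joined["se"].to_numpy(dtype=float), nan=0.0) ** 2
    else:
        se2 = np.zeros_like(y)
    cls_idx = pd.Categorical(joined["cls"], categories=labels).codes.astype(int)
    theta, sigma = _sample_hierarchical(y, cls_idx, se2, len(labels), spec.sampler)
    summaries = {
        f"mean[{lab}]": PosteriorSummary.from_draws(f"mean[{lab}]", theta[:, :, i])
        for i, lab in enumerate(labels)
    }
    summaries["sigma"] = PosteriorSummary.from_draws("sigma", sigma)
    fit = MetaFit(
        spec=spec, class_labels=labels, summaries=summaries,
        n_groups={lab: int(counts[lab]) for lab in labels},
    )
    if not fit.converged:
        logger.warning("MCMC convergence gates failed for %s/%s",
                       spec.outcome, spec.grouping)
    logger.info("fit %s by %s: %s", spec.outcome, spec.grouping, fit.n_groups)
    return fit


def contrast(fit: MetaFit, class_a: str, class_b: str) -> PosteriorSummary:
    """Posterior contrast mean[class_a] − mean[class_b], draw by draw."""
    for lab in (class_a, class_b):
        if f"mean[{lab}]" not in fit.summaries:
            raise ValidationError(
                f"unknown class {lab!r}; fitted classes: {fit.class_labels}"
            )
    diff = fit.summaries[f"mean[{class_a}]"].draws - fit.summaries[f"mean[{class_b}]"].draws
    return PosteriorSummary.from_draws(f"contrast[{class_a} - {class_b}]", diff)


def robustness_subset(
    estimates: pd.DataFrame, metadata: pd.DataFrame, spec: MetaSpec,
    flag_column: str = "high_quality_demography",
) -> MetaFit:
    """Replicate a fit keeping only flagged human groups.

    Human populations without the quality flag are dropped; nonhuman
    groups are retained.  The result carries the subset name.
    """
    flagged = metadata[flag_column].fillna(False).astype(bool)
    meta_sub = metadata[(metadata["taxon"] != "human") | flagged]
    n_humans = int((meta_sub["taxon"] == "human").sum())
    if n_humans == 0:
        raise ValidationError("robustness subset contains no human groups")
    logger.info("robustness subset: %d flagged human groups retained", n_humans)
    est_sub = estimates[estimates["group_id"].isin(meta_sub["group_id"])]
    fit = fit_group_model(est_sub, meta_sub, spec)
    fit.subset = flag_column
    return fit


# ---------------------------------------------------------------------------
# Polygyny-intensity regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    """Bayesian simple linear regression of an M* outcome on % female polygyny."""

    outcome: str
    intercept: PosteriorSummary
    slope: PosteriorSummary
    sigma: PosteriorSummary
    n: int
    _coef_draws: np.ndarray  # (chains, draws, 2) on the natural x scale

    @property
    def converged(self) -> bool:
        return self.intercept.converged and self.slope.converged and self.sigma.converged

    def band(self, x_grid: np.ndarray, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean regression line with an equal-tailed credible band."""
        x_grid = np.asarray(x_grid, dtype=float)
        a = self._coef_draws[..., 0].reshape(-1, 1)
        b = self._coef_draws[..., 1].reshape(-1, 1)
        lines = a + b * x_grid[None, :]
        alpha = 1.0 - level
        lo, hi = np.quantile(lines, [alpha / 2, 1 - alpha / 2], axis=0)
        return pd.DataFrame({
            "pct_female_polygyny": x_grid, "mean": lines.mean(axis=0),
            "lo": lo, "hi": hi,
        })


def fit_polygyny_regression(
    estimates: pd.DataFrame, metadata: pd.DataFrame, outcome: str = "M_star_male",
    settings: SamplerSettings | None = None,
) -> RegressionFit:
    """Regress male skew (or the sex difference in skew) on polygyny intensity.

    The predictor is percent age-adjusted female polygyny — the fraction of
    women married to men with more than one wife — available for the human
    subset only.  The predictor is standardized internally; Normal(0, 1)
    priors on the standardized coefficients, HalfNormal(1) on sigma;
    coefficient summaries are reported on the natural (percent) scale.
    """
    if outcome not in ("M_star_male", "M_star_sexdiff"):
        raise ValidationError("regression outcome must be M_star_male or M_star_sexdiff")
    settings = settings or SamplerSettings()
    out = assemble_outcome(estimates, outcome)
    meta = metadata.set_index("group_id")
    x = pd.to_numeric(meta["pct_female_polygyny"], errors="coerce")
    joined = out.join(x.rename("x"), how="inner").dropna(subset=["x"])
    if len(joined) < 3:
        raise ValidationError(f"need >= 3 groups with polygyny data, got {len(joined)}")
    y = joined["y"].to_numpy(dtype=float)
    x = joined["x"].to_numpy(dtype=float)
    sx = x.std()
    if sx == 0:
        raise ValidationError("all predictor values identical; slope unidentified")
    mx = x.mean()
    xs = (x - mx) / sx
    X = np.column_stack([np.ones_like(xs), xs])

    rng = np.random.default_rng(settings.seed)
    chains, draws, warmup = settings.chains, settings.draws, settings.warmup
    beta = rng.normal(0.0, 0.5, size=(chains, 2))
    log_sigma = rng.normal(-1.0, 0.3, size=chains)
    step = np.full(chains, 0.5)
    accepts = np.zeros(chains)
    XtX = X.T @ X
    Xty = X.T @ y
    coef_out = np.empty((chains, draws, 2))
    sigma_out = np.empty((chains, draws))

    def logpost_sigma(log_sig, beta):
        sig2 = np.exp(2.0 * log_sig)
        resid2 = np.sum((y[None, :] - beta @ X.T) ** 2, axis=1)
        ll = -0.5 * (y.size * np.log(2 * np.pi * sig2) + resid2 / sig2)
        return ll - 0.5 * np.exp(log_sig) ** 2 + log_sig  # half-normal prior + Jacobian

    for it in range(warmup + draws):
        sig2 = np.exp(2.0 * log_sigma)
        # conjugate joint update of (intercept, slope) | sigma
        for c in range(chains):
            prec = np.eye(2) + XtX / sig2[c]
            cov = np.linalg.inv(prec)
            mean = cov @ (Xty / sig2[c])
            beta[c] = rng.multivariate_normal(mean, cov)
        prop = log_sigma + step * rng.standard_normal(chains)
        lp_cur = logpost_sigma(log_sigma, beta)
        lp_prop = logpost_sigma(prop, beta)
        accept = np.log(rng.random(chains)) < lp_prop - lp_cur
        log_sigma = np.where(accept, prop, log_sigma)
        accepts += accept
        if it < warmup and (it + 1) % 50 == 0:
            step *= np.exp(np.clip(accepts / 50.0 - 0.44, -0.5, 0.5))
            accepts[:] = 0.0
        if it >= warmup:
            coef_out[:, it - warmup] = beta
            sigma_out[:, it - warmup] = np.exp(log_sigma)

    natural = np.empty_like(coef_out)
    natural[..., 1] = coef_out[..., 1] / sx
    natural[..., 0] = coef_out[..., 0] - coef_out[..., 1] * mx / sx
    fit = RegressionFit(
        outcome=outcome,
        intercept=PosteriorSummary.from_draws("intercept", natural[..., 0]),
        slope=PosteriorSummary.from_draws("slope", natural[..., 1]),
        sigma=PosteriorSummary.from_draws("sigma", sigma_out),
        n=len(joined),
        _coef_draws=natural,
    )
    if not fit.converged:
        logger.warning("polygyny regression failed convergence gates")
    return fit
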