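"""Two-stage latent-treatment causal effect estimation.

The treatment of interest — a latent tumor construct — is never observed
directly; a high-dimensional block of radiomics features U measures it,
and clinical covariates X confound it. Because the latent variable
d-separates both the features and the outcome from the confounders, a
two-stage strategy identifies a local causal effect (LCE):

1. Regress the feature block on the confounders with multivariate PLS and
   take the first-component scores t_1 = X r_1, rescaled to unit variance,
   as the inferred latent treatment z_hat.
2. Regress the continuous working response on z_hat by ordinary least
   squares; the slope is the LCE, reported per standard deviation of the
   inferred treatment (the latent scale is indeterminate, so a fixed
   per-SD convention keeps bootstrap replicates comparable).

Confidence intervals come from the nonparametric bootstrap: subjects are
resampled with replacement and the *entire* pipeline — outcome
preparation, standardization, PLS, outcome regression — is re-run per
replicate, with replicate signs aligned to the original rotation (the
latent direction is only identified up to sign).

z_hat lies exactly in the column space of X, so the outcome regression
cannot also adjust for X (the design would be singular); the d-separation
assumption Y independent of X given Z is what licenses the unadjusted
fit. A first-principal-component baseline, which instead summarizes U
ignoring X and adjusts for the confounders explicitly, is provided for
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import (ConfounderMatrix, StandardizedMatrix, complete_cases,
                        encode_confounders, standardize)
from .kernel_pls import PLSModel, dominant_eigenvector, fit_kernel_pls
from .outcome_prep import (OutcomeSpec, SurvivalOutcome, WorkingResponse,
                           martingale_residuals, prepare_outcome)

logger = logging.getLogger(__name__)


@dataclass
class LatentScores:
    """Inferred latent treatment: unit-variance first-component PLS scores."""

    z_hat: np.ndarray
    components_used: int
    orientation_anchor: np.ndarray  # r_1, the first rotation
    model: PLSModel
    all_scores: np.ndarray  # n x l, each column standardized to unit variance


def infer_latent_treatment(U_std: np.ndarray, X_std: np.ndarray,
                           l: int = 1) -> LatentScores:
    """Infer the latent treatment as PLS scores of features U on confounders X.

    Fits multivariate PLS with X (n x p) as predictors and U (n x K) as the
    multivariate response, and returns the first-component score
    t_1 = X r_1 centered and rescaled to unit variance. The rotation r_1
    (already sign-fixed by the PLS orientation convention) is kept as the
    anchor against which bootstrap replicates align their signs.
    """
    U_std = _values(U_std)
    X_std = _values(X_std)
    model = fit_kernel_pls(X_std, U_std, l)
    scores = model.scores - model.scores.mean(axis=0)
    sds = scores.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("degenerate PLS score with zero variance")
    scores = scores / sds
    return LatentScores(z_hat=scores[:, 0], components_used=l,
                        orientation_anchor=model.rotations[:, 0].copy(),
                        model=model, all_scores=scores)


def _values(mat):
    if isinstance(mat, StandardizedMatrix):
        return mat.values
    return np.asarray(mat, dtype=float)


@dataclass
class OutcomeRegression:
    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    n: int


def fit_outcome_regression(y, z) -> OutcomeRegression:
    """OLS of the working response on (1, z_hat); the slope is the LCE."""
    if isinstance(y, WorkingResponse):
        y = y.y
    if isinstance(z, LatentScores):
        z = z.z_hat
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape:
        raise ValueError("y and z must have the same length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if y.max() == y.min():  # constant response: the slope is identically zero
        return OutcomeRegression(slope=0.0, intercept=float(y[0]),
                                 residual_sd=0.0, r_squared=0.0, n=n)
    yc = y - y.mean()
    zc = z - z.mean()
    szz = zc @ zc
    if szz == 0.0:
        raise ValueError("latent score has zero variance")
    slope = (yc @ zc) / szz
    intercept = y.mean() - slope * z.mean()
    resid = yc - slope * zc
    syy = yc @ yc
    r2 = 0.0 if syy == 0.0 else 1.0 - (resid @ resid) / syy
    residual_sd = float(np.sqrt((resid @ resid) / max(n - 2, 1)))
    return OutcomeRegression(slope=float(slope), intercept=float(intercept),
                             residual_sd=residual_sd, r_squared=float(r2), n=n)


@dataclass
class RawOutcome:
    """Outcome columns in raw (pre-working-response) form.

    The bootstrap must recompute the working response inside each replicate
    — for survival outcomes the Nelson-Aalen hazard, and hence the
    martingale residuals, depend on which subjects were resampled.
    """

    kind: str
    values: np.ndarray | None = None  # continuous values or 0/1 labels
    times: np.ndarray | None = None
    events: np.ndarray | None = None

    @classmethod
    def from_working(cls, resp: WorkingResponse, table=None,
                     spec: OutcomeSpec | None = None) -> "RawOutcome":
        if resp.kind == "survival":
            return cls(kind="survival",
                       times=pd.to_numeric(table[spec.time_column]).to_numpy(float),
                       events=pd.to_numeric(table[spec.event_column]).to_numpy(float))
        return cls(kind=resp.kind, values=resp.y.copy())

    def working(self, idx: np.ndarray) -> np.ndarray:
        if self.kind == "survival":
            surv = SurvivalOutcome(times=self.times[idx], events=self.events[idx])
            return martingale_residuals(surv).y
        return self.values[idx]

    @property
    def n(self) -> int:
        arr = self.values if self.values is not None else self.times
        return arr.shape[0]


@dataclass
class CausalEstimate:
    """Point estimate of the local causal effect with bootstrap interval."""

    lce: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_boot: int
    n_used: int
    seed: int
    boot_replicates: np.ndarray
    dropped_subjects: int = 0
    dropped_features: int = 0
    components_used: int = 1
    outcome_kind: str = "continuous"
    n_boot_failed: int = 0
    per_component_lce: list = field(default_factory=list)
    z_hat: np.ndarray | None = None
    subject_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lce": self.lce, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "ci_level": self.ci_level, "n_boot": self.n_boot,
            "n_used": self.n_used, "seed": self.seed,
            "dropped_subjects": self.dropped_subjects,
            "dropped_features": self.dropped_features,
            "components_used": self.components_used,
            "outcome_kind": self.outcome_kind,
            "n_boot_failed": self.n_boot_failed,
            "per_component_lce": list(self.per_component_lce),
        }


@dataclass
class EstimatorConfig:
    seed: int
    l: int = 1
    n_boot: int = 1000
    ci_level: float = 0.95

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class BootstrapResult:
    ci_lower: float
    ci_upper: float
    replicates: np.ndarray
    n_failed: int


def bootstrap_ci(fit_once, n: int, n_boot: int, ci_level: float, seed,
                 orientation_anchor: np.ndarray) -> BootstrapResult:
    """Percentile bootstrap over subject resamples.

    ``fit_once(idx)`` re-runs the full pipeline on the rows ``idx`` and
    returns ``(lce, r1)``; each replicate LCE is multiplied by
    sign(r1 . orientation_anchor) so that replicates estimating the
    latent direction with flipped sign are comparable. Degenerate
    replicates (e.g. a resample with a constant confounder column) are
    skipped; more than 20% failures is an error.
    """
    if n_boot < 50:
        warnings.warn("n_boot < 50: percentile interval will be unreliable",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            lce_b, r1_b = fit_once(idx)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.debug("bootstrap replicate failed: %s", exc)
            continue
        s = np.sign(r1_b @ orientation_anchor)
        reps.append(lce_b * (s if s != 0 else 1.0))
    if n_failed > 0.2 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed; "
            "data too degenerate for interval estimation"
        )
    reps = np.asarray(reps)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(ci_lower=float(lo), ci_upper=float(hi),
                           replicates=reps, n_failed=n_failed)


def estimate_lce_arrays(U_raw: np.ndarray, X_raw: np.ndarray,
                        outcome: RawOutcome, config: EstimatorConfig,
                        ) -> CausalEstimate:
    """Run the two-stage estimator on aligned raw arrays.

    Standardization, outcome preparation and PLS are all treated as part of
    the estimator and re-run inside every bootstrap replicate.
    """
    U_raw = np.asarray(U_raw, dtype=float)
    X_raw = np.asarray(X_raw, dtype=float)
    n = U_raw.shape[0]
    if X_raw.shape[0] != n or outcome.n != n:
        raise ValueError("U, X and outcome must be row-aligned")

    def fit_once(idx):
        U_std = standardize(U_raw[idx], on_constant="drop")
        X_std = standardize(X_raw[idx], on_constant="error")
        y = outcome.working(idx)
        scores = infer_latent_treatment(U_std.values, X_std.values, config.l)
        per_comp = [fit_outcome_regression(y, scores.all_scores[:, b]).slope
                    for b in range(config.l)]
        return per_comp, scores

    full_idx = np.arange(n)
    per_comp, scores = fit_once(full_idx)
    anchor = scores.orientation_anchor

    def fit_boot(idx):
        per_comp_b, scores_b = fit_once(idx)
        return per_comp_b[0], scores_b.orientation_anchor

    boot = bootstrap_ci(fit_boot, n, config.n_boot, config.ci_level,
                        np.random.default_rng(config.seed), anchor)
    return CausalEstimate(
        lce=per_comp[0], ci_lower=boot.ci_lower, ci_upper=boot.ci_upper,
        ci_level=config.ci_level, n_boot=config.n_boot, n_used=n,
        seed=config.seed, boot_replicates=boot.replicates,
        components_used=config.l, outcome_kind=outcome.kind,
        n_boot_failed=boot.n_failed, per_component_lce=per_comp,
        z_hat=scores.z_hat,
    )


def estimate_lce(features: pd.DataFrame, clinical: pd.DataFrame,
                 covariate_schema, spec: OutcomeSpec,
                 config: EstimatorConfig) -> CausalEstimate:
    """End-to-end pipeline from raw tables to a causal estimate.

    encode -> complete cases -> prepare outcome -> standardize ->
    PLS latent scores -> outcome regression -> bootstrap interval.
    """
    conf = encode_confounders(clinical, covariate_schema)
    feat, conf, clin, report = complete_cases(features, conf, clinical,
                                              spec.columns)
    resp = prepare_outcome(clin, spec)
    raw = RawOutcome.from_working(resp, table=clin, spec=spec)

    n_feat_before = feat.shape[1]
    trial = standardize(feat.to_numpy(float), on_constant="drop")
    dropped_features = n_feat_before - trial.values.shape[1]

    est = estimate_lce_arrays(feat.to_numpy(float),
                              conf.values.to_numpy(float), raw, config)
    est.dropped_subjects = report.dropped_count
    est.dropped_features = dropped_features
    est.subject_ids = list(feat.index)
    return est


@dataclass
class PCABaselineFit:
    """OLS of the outcome on the first principal component of U plus confounders."""

    intercept: float
    pc1_coefficient: float
    confounder_coefficients: np.ndarray
    confounder_names: list[str]
    standard_errors: np.ndarray  # ordered (intercept, pc1, confounders...)
    pc1_scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "pc1_coefficient": self.pc1_coefficient,
            "confounder_coefficients": dict(zip(self.confounder_names,
                                                map(float,
                                                    self.confounder_coefficients))),
            "standard_errors": {
                "intercept": float(self.standard_errors[0]),
                "pc1": float(self.standard_errors[1]),
                **{name: float(se) for name, se
                   in zip(self.confounder_names, self.standard_errors[2:])},
            },
        }


def pca_baseline(U_std, confounders, y) -> PCABaselineFit:
    """First-principal-component regression baseline.

    PC1 is the projection of the standardized feature block on the dominant
    eigenvector of its covariance; the outcome is then regressed on
    (1, PC1, confounders) by OLS with conventional standard errors. Unlike
    the PLS estimator, this summarizes U without reference to X and adjusts
    for the confounders explicitly.
    """
    import statsmodels.api as sm

    U_std = _values(U_std)
    if isinstance(confounders, ConfounderMatrix):
        conf_names = confounders.column_names
        C = confounders.values.to_numpy(float)
    elif isinstance(confounders, pd.DataFrame):
        conf_names = list(confounders.columns)
        C = confounders.to_numpy(float)
    else:
        C = np.asarray(confounders, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        conf_names = [f"x{j}" for j in range(C.shape[1])]
    if isinstance(y, WorkingResponse):
        y = y.y
    y = np.asarray(y, dtype=float)
    n, p = C.shape
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations for the baseline fit")

    cov = U_std.T @ U_std / (n - 1)
    v = dominant_eigenvector(cov)
    pc1 = U_std @ v

    design = np.column_stack([np.ones(n), pc1, C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("baseline design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    return PCABaselineFit(
        intercept=float(fit.params[0]), pc1_coefficient=float(fit.params[1]),
        confounder_coefficients=np.asarray(fit.params[2:], dtype=float),
        confounder_names=conf_names,
        standard_errors=np.asarray(fit.bse, dtype=float),
        pc1_scores=pc1,
    )
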