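"""Behavioral inference and data-exclusion machinery.

* ``accuracy_validity_model`` — the behavioral cueing effect: a mixed
  logistic regression of accuracy on cue validity with by-participant
  random intercepts and validity slopes.
* ``rt_model`` — task-difficulty check: a linear mixed model of reaction
  time on ordinal cue eccentricity with random intercepts and slopes.
* ``bf01_staircase_efficacy`` — staircase-efficacy check: a one-factor
  repeated-measures Bayes factor (default JZS priors, BIC fallback) on
  valid-trial accuracy per cued eccentricity; BF01 > 3 reads as
  substantial evidence that the staircases equated difficulty.
* ``performance_deviance`` / ``iterative_exclusion`` — the absolute
  performance-deviance score and the loop that drops the most deviant
  participants until the staircase-efficacy null is supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln, logsumexp

from .windowstats import ECC_CODE, LmeResult

__all__ = [
    "BfResult",
    "DevianceScore",
    "ExclusionResult",
    "accuracy_validity_model",
    "rt_model",
    "bf01_staircase_efficacy",
    "performance_deviance",
    "iterative_exclusion",
    "jzs_bf01_oneway_rm",
]


@dataclass(frozen=True)
class BfResult:
    bf01: float
    method: str
    n_participants: int

    def __post_init__(self):
        if not self.bf01 > 0:
            raise ValueError("bf01 must be positive")


@dataclass(frozen=True)
class DevianceScore:
    participant_id: str
    acc_near: float
    acc_medium: float
    acc_far: float
    acc_overall: float
    deviance: float


@dataclass
class ExclusionResult:
    kept: list
    dropped: list
    bf_trace: list
    status: str  # passed | failed


# ---------------------------------------------------------------------------
# JZS Bayes factor for a one-way repeated-measures design


def _log_invgamma_half(g: float, h: float) -> float:
    # scaled inverse-chi-square(1, h^2) == InvGamma(1/2, h^2/2)
    return (0.5 * np.log(h * h / 2.0) - gammaln(0.5)
            - 1.5 * np.log(g) - h * h / (2.0 * g))


def _log_marginal(y: np.ndarray, gram_blocks: list, gs: list) -> float:
    """Log marginal likelihood (up to a model-independent constant).

    Linear model y = mu*1 + sum_b X_b theta_b + e with theta_b ~
    N(0, g_b sigma^2 I) and the Jeffreys prior on (mu, sigma^2); theta is
    integrated analytically, leaving V = I + sum_b g_b X_b X_b'.
    """
    n = y.size
    v = np.eye(n)
    for p, g in zip(gram_blocks, gs):
        v += g * p
    c, low = cho_factor(v, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    one = np.ones(n)
    vi1 = cho_solve((c, low), one)
    viy = cho_solve((c, low), y)
    a = one @ vi1
    q = y @ viy - (one @ viy) ** 2 / a
    return -0.5 * logdet - 0.5 * np.log(a) - 0.5 * (n - 1) * np.log(q)


def _integrate_g(y, gram_blocks, scales, n_nodes=64, lo=-18.0, hi=12.0):
    """log of the g-integrated marginal via trapezoid on log(g) axes."""
    u = np.linspace(lo, hi, n_nodes)
    du = u[1] - u[0]
    if len(gram_blocks) == 1:
        vals = np.array([
            _log_marginal(y, gram_blocks, [np.exp(ui)])
            + _log_invgamma_half(np.exp(ui), scales[0]) + ui
            for ui in u])
        return logsumexp(vals) + np.log(du)
    vals = np.empty((n_nodes, n_nodes))
    for i, ui in enumerate(u):
        for j, uj in enumerate(u):
            g = [np.exp(ui), np.exp(uj)]
            vals[i, j] = (_log_marginal(y, gram_blocks, g)
                          + _log_invgamma_half(g[0], scales[0])
                          + _log_invgamma_half(g[1], scales[1]) + ui + uj)
    return logsumexp(vals) + 2.0 * np.log(du)


def jzs_bf01_oneway_rm(acc: np.ndarray, h_fixed: float = 0.5,
                       h_random: float = 1.0, n_nodes: int = 64) -> float:
    """BF01 for a one-factor within-participant design (rows = participants).

    Default-prior (JZS) ANOVA formulation: the condition factor enters
    through an orthonormalized, centered contrast design with a g-prior of
    scale ``h_fixed``; participants enter as a random nuisance factor with
    scale ``h_random``.  Both models (null: participants only;
    alternative: participants + condition) integrate g over its default
    scaled-inverse-chi-square prior; BF01 is the ratio of the marginals.
    """
    acc = np.asarray(acc, dtype=np.float64)
    n, k = acc.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    y = acc.ravel()  # participant-major
    # orthonormal contrast columns spanning the centered condition space
    sig = np.eye(k) - np.ones((k, k)) / k
    w, q = np.linalg.eigh(sig)
    qc = q[:, w > 0.5]  # k x (k-1)
    x_cond = np.tile(qc, (n, 1))
    x_subj = np.kron(np.eye(n), np.ones((k, 1)))
    p_cond = x_cond @ x_cond.T
    p_subj = x_subj @ x_subj.T
    log_m1 = _integrate_g(y, [p_cond, p_subj], [h_fixed, h_random], n_nodes)
    log_m0 = _integrate_g(y, [p_subj], [h_random], n_nodes)
    return float(np.exp(log_m0 - log_m1))


def _bic_bf01_oneway_rm(acc: np.ndarray) -> float:
    """BIC-approximation fallback: exp((BIC_alt - BIC_null) / 2)."""
    import statsmodels.formula.api as smf

    n, k = acc.shape
    df = pd.DataFrame({
        "y": acc.ravel(),
        "subj": np.repeat(np.arange(n), k).astype(str),
        "cond": np.tile(np.arange(k), n).astype(str),
    })
    null = smf.ols("y ~ C(subj)", df).fit()
    alt = smf.ols("y ~ C(subj) + C(cond)", df).fit()
    return float(np.exp((alt.bic - null.bic) / 2.0))


# ---------------------------------------------------------------------------
# behavioral mixed models


def _analyzed(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials
    if "phase" in t:
        t = t[t["phase"] == "experimental"]
    if "excluded" in t:
        t = t[~t["excluded"].astype(bool)]
    return t[np.isfinite(t["accuracy"].to_numpy(np.float64))]


def accuracy_validity_model(trials: pd.DataFrame) -> LmeResult:
    """Mixed logistic regression of accuracy on cue validity.

    Invalid trials are the reference level; by-participant random
    intercepts and random validity slopes (binomial GLMM, variational
    Bayes fit; the reported statistic is a posterior z).  Participants
    observed at only one validity level are dropped with a warning.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    d = _analyzed(trials).copy()
    n_lvl = d.groupby("participant_id", observed=True)["validity"].nunique()
    bad = n_lvl[n_lvl < 2].index
    if len(bad):
        warnings.warn(f"dropping participants with a single validity level: {list(bad)}")
        d = d[~d["participant_id"].isin(bad)]
    if d["participant_id"].nunique() < 2:
        raise ValueError("at least 2 participants with both validity levels required")
    d["valid01"] = (d["validity"] == "valid").astype(float)
    d["acc"] = d["accuracy"].astype(float)
    d["pid"] = d["participant_id"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = BinomialBayesMixedGLM.from_formula(
            "acc ~ valid01",
            {"icept": "0 + C(pid)", "slope": "0 + C(pid):valid01"}, d)
        # deterministic start (the library default draws it from the
        # global RNG, which would break run-to-run reproducibility)
        npar = md.k_fep + md.k_vcp + md.k_vc
        res = md.fit_vb(mean=np.zeros(npar), sd=np.full(npar, np.exp(-0.5)))
    i = list(res.model.exog_names).index("valid01")
    b, se = float(res.fe_mean[i]), float(res.fe_sd[i])
    z = b / se
    return LmeResult(term="cue_validity[valid]", b=b, se=se, stat=z,
                     p=float(2 * stats.norm.sf(abs(z))),
                     converged=True, random_structure="intercepts_and_slopes")


def rt_model(trials: pd.DataFrame) -> LmeResult:
    """Linear mixed model of reaction time (ms) on ordinal cue eccentricity.

    By-participant random intercepts and eccentricity slopes; downgraded to
    intercepts only if the slopes model does not converge.
    """
    import statsmodels.api as sm

    d = _analyzed(trials)
    d = d[np.isfinite(d["rt_ms"].to_numpy(np.float64))]
    if d["participant_id"].nunique() < 2:
        raise ValueError("at least 2 participants required")
    y = d["rt_ms"].to_numpy(np.float64)
    code = d["cued_ecc"].map(ECC_CODE).to_numpy(np.float64)
    exog = np.column_stack([np.ones(len(d)), code])
    groups = d["participant_id"].to_numpy()

    def _fit(slopes: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, exog, groups=groups,
                            exog_re=exog if slopes else exog[:, :1])
            res = md.fit(reml=True)
        ok = bool(getattr(res, "converged", True)) and np.isfinite(res.bse[1])
        return res, ok

    res, ok = _fit(True)
    structure = "intercepts_and_slopes"
    if not ok:
        res, ok = _fit(False)
        structure = "intercepts_only"
    return LmeResult(term="cue_eccentricity", b=float(res.params[1]),
                     se=float(res.bse[1]), stat=float(res.tvalues[1]),
                     p=float(res.pvalues[1]), converged=ok,
                     random_structure=structure)


# ---------------------------------------------------------------------------
# staircase efficacy and exclusion


def _valid_accuracy_matrix(trials: pd.DataFrame):
    """Per-participant mean valid-trial accuracy per cued eccentricity."""
    d = _analyzed(trials)
    d = d[d["validity"] == "valid"]
    pv = d.pivot_table(index="participant_id", columns="cued_ecc",
                       values="accuracy", aggfunc="mean", observed=True)
    want = ["near", "medium", "far"]
    for c in want:
        if c not in pv.columns:
            pv[c] = np.nan
    pv = pv[want]
    incomplete = pv.index[pv.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn("dropping participants with missing eccentricity cells: "
                      f"{list(incomplete)}")
        pv = pv.dropna()
    return pv


def bf01_staircase_efficacy(trials: pd.DataFrame) -> BfResult:
    """Bayes factor for the null of equal valid-trial accuracy across
    cued eccentricities (one-factor repeated-measures design)."""
    pv = _valid_accuracy_matrix(trials)
    if len(pv) < 2:
        raise ValueError("need >= 2 participants with valid trials at all "
                         "three eccentricities")
    acc = pv.to_numpy(np.float64)
    try:
        bf01 = jzs_bf01_oneway_rm(acc)
        method = "jzs(h_fixed=0.5, h_random=1)"
        if not np.isfinite(bf01) or bf01 <= 0:
            raise FloatingPointError
    except Exception:
        bf01 = _bic_bf01_oneway_rm(acc)
        method = "bic-approximation"
    return BfResult(bf01=bf01, method=method, n_participants=len(pv))


def performance_deviance(acc_near: float, acc_medium: float, acc_far: float,
                         participant_id: str = "",
                         printed_formula: bool = False) -> DevianceScore:
    """Absolute performance deviance across the three eccentricities.

    ``acc_overall`` is the unweighted mean of the three accuracies and the
    deviance sums the absolute deviations of each eccentricity from it.
    ``printed_formula=True`` reproduces a published variant that counts the
    near term twice and omits the far term.
    """
    for a in (acc_near, acc_medium, acc_far):
        if not 0 <= a <= 1:
            raise ValueError("accuracies must lie in [0, 1]")
    overall = (acc_near + acc_medium + acc_far) / 3.0
    if acc_near == acc_medium == acc_far:
        # deviance is identically zero at equality (avoid roundoff residue)
        return DevianceScore(participant_id=participant_id, acc_near=acc_near,
                             acc_medium=acc_medium, acc_far=acc_far,
                             acc_overall=overall, deviance=0.0)
    if printed_formula:
        dev = 2 * abs(acc_near - overall) + abs(acc_medium - overall)
    else:
        dev = (abs(acc_near - overall) + abs(acc_medium - overall)
               + abs(acc_far - overall))
    return DevianceScore(participant_id=participant_id, acc_near=acc_near,
                         acc_medium=acc_medium, acc_far=acc_far,
                         acc_overall=overall, deviance=dev)


def iterative_exclusion(trials: pd.DataFrame, target_n: int,
                        bf_threshold: float = 3.0) -> ExclusionResult:
    """Iteratively drop the most performance-deviant participants until the
    staircase-efficacy Bayes factor supports the null (BF01 > threshold).

    Ties in deviance break by participant id order.  If the cohort is
    exhausted before the criterion is met the result status is
    ``"failed"``.  A warning notes when fewer than ``target_n``
    participants remain.
    """
    pv = _valid_accuracy_matrix(trials)
    kept = list(pv.index)
    dropped: list = []
    bf_trace: list = []
    while True:
        if len(kept) < 2:
            return ExclusionResult(kept=kept, dropped=dropped,
                                   bf_trace=bf_trace, status="failed")
        acc = pv.loc[kept].to_numpy(np.float64)
        try:
            bf01 = jzs_bf01_oneway_rm(acc)
        except Exception:
            bf01 = _bic_bf01_oneway_rm(acc)
        bf_trace.append(float(bf01))
        if bf01 > bf_threshold:
            if len(kept) < target_n:
                warnings.warn(f"{len(kept)} participants retained, below the "
                              f"target sample size of {target_n}")
            return ExclusionResult(kept=kept, dropped=dropped,
                                   bf_trace=bf_trace, status="passed")
        devs = [(performance_deviance(*pv.loc[p], participant_id=str(p)).deviance, str(p))
                for p in kept]
        # tie-break: among equal deviances drop the earliest participant id
        top = max(d[0] for d in devs)
        worst_pid = sorted(p for d, p in devs if d == top)[0]
        kept = [p for p in kept if str(p) != worst_pid]
        dropped.append(worst_pid)
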