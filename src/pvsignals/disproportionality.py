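"""Disproportionality indices for drug-event signal detection.

For each drug-event pair the whole database collapses to a 2x2 table

====================  ===========  ==============
..                    event        all other events
====================  ===========  ==============
drug primary suspect  a            b
all other reports     c            d
====================  ===========  ==============

with N = a + b + c + d, and four indices are computed:

* **ROR** (reporting odds ratio) ``ad/bc`` with the log-normal 95% interval
  ``exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``;
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` paired
  with the 2x2 Pearson chi-square (no Yates correction by default);
* **BCPNN information component**: the plug-in point value
  ``IC = log2[a N / ((a+b)(a+c))]`` and the closed-form Bayesian lower
  credibility bound ``IC025 = E(IC) - 2 sqrt(V(IC))`` under the standard
  unit priors (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2);
* **MGPS**: by default the simplified empirical-Bayes variant in which the
  point value is the relative reporting ratio ``a N / ((a+b)(a+c))`` and
  ``EB05 = exp(ln EBGM - 1.645 sqrt(1/a + 1/b + 1/c + 1/d))``; the full
  DuMouchel gamma-Poisson shrinker (mixture-of-gammas prior fitted by
  marginal maximum likelihood, posterior geometric mean and exact posterior
  5th percentile) is available via :func:`fit_mgps_prior` /
  :func:`ebgm_full`.

A pair is a *combined-positive* signal only when all four indices pass
their conventional thresholds (see :class:`Thresholds`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    UndefinedEstimateError,
)
from .reports import ROLE_PRIMARY, ReportSet, normalize_name, normalize_pt

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair against the rest of the database."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def haldane(self) -> tuple[float, float, float, float]:
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass
class Thresholds:
    """Positivity cut-offs (field-standard defaults).

    ROR: lower 95% bound > 1 with at least ``min_a`` cases; PRR: PRR >= 2
    and chi-square >= 4 with at least ``min_a`` cases; BCPNN: IC025 > 0;
    MGPS: EB05 > 2.
    """

    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    eb05_min: float = 2.0
    ror_lo_min: float = 1.0
    ci_level: float = 0.95

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must lie in (0, 1)")


@dataclass
class SignalScores:
    """All four indices, interval bounds and positivity flags for one pair."""

    drug: str = ""
    pt: str = ""
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    eb05: float = math.nan
    positive_ror: bool = False
    positive_prr: bool = False
    positive_bcpnn: bool = False
    positive_mgps: bool = False
    positive_combined: bool = False


def build_contingency(
    rs: ReportSet, drug: str, event_pt: str, counting_unit: str = "report"
) -> ContingencyTable:
    """Count the 2x2 table for (drug as primary suspect, event PT).

    ``counting_unit="report"`` counts deduplicated reports (a report listing
    the PT twice counts once); ``"pair"`` counts distinct report-PT pairs,
    a sensitivity variant in which the margins are event mentions.
    """
    if counting_unit not in ("report", "pair"):
        raise ConfigurationError(f"unknown counting unit {counting_unit!r}")
    dnorm = normalize_name(drug)
    enorm = normalize_pt(event_pt)
    a = b = c = d = 0
    for r in rs.reports:
        has_drug = r.has_primary_suspect({dnorm})
        pts = r.event_pts_norm()
        if counting_unit == "report":
            has_event = enorm in pts
            if has_drug and has_event:
                a += 1
            elif has_drug:
                b += 1
            elif has_event:
                c += 1
            else:
                d += 1
        else:  # one unit per distinct report-PT pair
            for pt in pts:
                if has_drug and pt == enorm:
                    a += 1
                elif has_drug:
                    b += 1
                elif pt == enorm:
                    c += 1
                else:
                    d += 1
    t = ContingencyTable(a, b, c, d)
    if t.n == 0:
        raise DegenerateInputError("contingency table is empty (N = 0)")
    return t


def _z(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


def _cells(t: ContingencyTable, continuity: str) -> tuple[float, float, float, float]:
    if continuity == "haldane":
        return t.haldane()
    if continuity != "none":
        raise ConfigurationError(f"unknown continuity mode {continuity!r}")
    for name, v in zip("abcd", (t.a, t.b, t.c, t.d)):
        if v == 0:
            raise UndefinedEstimateError(
                f"cell {name} is zero; ROR undefined without continuity correction",
                cell=name,
            )
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def ror_score(
    t: ContingencyTable, ci_level: float = 0.95, continuity: str = "none"
) -> tuple[float, float, float]:
    """Reporting odds ratio with its two-sided log-normal interval.

    ``continuity="haldane"`` adds 0.5 to every cell first, making the
    estimate finite for tables with a zero cell.
    """
    a, b, c, d = _cells(t, continuity)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _z(ci_level)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def prr_score(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and the (uncorrected) Pearson
    chi-square of the 2x2 table.  ``c = 0`` yields an infinite PRR; the
    chi-square is still computed."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or a + c == 0:
        raise DegenerateInputError("PRR requires non-zero drug rows and event column")
    prr = (a / (a + b)) / (c / (c + d)) if c > 0 else math.inf
    if prr is math.inf:
        logger.info("prr_score: c = 0, PRR infinite")
    n = t.n
    chi2 = 0.0
    for obs, rm, cm in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        exp = rm * cm / n
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    return prr, chi2


# BCPNN hyperparameters: unit priors on the joint cell and margins
_G11 = 1.0  # gamma11
_A1 = 1.0  # alpha1 (drug margin)
_B1 = 1.0  # beta1  (event margin)
_AL = 2.0  # alpha
_BE = 2.0  # beta

_LN2 = math.log(2.0)


def bcpnn_ic(t: ContingencyTable, variant: str = "plugin") -> tuple[float, float]:
    """BCPNN information component and its lower credibility bound.

    The point value is the plug-in ``log2[a N / ((a+b)(a+c))]`` (the
    closed-form posterior expectation ``E(IC)`` via ``variant="posterior"``,
    and automatically when ``a = 0`` where the plug-in is undefined).
    ``IC025 = E(IC) - 2 sqrt(V(IC))`` always uses the closed-form posterior
    moments, so it is finite and negative even for ``a = 0``.
    """
    a, n = t.a, t.n
    cx = t.a + t.b  # drug margin
    cy = t.a + t.c  # event margin
    if cx == 0 or cy == 0:
        raise DegenerateInputError("BCPNN requires non-zero drug and event margins")

    gamma = _G11 * (n + _AL) * (n + _BE) / ((cx + _A1) * (cy + _B1))
    e_ic = math.log2(
        (a + _G11) * (n + _AL) * (n + _BE) / ((n + gamma) * (cx + _A1) * (cy + _B1))
    )
    v_ic = (
        (n - a + gamma - _G11) / ((a + _G11) * (1 + n + gamma))
        + (n - cx + _AL - _A1) / ((cx + _A1) * (1 + n + _AL))
        + (n - cy + _BE - _B1) / ((cy + _B1) * (1 + n + _BE))
    ) / (_LN2 ** 2)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)

    if variant == "posterior" or a == 0:
        ic = e_ic
    elif variant == "plugin":
        ic = math.log2(a * n / (cx * cy))
    else:
        raise ConfigurationError(f"unknown BCPNN variant {variant!r}")
    return ic, ic025


def ebgm_simple(t: ContingencyTable, continuity: str = "none") -> tuple[float, float]:
    """Simplified MGPS: point value = relative reporting ratio
    ``a N / ((a+b)(a+c))``; EB05 is the one-sided 95% lower bound
    ``exp(ln EBGM - 1.645 sqrt(1/a + 1/b + 1/c + 1/d))``."""
    a, b, c, d = _cells(t, continuity)
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, ebgm * math.exp(-1.645 * se)


# --------------------------------------------------------------------------
# full DuMouchel gamma-Poisson shrinker

@dataclass(frozen=True)
class MgpsPrior:
    """Five hyperparameters of the two-component gamma mixture prior on the
    relative reporting rate lambda: lambda ~ p Gamma(alpha1, rate beta1) +
    (1-p) Gamma(alpha2, rate beta2)."""

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    p_mix: float = 1.0 / 3.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie strictly inside (0, 1)")


#: conventional starting point for the marginal-likelihood fit
DEFAULT_MGPS_START = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    p = special.expit(theta[4])
    l1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    l2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    m = np.logaddexp(np.log(p) + l1, np.log1p(-p) + l2)
    return float(m.sum())


def fit_mgps_prior(
    counts,
    expected,
    start: MgpsPrior = DEFAULT_MGPS_START,
    maxiter: int = 2000,
) -> tuple[MgpsPrior, dict]:
    """Fit the mixture-of-gammas prior by marginal maximum likelihood.

    ``counts`` are the observed cell counts a over all drug-event pairs and
    ``expected`` the independence-expected counts E = (a+b)(a+c)/N.  The
    negative-binomial marginal of the gamma-Poisson model is maximized with
    L-BFGS-B on log/logit-transformed hyperparameters from ``start``.
    Returns the fitted prior and a fit-info dict (objective history, start
    and final log-likelihood).  Raises :class:`ConvergenceError` when the
    optimizer fails to improve the objective.
    """
    a = np.asarray(counts, dtype=np.int64)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape:
        raise ConfigurationError("counts and expected must have identical shapes")
    if a.size < 100:
        raise DegenerateInputError(f"MGPS prior fit needs >= 100 cells, got {a.size}")
    if (e <= 0).any():
        raise DegenerateInputError("expected counts must be positive")

    theta0 = np.array(
        [
            math.log(start.alpha1),
            math.log(start.beta1),
            math.log(start.alpha2),
            math.log(start.beta2),
            special.logit(start.p_mix),
        ]
    )
    history: list[float] = []

    def nll(theta):
        ll = _mixture_loglik(theta, a, e)
        history.append(ll)
        return -ll

    res = optimize.minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": maxiter})
    ll_start = _mixture_loglik(theta0, a, e)
    ll_final = -float(res.fun)
    if not res.success and ll_final < ll_start:
        raise ConvergenceError(
            f"MGPS prior fit failed to improve the marginal likelihood: {res.message}",
            trace=history,
        )
    a1, b1, a2, b2 = np.exp(res.x[:4])
    p = float(special.expit(res.x[4]))
    prior = MgpsPrior(float(a1), float(b1), float(a2), float(b2), p)
    info = {
        "loglik_start": ll_start,
        "loglik_final": ll_final,
        "n_eval": len(history),
        "converged": bool(res.success),
        "history": history,
    }
    logger.info(
        "fit_mgps_prior: loglik %.2f -> %.2f in %d evaluations", ll_start, ll_final, len(history)
    )
    return prior, info


def _posterior_mixture(a: int, e: float, prior: MgpsPrior):
    """Posterior over lambda given count a and expected e: gamma mixture
    with updated shapes/rates and marginal-likelihood mixing weight."""
    l1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    l2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    logw1 = math.log(prior.p_mix) + l1
    logw2 = math.log1p(-prior.p_mix) + l2
    mx = max(logw1, logw2)
    w1 = math.exp(logw1 - mx)
    w2 = math.exp(logw2 - mx)
    tot = w1 + w2
    w1, w2 = w1 / tot, w2 / tot
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    return (w1, w2), shapes, rates


def ebgm_full(t: ContingencyTable, prior: MgpsPrior) -> tuple[float, float]:
    """Full-MGPS posterior summary for one table under a fitted prior.

    EBGM is the posterior geometric mean ``2**E[log2 lambda | a]`` (digamma
    closed form per component); EB05 is the exact posterior 5th percentile,
    found by root-finding on the monotone mixture CDF.
    """
    e = t.expected
    if e <= 0:
        raise DegenerateInputError("expected count must be positive")
    (w1, w2), (s1, s2), (r1, r2) = _posterior_mixture(t.a, e, prior)
    elog = w1 * (special.digamma(s1) - math.log(r1)) + w2 * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(elog)

    def cdf(x):
        return w1 * stats.gamma.cdf(x, s1, scale=1.0 / r1) + w2 * stats.gamma.cdf(
            x, s2, scale=1.0 / r2
        )

    hi = ebgm if ebgm > 0 else 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
    lo = hi
    while cdf(lo) > 0.05 and lo > 1e-300:
        lo /= 2.0
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return ebgm, eb05


def classify_signal(s: SignalScores, th: Thresholds) -> SignalScores:
    """Fill the four positivity flags and their conjunction.  NaN scores
    never satisfy a threshold."""
    pos_ror = bool(s.ror_lo > th.ror_lo_min and s.a >= th.min_a)
    pos_prr = bool(s.prr >= th.prr_min and s.chi2 >= th.chi2_min and s.a >= th.min_a)
    pos_bcpnn = bool(s.ic025 > th.ic025_min)
    pos_mgps = bool(s.eb05 > th.eb05_min)
    return replace(
        s,
        positive_ror=pos_ror,
        positive_prr=pos_prr,
        positive_bcpnn=pos_bcpnn,
        positive_mgps=pos_mgps,
        positive_combined=pos_ror and pos_prr and pos_bcpnn and pos_mgps,
    )


def score_table(
    t: ContingencyTable,
    thresholds: Thresholds | None = None,
    drug: str = "",
    pt: str = "",
    mgps: str = "simple",
    prior: MgpsPrior | None = None,
    continuity: str = "none",
    bcpnn_variant: str = "plugin",
) -> SignalScores:
    """Compute all four indices for one table and classify.  Pairs whose
    estimates are undefined (zero cell, no correction) keep NaN scores and
    all-false flags rather than raising."""
    th = thresholds or Thresholds()
    s = SignalScores(drug=drug, pt=pt, a=t.a, b=t.b, c=t.c, d=t.d)
    try:
        s.ror, s.ror_lo, s.ror_hi = ror_score(t, th.ci_level, continuity)
    except UndefinedEstimateError:
        pass
    try:
        s.prr, s.chi2 = prr_score(t)
    except DegenerateInputError:
        pass
    try:
        s.ic, s.ic025 = bcpnn_ic(t, bcpnn_variant)
    except DegenerateInputError:
        pass
    try:
        if mgps == "full":
            if prior is None:
                raise ConfigurationError("full MGPS requires a fitted prior")
            s.ebgm, s.eb05 = ebgm_full(t, prior)
        else:
            s.ebgm, s.eb05 = ebgm_simple(t, continuity)
    except (UndefinedEstimateError, DegenerateInputError):
        pass
    return classify_signal(s, th)


def contingency_counts(rs: ReportSet, drugs: list[str], events: list[str]):
    """Vectorized 2x2 counts for every (drug, event) pair.

    Returns ``(A, drug_margin, event_margin, N)`` where ``A[i, j]`` is the
    number of reports with drug i as primary suspect carrying event j.
    """
    dnorm = [normalize_name(d) for d in drugs]
    enorm = [normalize_pt(e) for e in events]
    didx = {d: i for i, d in enumerate(dnorm)}
    eidx = {e: j for j, e in enumerate(enorm)}
    n = len(rs.reports)
    ps = np.zeros((n, len(dnorm)), dtype=bool)
    ev = np.zeros((n, len(enorm)), dtype=bool)
    for i, r in enumerate(rs.reports):
        for m in r.drugs:
            if m.role == ROLE_PRIMARY:
                j = didx.get(m.drug_name_norm)
                if j is not None:
                    ps[i, j] = True
        for em in r.events:
            j = eidx.get(normalize_pt(em.pt))
            if j is not None:
                ev[i, j] = True
    a = ps.T.astype(np.int64) @ ev.astype(np.int64)
    return a, ps.sum(axis=0).astype(np.int64), ev.sum(axis=0).astype(np.int64), n


def score_all_pairs(
    rs: ReportSet,
    drugs: list[str] | None = None,
    events: list[str] | None = None,
    thresholds: Thresholds | None = None,
    min_a: int = 1,
    include_zero: bool = False,
    mgps: str = "simple",
    prior: MgpsPrior | None = None,
    continuity: str = "none",
) -> pd.DataFrame:
    """Score every (drug, event) pair of the database.

    ``drugs``/``events`` default to all primary-suspect drug names and all
    PTs observed in the report set.  Pairs with ``a < min_a`` (default 1)
    are excluded unless ``include_zero``; zero-cell pairs carry NaN
    estimates and negative flags.  Returns one row per pair.
    """
    if rs.meta.get("dedup_removed") is None:
        logger.warning("score_all_pairs: report set has no deduplication marker")
    if drugs is None:
        drugs = sorted(
            {m.drug_name_norm for r in rs.reports for m in r.drugs if m.role == ROLE_PRIMARY}
        )
    if events is None:
        events = sorted({normalize_pt(e.pt) for r in rs.reports for e in r.events})
    if not drugs or not events:
        return pd.DataFrame(columns=_SCORE_COLUMNS)
    amat, dmar, emar, n = contingency_counts(rs, drugs, events)
    if mgps == "full" and prior is None:
        e_all = np.outer(dmar, emar) / n
        ok = e_all.ravel() > 0
        prior, _ = fit_mgps_prior(amat.ravel()[ok], e_all.ravel()[ok])
    rows = []
    for i, drug in enumerate(drugs):
        for j, event in enumerate(events):
            a = int(amat[i, j])
            if a < min_a and not include_zero:
                continue
            t = ContingencyTable(a, int(dmar[i] - a), int(emar[j] - a),
                                 int(n - dmar[i] - emar[j] + a))
            s = score_table(
                t, thresholds, drug=drug, pt=event, mgps=mgps, prior=prior,
                continuity=continuity,
            )
            rows.append(s.__dict__.copy())
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


_SCORE_COLUMNS = [
    "drug", "pt", "a", "b", "c", "d",
    "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "eb05",
    "positive_ror", "positive_prr", "positive_bcpnn", "positive_mgps", "positive_combined",
]


def reconstruct_contingency(
    ror: float,
    ror_lo: float,
    ror_hi: float,
    n_total: int,
    prr: float | None = None,
    a_min: int = 3,
    a_max: int = 274,
) -> tuple[ContingencyTable, float]:
    """Recover an integer 2x2 table from a published ROR and its 95% interval.

    For each candidate case count ``a`` the interval width fixes the
    standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``, which together with the
    point ROR and the known database size pins ``b`` and ``c`` (as the roots
    of a quadratic; the two root assignments are transposes with identical
    observed/expected statistics).  The published ROR and interval alone
    leave the case count weakly identified, so when a published ``prr`` is
    supplied its log-error joins the objective, which resolves ``a`` because
    PRR/ROR ~ b/(a+b).  Returns the best table and its squared log-error.
    """
    z = _z(0.95)
    se_target = math.log(ror_hi / ror_lo) / (2.0 * z)
    s2 = se_target ** 2

    best: tuple[float, ContingencyTable] | None = None
    for a in range(a_min, a_max + 1):
        rem = s2 - 1.0 / a
        if rem <= 0:
            continue
        # fixed-point on d (d ~ N dominates): solve b+c and b*c
        d_est = float(n_total - a)
        bc = ror and a * d_est / ror
        for _ in range(5):
            r = rem - 1.0 / d_est
            if r <= 0:
                break
            ssum = r * bc
            disc = ssum * ssum - 4.0 * bc
            if disc < 0:
                break
            root = math.sqrt(disc)
            b_f, c_f = (ssum + root) / 2.0, (ssum - root) / 2.0
            d_est = float(n_total - a - b_f - c_f)
            bc = a * d_est / ror
        else:
            pass
        r = rem - 1.0 / d_est
        if r <= 0 or d_est <= 0:
            continue
        ssum = r * bc
        disc = ssum * ssum - 4.0 * bc
        if disc < 0:
            continue
        root = math.sqrt(disc)
        cand = []
        for b_f in ((ssum + root) / 2.0, (ssum - root) / 2.0):
            c_f = bc / b_f if b_f > 0 else 0.0
            for bi in (math.floor(b_f), math.ceil(b_f)):
                for ci in (math.floor(c_f), math.ceil(c_f)):
                    di = n_total - a - bi - ci
                    if bi > 0 and ci > 0 and di > 0:
                        cand.append((bi, ci, di))
        for bi, ci, di in cand:
            t = ContingencyTable(a, bi, ci, di)
            try:
                r_hat, lo_hat, hi_hat = ror_score(t)
            except UndefinedEstimateError:
                continue
            err = (
                math.log(r_hat / ror) ** 2
                + math.log(lo_hat / ror_lo) ** 2
                + math.log(hi_hat / ror_hi) ** 2
            )
            if prr is not None:
                p_hat, _ = prr_score(t)
                err += math.log(p_hat / prr) ** 2
            if best is None or err < best[0]:
                best = (err, t)
    if best is None:
        raise DegenerateInputError(
            "no integer table is consistent with the published ROR and interval"
        )
    return best[1], best[0]
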