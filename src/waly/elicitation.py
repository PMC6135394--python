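"""Impaired welfare weight (IWW) elicitation.

The pipeline mirrors the paired-comparison approach used for disability
weights in burden-of-disease studies:

1. *Probit scaling.* Each answered paired comparison contributes a signed
   contrast row (+1 first impediment, -1 second) with outcome 1 when the
   first was judged to have better welfare. A probit regression on these
   contrasts recovers latent severities on an arbitrary interval scale; one
   reference impediment is pinned at 0 (the scale is location-free, and the
   final weights are invariant to this choice).
2. *Anchoring.* Five impediments are valued absolutely on a visual analogue
   scale (IWW = mean of 1 - value/100) and by time trade-off (IWW = mean of
   1 - years/10). A locally weighted (tricube, degree-1) regression of the
   anchors' logit-IWWs on their probit coefficients maps the whole latent
   scale onto the logit-IWW scale; the span starts at 0.75 and widens until
   the fit is well-posed, falling back to ordinary least squares.
3. *Uncertainty.* For each impediment, draws from a logit-normal
   distribution (normal on the logit scale with the predicted mean and
   prediction standard error, inverse-logit transformed) are summarised by
   their mean and 2.5th/97.5th percentiles.

Six model variants are produced: {VAS, TTO} x {all five anchors, without
"respiratory distress", without "cancer: lung metastasis ..."}; the extra
variants probe the rank inconsistency between the paired-comparison and
anchor orderings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .survey import AnchorResponse, PairedDesignRow

logger = logging.getLogger(__name__)

LOGIT_CLIP = 1e-4  # anchor IWWs are clipped to [LOGIT_CLIP, 1-LOGIT_CLIP]

#: Canonical variant labels mapped to the anchor impediment they exclude.
VARIANTS: dict[str, str | None] = {
    "all_anchors": None,
    "minus_respiratory_distress": "respiratory_distress",
    "minus_cancer_lung_metastasis": "cancer_lung_metastasis",
}


class ElicitationError(ValueError):
    pass


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Probit scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbitScale:
    """Latent severities from paired-comparison probit regression.

    Larger coefficient means more severe; the reference impediment is
    fixed at exactly 0.
    """

    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    reference_impediment_id: str
    n_rows: int

    def __post_init__(self) -> None:
        ref = self.coefficients.get(self.reference_impediment_id)
        if ref != 0.0:
            raise ElicitationError("reference coefficient must be exactly 0")

    @property
    def impediment_ids(self) -> list[str]:
        return list(self.coefficients)


def _check_connected(rows: Sequence[PairedDesignRow], ids: Sequence[str]) -> None:
    index = {imp: i for i, imp in enumerate(ids)}
    n = len(ids)
    r, c = [], []
    for row in rows:
        i, j = index[row.first_impediment], index[row.second_impediment]
        r += [i, j]
        c += [j, i]
    graph = csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        comps = [
            [imp for imp, k in zip(ids, labels) if k == lab]
            for lab in range(n_comp)
        ]
        raise ElicitationError(
            "comparison graph is disconnected; components: "
            + "; ".join("{" + ", ".join(c) + "}" for c in comps)
        )


def _probit_score(eta: np.ndarray, y: np.ndarray):
    """Per-row score factor lambda and curvature weight for probit.

    lambda = phi/Phi for successes and -phi/(1-Phi) for failures, computed
    on the log scale for numerical stability at extreme linear predictors;
    the observed-information weight is lambda * (lambda + eta).
    """
    from scipy.special import log_ndtr

    log_pdf = -0.5 * eta**2 - 0.5 * math.log(2 * math.pi)
    lam = np.where(
        y > 0.5,
        np.exp(log_pdf - log_ndtr(eta)),
        -np.exp(log_pdf - log_ndtr(-eta)),
    )
    w = lam * (lam + eta)
    return lam, np.clip(w, 0.0, None)


def fit_probit_scale(
    design: Sequence[PairedDesignRow],
    reference: str,
    ridge_alpha: float = 0.01,
) -> ProbitScale:
    """Probit severities from the signed contrast design by penalized ML.

    The recorded outcome is "first impediment chosen as *better* welfare",
    so the contrast matrix is negated before fitting; the returned
    coefficients then increase with severity. The reference impediment's
    coefficient is fixed at 0 and the comparison graph must be connected
    for the remaining contrasts to be identifiable.

    ``ridge_alpha`` weights a small ridge on all pairwise coefficient
    differences. The penalty depends only on severity contrasts, so the
    estimates remain invariant to the reference choice, and it keeps
    coefficients finite when an impediment wins or loses every one of its
    comparisons (quasi-separation). With ``ridge_alpha=0`` the fit is pure
    maximum likelihood and genuinely separated data raise an error.
    """
    if not design:
        raise ElicitationError("empty design")
    if ridge_alpha < 0:
        raise ElicitationError("ridge_alpha must be >= 0")
    ids: list[str] = []
    for row in design:
        for imp in (row.first_impediment, row.second_impediment):
            if imp not in ids:
                ids.append(imp)
    if reference not in ids:
        raise ElicitationError(
            f"reference {reference!r} does not appear in the design"
        )
    _check_connected(design, ids)

    free = [i for i in ids if i != reference]
    col = {imp: k for k, imp in enumerate(free)}
    X = np.zeros((len(design), len(free)))
    y = np.empty(len(design))
    for r, row in enumerate(design):
        # negate so that a positive coefficient marks worse welfare
        if row.first_impediment != reference:
            X[r, col[row.first_impediment]] = -1.0
        if row.second_impediment != reference:
            X[r, col[row.second_impediment]] = 1.0
        y[r] = row.outcome

    if ridge_alpha == 0.0:
        # pure ML: an impediment judged better (or worse) in every single
        # comparison has no finite maximum-likelihood severity
        better: dict[str, int] = {i: 0 for i in ids}
        worse: dict[str, int] = {i: 0 for i in ids}
        for row in design:
            if row.outcome == 1:
                better[row.first_impediment] += 1
                worse[row.second_impediment] += 1
            else:
                worse[row.first_impediment] += 1
                better[row.second_impediment] += 1
        degenerate = [
            i for i in ids if better[i] == 0 or worse[i] == 0
        ]
        if degenerate:
            raise ElicitationError(
                "perfect separation: "
                + ", ".join(degenerate)
                + " judged uniformly better or worse in every comparison; "
                "collect more comparisons or penalize (ridge_alpha > 0)"
            )

    from scipy.special import log_ndtr

    m = len(ids)  # impediments incl. reference; penalty spans all of them
    a = ridge_alpha / max(m - 1, 1)
    k = len(free)

    def objective(beta):
        eta = X @ beta
        nll = -float(np.sum(np.where(y > 0.5, log_ndtr(eta), log_ndtr(-eta))))
        s = beta.sum()
        pen = 0.5 * a * (m * float(beta @ beta) - s * s)
        return nll + pen

    beta = np.zeros(k)
    obj = objective(beta)
    converged = False
    for _ in range(200):
        eta = X @ beta
        lam, w = _probit_score(eta, y)
        grad = -X.T @ lam + a * (m * beta - beta.sum())
        if np.max(np.abs(grad)) < 1e-9:
            converged = True
            break
        H = (X.T * w) @ X + a * (m * np.eye(k) - np.ones((k, k)))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ElicitationError(
                "probit information matrix is singular (perfect "
                "separation); collect more comparisons or penalize"
            ) from exc
        # backtracking line search on the strictly convex objective
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            cand_obj = objective(cand)
            if cand_obj <= obj:
                beta, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            converged = np.max(np.abs(grad)) < 1e-6
            break
        if ridge_alpha == 0.0 and np.max(np.abs(beta)) > 12.0:
            raise ElicitationError(
                "probit coefficients diverging (perfect separation); "
                "collect more comparisons or penalize (ridge_alpha > 0)"
            )
    if not converged and np.max(np.abs(grad)) > 1e-6:
        raise ElicitationError(
            "probit fit did not converge; collect more comparisons or "
            "penalize (ridge_alpha > 0)"
        )
    if not np.all(np.isfinite(beta)):
        raise ElicitationError(
            "probit fit produced non-finite coefficients; likely perfect "
            "separation — collect more comparisons or penalize"
        )

    eta = X @ beta
    _lam, w = _probit_score(eta, y)
    H = (X.T * w) @ X + a * (m * np.eye(k) - np.ones((k, k)))
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.inf)

    coefs = {reference: 0.0}
    ses = {reference: 0.0}
    for imp in free:
        coefs[imp] = float(beta[col[imp]])
        ses[imp] = float(bse[col[imp]])
    return ProbitScale(
        coefficients=coefs,
        standard_errors=ses,
        reference_impediment_id=reference,
        n_rows=len(design),
    )


# ---------------------------------------------------------------------------
# Anchor values (VAS / TTO)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchorSet:
    """Per-impediment anchor IWWs for one method (vas or tto)."""

    method: str
    entries: Mapping[str, tuple[float, float, int]]  # mean, sample sd, n
    excluded_anchor: str | None = None

    def exclude(self, impediment_id: str) -> "AnchorSet":
        if impediment_id not in self.entries:
            raise ElicitationError(
                f"anchor {impediment_id!r} not present; cannot exclude"
            )
        entries = {k: v for k, v in self.entries.items() if k != impediment_id}
        if len(entries) < 2:
            raise ElicitationError("need at least two anchors after exclusion")
        return AnchorSet(self.method, entries, excluded_anchor=impediment_id)

    def means(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.entries.items()}


def _anchor_entries(
    responses: Iterable[AnchorResponse], method: str, scale: float
) -> AnchorSet:
    lo, hi = 0.0, scale
    by_imp: dict[str, list[float]] = {}
    for r in responses:
        if r.method != method:
            continue
        if not (lo <= r.value <= hi):
            raise ElicitationError(
                f"{method} value {r.value} for {r.impediment_id!r} outside "
                f"[{lo}, {hi}]; filter responses first"
            )
        by_imp.setdefault(r.impediment_id, []).append(1.0 - r.value / scale)
    entries = {}
    for imp, vals in by_imp.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        entries[imp] = (float(arr.mean()), sd, len(arr))
    return AnchorSet(method=method, entries=entries)


def anchor_iww_from_vas(responses: Iterable[AnchorResponse]) -> AnchorSet:
    """Mean of (1 - placement/100) per impediment, with SD and n."""
    return _anchor_entries(responses, "vas", 100.0)


def anchor_iww_from_tto(responses: Iterable[AnchorResponse]) -> AnchorSet:
    """Mean of (1 - traded years/10) per impediment, with SD and n."""
    return _anchor_entries(responses, "tto", 10.0)


# ---------------------------------------------------------------------------
# Loess anchoring
# ---------------------------------------------------------------------------


@dataclass
class AnchorMap:
    """Local-regression map from probit coefficient to logit-IWW.

    ``x``/``y`` are the anchor coefficients and logit-IWWs. ``span`` is the
    span at which the fit succeeded; ``used_ols`` marks the least-squares
    fallback. ``span_trace`` records the adaptation path.
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    used_ols: bool
    span_trace: list[float] = field(default_factory=list)
    sigma: float = 0.0
    _ols_coef: np.ndarray | None = None
    _ols_cov: np.ndarray | None = None

    def _local_weight_vector(self, x0: float) -> np.ndarray:
        """Equivalent-kernel weights l(x0) with sum(l * y) = prediction."""
        n = len(self.x)
        # at least four neighbours: the farthest carries zero tricube
        # weight, so fewer would leave the local line underdetermined
        q = max(4, math.ceil(self.span * n))
        q = min(q, n)
        d = np.abs(self.x - x0)
        order = np.argsort(d, kind="stable")
        dmax = d[order[q - 1]]
        if dmax == 0.0:
            raise ElicitationError("all anchors at identical coefficient")
        w = np.zeros(n)
        idx = order[:q]
        u = d[idx] / dmax
        w[idx] = np.clip(1.0 - u**3, 0.0, None) ** 3
        X = np.column_stack([np.ones(n), self.x - x0])
        WX = w[:, None] * X
        A = X.T @ WX
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise ElicitationError("singular local system") from exc
        if np.linalg.cond(A) > 1e10:
            raise ElicitationError("ill-conditioned local system")
        return (Ainv @ WX.T)[0]

    def predict(self, coef: float) -> tuple[float, float]:
        """Prediction mean and standard error at a probit coefficient.

        Beyond the anchor range the boundary local fit extrapolates
        linearly (flagged in the log).
        """
        if coef < self.x.min() - 1e-12 or coef > self.x.max() + 1e-12:
            logger.debug(
                "extrapolating anchor map at coefficient %.3f outside "
                "[%.3f, %.3f]", coef, self.x.min(), self.x.max()
            )
        if self.used_ols:
            assert self._ols_coef is not None and self._ols_cov is not None
            xv = np.array([1.0, coef])
            mean = float(xv @ self._ols_coef)
            se = float(math.sqrt(max(xv @ self._ols_cov @ xv, 0.0)))
            return mean, se
        l = self._local_weight_vector(float(coef))
        mean = float(l @ self.y)
        se = float(self.sigma * math.sqrt(l @ l))
        return mean, se


def fit_anchor_map(
    scale: ProbitScale,
    anchors: AnchorSet,
    span_start: float = 0.75,
    span_step: float = 0.05,
) -> AnchorMap:
    """Fit the loess map of logit(anchor IWW) on probit coefficient.

    The span starts at ``span_start`` and widens in ``span_step`` increments
    until the smoother is well-posed (non-singular local systems and
    positive residual degrees of freedom); if the span passes 1 the map
    falls back to ordinary least squares on the anchor points.
    """
    items = [
        (imp, scale.coefficients[imp], mean)
        for imp, (mean, _sd, _n) in anchors.entries.items()
        if imp in scale.coefficients
    ]
    missing = [imp for imp in anchors.entries if imp not in scale.coefficients]
    if missing:
        raise ElicitationError(
            "anchors without probit coefficients: " + ", ".join(missing)
        )
    if len(items) < 2:
        raise ElicitationError("need at least two anchors to fit the map")
    x = np.array([c for _, c, _ in items])
    y = logit(np.clip([m for _, _, m in items], LOGIT_CLIP, 1.0 - LOGIT_CLIP))
    if np.ptp(x) == 0.0:
        raise ElicitationError("all anchors at identical coefficient")

    trace: list[float] = []
    span = span_start
    while span <= 1.0 + 1e-9:
        trace.append(round(span, 4))
        m = AnchorMap(x=x, y=y, span=min(span, 1.0), used_ols=False,
                      span_trace=list(trace))
        try:
            L = np.vstack([m._local_weight_vector(xi) for xi in x])
        except ElicitationError:
            span += span_step
            continue
        fitted = L @ y
        df = len(x) - float(np.trace(L))
        if df <= 1e-9:
            span += span_step
            continue
        rss = float(np.sum((y - fitted) ** 2))
        m.sigma = math.sqrt(max(rss, 0.0) / df)
        if len(trace) > 1:
            logger.debug("anchor-map span adapted: %s", trace)
        return m

    # ordinary least squares fallback on the anchor points
    logger.debug("anchor-map span reached 1 without success; OLS fallback")
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = max(len(x) - 2, 1)
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    return AnchorMap(
        x=x, y=y, span=1.0, used_ols=True, span_trace=trace,
        sigma=math.sqrt(s2), _ols_coef=coef, _ols_cov=cov,
    )


def predict_iwws(
    mapping: AnchorMap, scale: ProbitScale
) -> dict[str, tuple[float, float]]:
    """Predicted (logit mean, prediction SE) for every impediment."""
    return {
        imp: mapping.predict(coef)
        for imp, coef in scale.coefficients.items()
    }


# ---------------------------------------------------------------------------
# Monte Carlo propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IWWEstimate:
    """Final IWW for one impediment: mean and 95% UI on [0,1]."""

    impediment_id: str
    logit_mean: float
    logit_se: float
    mean: float
    ui_low: float
    ui_high: float
    method: str
    variant: str
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ui_low <= self.ui_high <= 1.0
                and 0.0 <= self.mean <= 1.0):
            raise ElicitationError(
                f"{self.impediment_id}: UI outside [0,1] "
                f"({self.ui_low}, {self.mean}, {self.ui_high})"
            )
        if not self.ui_low <= self.mean <= self.ui_high:
            # possible for extremely skewed logit-normals (huge SE near a
            # boundary): the mean can leave the central 95% interval
            logger.warning(
                "%s: mean %.4f outside its 95%% UI (%.4f, %.4f); "
                "prediction SE is extreme", self.impediment_id,
                self.mean, self.ui_low, self.ui_high,
            )


def propagate_iww_uncertainty(
    predictions: Mapping[str, tuple[float, float]],
    n_sims: int = 100_000,
    seed: int = 0,
    method: str = "",
    variant: str = "",
) -> list[IWWEstimate]:
    """Summarise logit-normal draws per impediment.

    Draws z ~ Normal(logit_mean, logit_se) are inverse-logit transformed;
    the estimate carries the draw mean and the 2.5th/97.5th percentiles.
    A zero SE collapses the interval onto the point prediction. Each
    impediment gets its own name-keyed stream, so results do not depend on
    the order in which impediments appear.
    """
    import zlib

    if n_sims < 1:
        raise ElicitationError("n_sims must be >= 1")
    out = []
    for imp, (mu, se) in predictions.items():
        rng = np.random.default_rng([seed, zlib.crc32(imp.encode())])
        if se < 0:
            raise ElicitationError(f"{imp}: negative standard error")
        if se == 0.0:
            p = float(inv_logit(mu))
            out.append(
                IWWEstimate(imp, mu, se, p, p, p, method, variant, n_sims, seed)
            )
            continue
        draws = inv_logit(rng.normal(mu, se, n_sims))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out.append(
            IWWEstimate(
                impediment_id=imp,
                logit_mean=float(mu),
                logit_se=float(se),
                mean=float(draws.mean()),
                ui_low=float(lo),
                ui_high=float(hi),
                method=method,
                variant=variant,
                n_sims=n_sims,
                seed=seed,
            )
        )
    return out


def elicit_iwws(
    design: Sequence[PairedDesignRow],
    anchors: AnchorSet,
    variant: str = "all_anchors",
    reference: str | None = None,
    n_sims: int = 100_000,
    seed: int = 0,
    scale: ProbitScale | None = None,
) -> list[IWWEstimate]:
    """Full pipeline for one method/variant: probit -> loess -> Monte Carlo."""
    if variant not in VARIANTS:
        raise ElicitationError(f"unknown variant {variant!r}")
    if scale is None:
        if reference is None:
            reference = design[0].first_impediment
        scale = fit_probit_scale(design, reference)
    excluded = VARIANTS[variant]
    a = anchors.exclude(excluded) if excluded else anchors
    mapping = fit_anchor_map(scale, a)
    predictions = predict_iwws(mapping, scale)
    return propagate_iww_uncertainty(
        predictions, n_sims=n_sims, seed=seed,
        method=anchors.method, variant=variant,
    )


def run_variants(
    design: Sequence[PairedDesignRow],
    anchors_vas: AnchorSet,
    anchors_tto: AnchorSet,
    reference: str | None = None,
    n_sims: int = 100_000,
    seed: int = 0,
) -> dict[tuple[str, str], list[IWWEstimate]]:
    """The six model variants: {vas, tto} x three anchor subsets.

    The probit scale is fitted once and shared; each variant gets its own
    deterministic sub-seed so results are reproducible per table.
    """
    if reference is None:
        reference = design[0].first_impediment
    scale = fit_probit_scale(design, reference)
    tables: dict[tuple[str, str], list[IWWEstimate]] = {}
    for k, (method, anchors) in enumerate(
        [("vas", anchors_vas), ("tto", anchors_tto)]
    ):
        for j, variant in enumerate(VARIANTS):
            sub_seed = (seed + 1000 * k + 100 * j) % (2**31)
            tables[(method, variant)] = elicit_iwws(
                design, anchors, variant=variant, scale=scale,
                n_sims=n_sims, seed=sub_seed,
            )
    return tables


def estimates_to_frame(estimates: Iterable[IWWEstimate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "impediment": e.impediment_id,
                "method": e.method,
                "variant": e.variant,
                "mean": e.mean,
                "ui_low": e.ui_low,
                "ui_high": e.ui_high,
                "logit_mean": e.logit_mean,
                "logit_se": e.logit_se,
                "n_sims": e.n_sims,
                "seed": e.seed,
            }
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankInconsistency:
    impediment_a: str
    impediment_b: str
    coefficient_a: float
    coefficient_b: float
    anchor_a: float
    anchor_b: float


def check_rank_consistency(
    scale: ProbitScale, anchors: AnchorSet
) -> list[RankInconsistency]:
    """Anchor pairs whose probit severity order contradicts the anchor order.

    An empty list means the paired-comparison ranking and the direct
    valuation ranking agree on all shared impediments.
    """
    shared = [i for i in anchors.entries if i in scale.coefficients]
    if len(shared) < 2:
        raise ElicitationError("need at least two shared impediments")
    out = []
    means = anchors.means()
    for i, a in enumerate(shared):
        for b in shared[i + 1:]:
            dc = scale.coefficients[a] - scale.coefficients[b]
            da = means[a] - means[b]
            if dc * da < 0:
                out.append(
                    RankInconsistency(
                        a, b,
                        scale.coefficients[a], scale.coefficients[b],
                        means[a], means[b],
                    )
                )
    return out


GROUPINGS = (
    "gender",
    "age_lt_36",
    "graduation_lt_2005",
    "interest_small_animal",
    "works_with_livestock",
)


def _group_of(profile, grouping: str) -> str:
    if grouping == "gender":
        return "a" if profile.gender.lower().startswith("f") else "b"
    if grouping == "age_lt_36":
        return "a" if profile.age < 36 else "b"
    if grouping == "graduation_lt_2005":
        return "a" if profile.graduation_year < 2005 else "b"
    if grouping == "interest_small_animal":
        return "a" if profile.interest_small_animal else "b"
    if grouping == "works_with_livestock":
        return "a" if profile.works_with_livestock else "b"
    raise ElicitationError(f"unknown grouping {grouping!r}")


def subgroup_compare(
    anchors: Iterable[AnchorResponse],
    respondents,
    grouping: str,
    alpha: float = 0.05,
) -> list[dict]:
    """Welch two-sample t-test of anchor IWWs across a binary demographic.

    Returns one record per (method, impediment) with subgroup means, the
    t statistic and p value, and a significance flag at ``alpha``. Pairs
    where either subgroup has fewer than two responses are reported with a
    skip reason instead of a test.
    """
    groups = {p.respondent_id: _group_of(p, grouping) for p in respondents}
    cells: dict[tuple[str, str], dict[str, list[float]]] = {}
    for r in anchors:
        g = groups.get(r.respondent_id)
        if g is None:
            continue
        scale = 100.0 if r.method == "vas" else 10.0
        cell = cells.setdefault((r.method, r.impediment_id), {"a": [], "b": []})
        cell[g].append(1.0 - r.value / scale)
    out = []
    for (method, imp), cell in sorted(cells.items()):
        a, b = np.asarray(cell["a"]), np.asarray(cell["b"])
        rec = {
            "method": method,
            "impediment": imp,
            "grouping": grouping,
            "n_a": len(a),
            "n_b": len(b),
            "mean_a": float(a.mean()) if len(a) else math.nan,
            "mean_b": float(b.mean()) if len(b) else math.nan,
        }
        if len(a) < 2 or len(b) < 2:
            rec.update(t=math.nan, p_value=math.nan, significant=False,
                       skipped="subgroup with fewer than 2 responses")
            out.append(rec)
            continue
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            # degenerate: no within-group variance
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(t), float(p)
        rec.update(t=t, p_value=p, significant=bool(p < alpha), skipped=None)
        out.append(rec)
    return out
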