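"""Ranked species occupancy curves (RSOC) and multimodel OFD inference.

For each SRS, a taxon's relative occupancy O_i is the fraction of the SRS's
ARSs containing it; ranking the O_i in decreasing order gives the RSOC. Five
regression models — one per canonical occupancy-frequency-distribution (OFD)
shape — are fitted by Levenberg-Marquardt least squares:

=====================  ==============================  ====================
model                  equation                        OFD pattern
=====================  ==============================  ====================
exponential concave    O = y0 + a*exp(-b*R)            unimodal (satellite)
power exponential      O = a*R^b * exp(-c*R)           bimodal if b > 0,
                                                       unimodal if b <= 0
sigmoidal symmetric    O = a / (1 + exp(-b*R + c))     bimodal
sigmoidal asymmetric   O = a * (1 - exp(-b*R^c))       bimodal
linear                 O = a*R + b                     uniform / random
=====================  ==============================  ====================

Model support is quantified by small-sample AICc and Akaike weights; weights
are summed per OFD pattern family (the power exponential counts toward the
bimodal family only when its fitted exponent b is positive, since only then
does the curve have an inflection point).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import leastsq

from .resampling import SRS

logger = logging.getLogger("streamofd")

#: Relative floor for RSS (times n) guarding AICc against exact fits.
RSS_FLOOR_PER_POINT = 1e-12

#: Default minimum taxa number for fitting: n - k - 1 >= 1 for k = 4.
MIN_TAXA_FOR_FIT = 6


# ---------------------------------------------------------------------------
# RSOC construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSOC:
    """Ranked species occupancy curve of one SRS (optionally one group)."""

    ranks: np.ndarray  # 1..S
    occupancy: np.ndarray  # descending, in (0, 1]
    taxa: tuple[str, ...]
    group: str = "all"
    srs_index: int = -1

    @property
    def S(self) -> int:
        return len(self.ranks)


def occupancies(
    srs: SRS,
    taxa_subset: Iterable[str] | None = None,
    group: str = "all",
) -> RSOC | None:
    """Relative occupancy per taxon over the SRS's retained ARSs, ranked.

    Taxa absent from every ARS are excluded. Ties in occupancy are broken by
    taxon identifier so runs are reproducible. Returns None (and the caller
    should log/skip) when no taxon of the subset occurs.
    """
    pres = srs.presence_matrix()  # (n_ars, n_taxa)
    ids = np.asarray(srs.taxon_ids)
    if taxa_subset is not None:
        keep = np.isin(ids, np.asarray(sorted(taxa_subset)))
        pres = pres[:, keep]
        ids = ids[keep]
    occ = pres.mean(axis=0)
    nz = occ > 0
    if not nz.any():
        return None
    occ, ids = occ[nz], ids[nz]
    order = np.lexsort((ids, -occ))  # descending occupancy, ties by id
    occ, ids = occ[order], ids[order]
    return RSOC(
        ranks=np.arange(1, len(occ) + 1, dtype=float),
        occupancy=occ,
        taxa=tuple(ids),
        group=group,
        srs_index=srs.index,
    )


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One RSOC regression model: curve, initial parameters, pattern family."""

    name: str
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    param_names: tuple[str, ...]
    x0: tuple[float, ...]
    family: str  # 'unimodal' | 'bimodal' | 'random' | 'power_exp' (sign-dependent)
    jac: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None


def _exp_concave(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    y0, a, b = p
    return y0 + a * np.exp(-b * R)


def _exp_concave_jac(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    _, a, b = p
    e = np.exp(-b * R)
    return np.column_stack([np.ones_like(R), e, -a * R * e])


def _power_exp(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    return a * np.power(R, b) * np.exp(-c * R)


def _power_exp_jac(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    base = np.power(R, b) * np.exp(-c * R)
    f = a * base
    return np.column_stack([base, f * np.log(R), -R * f])


def _sig_symmetric(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    return a / (1.0 + np.exp(-b * R + c))


def _sig_symmetric_jac(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    u = np.exp(-b * R + c)
    denom = (1.0 + u) ** 2
    return np.column_stack([1.0 / (1.0 + u), a * R * u / denom, -a * u / denom])


def _sig_asymmetric(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    return a * (1.0 - np.exp(-b * np.power(R, c)))


def _sig_asymmetric_jac(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b, c = p
    rc = np.power(R, c)
    v = np.exp(-b * rc)
    return np.column_stack([1.0 - v, a * rc * v, a * b * rc * np.log(R) * v])


def _linear(p: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, b = p
    return a * R + b


#: The five-model candidate set with its published starting values. The
#: power-exponential starting values are mapped positionally onto (a, b, c).
DEFAULT_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("exp_concave", _exp_concave, ("y0", "a", "b"), (0.01, 1.0, 0.01),
              "unimodal", _exp_concave_jac),
    ModelSpec("power_exp", _power_exp, ("a", "b", "c"), (1.0, 0.01, 0.01),
              "power_exp", _power_exp_jac),
    ModelSpec("sig_symmetric", _sig_symmetric, ("a", "b", "c"), (1.0, -0.1, -1.0),
              "bimodal", _sig_symmetric_jac),
    ModelSpec("sig_asymmetric", _sig_asymmetric, ("a", "b", "c"), (1.0, -1.0, -1.0),
              "bimodal", _sig_asymmetric_jac),
    ModelSpec("linear", _linear, ("a", "b"), (0.0, 0.0), "random"),
)

MODELS_BY_NAME: Mapping[str, ModelSpec] = {m.name: m for m in DEFAULT_MODELS}


# ---------------------------------------------------------------------------
# Fitting, AICc, Akaike weights
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    rss: float
    n: int
    k: int  # regression parameters + 1 (residual variance)
    converged: bool
    aicc: float = float("nan")
    weight: float = 0.0
    rss_floored: bool = False


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample AIC for an OLS fit: n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss <= 0:
        raise ValueError("rss must be positive (apply the floor first)")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_model(
    rsoc: RSOC,
    spec: ModelSpec,
    max_iter: int = 999,
    tol: float = 1e-8,
    x0: Sequence[float] | None = None,
) -> ModelFit:
    """Least-squares fit of one RSOC model (damped/LM, published start values).

    Requires S >= k + 2 so the AICc denominator stays positive; smaller
    curves yield a non-converged (skipped) fit. Non-finite optima are also
    reported as non-converged and excluded from the weight set by the caller.
    """
    R, O = rsoc.ranks, rsoc.occupancy
    k = len(spec.param_names) + 1
    n = rsoc.S
    empty = ModelFit(spec.name, {}, float("nan"), n, k, converged=False)
    if n < k + 2:
        logger.debug("model %s skipped: S=%d < %d", spec.name, n, k + 2)
        return empty

    if spec.name == "linear":  # closed-form OLS
        A = np.column_stack([R, np.ones_like(R)])
        coef, *_ = np.linalg.lstsq(A, O, rcond=None)
        resid = O - A @ coef
        rss = float(resid @ resid)
        params = dict(zip(spec.param_names, map(float, coef)))
    else:
        start = np.asarray(x0 if x0 is not None else spec.x0, dtype=float)
        func, jac = spec.func, spec.jac

        def resid_fn(p: np.ndarray) -> np.ndarray:
            r = func(p, R) - O
            if not np.isfinite(r.sum()):  # +-inf/nan anywhere poisons the sum
                r = np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)
            return r

        def jac_fn(p: np.ndarray) -> np.ndarray:
            J = jac(p, R)
            if not np.isfinite(J.sum()):
                J = np.nan_to_num(J, nan=0.0, posinf=1e6, neginf=-1e6)
            return J

        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                x, ier = leastsq(
                    resid_fn, start, Dfun=jac_fn if jac else None,
                    maxfev=max_iter, xtol=tol, ftol=tol, gtol=tol,
                )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("model %s failed: %s", spec.name, exc)
            return empty
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            r = resid_fn(x)
            rss = float(r @ r)
        params = dict(zip(spec.param_names, map(float, x)))
        if ier not in (1, 2, 3, 4) or not (
            np.isfinite(rss) and all(np.isfinite(v) for v in params.values())
        ):
            return empty

    fit = ModelFit(spec.name, params, rss, n, k, converged=True)
    floor = RSS_FLOOR_PER_POINT * n
    if fit.rss < floor:
        fit.rss = floor
        fit.rss_floored = True
    fit.aicc = aicc(fit.rss, n, k)
    return fit


def akaike_weights(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Attach Akaike weights: w_i = exp(-d_i/2) / sum_j exp(-d_j/2).

    Only converged fits enter the candidate set; others get weight 0. Raises
    if no fit converged (the caller skips the SRS-group cell).
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged model fits")
    a = np.array([f.aicc for f in conv])
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    out = []
    it = iter(w)
    for f in fits:
        out.append(replace(f, weight=float(next(it)) if f.converged else 0.0))
    return out


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternProbs:
    """Summed Akaike weights of the three OFD pattern families for one cell."""

    w_bimodal: float
    w_unimodal: float
    w_random: float
    S: int
    b_hat_powexp: float = float("nan")
    converged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = self.w_bimodal + self.w_unimodal + self.w_random
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, not 1")


def classify_patterns(fits: Sequence[ModelFit]) -> PatternProbs:
    """Fold model weights into pattern-family probabilities.

    bimodal = sigmoidal symmetric + sigmoidal asymmetric + power exponential
    with fitted b > 0; unimodal = exponential concave + power exponential
    with b <= 0; random = linear.
    """
    w = {f.model: f.weight for f in fits}
    b_hat = float("nan")
    pe = next((f for f in fits if f.model == "power_exp"), None)
    if pe is not None and pe.converged:
        b_hat = pe.params["b"]
    w_bi = w.get("sig_symmetric", 0.0) + w.get("sig_asymmetric", 0.0)
    w_uni = w.get("exp_concave", 0.0)
    pe_w = w.get("power_exp", 0.0)
    if np.isfinite(b_hat) and b_hat > 0:
        w_bi += pe_w
    else:
        w_uni += pe_w
    n = fits[0].n if fits else 0
    return PatternProbs(
        w_bimodal=w_bi,
        w_unimodal=w_uni,
        w_random=w.get("linear", 0.0),
        S=n,
        b_hat_powexp=b_hat,
        converged=tuple(f.model for f in fits if f.converged),
    )


# ---------------------------------------------------------------------------
# Per-SRS composition
# ---------------------------------------------------------------------------

def fit_all(
    rsoc: RSOC,
    models: Sequence[ModelSpec] = DEFAULT_MODELS,
    max_iter: int = 999,
    tol: float = 1e-8,
) -> list[ModelFit]:
    return [fit_model(rsoc, m, max_iter=max_iter, tol=tol) for m in models]


def analyze_srs(
    srs: SRS,
    groups: Mapping[str, str] | None = None,
    models: Sequence[ModelSpec] = DEFAULT_MODELS,
    include_pooled: bool = False,
    max_iter: int = 999,
    tol: float = 1e-8,
) -> dict[str, PatternProbs]:
    """RSOC -> fits -> weights -> pattern probabilities for each group.

    *groups* maps taxon id to group label; None analyses the pooled
    assemblage only. Cells whose RSOC is empty or too short to fit every
    candidate's AICc precondition for at least one model are skipped (absent
    from the returned dict); callers count skips.
    """
    cells: dict[str, set[str] | None] = {}
    if groups:
        for g in sorted(set(groups.values())):
            cells[g] = {t for t, lab in groups.items() if lab == g}
        if include_pooled:
            cells["all"] = None
    else:
        cells["all"] = None

    out: dict[str, PatternProbs] = {}
    for gname, subset in cells.items():
        rsoc = occupancies(srs, subset, group=gname)
        if rsoc is None:
            logger.debug("SRS %d, group %s: empty RSOC, skipped", srs.index, gname)
            continue
        fits = fit_all(rsoc, models, max_iter=max_iter, tol=tol)
        try:
            fits = akaike_weights(fits)
        except ValueError:
            logger.debug("SRS %d, group %s: no converged fit, skipped", srs.index, gname)
            continue
        out[gname] = classify_patterns(fits)
    return out
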