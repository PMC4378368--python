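"""Bootstrap single-mediator analysis.

Quantifies how much of the association between an exposure summary (e.g.
multiplicity of maltreatment) and an outcome flows through a focal mediator
(e.g. severity of one maltreatment type at one age).  Standardized path
coefficients: a (x -> m), b (m -> y given x), c (total x -> y), c' (direct
x -> y given m).  The indirect effect ab is tested with a percentile
bootstrap over case resamples, which — unlike the Sobel test — does not
assume the sampling distribution of ab is normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, t as t_dist

__all__ = ["MediationResult", "mediate", "sobel_test"]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ab_ci: tuple
    ratio: float                # |ab| / |c'|
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    p_ab: float                 # bootstrap two-sided p (CI inversion grid)
    se_a: float
    se_b: float
    n: int
    n_boot: int
    level: float
    seed: int
    outcome_model: str          # "linear" | "logistic"
    flags: list

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "ab": self.ab, "ab_ci": list(self.ab_ci), "ratio": self.ratio,
            "p_a": self.p_a, "p_b": self.p_b, "p_c": self.p_c,
            "p_c_prime": self.p_c_prime, "p_ab": self.p_ab,
            "se_a": self.se_a, "se_b": self.se_b,
            "n": self.n, "n_boot": self.n_boot, "level": self.level,
            "seed": self.seed, "outcome_model": self.outcome_model,
            "flags": self.flags,
        }


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0.0:
        raise ValueError(f"zero-variance input: {name}")
    return (v - v.mean()) / sd


def _ols_1(x: np.ndarray, y: np.ndarray) -> tuple:
    """Slope, se, two-sided p for y ~ x (both standardized or not)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 / sxx)
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return beta, float(se), p


def _ols_2(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple:
    """Coefficients (bx, bm) with ses and ps for y ~ x + m."""
    n = x.size
    X = np.column_stack([np.ones(n), x, m])
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("collinear predictors: x and m are linearly dependent") from exc
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        raise ValueError("collinear predictors: x and m are (nearly) linearly dependent")
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    ses = np.sqrt(s2 * np.diag(XtX_inv))
    ts = beta / np.where(ses > 0, ses, np.inf)
    ps = 2.0 * t_dist.sf(np.abs(ts), df)
    return (float(beta[1]), float(beta[2]), float(ses[1]), float(ses[2]),
            float(ps[1]), float(ps[2]))


def _logit_paths(x: np.ndarray, m: np.ndarray, y01: np.ndarray) -> tuple:
    import statsmodels.api as sm

    X1 = np.column_stack([np.ones(x.size), x])
    X2 = np.column_stack([np.ones(x.size), x, m])
    f1 = sm.Logit(y01, X1).fit(disp=0)
    f2 = sm.Logit(y01, X2).fit(disp=0)
    c, p_c = float(f1.params[1]), float(f1.pvalues[1])
    c_prime, p_cp = float(f2.params[1]), float(f2.pvalues[1])
    b, p_b = float(f2.params[2]), float(f2.pvalues[2])
    se_b = float(f2.bse[2])
    return c, p_c, c_prime, p_cp, b, p_b, se_b


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    outcome_model: str = "linear",
) -> MediationResult:
    """Single-mediator model with percentile-bootstrap CI for ab.

    Variables are standardized internally, so coefficients are on the
    correlation scale.  Binary outcomes are fitted as a linear-probability
    model by default (``outcome_model="linear"``); ``"logistic"`` fits
    logit outcome paths instead (flagged, since a and b then live on
    different scales and c = c' + ab no longer holds exactly).
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal lengths")
    if n < 10:
        raise ValueError("need at least 10 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")

    flags: list = []
    binary_y = np.isin(np.unique(y), [0.0, 1.0]).all() and np.unique(y).size == 2
    if binary_y and outcome_model == "linear":
        flags.append("binary outcome fitted as linear-probability model")

    xs = _zscore(x, "x")
    ms = _zscore(m, "m")
    if binary_y and outcome_model == "logistic":
        ys = y  # keep 0/1 for the logit fits
    else:
        ys = _zscore(y, "y")

    a, se_a, p_a = _ols_1(xs, ms)
    if outcome_model == "logistic" and binary_y:
        c, p_c, c_prime, p_cp, b, p_b, se_b = _logit_paths(xs, ms, ys)
        flags.append("logistic outcome paths: c != c' + a*b in general")
    else:
        c, _, p_c = _ols_1(xs, ys)
        c_prime, b, se_cp, se_b, p_cp, p_b = _ols_2(xs, ms, ys)
    ab = a * b

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = xs[idx]
    mb = ms[idx]
    yb = ys[idx] if not (binary_y and outcome_model == "logistic") else y[idx]
    ab_boot = _bootstrap_ab(xb, mb, yb, logistic=binary_y and outcome_model == "logistic")
    lo_q = (1.0 - level) / 2.0
    ab_lo, ab_hi = np.quantile(ab_boot, [lo_q, 1.0 - lo_q])
    # two-sided bootstrap p: smallest (1 - level) at which the CI excludes 0
    prop_le = float(np.mean(ab_boot <= 0.0))
    p_ab = float(min(1.0, 2.0 * min(prop_le, 1.0 - prop_le)))

    ratio = abs(ab) / abs(c_prime) if c_prime != 0 else float("inf")
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, ab=ab,
        ab_ci=(float(ab_lo), float(ab_hi)), ratio=float(ratio),
        p_a=p_a, p_b=p_b, p_c=p_c, p_c_prime=p_cp, p_ab=p_ab,
        se_a=se_a, se_b=se_b,
        n=n, n_boot=n_boot, level=level, seed=int(seed),
        outcome_model="logistic" if (binary_y and outcome_model == "logistic") else "linear",
        flags=flags,
    )


def _bootstrap_ab(xb: np.ndarray, mb: np.ndarray, yb: np.ndarray, logistic: bool = False) -> np.ndarray:
    """Vectorized ab over B case-resampled replicates (rows of xb/mb/yb)."""
    if logistic:
        # replicate-by-replicate logit fits are costly; fall back to a loop
        import statsmodels.api as sm

        out = np.empty(xb.shape[0])
        for i in range(xb.shape[0]):
            x, m, y = xb[i], mb[i], yb[i]
            xc = x - x.mean()
            a_i = float(xc @ (m - m.mean())) / float(xc @ xc)
            X2 = np.column_stack([np.ones(x.size), x, m])
            try:
                f2 = sm.Logit(y, X2).fit(disp=0)
                out[i] = a_i * float(f2.params[2])
            except Exception:
                out[i] = np.nan
        return out[np.isfinite(out)]

    n = xb.shape[1]
    xm = xb.mean(axis=1, keepdims=True)
    mm = mb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    xc, mc, yc = xb - xm, mb - mm, yb - ym
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    a = sxm / sxx
    # y ~ x + m: solve the 2x2 normal equations per replicate
    det = sxx * smm - sxm**2
    ok = det > 1e-12 * np.maximum(sxx * smm, 1e-300)
    b = np.where(ok, (sxx * smy - sxm * sxy) / np.where(ok, det, 1.0), np.nan)
    ab = a * b
    return ab[np.isfinite(ab)]


def sobel_test(a: float, b: float, se_a: float, se_b: float) -> tuple:
    """Normal-theory z-test of the indirect effect ab.

    z = ab / sqrt(b^2 se_a^2 + a^2 se_b^2); two-sided p.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    if denom == 0.0:
        return 0.0, 1.0
    z = float(a * b / denom)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p
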