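"""Response inference: the theta statistic, BCa intervals, and the
embedded bootstrap-t test against the limit of decision.

Statistical significance alone is a poor criterion when thousands of cells
are measured per condition: trivially small distribution differences become
significant.  The test here therefore targets a *non-zero null*.  With Z the
vehicle-treated reference, Y the vehicle-treated control measured at the end
of the session, and X a drug-treated sample, the test statistic is

    theta(X, Y, Z) = mass_response(X, Z) - mass_response(Y, Z)

i.e. the drug signal in excess of the drift/noise signal carried by the
control.  The hypothesis H0: theta <= theta0 (theta0 the limit of decision,
3% by default) is tested one-sided with the bootstrap-t method: the pivot
T = (theta_hat - theta)/S is studentized by a standard error S estimated
from r inner bootstrap replicates, and the null distribution of T is
simulated by R outer bootstrap replicates, each studentized by its own inner
bootstrap — an embedded (nested) bootstrap.  The achievable p-values lie on
the grid k/(1+R), k = 1..1+R, so with R = 999 the minimum p is 0.001.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import bootstrap as _scipy_bootstrap
from scipy.stats import wasserstein_distance

from .datamodel import Call, ConditionSample, InferenceConfig, TestResult, ValidationError
from .response import _as_masses, mass_response

__all__ = [
    "theta_stat",
    "bca_ci",
    "bootstrap_t_test",
    "call_response",
]


def theta_stat(X, Y, Z) -> float:
    """Test statistic: mass response of X minus mass response of Y, both
    against the reference Z.  May be negative (control drifted further than
    the drug moved the cells)."""
    return float(mass_response(X, Z) - mass_response(Y, Z))


# ---------------------------------------------------------------------------
# BCa confidence interval for the mass response


def _mr_stat_vectorized(x, z, axis=-1):
    """Batched mass response over the trailing axis.

    Equal sizes use the order-statistic pairing; unequal sizes (as arise in
    the BCa jackknife) evaluate the quantile-function form of the W1
    distance on the fixed union grid of the two samples' quantile levels.
    """
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    z = np.moveaxis(np.asarray(z, dtype=float), axis, -1)
    x = np.sort(x, axis=-1)
    z = np.sort(z, axis=-1)
    m, n = x.shape[-1], z.shape[-1]
    if m == n:
        return np.abs(x - z).sum(axis=-1) / z.sum(axis=-1)
    bounds = np.union1d(np.arange(m + 1) / m, np.arange(n + 1) / n)
    w = np.diff(bounds)
    mid = (bounds[:-1] + bounds[1:]) / 2.0
    ix = np.floor(mid * m).astype(np.intp)
    iz = np.floor(mid * n).astype(np.intp)
    W1 = (np.abs(x[..., ix] - z[..., iz]) * w).sum(axis=-1)
    return W1 / z.mean(axis=-1)


def bca_ci(
    sample_x,
    sample_z,
    level: float = 0.90,
    R_ci: int = 5000,
    rng: np.random.Generator | int | None = None,
    method: str = "bca",
) -> tuple[float, float]:
    """Bootstrap CI for the mass response: BCa (default) or percentile.

    Both samples are resampled independently with replacement, sizes
    preserved.  If the data admit no resampling variability (all masses in
    both samples identical) the interval degenerates to the point estimate.

    Near the null (two samples from one distribution) the distance statistic
    is biased upward under resampling and the BCa bias correction saturates,
    collapsing the interval toward the point estimate; the percentile method
    does not share this pathology but is first-order only.
    """
    if method not in ("bca", "percentile"):
        raise ValidationError("method must be 'bca' or 'percentile'")
    x = _as_masses(sample_x)
    z = _as_masses(sample_z)
    point = mass_response(x, z)
    if np.ptp(x) == 0 and np.ptp(z) == 0:
        return (point, point)
    gen = np.random.default_rng(rng)
    res = _scipy_bootstrap(
        (x, z),
        _mr_stat_vectorized,
        method="BCa" if method == "bca" else "percentile",
        n_resamples=R_ci,
        confidence_level=level,
        vectorized=True,
        rng=gen,
    )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):  # degenerate resampling
        return (point, point)
    return (lo, hi)


# ---------------------------------------------------------------------------
# Embedded bootstrap-t test


def _sorted_resample(sorted_vals: np.ndarray, shape_rows: int,
                     gen: np.random.Generator) -> np.ndarray:
    """With-replacement resamples of a sorted sample, rows returned sorted.

    Sorting the integer indices instead of the values keeps the rows in
    order-statistic form without re-sorting floats.
    """
    n = sorted_vals.size
    idx = gen.integers(0, n, size=(shape_rows, n))
    idx.sort(axis=1)
    return sorted_vals[idx]


def _theta_rows(Xr: np.ndarray, Yr: np.ndarray, Zr: np.ndarray) -> np.ndarray:
    """theta for each row of resampled (sorted) X, Y, Z."""
    if Xr.shape[-1] == Zr.shape[-1] and Yr.shape[-1] == Zr.shape[-1]:
        sz = Zr.sum(axis=-1)
        return (np.abs(Xr - Zr).sum(axis=-1) - np.abs(Yr - Zr).sum(axis=-1)) / sz
    out = np.empty(Xr.shape[0])
    for i in range(Xr.shape[0]):
        mz = Zr[i].mean()
        out[i] = (wasserstein_distance(Xr[i], Zr[i])
                  - wasserstein_distance(Yr[i], Zr[i])) / mz
    return out


def _joint_theta_replicates(Xs, Ys, Zs, r: int, gen: np.random.Generator) -> np.ndarray:
    """theta over r joint resamples of (X, Y, Z), each sample resampled
    independently within itself, sizes preserved."""
    Xr = _sorted_resample(Xs, r, gen)
    Yr = _sorted_resample(Ys, r, gen)
    Zr = _sorted_resample(Zs, r, gen)
    return _theta_rows(Xr, Yr, Zr)


def bootstrap_t_test(
    X,
    Y,
    Z,
    cfg: InferenceConfig | None = None,
    *,
    seed: int | None = None,
    condition_id: str | None = None,
) -> TestResult:
    """One-sided embedded bootstrap-t test of H0: theta <= theta0.

    Procedure (deterministic given the seed):

    1. theta_hat = theta_stat(X, Y, Z).
    2. S = sample SD of theta over ``r_inner`` joint resamples of (X, Y, Z).
    3. t_obs = (theta_hat - theta0) / S.
    4. For each of ``R_test`` outer replicates: resample (X*, Y*, Z*),
       compute theta_hat* and its own inner-bootstrap standard error S*
       (``r_inner`` replicates of the resample), and form
       T* = (theta_hat* - theta_hat) / S*.
    5. p = (1 + #{T* >= t_obs}) / (1 + R_test).

    Samples larger than ``cfg.N`` are first subsampled to N without
    replacement (seeded); smaller samples are used whole and flagged low-n.
    Each outer replicate consumes an independent RNG substream spawned from
    the master seed, so results do not depend on evaluation order.
    """
    cfg = cfg if cfg is not None else InferenceConfig()
    master = cfg.seed if seed is None else seed
    if isinstance(X, ConditionSample) and condition_id is None:
        condition_id = X.condition_id

    ss = np.random.SeedSequence(master)
    sub_ss, inner_ss, outer_root = ss.spawn(3)
    outer_children = outer_root.spawn(cfg.R_test)

    samples = []
    sub_gen = np.random.default_rng(sub_ss)
    for raw in (X, Y, Z):
        m = np.sort(_as_masses(raw))
        if m.size > cfg.N:
            m = np.sort(sub_gen.choice(m, size=cfg.N, replace=False))
        if m.size == 0:
            raise ValidationError("empty sample")
        samples.append(m)
    Xs, Ys, Zs = samples
    low_n = min(s.size for s in samples) < cfg.min_n

    theta_hat = float(_theta_rows(Xs[None], Ys[None], Zs[None])[0])
    inner = _joint_theta_replicates(Xs, Ys, Zs, cfg.r_inner,
                                    np.random.default_rng(inner_ss))
    S = float(inner.std(ddof=1))
    if S == 0.0:
        raise ValidationError(
            "standard error of theta is zero (zero-variance resampling); "
            "the samples carry no resampling variability"
        )
    t_obs = (theta_hat - cfg.theta0) / S

    count = 0
    for child in outer_children:
        gen = np.random.default_rng(child)
        Xb = _sorted_resample(Xs, 1, gen)[0]
        Yb = _sorted_resample(Ys, 1, gen)[0]
        Zb = _sorted_resample(Zs, 1, gen)[0]
        theta_b = float(_theta_rows(Xb[None], Yb[None], Zb[None])[0])
        inner_b = _joint_theta_replicates(Xb, Yb, Zb, cfg.r_inner, gen)
        S_b = inner_b.std(ddof=1)
        if S_b == 0.0:
            # a degenerate replicate pushes T* to +/-inf with the sign of
            # its numerator; a zero numerator contributes T* = 0
            diff = theta_b - theta_hat
            t_star = np.inf * np.sign(diff) if diff != 0 else 0.0
        else:
            t_star = (theta_b - theta_hat) / S_b
        if t_star >= t_obs:
            count += 1
    p = (1 + count) / (1 + cfg.R_test)

    test_signal = float(mass_response(Xs, Zs))
    ctrl_signal = float(mass_response(Ys, Zs))
    return TestResult(
        condition_id=condition_id or "",
        test_signal=test_signal,
        ctrl_signal=ctrl_signal,
        theta_hat=theta_hat,
        se_hat=S,
        t_obs=float(t_obs),
        p_value=float(p),
        n_used={"test": Xs.size, "control": Ys.size, "reference": Zs.size},
        seed=master,
        low_n=low_n,
    )


def call_response(result: TestResult, cfg: InferenceConfig | None = None) -> TestResult:
    """Attach the final call to a test result.

    Inconclusive if the control signal exceeds the drift limit (the session
    itself moved by more than the tolerated phenotypic drift); otherwise a
    response iff p < alpha.
    """
    cfg = cfg if cfg is not None else InferenceConfig()
    if result.ctrl_signal > cfg.drift_limit:
        result.call = Call.INCONCLUSIVE
    elif result.p_value < cfg.alpha:
        result.call = Call.RESPONSE
    else:
        result.call = Call.NO_RESPONSE
    return result
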