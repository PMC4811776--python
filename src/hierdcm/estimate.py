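"""MAP estimation of bilinear DCM parameters and Laplace model evidence.

The observation model is region-wise Gaussian: y_r = g_r(theta) + e_r with
e_r ~ N(0, sigma_r^2 I), where g is the deterministic forward model
(bilinear neural ODE -> balloon model -> decimation to scan times).
Neural parameters carry zero-mean Gaussian shrinkage priors;
self-connections are parameterized as a_ii = -0.5 exp(theta_ii) to enforce
negativity; noise enters as log sigma_r with a Gaussian prior.  The MAP is
found by multi-restart optimization of the penalized log-likelihood:
Levenberg-Marquardt-damped Gauss-Newton steps built on the exact
forward-model Jacobian (forward-mode tangents through the integrator),
with a quasi-Newton (L-BFGS) run from the standard start guarding against
local basins.  Model evidence is a Laplace approximation with
Gauss-Newton curvature, so higher values trade data fit against prior
complexity.

Hemodynamic parameters are held at canonical balloon-model values rather
than estimated; this keeps desk-scale fits identifiable and fast, and is
configurable through the ``hemo`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .design import DRIVE_CHANNELS, MOD_CHANNELS, InputTimeline
from .modelspace import ModelSpec
from .simulate import DCMParameters, HemodynamicParams, ROITimeSeries, fast_forward, fast_forward_jac

_LOG2PI = np.log(2.0 * np.pi)
_SELF_SCALE = 0.5  # a_ii = -_SELF_SCALE * exp(theta_ii)


@dataclass
class PriorSpec:
    """Gaussian prior (mean, variance) per free-parameter class."""

    a_offdiag: tuple[float, float] = (0.0, 1.0 / 16.0)
    a_self: tuple[float, float] = (0.0, 1.0 / 16.0)
    b: tuple[float, float] = (0.0, 1.0)
    c: tuple[float, float] = (0.0, 1.0)
    log_sd: tuple[float, float] = (np.log(0.2), 1.0)

    def __post_init__(self) -> None:
        for name in ("a_offdiag", "a_self", "b", "c", "log_sd"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"prior variance for {name} must be positive")


def default_priors(spec: ModelSpec) -> PriorSpec:  # noqa: ARG001 - per-spec hook
    """Zero-mean shrinkage priors (the spec argument reserves room for
    structure-dependent priors; the defaults do not depend on it)."""
    return PriorSpec()


class ParameterMap:
    """Layout of the free-parameter vector for one model structure.

    Order: A off-diagonal entries (per directed edge), self log-scales,
    B entries (timeline factor order), C entries, then per-region log
    noise sd.  Neural = everything except the log-sd block.
    """

    def __init__(
        self,
        spec: ModelSpec,
        drive_names: tuple[str, ...] = DRIVE_CHANNELS,
        mod_names: tuple[str, ...] = MOD_CHANNELS,
    ):
        self.spec = spec
        self.regions = spec.regions
        n = spec.n_regions
        self.n_regions = n
        self.drive_names = drive_names
        self.mod_names = mod_names

        self.a_entries: list[tuple[int, int]] = []
        for a, b in spec.edges:
            ia, ib = spec.index(a), spec.index(b)
            self.a_entries.append((ib, ia))  # a -> b
            self.a_entries.append((ia, ib))  # b -> a
        self.b_entries: list[tuple[int, int, int]] = []
        for jm, factor in enumerate(mod_names):
            for src, dst in spec.modulation(factor):
                self.b_entries.append((jm, spec.index(dst), spec.index(src)))
        cmask = spec.c_mask(drive_names)
        self.c_entries: list[tuple[int, int]] = [tuple(idx) for idx in np.argwhere(cmask)]

        self.n_a = len(self.a_entries)
        self.n_b = len(self.b_entries)
        self.n_c = len(self.c_entries)
        self.n_neural = self.n_a + n + self.n_b + self.n_c
        self.n_total = self.n_neural + n

        self.labels: list[str] = []
        for i, j in self.a_entries:
            self.labels.append(f"A:{self.regions[i]}<-{self.regions[j]}")
        for r in self.regions:
            self.labels.append(f"Aself:{r}")
        for jm, i, j in self.b_entries:
            self.labels.append(f"B:{self.mod_names[jm]}:{self.regions[i]}<-{self.regions[j]}")
        for i, k in self.c_entries:
            self.labels.append(f"C:{self.regions[i]}<-{drive_names[k]}")
        for r in self.regions:
            self.labels.append(f"logsd:{r}")

    def prior_vectors(self, priors: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
        mu = np.empty(self.n_total)
        var = np.empty(self.n_total)
        n = self.n_regions
        blocks = [
            (self.n_a, priors.a_offdiag),
            (n, priors.a_self),
            (self.n_b, priors.b),
            (self.n_c, priors.c),
            (n, priors.log_sd),
        ]
        pos = 0
        for size, (m, v) in blocks:
            mu[pos : pos + size] = m
            var[pos : pos + size] = v
            pos += size
        return mu, var

    def unpack(self, theta: np.ndarray):
        n = self.n_regions
        A = np.zeros((n, n))
        pos = 0
        for i, j in self.a_entries:
            A[i, j] = theta[pos]
            pos += 1
        A[np.diag_indices(n)] = -_SELF_SCALE * np.exp(theta[pos : pos + n])
        pos += n
        Bstack = np.zeros((len(self.mod_names), n, n))
        for jm, i, j in self.b_entries:
            Bstack[jm, i, j] = theta[pos]
            pos += 1
        C = np.zeros((n, len(self.drive_names)))
        for i, k in self.c_entries:
            C[i, k] = theta[pos]
            pos += 1
        logsd = theta[pos : pos + n]
        return A, Bstack, C, logsd

    def directions(self, theta: np.ndarray):
        """Tangent-direction encoding of the neural parameters at theta.

        Self log-scales enter with coefficient a_ii (chain rule through
        a_ii = -0.5 exp(theta_ii)), so this depends on the current point.
        """
        P = self.n_neural
        ptype = np.zeros(P, dtype=np.int64)
        pri = np.zeros(P, dtype=np.int64)
        prj = np.zeros(P, dtype=np.int64)
        pmod = np.full(P, -1, dtype=np.int64)
        pcoef = np.ones(P)
        pos = 0
        for i, j in self.a_entries:
            pri[pos], prj[pos] = i, j
            pos += 1
        for r in range(self.n_regions):
            pri[pos] = prj[pos] = r
            pcoef[pos] = -_SELF_SCALE * np.exp(theta[self.n_a + r])
            pos += 1
        for jm, i, j in self.b_entries:
            pri[pos], prj[pos], pmod[pos] = i, j, jm
            pos += 1
        for i, k in self.c_entries:
            ptype[pos] = 1
            pri[pos], prj[pos] = i, k
            pos += 1
        return ptype, pri, prj, pmod, pcoef

    def pack(self, params: DCMParameters, sigma: np.ndarray | float) -> np.ndarray:
        """Parameter vector for known quantities (ground truth, warm starts)."""
        n = self.n_regions
        theta = np.empty(self.n_total)
        pos = 0
        for i, j in self.a_entries:
            theta[pos] = params.A[i, j]
            pos += 1
        diag = np.diag(params.A)
        theta[pos : pos + n] = np.log(-diag / _SELF_SCALE)
        pos += n
        bstack = params.b_stack(self.mod_names)
        for jm, i, j in self.b_entries:
            theta[pos] = bstack[jm, i, j]
            pos += 1
        for i, k in self.c_entries:
            theta[pos] = params.C[i, k] if params.C.shape[1] > k else 0.0
            pos += 1
        theta[pos : pos + n] = np.log(np.broadcast_to(np.atleast_1d(sigma), (n,)))
        return theta


@dataclass
class FitResult:
    """MAP fit of one model structure to one subject's data."""

    spec: ModelSpec
    labels: list[str]
    theta: np.ndarray
    A: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    sigma: np.ndarray
    cov: np.ndarray
    log_evidence: float
    r2: np.ndarray
    converged: bool
    objective: float
    restart_index: int

    def parameter_series(self, include_noise: bool = False) -> pd.Series:
        values = pd.Series(self.theta, index=self.labels)
        if not include_noise:
            values = values[~values.index.str.startswith("logsd:")]
        return values


_DIVERGENCE_PENALTY = 1e12


class DCMEstimator(BaseEstimator):
    """Scikit-learn style MAP estimator for a bilinear DCM.

    Parameters
    ----------
    spec : ModelSpec
        Which connections, modulations and inputs are free.
    priors : PriorSpec, optional
        Shrinkage priors; defaults to :func:`default_priors`.
    hemo : HemodynamicParams, optional
        Fixed hemodynamics for the forward model.
    dt : float
        Integration step used during fitting (the timeline is resampled).
    tr : float
        Scan repetition time of the data.
    restarts : int
        Optimizer restarts from jittered prior draws; the best penalized
        likelihood wins, ties broken by lowest restart index.
    likelihood_weight : float
        Scales the likelihood against the prior (0 reduces the MAP to the
        prior mean; diagnostic use only).

    Attributes (after ``fit``)
    --------------------------
    theta_, A_, B_, C_, sigma_ : MAP estimates.
    cov_ : posterior covariance (inverse Gauss-Newton Hessian).
    log_evidence_ : Laplace-approximate log model evidence.
    r2_ : per-region variance explained.
    converged_ : False flags optimizer non-convergence (also warned).
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
        hemo: HemodynamicParams | None = None,
        dt: float = 0.5,
        tr: float = 2.0,
        restarts: int = 8,
        maxiter: int = 200,
        fd_step: float = 1e-4,
        jitter: float = 0.25,
        likelihood_weight: float = 1.0,
        gradient: str = "analytic",
        method: str = "auto",
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.priors = priors
        self.hemo = hemo
        self.dt = dt
        self.tr = tr
        self.restarts = restarts
        self.maxiter = maxiter
        self.fd_step = fd_step
        self.jitter = jitter
        self.likelihood_weight = likelihood_weight
        self.gradient = gradient
        self.method = method
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _objective_factory(self, Y: np.ndarray, timeline: InputTimeline, pmap: ParameterMap,
                           mu: np.ndarray, prec: np.ndarray, hemo: HemodynamicParams, decim: int):
        m = Y.shape[0]
        lw = self.likelihood_weight
        h = self.fd_step
        n_neural = pmap.n_neural
        n = pmap.n_regions

        def nll_lik(theta_neural, logsd):
            A, Bstack, C, _ = pmap.unpack(np.concatenate([theta_neural, logsd]))
            yhat, status = fast_forward(A, Bstack, C, timeline, hemo, decim)
            if status != 0:
                return None, None
            resid = Y - yhat
            ss = np.einsum("ij,ij->j", resid, resid)
            sd2 = np.exp(2.0 * logsd)
            val = float(np.sum(m * logsd + 0.5 * ss / sd2) + 0.5 * m * n * _LOG2PI)
            return val, ss

        analytic = self.gradient == "analytic"
        if not analytic and self.gradient != "fd":
            raise ValueError("gradient must be 'analytic' or 'fd'")

        def fun_and_grad(theta):
            tn = theta[:n_neural]
            logsd = theta[n_neural:]
            dev = theta - mu
            prior_val = 0.5 * float(dev @ (prec * dev))
            prior_grad = prec * dev
            if lw == 0.0:
                return prior_val, prior_grad
            grad = np.empty_like(theta)
            sd2 = np.exp(2.0 * logsd)
            if analytic:
                A, Bstack, C, _ = pmap.unpack(theta)
                yhat, Jm, status = fast_forward_jac(
                    A, Bstack, C, timeline, hemo, decim, pmap.directions(theta)
                )
                if status != 0:
                    return _DIVERGENCE_PENALTY + prior_val, prior_grad
                resid = Y - yhat
                ss = np.einsum("ij,ij->j", resid, resid)
                base = float(np.sum(m * logsd + 0.5 * ss / sd2) + 0.5 * m * n * _LOG2PI)
                grad[:n_neural] = -np.einsum("tr,trp->p", resid / sd2[None, :], Jm)
            else:
                base, ss = nll_lik(tn, logsd)
                if base is None:
                    # diverged: large penalty sloping back toward the prior mean
                    return _DIVERGENCE_PENALTY + prior_val, prior_grad
                for i in range(n_neural):
                    tp = tn.copy()
                    tp[i] += h
                    vi, _ = nll_lik(tp, logsd)
                    grad[i] = (_DIVERGENCE_PENALTY if vi is None else vi - base) / h
            grad[n_neural:] = m - ss / sd2
            return lw * base + prior_val, lw * grad + prior_grad

        return fun_and_grad, nll_lik

    def _gn_factory(self, Y, timeline, pmap, mu, prec, hemo, decim):
        """Closures for the damped Gauss-Newton loop: full evaluation
        (value, gradient, GN Hessian) and a cheap value-only evaluation."""
        m = Y.shape[0]
        n = pmap.n_regions
        nn = pmap.n_neural
        nt = pmap.n_total
        lw = self.likelihood_weight

        def eval_gn(theta):
            logsd = theta[nn:]
            sd2 = np.exp(2.0 * logsd)
            sigma = np.exp(logsd)
            A, Bstack, C, _ = pmap.unpack(theta)
            yhat, Jm, status = fast_forward_jac(
                A, Bstack, C, timeline, hemo, decim, pmap.directions(theta)
            )
            if status != 0:
                return None
            resid = Y - yhat
            ss = np.einsum("ij,ij->j", resid, resid)
            base = float(np.sum(m * logsd + 0.5 * ss / sd2) + 0.5 * m * n * _LOG2PI)
            dev = theta - mu
            fun = lw * base + 0.5 * float(dev @ (prec * dev))
            grad = np.empty(nt)
            grad[:nn] = -lw * np.einsum("tr,trp->p", resid / sd2[None, :], Jm)
            grad[nn:] = lw * (m - ss / sd2)
            grad += prec * dev
            Jw = (Jm / sigma[None, :, None]).reshape(m * n, nn)
            H = np.zeros((nt, nt))
            H[:nn, :nn] = lw * (Jw.T @ Jw)
            H[range(nn, nt), range(nn, nt)] = lw * 2.0 * ss / sd2
            H[np.diag_indices(nt)] += prec
            return fun, grad, H

        def fun_only(theta):
            logsd = theta[nn:]
            sd2 = np.exp(2.0 * logsd)
            A, Bstack, C, _ = pmap.unpack(theta)
            yhat, status = fast_forward(A, Bstack, C, timeline, hemo, decim)
            if status != 0:
                return None
            resid = Y - yhat
            ss = np.einsum("ij,ij->j", resid, resid)
            base = float(np.sum(m * logsd + 0.5 * ss / sd2) + 0.5 * m * n * _LOG2PI)
            dev = theta - mu
            return lw * base + 0.5 * float(dev @ (prec * dev))

        return eval_gn, fun_only

    def _minimize_gn(self, eval_gn, fun_only, theta0, ftol: float = 1e-7):
        """Levenberg-Marquardt-damped Gauss-Newton on the penalized
        objective; quadratic convergence near the MAP makes the evidence
        comparisons sharp at a handful of Jacobian evaluations."""
        out = eval_gn(theta0)
        if out is None:
            return theta0, _DIVERGENCE_PENALTY, False
        fun, grad, H = out
        theta = theta0
        lam = 1e-3
        success = False
        for _ in range(int(self.maxiter)):
            accepted = False
            for _ in range(15):
                Hd = H.copy()
                Hd[np.diag_indices_from(Hd)] += lam * np.abs(np.diag(H)) + 1e-12
                try:
                    delta = np.linalg.solve(Hd, -grad)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                f_new = fun_only(theta + delta)
                if f_new is not None and f_new <= fun:
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                success = True  # no descent direction left: at a minimum
                break
            improvement = fun - f_new
            theta = theta + delta
            out = eval_gn(theta)
            if out is None:
                return theta, _DIVERGENCE_PENALTY, False
            fun, grad, H = out
            lam = max(lam * 0.25, 1e-9)
            if improvement < ftol * (1.0 + abs(fun)) and np.max(np.abs(delta)) < 1e-4:
                success = True
                break
        return theta, fun, success

    # -- API -------------------------------------------------------------
    def fit(self, Y, timeline: InputTimeline, warm_start=None):
        """Fit the model to one subject's ROI time series.

        ``warm_start`` may be a (labels, theta) pair from a previous fit of
        a related structure; matching labels seed the first restart.
        """
        if self.spec is None:
            raise ValueError("a ModelSpec is required")
        if isinstance(Y, ROITimeSeries):
            Y = Y.data
        Y = np.asarray(Y, dtype=float)
        tl = timeline.resample(self.dt)
        decim_f = self.tr / tl.dt
        decim = int(round(decim_f))
        if abs(decim_f - decim) > 1e-9:
            raise ValueError("fit dt must divide the TR")
        n = self.spec.n_regions
        if Y.ndim != 2 or Y.shape[1] != n:
            raise ValueError(f"data must be (scans, {n})")
        if tl.n_steps // decim != Y.shape[0]:
            raise ValueError(
                f"data has {Y.shape[0]} scans but the timeline implies {tl.n_steps // decim}"
            )
        pmap = ParameterMap(self.spec, tl.drive_names, tl.mod_names)
        priors = self.priors if self.priors is not None else default_priors(self.spec)
        mu, var = pmap.prior_vectors(priors)
        prec = 1.0 / var
        hemo = self.hemo or HemodynamicParams()
        fun_and_grad, nll_lik = self._objective_factory(Y, tl, pmap, mu, prec, hemo, decim)

        theta_first = mu.copy()
        # data-driven noise initialization: starting log-sd well below the
        # raw data sd keeps the optimizer out of the all-noise local optimum
        logsd_init = np.log(np.maximum(0.25 * Y.std(axis=0), 1e-6))
        theta_first[pmap.n_neural :] = logsd_init
        if warm_start is not None:
            w_labels, w_theta = warm_start
            lut = {lab: v for lab, v in zip(w_labels, w_theta)}
            for i, lab in enumerate(pmap.labels):
                if lab in lut:
                    theta_first[i] = lut[lab]

        if self.method not in ("gn", "lbfgs", "auto"):
            raise ValueError("method must be 'gn', 'lbfgs' or 'auto'")
        gn_available = self.gradient == "analytic" and self.likelihood_weight > 0 and self.method != "lbfgs"
        eval_gn, fun_only = None, None
        if gn_available:
            eval_gn, fun_only = self._gn_factory(Y, tl, pmap, mu, prec, hemo, decim)
        rng = np.random.default_rng(self.seed)
        best = None
        for r in range(max(1, int(self.restarts))):
            if r == 0:
                theta0 = theta_first
            else:
                theta0 = mu + self.jitter * np.sqrt(var) * rng.standard_normal(mu.size)
                theta0[pmap.n_neural :] = logsd_init
            if r == 1 and self.method == "auto":
                # one quasi-Newton run from the standard start guards
                # against local basins the damped Gauss-Newton can enter
                theta0 = theta_first
                use_gn = False
            else:
                use_gn = gn_available
            if use_gn:
                theta_r, fval, success = self._minimize_gn(eval_gn, fun_only, theta0)
            else:
                res = optimize.minimize(
                    fun_and_grad,
                    theta0,
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": self.maxiter, "ftol": 1e-10, "gtol": 1e-6},
                )
                theta_r, fval, success = res.x, float(res.fun), bool(res.success) or res.status == 1
            if best is None or fval < best[1] - 1e-9:
                best = (theta_r, fval, success, r)
        theta, fval, success, restart_index = best
        self.converged_ = success
        if not success:
            warnings.warn("DCM fit did not converge", RuntimeWarning)
        res = optimize.OptimizeResult(x=theta, fun=fval)

        A, Bstack, C, logsd = pmap.unpack(theta)
        sigma = np.exp(logsd)
        base, ss = nll_lik(theta[: pmap.n_neural], logsd)
        if base is None:
            raise RuntimeError("MAP estimate diverged; model is unstable")
        m = Y.shape[0]
        var_y = np.maximum(np.var(Y, axis=0) * m, 1e-300)
        self.r2_ = 1.0 - ss / var_y

        # Gauss-Newton curvature: Jacobian of the forward model at the MAP
        if self.gradient == "analytic":
            _, J3, _ = fast_forward_jac(A, Bstack, C, tl, hemo, decim, pmap.directions(theta))
            J = (J3 / sigma[None, :, None]).reshape(m * n, pmap.n_neural)
        else:
            yhat0, _ = fast_forward(A, Bstack, C, tl, hemo, decim)
            J = np.empty((m * n, pmap.n_neural))
            w = np.repeat(1.0 / sigma, m)  # column-major flatten: region blocks
            for i in range(pmap.n_neural):
                tp = theta.copy()
                tp[i] += self.fd_step
                Ai, Bi, Ci, _ = pmap.unpack(tp)
                yi, status = fast_forward(Ai, Bi, Ci, tl, hemo, decim)
                if status != 0:
                    yi = yhat0
                J[:, i] = ((yi - yhat0) / self.fd_step).flatten(order="F") * w
        lwt = self.likelihood_weight
        H = np.zeros((pmap.n_total, pmap.n_total))
        H[: pmap.n_neural, : pmap.n_neural] = lwt * (J.T @ J)
        sd2 = np.exp(2.0 * logsd)
        H[range(pmap.n_neural, pmap.n_total), range(pmap.n_neural, pmap.n_total)] = lwt * 2.0 * ss / sd2
        H[np.diag_indices(pmap.n_total)] += prec

        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0 or not np.isfinite(logdetH):
            warnings.warn("singular curvature at the MAP; ridge-regularizing", RuntimeWarning)
            ridge = 1e-6 * max(1.0, float(np.mean(np.diag(H))))
            H = H + ridge * np.eye(pmap.n_total)
            _, logdetH = np.linalg.slogdet(H)
        self.cov_ = np.linalg.inv(H)

        dev = theta - mu
        log_prior = -0.5 * float(dev @ (prec * dev)) - 0.5 * float(np.sum(np.log(2.0 * np.pi * var)))
        self.log_evidence_ = float(-base + log_prior + 0.5 * pmap.n_total * _LOG2PI - 0.5 * logdetH)

        self.pmap_ = pmap
        self.labels_ = pmap.labels
        self.theta_ = theta
        self.A_ = A
        self.B_ = {
            tl.mod_names[jm]: Bstack[jm]
            for jm in range(len(tl.mod_names))
            if np.any(Bstack[jm])
        }
        self.C_ = C
        self.sigma_ = sigma
        self.objective_ = float(res.fun)
        self.restart_index_ = int(restart_index)
        self.n_scans_ = m
        return self

    def result(self) -> FitResult:
        return FitResult(
            spec=self.spec,
            labels=list(self.labels_),
            theta=self.theta_.copy(),
            A=self.A_.copy(),
            B={k: v.copy() for k, v in self.B_.items()},
            C=self.C_.copy(),
            sigma=self.sigma_.copy(),
            cov=self.cov_.copy(),
            log_evidence=self.log_evidence_,
            r2=self.r2_.copy(),
            converged=self.converged_,
            objective=self.objective_,
            restart_index=self.restart_index_,
        )


def fit_dcm(
    data,
    timeline: InputTimeline,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    options: dict | None = None,
) -> FitResult:
    """Fit one subject's data under one model structure (MAP + evidence)."""
    est = DCMEstimator(spec=spec, priors=priors, **(options or {}))
    est.fit(data, timeline)
    return est.result()


def log_evidence(fit: FitResult, priors: PriorSpec | None = None) -> float:  # noqa: ARG001
    """Laplace-approximate log evidence of a fit (computed during fitting;
    identical fits give identical evidence)."""
    return fit.log_evidence


def parameter_table(fits: list[FitResult], include_noise: bool = False) -> pd.DataFrame:
    """Subjects x parameters table of MAP estimates from a common structure."""
    if not fits:
        raise ValueError("no fits given")
    key = fits[0].spec.key()
    for f in fits[1:]:
        if f.spec.key() != key:
            raise ValueError("fits mix different model structures")
    return pd.DataFrame([f.parameter_series(include_noise=include_noise) for f in fits]).reset_index(
        drop=True
    )


def group_parameter_inference(fits_or_table, q_threshold: float = 0.05) -> pd.DataFrame:
    """Random-effects inference on parameters across subjects.

    One-sample t-test per free parameter with Benjamini-Hochberg FDR
    correction.  Accepts a list of FitResult (common structure required)
    or a subjects x parameters DataFrame.  A parameter constant and
    nonzero across subjects gets t = +/-inf, p = 0 and is flagged.
    """
    if isinstance(fits_or_table, pd.DataFrame):
        table = fits_or_table
    else:
        table = parameter_table(list(fits_or_table))
    n = table.shape[0]
    if n < 3:
        raise ValueError("group inference needs at least 3 subjects")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    tvals = np.full(table.shape[1], np.nan)
    pvals = np.ones(table.shape[1])
    degenerate = np.zeros(table.shape[1], dtype=bool)
    for j in range(table.shape[1]):
        x = table.iloc[:, j].to_numpy()
        if sds.iloc[j] == 0:
            degenerate[j] = True
            if means.iloc[j] != 0:
                tvals[j] = np.inf * np.sign(means.iloc[j])
                pvals[j] = 0.0
            else:
                tvals[j] = 0.0
                pvals[j] = 1.0
        else:
            t, p = stats.ttest_1samp(x, 0.0)
            tvals[j], pvals[j] = t, p
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean": means,
            "sd": sds,
            "t": tvals,
            "p": pvals,
            "q": qvals,
            "significant": qvals < q_threshold,
            "degenerate": degenerate,
        }
    )
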