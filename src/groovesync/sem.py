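"""Observed-variable path analysis: ML covariance-structure fitting, fit indices,
and multi-group invariance testing with stepwise constraint release.

The structural model over endogenous variables ``y`` and exogenous variables
``x`` is

    y = B y + Gamma x + zeta,   Cov(zeta) = Psi,  Cov(x) = Phi (free),

with implied covariance

    Cov(y)    = (I - B)^-1 (Gamma Phi Gamma' + Psi) (I - B)^-T
    Cov(y, x) = (I - B)^-1 Gamma Phi
    Cov(x)    = Phi.

Estimation minimizes the maximum-likelihood discrepancy

    F_ML = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

by quasi-Newton search from regression-based starting values, with jittered
restarts.  The test statistic is ``T = (N - 1) F_ML``; CFI, TLI, RMSEA and
SRMR are computed against the independence baseline.  Feedback loops
(non-recursive systems) are estimable through the ``(I - B)^-1``
formulation; local identification is pre-checked through the rank of the
Jacobian of the implied moments, and unidentified specifications are
rejected with a diagnostic.

Models are written in a small declarative syntax, one path per line::

    urge <- pleasure @b_pu     # '@label' names a parameter (optional)
    plv1 <- urge
    urge ~~ pleasure           # residual covariance between endogenous terms

Residual variances, and the exogenous covariance block, are always free and
need not be declared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

_PSI_FLOOR = 1e-10

#: Fit-index thresholds: good (CFI/TLI >= .95, RMSEA <= .06, SRMR <= .08) and
#: acceptable (CFI/TLI >= .90, RMSEA <= .08, SRMR <= .08).
GOOD_FIT = {"cfi": 0.95, "tli": 0.95, "rmsea": 0.06, "srmr": 0.08}
ACCEPTABLE_FIT = {"cfi": 0.90, "tli": 0.90, "rmsea": 0.08, "srmr": 0.08}


class IdentificationError(ValueError):
    """The model's free parameters are not identified by the covariance moments."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge after all restarts."""


@dataclass(frozen=True)
class Parameter:
    """One free or fixed entry of B, Gamma, Psi or Phi."""

    matrix: str  # 'B' | 'Gamma' | 'Psi' | 'Phi'
    lhs: str
    rhs: str
    label: str
    free: bool = True
    value: float = 0.0


@dataclass(frozen=True)
class PathModelSpec:
    """Directed-path structure among observed variables.

    ``paths`` hold the user-declared regressions and residual covariances;
    residual variances (Psi diagonal) and the full exogenous covariance block
    (Phi) are appended automatically as free parameters.
    """

    endogenous: tuple[str, ...]
    exogenous: tuple[str, ...]
    paths: tuple[Parameter, ...]

    def __post_init__(self) -> None:
        if not self.endogenous:
            raise ValueError("at least one endogenous variable required")
        overlap = set(self.endogenous) & set(self.exogenous)
        if overlap:
            raise ValueError(f"variables cannot be both endogenous and exogenous: {overlap}")
        seen = set()
        for p in self.paths:
            key = (p.matrix, p.lhs, p.rhs)
            if key in seen:
                raise ValueError(f"duplicate parameter {key}")
            seen.add(key)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.endogenous + self.exogenous

    @property
    def n_var(self) -> int:
        return len(self.variables)

    def parameters(self) -> tuple[Parameter, ...]:
        """All parameters in canonical order: declared paths/covariances,
        residual variances, exogenous (co)variances."""
        full = list(self.paths)
        for v in self.endogenous:
            full.append(Parameter("Psi", v, v, f"{v}~~{v}"))
        nx = len(self.exogenous)
        for i in range(nx):
            for j in range(i, nx):
                a, b = self.exogenous[i], self.exogenous[j]
                full.append(Parameter("Phi", a, b, f"{a}~~{b}"))
        return tuple(full)

    def free_labels(self) -> tuple[str, ...]:
        out, seen = [], set()
        for p in self.parameters():
            if p.free and p.label not in seen:
                out.append(p.label)
                seen.add(p.label)
        return tuple(out)

    def path_labels(self) -> tuple[str, ...]:
        """Labels of the structural coefficients (B and Gamma entries)."""
        return tuple(
            p.label for p in self.paths if p.free and p.matrix in ("B", "Gamma")
        )


def parse_model(text: str) -> PathModelSpec:
    """Parse the declarative model syntax into a :class:`PathModelSpec`."""
    raw_paths: list[tuple[str, str, str | None]] = []
    raw_covs: list[tuple[str, str, str | None]] = []
    mentioned: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        label = None
        if "@" in line:
            line, label = (part.strip() for part in line.rsplit("@", 1))
        if "<-" in line:
            lhs, rhs = (part.strip() for part in line.split("<-", 1))
            sources = [s.strip() for s in rhs.split("+")]
            if not lhs or any(not s for s in sources):
                raise ValueError(f"line {lineno}: malformed path {line!r}")
            if label is not None and len(sources) > 1:
                raise ValueError(f"line {lineno}: '@label' requires a single source")
            for src in sources:
                raw_paths.append((lhs, src, label))
                mentioned.extend([lhs, src])
        elif "~~" in line:
            a, b = (part.strip() for part in line.split("~~", 1))
            if not a or not b or a == b:
                raise ValueError(f"line {lineno}: malformed covariance {line!r}")
            raw_covs.append((a, b, label))
            mentioned.extend([a, b])
        else:
            raise ValueError(f"line {lineno}: unrecognized statement {line!r}")
    endo = tuple(dict.fromkeys(lhs for lhs, _, _ in raw_paths))
    if not endo:
        raise ValueError("model declares no regression paths")
    exo = tuple(dict.fromkeys(v for v in mentioned if v not in endo))
    params = []
    for lhs, src, label in raw_paths:
        if lhs == src:
            raise ValueError(f"self-loop on {lhs}")
        matrix = "B" if src in endo else "Gamma"
        params.append(Parameter(matrix, lhs, src, label or f"{lhs}<-{src}"))
    for a, b, label in raw_covs:
        if a not in endo or b not in endo:
            raise ValueError(
                f"residual covariance {a}~~{b} must involve endogenous variables "
                "(exogenous covariances are always free)"
            )
        a, b = sorted((a, b), key=endo.index)
        params.append(Parameter("Psi", a, b, label or f"{a}~~{b}"))
    return PathModelSpec(endogenous=endo, exogenous=exo, paths=tuple(params))


# ---------------------------------------------------------------------------
# shipped model fixtures for the groove-synchrony analysis
# ---------------------------------------------------------------------------

#: Recursive formulation: syncopation dummies -> ratings -> coupling.
EMBODIED_MODEL = """
pleasure <- sync_mid
pleasure <- sync_high
urge <- sync_mid
urge <- sync_high
urge <- pleasure
plv1 <- urge
plv2 <- urge
"""

#: Non-recursive formulation with the reciprocal coupling-to-groove paths.
EMBODIED_MODEL_FEEDBACK = EMBODIED_MODEL + """
urge <- plv1
pleasure <- plv2
"""


def embodied_model_spec(feedback: bool = False) -> PathModelSpec:
    """The groove-synchrony path model over (pleasure, urge, plv1, plv2 | dummies)."""
    return parse_model(EMBODIED_MODEL_FEEDBACK if feedback else EMBODIED_MODEL)


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


class _Engine:
    """Maps a flat free-parameter vector to model matrices and F_ML."""

    def __init__(self, spec: PathModelSpec, labels: tuple[str, ...] | None = None):
        self.spec = spec
        self.params = spec.parameters()
        self.labels = labels if labels is not None else spec.free_labels()
        self.col = {lab: i for i, lab in enumerate(self.labels)}
        self.ny = len(spec.endogenous)
        self.nx = len(spec.exogenous)
        self.ei = {v: i for i, v in enumerate(spec.endogenous)}
        self.xi = {v: i for i, v in enumerate(spec.exogenous)}

    def matrices(self, theta: np.ndarray):
        ny, nx = self.ny, self.nx
        b = np.zeros((ny, ny))
        gamma = np.zeros((ny, nx))
        psi = np.zeros((ny, ny))
        phi = np.zeros((nx, nx))
        for p in self.params:
            val = theta[self.col[p.label]] if p.free else p.value
            if p.matrix == "B":
                b[self.ei[p.lhs], self.ei[p.rhs]] = val
            elif p.matrix == "Gamma":
                gamma[self.ei[p.lhs], self.xi[p.rhs]] = val
            elif p.matrix == "Psi":
                i, j = self.ei[p.lhs], self.ei[p.rhs]
                psi[i, j] = psi[j, i] = val
            else:
                i, j = self.xi[p.lhs], self.xi[p.rhs]
                phi[i, j] = phi[j, i] = val
        return b, gamma, psi, phi

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        b, gamma, psi, phi = self.matrices(theta)
        ib = np.eye(self.ny) - b
        det = np.linalg.det(ib)
        if abs(det) < 1e-12:
            raise np.linalg.LinAlgError("(I - B) is singular")
        ib_inv = np.linalg.inv(ib)
        if self.nx:
            cov_y = ib_inv @ (gamma @ phi @ gamma.T + psi) @ ib_inv.T
            cov_yx = ib_inv @ gamma @ phi
            top = np.hstack([cov_y, cov_yx])
            bottom = np.hstack([cov_yx.T, phi])
            sigma = np.vstack([top, bottom])
        else:
            sigma = ib_inv @ psi @ ib_inv.T
        return 0.5 * (sigma + sigma.T)

    def discrepancy(self, theta: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
        """F_ML, with a smooth penalty outside the positive-definite region."""
        p = s.shape[0]
        try:
            sigma = self.sigma(theta)
            c, low = cho_factor(sigma, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return 1e10 + float(np.sum(theta**2))
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        trace = float(np.trace(cho_solve((c, low), s, check_finite=False)))
        f = logdet + trace - logdet_s - p
        if not np.isfinite(f):
            return 1e10 + float(np.sum(theta**2))
        return f

    def value_and_grad(self, theta, s, logdet_s):
        """F_ML and its analytic gradient over the free parameters.

        With W = Sigma^-1 (Sigma - S) Sigma^-1, dF = tr(W dSigma); the
        derivative of the implied covariance with respect to each entry of
        B, Gamma, Psi and Phi reduces to an indexed read from four small
        matrices (A = (I - B)^-1):

            dF/dB_ij     = 2 [A' (Wyy Syy + Wyx Syx')]_ij
            dF/dGamma_ij = 2 [A' Wyy A G Phi + A' Wyx Phi]_ij
            dF/dPsi_ij   = (2 - delta_ij) [A' Wyy A]_ij
            dF/dPhi_ij   = (2 - delta_ij) [G'A'Wyy A G + G'A'Wyx + Wyx'A G + Wxx]_ij
        """
        p = s.shape[0]
        penalty = 1e10 + float(np.sum(theta**2))
        try:
            b, gamma, psi, phi = self.matrices(theta)
            ib = np.eye(self.ny) - b
            a = np.linalg.inv(ib)
        except np.linalg.LinAlgError:
            return penalty, 2.0 * theta
        ny, nx = self.ny, self.nx
        if nx:
            m = gamma @ phi @ gamma.T + psi
            syy = a @ m @ a.T
            syx = a @ gamma @ phi
            sigma = np.block([[syy, syx], [syx.T, phi]])
        else:
            syy = a @ psi @ a.T
            syx = np.zeros((ny, 0))
            sigma = syy
        sigma = 0.5 * (sigma + sigma.T)
        try:
            c, low = cho_factor(sigma, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return penalty, 2.0 * theta
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        siginv = cho_solve((c, low), np.eye(p), check_finite=False)
        trace = float(np.sum(siginv * s))
        f = logdet + trace - logdet_s - p
        if not np.isfinite(f):
            return penalty, 2.0 * theta
        w = siginv - siginv @ s @ siginv
        wyy, wyx, wxx = w[:ny, :ny], w[:ny, ny:], w[ny:, ny:]
        g_psi = a.T @ wyy @ a
        g_b = 2.0 * a.T @ (wyy @ syy + wyx @ syx.T)
        if nx:
            g_gamma = 2.0 * (g_psi @ gamma @ phi + a.T @ wyx @ phi)
            ag = a @ gamma
            g_phi = ag.T @ wyy @ ag + ag.T @ wyx + wyx.T @ ag + wxx
        grad = np.zeros(len(self.labels))
        for prm in self.params:
            if not prm.free:
                continue
            if prm.matrix == "B":
                val = g_b[self.ei[prm.lhs], self.ei[prm.rhs]]
            elif prm.matrix == "Gamma":
                val = g_gamma[self.ei[prm.lhs], self.xi[prm.rhs]]
            elif prm.matrix == "Psi":
                i, j = self.ei[prm.lhs], self.ei[prm.rhs]
                val = g_psi[i, j] * (2.0 if i != j else 1.0)
            else:
                i, j = self.xi[prm.lhs], self.xi[prm.rhs]
                val = g_phi[i, j] * (2.0 if i != j else 1.0)
            grad[self.col[prm.label]] += val
        return f, grad

    def start_values(self, s_frame: pd.DataFrame) -> np.ndarray:
        """Per-equation regression starts from the sample covariance."""
        theta = np.zeros(len(self.labels))
        s = s_frame.to_numpy()
        var_names = list(s_frame.columns)
        vi = {v: i for i, v in enumerate(var_names)}
        for dep in self.spec.endogenous:
            preds = [
                p.rhs
                for p in self.params
                if p.matrix in ("B", "Gamma") and p.lhs == dep
            ]
            d = vi[dep]
            resid_var = s[d, d]
            if preds:
                idx = [vi[v] for v in preds]
                sub = s[np.ix_(idx, idx)]
                sy = s[idx, d]
                try:
                    beta = np.linalg.solve(sub, sy)
                except np.linalg.LinAlgError:
                    beta = np.zeros(len(idx))
                resid_var = max(resid_var - beta @ sy, 0.05 * s[d, d])
                for pred, b_val in zip(preds, beta):
                    for p in self.params:
                        if (
                            p.free
                            and p.matrix in ("B", "Gamma")
                            and p.lhs == dep
                            and p.rhs == pred
                        ):
                            theta[self.col[p.label]] = b_val
            theta[self.col[f"{dep}~~{dep}"]] = resid_var
        for p in self.params:
            if p.matrix == "Phi" and p.free:
                theta[self.col[p.label]] = s[vi[p.lhs], vi[p.rhs]]
        return theta

    def bounds(self) -> list[tuple[float | None, float | None]]:
        lower: dict[str, float] = {}
        for p in self.params:
            if p.free and p.matrix in ("Psi", "Phi") and p.lhs == p.rhs:
                lower[p.label] = _PSI_FLOOR
        return [(lower.get(lab), None) for lab in self.labels]

    def variance_labels(self) -> set[str]:
        return {
            p.label
            for p in self.params
            if p.free and p.matrix in ("Psi", "Phi") and p.lhs == p.rhs
        }

    def check_identification(self, theta0: np.ndarray, rng: np.random.Generator) -> None:
        """Local identification: the Jacobian of vech(Sigma) must have full rank."""
        q = len(self.labels)
        p = self.spec.n_var
        n_mom = p * (p + 1) // 2
        if q > n_mom:
            raise IdentificationError(
                f"{q} free parameters exceed {n_mom} covariance moments"
            )
        iu = np.triu_indices(p)
        point = theta0 + 0.05 * rng.standard_normal(q) + 0.01
        eps = 1e-6
        jac = np.empty((n_mom, q))
        try:
            for k in range(q):
                up, dn = point.copy(), point.copy()
                up[k] += eps
                dn[k] -= eps
                jac[:, k] = (self.sigma(up)[iu] - self.sigma(dn)[iu]) / (2 * eps)
        except np.linalg.LinAlgError as exc:
            raise IdentificationError(f"implied covariance undefined near start: {exc}")
        rank = np.linalg.matrix_rank(jac, tol=1e-8)
        if rank < q:
            raise IdentificationError(
                f"model locally unidentified: moment Jacobian rank {rank} < {q} "
                "free parameters"
            )


def implied_covariance(spec: PathModelSpec, theta) -> pd.DataFrame:
    """Model-implied covariance matrix over (endogenous, exogenous) variables.

    ``theta`` is either a mapping from parameter labels to values or a flat
    vector over ``spec.free_labels()``.
    """
    engine = _Engine(spec)
    if isinstance(theta, dict):
        vec = np.zeros(len(engine.labels))
        unknown = set(theta) - set(engine.labels)
        if unknown:
            raise KeyError(f"unknown parameter labels: {sorted(unknown)}")
        for lab, val in theta.items():
            vec[engine.col[lab]] = val
    else:
        vec = np.asarray(theta, dtype=float)
        if vec.shape != (len(engine.labels),):
            raise ValueError(
                f"theta must have length {len(engine.labels)} (free parameters)"
            )
    sigma = engine.sigma(vec)
    names = list(spec.variables)
    return pd.DataFrame(sigma, index=names, columns=names)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class PathFit:
    """Fitted path model: estimates, discrepancy, test statistic, fit indices."""

    spec: PathModelSpec
    params: pd.DataFrame
    f_ml: float
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_obs: int
    sample_cov: pd.DataFrame
    implied_cov: pd.DataFrame
    baseline_chi2: float
    baseline_df: int
    converged: bool
    heywood: tuple[str, ...] = ()
    n_restarts: int = 0

    def estimate(self, label: str) -> float:
        return float(self.params.set_index("label").loc[label, "est"])

    def standardized(self, label: str) -> float:
        return float(self.params.set_index("label").loc[label, "std_all"])


def _sample_cov(data: pd.DataFrame, variables: tuple[str, ...]) -> tuple[pd.DataFrame, int]:
    missing = set(variables) - set(data.columns)
    if missing:
        raise KeyError(f"data lacks model variables {sorted(missing)}")
    sub = data[list(variables)].dropna()
    n = len(sub)
    s = np.cov(sub.to_numpy(dtype=float), rowvar=False, ddof=1)
    return pd.DataFrame(s, index=list(variables), columns=list(variables)), n


def _srmr(s: np.ndarray, sigma: np.ndarray) -> float:
    p = s.shape[0]
    sd = np.sqrt(np.diag(s))
    resid = (s - sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def _baseline(s: np.ndarray, n_obs: int) -> tuple[float, int]:
    """Independence model: all covariances zero, variances free."""
    p = s.shape[0]
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")
    f_b = float(np.sum(np.log(np.diag(s))) - logdet_s)
    return (n_obs - 1) * f_b, p * (p - 1) // 2


def _fit_indices(chi2, df, base_chi2, base_df, n_eff):
    delta = max(chi2 - df, 0.0)
    delta_b = max(base_chi2 - base_df, 0.0)
    cfi = 1.0 - delta / max(delta_b, delta, np.finfo(float).tiny)
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df > 0 and base_df > 0 and base_chi2 / base_df > 1.0:
        tli = ((base_chi2 / base_df) - (chi2 / df)) / ((base_chi2 / base_df) - 1.0)
    else:
        tli = 1.0
    rmsea = math.sqrt(delta / (df * n_eff)) if df > 0 else 0.0
    return cfi, float(tli), float(rmsea)


def _optimize(fun, x0, bounds, rng, max_restarts=10):
    """L-BFGS-B on a (value, gradient) objective with jittered restarts."""
    best = None
    n_restarts = 0
    start = x0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            fun,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        grad_ok = np.max(np.abs(res.jac)) < 1e-4 if res.jac is not None else False
        if res.fun < 1e9 and (res.success or grad_ok):
            return best, attempt
        n_restarts = attempt + 1
        scale = np.maximum(np.abs(x0), 0.1)
        start = x0 + 0.3 * scale * rng.standard_normal(len(x0))
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
        start = np.maximum(start, lo + 1e-6)
    if best is None or best.fun >= 1e9:
        raise ConvergenceError("path-model optimization failed after all restarts")
    return best, n_restarts  # best effort: gradient tolerance not met but F finite


def _parameter_frame(engine, theta, se_by_col, sigma):
    sd = np.sqrt(np.diag(sigma))
    names = list(engine.spec.variables)
    vi = {v: i for i, v in enumerate(names)}
    rows = []
    for p in engine.params:
        est = theta[engine.col[p.label]] if p.free else p.value
        se = se_by_col.get(engine.col[p.label], np.nan) if p.free else np.nan
        if p.matrix in ("B", "Gamma"):
            std = est * sd[vi[p.rhs]] / sd[vi[p.lhs]]
        elif p.lhs == p.rhs:
            std = est / sd[vi[p.lhs]] ** 2
        else:
            std = est / (sd[vi[p.lhs]] * sd[vi[p.rhs]])
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        rows.append(
            {
                "label": p.label,
                "matrix": p.matrix,
                "lhs": p.lhs,
                "rhs": p.rhs,
                "free": p.free,
                "est": est,
                "se": se,
                "z": z,
                "p": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                "std_all": std,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.drop_duplicates(subset="label").reset_index(drop=True)


def _hessian(fun, x, step=1e-5):
    q = len(x)
    h = np.empty((q, q))
    f0 = fun(x)
    steps = step * np.maximum(np.abs(x), 1.0)
    for i in range(q):
        for j in range(i, q):
            xi, xj = steps[i], steps[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += xi
                xm[i] -= xi
                h[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / xi**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [xi, xj]
                xpm[i] += xi
                xpm[j] -= xj
                xmp[i] -= xi
                xmp[j] += xj
                xmm[[i, j]] -= [xi, xj]
                h[i, j] = h[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4 * xi * xj
                )
    return h


def fit_ml(
    spec: PathModelSpec,
    data: pd.DataFrame | None = None,
    sample_cov: pd.DataFrame | None = None,
    n_obs: int | None = None,
    compute_se: bool = True,
    max_restarts: int = 10,
    seed: int = 0,
) -> PathFit:
    """Fit the path model by maximum likelihood to data or to ``(S, N)``.

    Trial-level rows are treated as independent observations in the
    likelihood (any clustering is ignored; see the methods note).
    """
    if sample_cov is None:
        if data is None:
            raise ValueError("provide either data or (sample_cov, n_obs)")
        s_frame, n_obs = _sample_cov(data, spec.variables)
    else:
        if n_obs is None:
            raise ValueError("n_obs is required with a covariance input")
        s_frame = sample_cov.loc[list(spec.variables), list(spec.variables)]
    p = spec.n_var
    if n_obs <= p:
        raise ValueError(f"need more observations ({n_obs}) than variables ({p})")
    s = s_frame.to_numpy()
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")

    rng = np.random.default_rng(seed)
    engine = _Engine(spec)
    theta0 = engine.start_values(s_frame)
    engine.check_identification(theta0, rng)

    fun = lambda th: engine.discrepancy(th, s, logdet_s)
    vg = lambda th: engine.value_and_grad(th, s, logdet_s)
    res, n_restarts = _optimize(vg, theta0, engine.bounds(), rng, max_restarts)
    theta = res.x
    f_val = max(float(res.fun), 0.0)  # guard fp noise on saturated models

    heywood = tuple(
        lab
        for lab in engine.variance_labels()
        if theta[engine.col[lab]] <= _PSI_FLOOR * 10
    )

    se_by_col: dict[int, float] = {}
    if compute_se and len(theta):
        h = _hessian(fun, theta)
        try:
            cov = 2.0 / (n_obs - 1) * np.linalg.inv(h)
            diag = np.diag(cov)
            se_by_col = {
                i: float(np.sqrt(d)) if d > 0 else np.nan for i, d in enumerate(diag)
            }
        except np.linalg.LinAlgError:
            se_by_col = {}

    sigma = engine.sigma(theta)
    chi2 = (n_obs - 1) * f_val
    df = p * (p + 1) // 2 - len(engine.labels)
    base_chi2, base_df = _baseline(s, n_obs)
    cfi, tli, rmsea = _fit_indices(chi2, df, base_chi2, base_df, n_obs - 1)
    names = list(spec.variables)
    return PathFit(
        spec=spec,
        params=_parameter_frame(engine, theta, se_by_col, sigma),
        f_ml=f_val,
        chi2=float(chi2),
        df=int(df),
        p_value=float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        srmr=_srmr(s, sigma),
        n_obs=int(n_obs),
        sample_cov=s_frame,
        implied_cov=pd.DataFrame(sigma, index=names, columns=names),
        baseline_chi2=float(base_chi2),
        baseline_df=int(base_df),
        converged=True,
        heywood=heywood,
        n_restarts=n_restarts,
    )


def classify_fit(fit) -> str:
    """'good', 'acceptable' or 'poor' by the conventional index thresholds."""
    cfi = fit.cfi if hasattr(fit, "cfi") else fit["cfi"]
    tli = fit.tli if hasattr(fit, "tli") else fit["tli"]
    rmsea = fit.rmsea if hasattr(fit, "rmsea") else fit["rmsea"]
    srmr = fit.srmr if hasattr(fit, "srmr") else fit["srmr"]
    for name, th in (("good", GOOD_FIT), ("acceptable", ACCEPTABLE_FIT)):
        if (
            cfi >= th["cfi"]
            and tli >= th["tli"]
            and rmsea <= th["rmsea"]
            and srmr <= th["srmr"]
        ):
            return name
    return "poor"


# ---------------------------------------------------------------------------
# multi-group estimation and invariance testing
# ---------------------------------------------------------------------------


@dataclass
class MultiGroupFit:
    """Joint fit across groups with optional cross-group equality constraints."""

    spec: PathModelSpec
    groups: tuple[str, ...]
    constrained_labels: tuple[str, ...]
    params: dict[str, pd.DataFrame]
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_obs: dict[str, int]
    converged: bool

    def estimate(self, group: str, label: str) -> float:
        return float(self.params[group].set_index("label").loc[label, "est"])


@dataclass(frozen=True)
class ReleaseStep:
    """One step of the constraint-release procedure."""

    label: str
    delta_chi2: float
    delta_df: int
    p: float
    released: bool


@dataclass
class MultiGroupResult:
    """Full invariance analysis: per-group fits, joint fits, release registry."""

    group_fits: dict[str, PathFit]
    free_fit: MultiGroupFit
    constrained_fit: MultiGroupFit
    final_fit: MultiGroupFit
    steps: tuple[ReleaseStep, ...]
    released: tuple[str, ...]


def chi_square_difference(
    restricted: MultiGroupFit | PathFit, full: MultiGroupFit | PathFit
) -> tuple[float, int, float]:
    """Likelihood-ratio comparison of nested fits: (delta chi2, delta df, p)."""
    d_chi2 = restricted.chi2 - full.chi2
    d_df = restricted.df - full.df
    if d_df <= 0:
        raise ValueError("models are not nested in the expected direction")
    return float(d_chi2), int(d_df), float(sps.chi2.sf(max(d_chi2, 0.0), d_df))


def fit_multigroup(
    spec: PathModelSpec,
    data_by_group: dict[str, pd.DataFrame],
    constrained_labels=() ,
    compute_se: bool = False,
    max_restarts: int = 10,
    seed: int = 0,
) -> MultiGroupFit:
    """Simultaneous ML fit across groups.

    Parameters named in ``constrained_labels`` (or the shorthand ``"paths"``
    for every structural coefficient, ``"all"`` for every free parameter) are
    constrained equal across groups; everything else is group-specific.  The
    joint discrepancy is ``sum_g (N_g - 1) F_g``.
    """
    group_names = tuple(data_by_group)
    if len(group_names) < 2:
        raise ValueError("multi-group estimation requires at least two groups")
    if constrained_labels == "paths":
        constrained_labels = spec.path_labels()
    elif constrained_labels == "all":
        constrained_labels = spec.free_labels()
    constrained = tuple(constrained_labels)
    unknown = set(constrained) - set(spec.free_labels())
    if unknown:
        raise KeyError(f"unknown constraint labels: {sorted(unknown)}")

    engine = _Engine(spec)
    free_labels = engine.labels
    s_list, n_list, start_list = [], [], []
    rng = np.random.default_rng(seed)
    for g in group_names:
        s_frame, n_g = _sample_cov(data_by_group[g], spec.variables)
        s = s_frame.to_numpy()
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise ValueError(f"group {g}: sample covariance not positive definite")
        if n_g <= spec.n_var:
            raise ValueError(f"group {g}: too few observations ({n_g})")
        theta_g = engine.start_values(s_frame)
        s_list.append((s, logdet, s_frame))
        n_list.append(n_g)
        start_list.append(theta_g)
    engine.check_identification(start_list[0], rng)

    # joint parameter layout: shared columns first, then per-group columns
    shared = [lab for lab in free_labels if lab in constrained]
    per_group = [lab for lab in free_labels if lab not in constrained]
    col_of: dict[tuple[str, str], int] = {}
    for k, lab in enumerate(shared):
        for g in group_names:
            col_of[(g, lab)] = k
    offset = len(shared)
    for gi, g in enumerate(group_names):
        for k, lab in enumerate(per_group):
            col_of[(g, lab)] = offset + gi * len(per_group) + k
    q_total = offset + len(group_names) * len(per_group)
    idx_by_group = [
        np.array([col_of[(g, lab)] for lab in free_labels]) for g in group_names
    ]

    x0 = np.zeros(q_total)
    counts = np.zeros(q_total)
    for gi, g in enumerate(group_names):
        np.add.at(x0, idx_by_group[gi], start_list[gi])
        np.add.at(counts, idx_by_group[gi], 1.0)
    x0 /= counts

    var_labels = engine.variance_labels()
    bounds = [(None, None)] * q_total
    for (g, lab), c in col_of.items():
        if lab in var_labels:
            bounds[c] = (_PSI_FLOOR, None)

    weights = np.array(n_list, dtype=float) - 1.0

    def fun(theta: np.ndarray) -> float:
        total = 0.0
        for gi in range(len(group_names)):
            s, logdet, _ = s_list[gi]
            total += weights[gi] * engine.discrepancy(theta[idx_by_group[gi]], s, logdet)
        return total

    def fun_and_grad(theta: np.ndarray):
        total = 0.0
        grad = np.zeros_like(theta)
        for gi in range(len(group_names)):
            s, logdet, _ = s_list[gi]
            f_g, g_g = engine.value_and_grad(theta[idx_by_group[gi]], s, logdet)
            total += weights[gi] * f_g
            np.add.at(grad, idx_by_group[gi], weights[gi] * g_g)
        return total, grad

    res, _ = _optimize(fun_and_grad, x0, bounds, rng, max_restarts)
    theta = res.x
    chi2 = float(res.fun)
    p = spec.n_var
    df = len(group_names) * p * (p + 1) // 2 - q_total

    base_chi2, base_df = 0.0, 0
    srmr_vals = []
    params: dict[str, pd.DataFrame] = {}
    for gi, g in enumerate(group_names):
        s, logdet, s_frame = s_list[gi]
        bc, bdf = _baseline(s, n_list[gi])
        base_chi2 += bc
        base_df += bdf
        theta_g = theta[idx_by_group[gi]]
        sigma_g = engine.sigma(theta_g)
        srmr_vals.append(_srmr(s, sigma_g))
        params[g] = _parameter_frame(engine, theta_g, {}, sigma_g)
    n_eff = sum(n_list) - len(group_names)
    cfi, tli, rmsea = _fit_indices(chi2, df, base_chi2, base_df, n_eff)
    rmsea *= math.sqrt(len(group_names))  # multi-group convention

    if compute_se:
        h = _hessian(fun, theta)
        try:
            cov = 2.0 * np.linalg.inv(h)
            diag = np.diag(cov)
            for gi, g in enumerate(group_names):
                se_map = {
                    k: float(np.sqrt(diag[c])) if diag[c] > 0 else np.nan
                    for k, c in enumerate(idx_by_group[gi])
                }
                sigma_g = engine.sigma(theta[idx_by_group[gi]])
                params[g] = _parameter_frame(engine, theta[idx_by_group[gi]], se_map, sigma_g)
        except np.linalg.LinAlgError:
            pass

    return MultiGroupFit(
        spec=spec,
        groups=group_names,
        constrained_labels=constrained,
        params=params,
        chi2=chi2,
        df=int(df),
        p_value=float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        srmr=float(np.mean(srmr_vals)),
        n_obs=dict(zip(group_names, n_list)),
        converged=True,
    )


def release_stepwise(
    spec: PathModelSpec,
    data_by_group: dict[str, pd.DataFrame],
    candidate_labels=None,
    alpha: float = 0.05,
    max_release: int | None = None,
    seed: int = 0,
) -> MultiGroupResult:
    """Partial-invariance search by stepwise release of equality constraints.

    Starting from a model with all candidate structural paths constrained
    equal across groups, each step frees the single constraint whose release
    most improves fit (by the chi-square difference test); the procedure
    stops when no release is significant at ``alpha``.  Each released
    constraint contributes ``(n_groups - 1)`` degrees of freedom.
    """
    candidates = tuple(candidate_labels or spec.path_labels())
    group_fits = {
        g: fit_ml(spec, data=df_g, compute_se=False, seed=seed)
        for g, df_g in data_by_group.items()
    }
    free_fit = fit_multigroup(spec, data_by_group, (), seed=seed)
    constrained_fit = fit_multigroup(spec, data_by_group, candidates, seed=seed)

    current = constrained_fit
    remaining = list(candidates)
    released: list[str] = []
    steps: list[ReleaseStep] = []
    budget = max_release if max_release is not None else len(candidates)
    while remaining and len(released) < budget:
        trials = []
        for lab in remaining:
            trial_constraints = tuple(l for l in remaining if l != lab)
            fit_try = fit_multigroup(spec, data_by_group, trial_constraints, seed=seed)
            d_chi2, d_df, p_val = chi_square_difference(current, fit_try)
            trials.append((p_val, d_chi2, d_df, lab, fit_try))
        trials.sort(key=lambda t: (t[0], -t[1]))
        p_val, d_chi2, d_df, lab, fit_try = trials[0]
        if p_val < alpha:
            steps.append(ReleaseStep(lab, d_chi2, d_df, p_val, True))
            released.append(lab)
            remaining.remove(lab)
            current = fit_try
        else:
            steps.append(ReleaseStep(lab, d_chi2, d_df, p_val, False))
            break
    return MultiGroupResult(
        group_fits=group_fits,
        free_fit=free_fit,
        constrained_fit=constrained_fit,
        final_fit=current,
        steps=tuple(steps),
        released=tuple(released),
    )
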