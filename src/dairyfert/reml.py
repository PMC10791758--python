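"""Single-trait animal-model REML.

The model is ``y = Xb + sum_i Z_i u_i + e`` with additive animal effects
``a ~ N(0, A sigma_a^2)``, herd-year ``HY ~ N(0, I sigma_hy^2)``, service
sire ``SS ~ N(0, A_ss sigma_ss^2)`` and ``e ~ N(0, I sigma_e^2)``.
Variance components are estimated by maximizing the restricted likelihood,
evaluated through the sparse mixed-model equations (never forming dense V):

    -2 lR = (n-p) log 2pi + log|R| + log|G| + log|C| + y'Py

where C is Henderson's coefficient matrix on the R^-1 scale and
``y'Py = (y'y - sol'rhs)/sigma_e^2``.  Residual variance is profiled out.
The optimizer runs EM warm-start iterations (exact prediction-error
traces, affordable only while the system is small), then Nelder-Mead on
the profiled likelihood over log variance ratios, then Newton polish
steps whose curvature is the average-information (AI) matrix and whose
score comes from central finite differences; the inverse AI matrix
supplies standard errors.  Components that collapse are pinned at a small
floor and flagged rather than allowed to go negative.  Heritability is
``h2 = sigma_a^2 / (sigma_a^2 + sigma_hy^2 + sigma_ss^2 + sigma_e^2)``;
every fitted random component enters the phenotypic denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from ._sparse_ldl import (
    NotPositiveDefinite,
    SparseLDL,
    align_pattern,
    fill_reducing_ordering,
)
from .dataprep import ModelSpec, TraitDataset
from .pedigree import AInverse

log = logging.getLogger(__name__)

__all__ = [
    "MixedModelError",
    "MMESystem",
    "VarianceComponents",
    "REMLOptions",
    "build_mme",
    "solve_blup",
    "reml_loglik",
    "estimate_reml",
    "design_engine",
    "heritability",
    "write_results_csv",
    "write_run_log",
]

LOG2PI = float(np.log(2.0 * np.pi))


class MixedModelError(RuntimeError):
    """Singular or inconsistent mixed-model system."""


@dataclass
class VarianceComponents:
    """REML estimates with AI-matrix standard errors."""

    sigma2_a: float
    sigma2_e: float
    sigma2_hy: float | None = None
    sigma2_ss: float | None = None
    se: dict[str, float] = field(default_factory=dict)
    h2: float | None = None
    h2_se: float | None = None
    converged: bool = True
    floored: tuple[str, ...] = ()
    n_iter: int = 0
    neg2ll: float | None = None
    trace: list = field(default_factory=list)
    cov: np.ndarray | None = None        # covariance of (components..., e)
    names: tuple[str, ...] = ()          # order matching cov

    def as_dict(self) -> dict[str, float]:
        out = {"a": self.sigma2_a, "e": self.sigma2_e}
        if self.sigma2_hy is not None:
            out["HY"] = self.sigma2_hy
        if self.sigma2_ss is not None:
            out["SS"] = self.sigma2_ss
        return out

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass
class REMLOptions:
    """Tuning knobs for :func:`estimate_reml`."""

    start_frac: float = 0.10     # start: this fraction of var(y) per random term
    max_iter: int = 20           # Newton polish iterations
    tol: float = 1e-8            # relative parameter-change convergence
    em_max_dim: int = 600        # EM warm start only below this system size
    em_iters: int = 15
    em_rtol: float = 5e-3        # EM considered stabilized below this change
    floor_frac: float = 1e-8     # variance floor as fraction of var(y)
    nm_maxfev: int = 300
    nm_xatol: float = 1e-5
    nm_fatol: float = 1e-8


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _RandomTerm:
    name: str
    Z: sp.csr_matrix
    Kinv: sp.csc_matrix          # q x q (identity for HY)
    logdetK: float
    q: int
    labels: tuple


def _dummy(labels: np.ndarray, drop_first: bool) -> tuple[sp.csr_matrix, tuple]:
    levels, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    n, q = len(codes), len(levels)
    if drop_first:
        keep = codes > 0
        mat = sp.csr_matrix(
            (np.ones(keep.sum()), (np.nonzero(keep)[0], codes[keep] - 1)),
            shape=(n, q - 1),
        )
        return mat, tuple(levels[1:])
    mat = sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
    return mat, tuple(levels)


def _incidence(ids: np.ndarray, target_ids: tuple) -> sp.csr_matrix:
    pos = {a: i for i, a in enumerate(target_ids)}
    missing = sorted({a for a in ids if a not in pos})
    if missing:
        raise MixedModelError(f"ids missing from relationship structure: {missing[:10]}")
    codes = np.array([pos[a] for a in ids])
    return sp.csr_matrix(
        (np.ones(len(ids)), (np.arange(len(ids)), codes)),
        shape=(len(ids), len(target_ids)),
    )


def _build_design(
    ds: TraitDataset,
    spec: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None,
) -> tuple[sp.csr_matrix, dict, list[_RandomTerm]]:
    """X (full rank via drop-first constraints), fixed index map, random terms.

    Solution ordering: fixed-effect levels, HY levels, SS ids, animals in
    pedigree order.
    """
    if ds.n == 0:
        raise MixedModelError("empty dataset")
    blocks, fixed_index = [], {}
    col = 0
    if not spec.fixed_effects:
        blocks.append(sp.csr_matrix(np.ones((ds.n, 1))))
        fixed_index["mu"] = (slice(0, 1), ("mu",))
        col = 1
    for j, eff in enumerate(spec.fixed_effects):
        mat, levels = _dummy(ds.fixed[eff], drop_first=(j > 0))
        blocks.append(mat)
        fixed_index[eff] = (slice(col, col + mat.shape[1]), levels)
        col += mat.shape[1]
    X = sp.hstack(blocks, format="csr")

    randoms: list[_RandomTerm] = []
    if spec.has_hy:
        if ds.hy_labels is None:
            raise MixedModelError("spec includes HY but dataset has no hy_labels")
        Z, levels = _dummy(ds.hy_labels, drop_first=False)
        q = Z.shape[1]
        randoms.append(_RandomTerm("HY", Z, sp.identity(q, format="csc"), 0.0, q, levels))
    if spec.has_ss:
        if ass_inv is None or ds.ss_ids is None:
            raise MixedModelError("spec includes SS but no service-sire structure given")
        if any(s is None for s in ds.ss_ids):
            raise MixedModelError("missing service-sire ids in dataset")
        Z = _incidence(ds.ss_ids, ass_inv.ids)
        randoms.append(
            _RandomTerm("SS", Z, ass_inv.matrix.tocsc(), ass_inv.log_det_a,
                        len(ass_inv.ids), ass_inv.ids)
        )
    Z = _incidence(ds.animal_ids, ainv.ids)
    randoms.append(
        _RandomTerm("a", Z, ainv.matrix.tocsc(), ainv.log_det_a, len(ainv.ids), ainv.ids)
    )
    return X, fixed_index, randoms


# ---------------------------------------------------------------------------
# factorization helpers


def _factor(C: sp.csc_matrix):
    """One-shot sparse factorization (for public single-solve operations)."""
    try:
        lu = splu(
            C.tocsc(),
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options=dict(SymmetricMode=True),
        )
    except RuntimeError as err:
        raise MixedModelError(f"mixed-model equations singular: {err}") from err
    diag = lu.U.diagonal()
    if np.any(diag <= 0):
        raise MixedModelError("coefficient matrix not positive definite")
    return lu, float(np.sum(np.log(diag)))


class _REMLEngine:
    """Likelihood/EM/AI machinery for one univariate mixed model.

    The coefficient-matrix sparsity pattern is fixed across iterations;
    only the variance ratios scaling the K^-1 blocks change.  All
    components are pre-aligned onto the union pattern so an iteration is a
    vector combination plus an O(nnz(L)) numeric refactorization.
    """

    def __init__(self, y: np.ndarray, X: sp.csr_matrix, randoms: list[_RandomTerm]):
        self.y = np.asarray(y, dtype=float)
        self.X = X.tocsr()
        self.randoms = randoms
        self.n = len(self.y)
        self.p = X.shape[1]
        self.Omega = sp.hstack([X] + [r.Z for r in randoms], format="csr")
        self.M = self.Omega.shape[1]
        OtO = (self.Omega.T @ self.Omega).tocsc()
        self.Oty = np.asarray(self.Omega.T @ self.y).ravel()
        self.yty = float(self.y @ self.y)
        self.slices = {}
        col = self.p
        for r in randoms:
            self.slices[r.name] = slice(col, col + r.q)
            col += r.q
        Kpads = {}
        for r in randoms:
            K = r.Kinv.tocoo()
            off = self.slices[r.name].start
            Kpads[r.name] = sp.coo_matrix(
                (K.data, (K.row + off, K.col + off)), shape=(self.M, self.M)
            ).tocsc()
        pattern = abs(OtO)
        for mat in Kpads.values():
            pattern = pattern + abs(mat)
        pattern = pattern.tocsc()
        pattern.sort_indices()
        self.pattern = pattern
        self.base = align_pattern(OtO, pattern)
        self.Kdata = {k: align_pattern(v, pattern) for k, v in Kpads.items()}
        self.logdetK = {r.name: r.logdetK for r in randoms}
        self.q = {r.name: r.q for r in randoms}
        self.names = [r.name for r in randoms]
        self._ldl: SparseLDL | None = None

    def set_response(self, y: np.ndarray) -> None:
        """Swap the response vector, keeping design and symbolic analysis.

        For replicate studies that re-draw the random effects on a fixed
        design; the caller guarantees ``y`` is ordered like the original.
        """
        if len(y) != self.n:
            raise ValueError("response length does not match the design")
        self.y = np.asarray(y, dtype=float)
        self.Oty = np.asarray(self.Omega.T @ self.y).ravel()
        self.yty = float(self.y @ self.y)

    # -- factorization ---------------------------------------------------

    def _data(self, gammas: dict[str, float]) -> np.ndarray:
        data = self.base.copy()
        for k in self.names:
            data += self.Kdata[k] * (1.0 / gammas[k])
        return data

    def _ldl_solve(self, gammas: dict[str, float]):
        if self._ldl is None:
            self._ldl = SparseLDL(self.pattern, fill_reducing_ordering(self.pattern))
        try:
            logdetC1 = self._ldl.factor(self._data(gammas))
        except NotPositiveDefinite as err:
            raise MixedModelError(str(err)) from err
        sol = self._ldl.solve(self.Oty.copy())
        ssr = self.yty - float(sol @ self.Oty)
        return logdetC1, sol, max(ssr, 1e-300)

    # -- likelihood ------------------------------------------------------

    def neg2ll(self, theta: dict[str, float]) -> float:
        """-2 restricted log-likelihood at variances ``theta`` (incl 'e')."""
        se2 = theta["e"]
        gammas = {k: theta[k] / se2 for k in self.names}
        logdetC1, _, ssr = self._ldl_solve(gammas)
        val = (self.n - self.p) * (LOG2PI + np.log(se2)) + logdetC1 + ssr / se2
        for k in self.names:
            val += self.q[k] * np.log(gammas[k]) + self.logdetK[k]
        return float(val)

    def profile(self, gammas: dict[str, float]) -> tuple[float, float]:
        """(profiled -2 lR, sigma_e^2 hat) at given variance ratios."""
        logdetC1, _, ssr = self._ldl_solve(gammas)
        se2 = ssr / (self.n - self.p)
        val = (self.n - self.p) * (LOG2PI + np.log(se2) + 1.0) + logdetC1
        for k in self.names:
            val += self.q[k] * np.log(gammas[k]) + self.logdetK[k]
        return float(val), float(se2)

    # -- EM --------------------------------------------------------------

    def em_step(self, theta: dict[str, float]) -> dict[str, float]:
        """One exact EM update (dense prediction-error covariance)."""
        se2 = theta["e"]
        gammas = {k: theta[k] / se2 for k in self.names}
        data = self._data(gammas)
        C1 = sp.csc_matrix(
            (data, self.pattern.indices, self.pattern.indptr), shape=(self.M, self.M)
        )
        lu, _ = _factor(C1)
        sol = lu.solve(self.Oty)
        Cinv = np.linalg.inv(C1.toarray()) * se2   # PEV matrix
        new = {}
        for k in self.names:
            sl = self.slices[k]
            u = sol[sl]
            Kinv = next(r.Kinv for r in self.randoms if r.name == k)
            quad = float(u @ (Kinv @ u))
            tr = float(np.sum(Kinv.multiply(Cinv[sl, sl])))
            new[k] = (quad + tr) / self.q[k]
        new["e"] = (self.yty - float(sol @ self.Oty)) / (self.n - self.p)
        return new

    # -- AI matrix -------------------------------------------------------

    def ai_matrix(self, theta: dict[str, float]) -> tuple[np.ndarray, list[str]]:
        """Average-information matrix for (randoms..., e) at ``theta``."""
        se2 = theta["e"]
        gammas = {k: theta[k] / se2 for k in self.names}
        _, sol, _ = self._ldl_solve(gammas)
        resid = self.y - np.asarray(self.Omega @ sol).ravel()
        Py = resid / se2
        fs = []
        order = list(self.names) + ["e"]
        for k in self.names:
            u = sol[self.slices[k]]
            Zk = next(r.Z for r in self.randoms if r.name == k)
            fs.append(np.asarray(Zk @ u).ravel() / theta[k])
        fs.append(Py)
        # P f = (f - Omega C^-1 Omega' R^-1 f) / sigma_e^2
        Pf = []
        for f in fs:
            rhs = np.asarray(self.Omega.T @ f).ravel()
            sol_f = self._ldl.solve(rhs)
            Pf.append((f - np.asarray(self.Omega @ sol_f).ravel()) / se2)
        m = len(fs)
        AI = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])
        return AI, order

    def fd_grad(self, theta: dict[str, float], free: list[str], rel_h: float = 1e-4
                ) -> np.ndarray:
        """Central finite-difference gradient of -2 lR w.r.t. free variances."""
        g = np.empty(len(free))
        for i, k in enumerate(free):
            h = rel_h * theta[k]
            up = dict(theta); up[k] = theta[k] + h
            dn = dict(theta); dn[k] = max(theta[k] - h, 1e-300)
            g[i] = (self.neg2ll(up) - self.neg2ll(dn)) / (up[k] - dn[k])
        return g


# ---------------------------------------------------------------------------
# public operations


@dataclass
class MMESystem:
    """Henderson's mixed-model equations in variance-ratio (lambda) form."""

    C: sp.csc_matrix
    rhs: np.ndarray
    index: dict
    n_records: int
    p: int
    sigma2_e: float


def _theta_dict(theta, names: list[str]) -> dict[str, float]:
    if isinstance(theta, VarianceComponents):
        d = theta.as_dict()
    else:
        d = dict(theta)
    missing = [k for k in names + ["e"] if k not in d]
    if missing:
        raise MixedModelError(f"missing variance components: {missing}")
    if any(d[k] <= 0 for k in names + ["e"]):
        raise MixedModelError("variance components must be strictly positive")
    return d


def build_mme(
    ds: TraitDataset,
    spec: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None = None,
    theta=None,
) -> MMESystem:
    """Assemble the MME ``[X'X X'Z; Z'X Z'Z + blockdiag(K^-1 lambda)]``."""
    X, fixed_index, randoms = _build_design(ds, spec, ainv, ass_inv)
    eng = _REMLEngine(ds.y, X, randoms)
    th = _theta_dict(theta, eng.names)
    gammas = {k: th[k] / th["e"] for k in eng.names}
    C = sp.csc_matrix(
        (eng._data(gammas), eng.pattern.indices, eng.pattern.indptr),
        shape=(eng.M, eng.M),
    )
    index = {"fixed": fixed_index}
    for r in randoms:
        index[r.name] = (eng.slices[r.name], r.labels)
    return MMESystem(
        C=C, rhs=eng.Oty, index=index, n_records=ds.n, p=eng.p, sigma2_e=th["e"]
    )


def solve_blup(mme: MMESystem) -> dict:
    """Solve the MME; returns per-block solutions keyed like ``mme.index``."""
    lu, _ = _factor(mme.C)
    sol = lu.solve(mme.rhs)
    resid_norm = float(np.linalg.norm(mme.C @ sol - mme.rhs))
    if not np.isfinite(resid_norm) or resid_norm > 1e-6 * (1.0 + np.linalg.norm(mme.rhs)):
        raise MixedModelError(f"MME solve did not converge, residual {resid_norm:.3e}")
    out = {"solution": sol}
    for name, entry in mme.index.items():
        if name == "fixed":
            out["fixed"] = {
                eff: dict(zip(levels, sol[sl])) for eff, (sl, levels) in entry.items()
            }
        else:
            sl, labels = entry
            out[name] = dict(zip(labels, sol[sl]))
    return out


def reml_loglik(
    theta,
    ds: TraitDataset,
    spec: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None = None,
) -> float:
    """Restricted log-likelihood (including constants) at ``theta``."""
    X, _, randoms = _build_design(ds, spec, ainv, ass_inv)
    eng = _REMLEngine(ds.y, X, randoms)
    return -0.5 * eng.neg2ll(_theta_dict(theta, eng.names))


def _estimate(eng: _REMLEngine, opts: REMLOptions) -> VarianceComponents:
    var_p = float(np.var(eng.y, ddof=1))
    if var_p <= 0:
        raise MixedModelError("response has zero variance")
    floor = opts.floor_frac * var_p
    names = eng.names
    theta = {k: opts.start_frac * var_p for k in names}
    theta["e"] = max(var_p * (1.0 - opts.start_frac * len(names)), 0.1 * var_p)
    trace: list[tuple[str, float]] = []
    n_iter = 0

    # EM warm start (exact traces; small systems only)
    if eng.M <= opts.em_max_dim:
        prev_ll = eng.neg2ll(theta)
        trace.append(("start", prev_ll))
        for _ in range(opts.em_iters):
            new = eng.em_step(theta)
            new = {k: max(v, floor) for k, v in new.items()}
            rel = max(abs(new[k] - theta[k]) / max(theta[k], floor) for k in new)
            theta = new
            ll = eng.neg2ll(theta)
            trace.append(("em", ll))
            n_iter += 1
            if ll > prev_ll + 1e-6 * abs(prev_ll):
                log.warning("EM step decreased the restricted likelihood")
            prev_ll = ll
            if rel < opts.em_rtol:
                break

    # Nelder-Mead on the profiled likelihood over log variance ratios
    gmin = floor / var_p

    def objective(x):
        gam = {k: max(float(np.exp(xi)), gmin) for k, xi in zip(names, x)}
        try:
            val, _ = eng.profile(gam)
        except MixedModelError:
            return np.inf
        return val

    x0 = np.log([max(theta[k] / theta["e"], gmin) for k in names])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options=dict(
            xatol=opts.nm_xatol, fatol=opts.nm_fatol, maxfev=opts.nm_maxfev,
            disp=False,
        ),
    )
    n_iter += res.nfev
    gam = {k: max(float(np.exp(xi)), gmin) for k, xi in zip(names, res.x)}
    val, se2 = eng.profile(gam)
    theta = {k: gam[k] * se2 for k in names}
    theta["e"] = se2
    trace.append(("nm", val))

    # floor-and-flag, then AI-Newton polish on the free components
    floored = tuple(k for k in names if theta[k] <= 1.05 * floor)
    for k in floored:
        theta[k] = floor
    free = [k for k in names if k not in floored] + ["e"]
    f_cur = eng.neg2ll(theta)
    converged = False
    for _ in range(opts.max_iter):
        g = eng.fd_grad(theta, free)
        AI, order = eng.ai_matrix(theta)
        idx = [order.index(k) for k in free]
        AI_free = AI[np.ix_(idx, idx)]
        try:
            step = -0.5 * np.linalg.solve(AI_free, g)
        except np.linalg.LinAlgError:
            step = -0.5 * np.linalg.lstsq(AI_free, g, rcond=None)[0]
        # damped line search keeping variances above the floor
        improved = False
        for _half in range(12):
            cand = dict(theta)
            for k, d in zip(free, step):
                cand[k] = max(theta[k] + d, floor)
            try:
                f_new = eng.neg2ll(cand)
            except MixedModelError:
                f_new = np.inf
            if f_new <= f_cur + 1e-12 * abs(f_cur):
                improved = True
                break
            step *= 0.5
        n_iter += 1
        if not improved:
            # no ascent left at finite-difference resolution
            converged = True
            break
        rel = max(abs(cand[k] - theta[k]) / max(theta[k], floor) for k in free)
        df = f_cur - f_new
        theta, f_cur = cand, f_new
        trace.append(("ai", f_cur))
        if rel < opts.tol or df < 1e-9 * (1.0 + abs(f_cur)):
            converged = True
            break
    else:
        log.warning("REML polish hit max_iter; returning best point")

    # SEs from the inverse AI matrix over all components (incl floored)
    AI, order = eng.ai_matrix(theta)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    se = {k: float(np.sqrt(max(cov[i, i], 0.0))) for i, k in enumerate(order)}

    vc = VarianceComponents(
        sigma2_a=theta["a"] if "a" in theta else 0.0,
        sigma2_e=theta["e"],
        sigma2_hy=theta.get("HY"),
        sigma2_ss=theta.get("SS"),
        se=se,
        converged=converged,
        floored=floored,
        n_iter=n_iter,
        neg2ll=f_cur,
        trace=trace,
        cov=cov,
        names=tuple(order),
    )
    if "a" in theta:
        vc.h2, vc.h2_se = heritability(vc)
    return vc


def estimate_reml(
    ds: TraitDataset,
    spec: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None = None,
    opts: REMLOptions | None = None,
    engine: "_REMLEngine | None" = None,
) -> VarianceComponents:
    """Animal-model REML variance components for one trait x stage.

    Pass ``engine`` (from a previous call via :func:`design_engine`) to
    reuse the design and symbolic factorization across replicates that
    only change the response.
    """
    if engine is None:
        engine = design_engine(ds, spec, ainv, ass_inv)
    else:
        engine.set_response(ds.y)
    return _estimate(engine, opts or REMLOptions())


def design_engine(
    ds: TraitDataset,
    spec: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None = None,
) -> _REMLEngine:
    """Build the reusable design/factorization engine for a dataset."""
    X, _, randoms = _build_design(ds, spec, ainv, ass_inv)
    return _REMLEngine(ds.y, X, randoms)


def heritability(vc: VarianceComponents | None = None, **components) -> tuple[float, float | None]:
    """h2 = sigma_a^2 / (sigma_a^2 + sigma_hy^2 + sigma_ss^2 + sigma_e^2).

    Accepts a :class:`VarianceComponents` (delta-method SE from its AI
    covariance) or raw keyword components ``sigma2_a``, ``sigma2_e``,
    optional ``sigma2_hy``, ``sigma2_ss`` (SE ``None`` unless ``cov`` and
    ``names`` are supplied alongside).
    """
    if vc is not None:
        comp = vc.as_dict()
        cov, names = vc.cov, vc.names
    else:
        comp = {"a": components["sigma2_a"], "e": components["sigma2_e"]}
        if components.get("sigma2_hy") is not None:
            comp["HY"] = components["sigma2_hy"]
        if components.get("sigma2_ss") is not None:
            comp["SS"] = components["sigma2_ss"]
        cov = components.get("cov")
        names = components.get("names", ())
    total = sum(comp.values())
    if total <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    h2 = comp["a"] / total
    se = None
    if cov is not None and len(names) == cov.shape[0]:
        grad = np.array(
            [((total - comp["a"]) if k == "a" else -comp["a"]) / total**2 for k in names]
        )
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(h2), se


def write_results_csv(results: dict[str, VarianceComponents], path) -> None:
    """Variance-component table: one row per trait, SEs in parentheses."""
    import pandas as pd

    def fmt(v, s):
        if v is None:
            return ""
        return f"{v:.4f} ({s:.4f})" if s is not None else f"{v:.4f}"

    rows = []
    for name, vc in results.items():
        rows.append(
            {
                "trait": name,
                "sigma2_a": fmt(vc.sigma2_a, vc.se.get("a")),
                "sigma2_hy": fmt(vc.sigma2_hy, vc.se.get("HY")),
                "sigma2_ss": fmt(vc.sigma2_ss, vc.se.get("SS")),
                "sigma2_e": fmt(vc.sigma2_e, vc.se.get("e")),
                "h2": fmt(vc.h2, vc.h2_se),
                "converged": vc.converged,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_log(vc: VarianceComponents, path) -> None:
    """JSON run log with the iteration trace of the restricted likelihood."""
    import json

    payload = {
        "converged": bool(vc.converged),
        "n_iter": int(vc.n_iter),
        "neg2ll": vc.neg2ll,
        "floored": list(vc.floored),
        "components": vc.as_dict(),
        "se": vc.se,
        "h2": vc.h2,
        "h2_se": vc.h2_se,
        "trace": [[tag, float(v)] for tag, v in vc.trace],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
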