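"""Two-trait REML for heifer/cow pairs of one fertility trait.

The stacked model places heifer records (trait 1) and cow records
(trait 2) in one system: additive effects follow ``N(0, G (x) A)`` with a
2x2 genetic covariance G, herd-year and service-sire blocks are 2x2
analogues, and residuals are correlated only within animals that carry a
record at both stages.  The genetic correlation is
``rg = G12 / sqrt(G11 G22)``.

Estimation is AI-REML on the unique elements of the 2x2 blocks: Newton
steps with the average-information matrix and central finite-difference
scores, each accepted update projected back to the PSD cone by eigenvalue
clipping.  The residual covariance is estimated only when enough animals
carry both records (default 30), otherwise fixed at 0 and flagged.  The
coefficient matrix is a fixed-pattern combination of precomputed pieces
(residual-structure cross-products and ``kron(E_ij, K^-1)`` blocks), so
one likelihood evaluation is a vector combination plus a numeric
refactorization with a cached symbolic analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._sparse_ldl import (
    NotPositiveDefinite,
    SparseLDL,
    align_pattern,
    fill_reducing_ordering,
)
from .dataprep import ModelSpec, TraitDataset
from .pedigree import AInverse
from .reml import (
    LOG2PI,
    MixedModelError,
    REMLOptions,
    VarianceComponents,
    _dummy,
    _incidence,
    estimate_reml,
)

log = logging.getLogger(__name__)

__all__ = [
    "CovarianceSet",
    "BivariateData",
    "BivariateOptions",
    "stack_bivariate",
    "estimate_bivariate_reml",
    "merge_traits",
    "write_covariance_csv",
]


@dataclass
class CovarianceSet:
    """2x2 (co)variance blocks of a heifer/cow trait pair."""

    G: np.ndarray
    HY: np.ndarray
    R: np.ndarray
    SS: np.ndarray | None = None
    se: dict[str, float] = field(default_factory=dict)
    rg: float = np.nan
    rg_se: float | None = None
    rp: float = np.nan
    h2: tuple[float, float] = (np.nan, np.nan)
    h2_se: tuple[float, float] = (np.nan, np.nan)
    converged: bool = True
    near_boundary: bool = False
    residual_cov_fixed: bool = False
    n_iter: int = 0
    neg2ll: float | None = None

    def phenotypic(self) -> np.ndarray:
        P = self.G + self.HY + self.R
        if self.SS is not None:
            P = P + self.SS
        return P


@dataclass
class BivariateData:
    """Stacked heifer/cow datasets plus identifiability diagnostics."""

    ds1: TraitDataset
    ds2: TraitDataset
    n_both: int
    common_animals: tuple
    connected: bool


@dataclass
class BivariateOptions:
    max_iter: int = 25
    tol: float = 1e-6            # relative parameter change
    f_tol: float = 1e-4          # absolute -2logL improvement considered nil
    boundary_f_tol: float = 0.2  # creep threshold while pinned to the PSD cone
    verbose: bool = False
    min_pairs: int = 30          # animals with both records to free R12
    start_rg: float = 0.5
    start_g12: float | None = None   # override genetic covariance start
    eig_floor: float = 1e-8      # eigenvalue clip, x geometric-mean variance
    boundary_rg: float = 0.98
    boundary_se: float = 0.5


def _pedigree_components(ped) -> dict[str, int]:
    """Union-find over parent links -> component label per animal."""
    n = len(ped)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                parent[find(i)] = find(p)
    return {ped.ids[i]: find(i) for i in range(n)}


def stack_bivariate(
    ds1: TraitDataset, ds2: TraitDataset, ped, on_disconnected: str = "raise"
) -> BivariateData:
    """Pair the stage datasets and check genetic connectedness.

    Raises ``MixedModelError("traits genetically disconnected")`` when no
    pedigree relationship links any heifer-recorded animal to any
    cow-recorded animal (``on_disconnected="flag"`` records it instead).
    """
    set1, set2 = set(ds1.animal_ids), set(ds2.animal_ids)
    common = tuple(sorted(set1 & set2))
    comp = _pedigree_components(ped)
    comps1 = {comp[a] for a in set1 if a in comp}
    comps2 = {comp[a] for a in set2 if a in comp}
    connected = bool(comps1 & comps2)
    if not connected and on_disconnected == "raise":
        raise MixedModelError(
            "traits genetically disconnected: no pedigree path joins the "
            "heifer and cow record sets; rg is unidentifiable"
        )
    return BivariateData(
        ds1=ds1, ds2=ds2, n_both=len(common), common_animals=common,
        connected=connected,
    )


# ---------------------------------------------------------------------------


def _psd_clip(M: np.ndarray, floor_frac: float) -> np.ndarray:
    d = np.sqrt(max(M[0, 0] * M[1, 1], 0.0))
    eps = floor_frac * max(d, 1e-300)
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    w = np.maximum(w, eps)
    return V @ np.diag(w) @ V.T


class _BivariateEngine:
    """Stacked two-trait MME with structured residual covariance."""

    def __init__(
        self,
        joint: BivariateData,
        spec1: ModelSpec,
        spec2: ModelSpec,
        ainv: AInverse,
        ass_inv: AInverse | None,
    ):
        ds1, ds2 = joint.ds1, joint.ds2
        if spec1.has_ss != spec2.has_ss or spec1.has_hy != spec2.has_hy:
            raise MixedModelError("stage specs must share their random-effect set")
        self.has_ss = spec1.has_ss
        if self.has_ss and ass_inv is None:
            raise MixedModelError("spec includes SS but no service-sire structure given")
        self.n1, self.n2 = ds1.n, ds2.n
        self.n = self.n1 + self.n2
        self.tvec = np.concatenate([np.zeros(self.n1, int), np.ones(self.n2, int)])

        # fixed effects: separate block per trait
        X_blocks = []
        for ds, spec in ((ds1, spec1), (ds2, spec2)):
            cols = []
            if not spec.fixed_effects:
                cols.append(sp.csr_matrix(np.ones((ds.n, 1))))
            for j, eff in enumerate(spec.fixed_effects):
                mat, _ = _dummy(ds.fixed[eff], drop_first=(j > 0))
                cols.append(mat)
            X_blocks.append(sp.hstack(cols, format="csr"))
        X = sp.block_diag(X_blocks, format="csr")
        self.p = X.shape[1]

        # random terms: trait-major level layout [levels(t=1); levels(t=2)]
        def two_trait_Z(codes1, codes2, q):
            rows = np.arange(self.n)
            cols = np.concatenate([codes1, codes2 + q])
            return sp.csr_matrix(
                (np.ones(self.n), (rows, cols)), shape=(self.n, 2 * q)
            )

        self.terms: list[tuple] = []  # (name, Z, Kinv, logdetK, q)
        hy_all = np.concatenate([ds1.hy_labels, ds2.hy_labels])
        levels, codes = np.unique(hy_all.astype(object), return_inverse=True)
        qh = len(levels)
        self.terms.append(
            ("HY", two_trait_Z(codes[: self.n1], codes[self.n1:], qh),
             sp.identity(qh, format="csc"), 0.0, qh)
        )
        if self.has_ss:
            pos = {a: i for i, a in enumerate(ass_inv.ids)}
            _incidence(ds1.ss_ids, ass_inv.ids)  # validates membership
            _incidence(ds2.ss_ids, ass_inv.ids)
            codes1 = np.array([pos[a] for a in ds1.ss_ids])
            codes2 = np.array([pos[a] for a in ds2.ss_ids])
            qs = len(ass_inv.ids)
            self.terms.append(
                ("SS", two_trait_Z(codes1, codes2, qs),
                 ass_inv.matrix.tocsc(), ass_inv.log_det_a, qs)
            )
        pos = {a: i for i, a in enumerate(ainv.ids)}
        for a in np.concatenate([ds1.animal_ids, ds2.animal_ids]):
            if a not in pos:
                raise MixedModelError(f"animal {a!r} missing from pedigree structure")
        codes1 = np.array([pos[a] for a in ds1.animal_ids])
        codes2 = np.array([pos[a] for a in ds2.animal_ids])
        qa = len(ainv.ids)
        self.terms.append(
            ("a", two_trait_Z(codes1, codes2, qa),
             ainv.matrix.tocsc(), ainv.log_det_a, qa)
        )

        self.Omega = sp.hstack([X] + [t[1] for t in self.terms], format="csr")
        self.M = self.Omega.shape[1]
        self.slices = {}
        col = self.p
        for name, Z, _, _, q in self.terms:
            self.slices[name] = slice(col, col + 2 * q)
            col += 2 * q

        # residual pairing: one record per stage per animal
        idx1 = {a: i for i, a in enumerate(ds1.animal_ids)}
        idx2 = {a: i for i, a in enumerate(ds2.animal_ids)}
        pairs = [(idx1[a], idx2[a]) for a in joint.common_animals]
        self.pair1 = np.array([i for i, _ in pairs], dtype=int)
        self.pair2 = np.array([j for _, j in pairs], dtype=int) + self.n1
        paired = np.zeros(self.n, bool)
        paired[self.pair1] = True
        paired[self.pair2] = True
        self.single1 = np.nonzero((self.tvec == 0) & ~paired)[0]
        self.single2 = np.nonzero((self.tvec == 1) & ~paired)[0]
        self.n_pairs = len(pairs)

        # precomputed residual-structure cross products
        def seldiag(rows):
            v = np.zeros(self.n)
            v[rows] = 1.0
            return sp.diags(v)

        S_list = {
            "s1": seldiag(self.single1),
            "s2": seldiag(self.single2),
            "p1": seldiag(self.pair1),
            "p2": seldiag(self.pair2),
        }
        if self.n_pairs:
            S_list["off"] = sp.coo_matrix(
                (np.ones(2 * self.n_pairs),
                 (np.concatenate([self.pair1, self.pair2]),
                  np.concatenate([self.pair2, self.pair1]))),
                shape=(self.n, self.n),
            ).tocsr()
        self._S = S_list
        self._OSO = {k: (self.Omega.T @ (S @ self.Omega)).tocsc()
                     for k, S in S_list.items()}

        # kron(E_ij, K^-1) pieces padded to MME shape
        self._kron = {}
        for name, _, Kinv, _, q in self.terms:
            off = self.slices[name].start
            pieces = {}
            for key, E in (("11", np.array([[1.0, 0], [0, 0]])),
                           ("12", np.array([[0, 1.0], [1.0, 0]])),
                           ("22", np.array([[0, 0], [0, 1.0]]))):
                K = sp.kron(E, Kinv).tocoo()
                pieces[key] = sp.coo_matrix(
                    (K.data, (K.row + off, K.col + off)), shape=(self.M, self.M)
                ).tocsc()
            self._kron[name] = pieces

        pattern = None
        for mat in list(self._OSO.values()) + [
            m for d in self._kron.values() for m in d.values()
        ]:
            pattern = abs(mat) if pattern is None else pattern + abs(mat)
        pattern = pattern.tocsc()
        pattern.sort_indices()
        self.pattern = pattern
        self._OSO_data = {k: align_pattern(v, pattern) for k, v in self._OSO.items()}
        self._kron_data = {
            name: {k: align_pattern(v, pattern) for k, v in d.items()}
            for name, d in self._kron.items()
        }
        self._ldl: SparseLDL | None = None
        self.set_response(np.concatenate([ds1.y, ds2.y]))

    def set_response(self, y: np.ndarray) -> None:
        if len(y) != self.n:
            raise ValueError("response length does not match the design")
        self.y = np.asarray(y, dtype=float)
        self._OSy = {k: np.asarray(self.Omega.T @ (S @ self.y)).ravel()
                     for k, S in self._S.items()}
        self._ySy = {k: float(self.y @ (S @ self.y)) for k, S in self._S.items()}

    # -- residual weights ------------------------------------------------

    def _rweights(self, R: np.ndarray) -> tuple[dict[str, float], float]:
        r11, r12, r22 = R[0, 0], R[0, 1], R[1, 1]
        det = r11 * r22 - r12 * r12
        if r11 <= 0 or r22 <= 0 or det <= 0:
            raise MixedModelError("residual covariance not positive definite")
        w = {"s1": 1.0 / r11, "s2": 1.0 / r22,
             "p1": r22 / det, "p2": r11 / det}
        if self.n_pairs:
            w["off"] = -r12 / det
        logdetR = (
            len(self.single1) * np.log(r11)
            + len(self.single2) * np.log(r22)
            + self.n_pairs * np.log(det)
        )
        return w, float(logdetR)

    def _rinv_apply(self, v: np.ndarray, R: np.ndarray) -> np.ndarray:
        r11, r12, r22 = R[0, 0], R[0, 1], R[1, 1]
        det = r11 * r22 - r12 * r12
        out = np.empty_like(v)
        out[self.single1] = v[self.single1] / r11
        out[self.single2] = v[self.single2] / r22
        out[self.pair1] = (r22 * v[self.pair1] - r12 * v[self.pair2]) / det
        out[self.pair2] = (r11 * v[self.pair2] - r12 * v[self.pair1]) / det
        return out

    # -- likelihood ------------------------------------------------------

    def _factorize(self, blocks: dict[str, np.ndarray], R: np.ndarray):
        w, logdetR = self._rweights(R)
        data = np.zeros(self.pattern.nnz)
        for k, wk in w.items():
            data += wk * self._OSO_data[k]
        logdetG = 0.0
        for name, _, _, logdetK, q in self.terms:
            Mb = blocks[name]
            det = Mb[0, 0] * Mb[1, 1] - Mb[0, 1] ** 2
            if Mb[0, 0] <= 0 or Mb[1, 1] <= 0 or det <= 0:
                raise MixedModelError(f"{name} covariance not positive definite")
            Minv = np.array([[Mb[1, 1], -Mb[0, 1]], [-Mb[0, 1], Mb[0, 0]]]) / det
            kd = self._kron_data[name]
            data += Minv[0, 0] * kd["11"] + Minv[0, 1] * kd["12"] + Minv[1, 1] * kd["22"]
            logdetG += q * np.log(det) + 2.0 * logdetK
        rhs = np.zeros(self.M)
        yry = 0.0
        for k, wk in w.items():
            rhs += wk * self._OSy[k]
            yry += wk * self._ySy[k]
        if self._ldl is None:
            self._ldl = SparseLDL(self.pattern, fill_reducing_ordering(self.pattern))
        try:
            logdetC = self._ldl.factor(data)
        except NotPositiveDefinite as err:
            raise MixedModelError(str(err)) from err
        sol = self._ldl.solve(rhs)
        return sol, rhs, yry, logdetR, logdetG, logdetC

    def neg2ll(self, theta: np.ndarray) -> float:
        blocks, R = self.unpack(theta)
        try:
            sol, rhs, yry, logdetR, logdetG, logdetC = self._factorize(blocks, R)
        except MixedModelError:
            return np.inf
        ypy = yry - float(sol @ rhs)
        return float((self.n - self.p) * LOG2PI + logdetR + logdetG + logdetC + ypy)

    # -- parameter packing -----------------------------------------------

    def param_names(self, free_r12: bool) -> list[str]:
        names = ["G11", "G12", "G22", "HY11", "HY12", "HY22"]
        if self.has_ss:
            names += ["SS11", "SS12", "SS22"]
        names += ["R11", "R12", "R22"] if free_r12 else ["R11", "R22"]
        return names

    def set_free_r12(self, free: bool):
        self.free_r12 = free
        self.names = self.param_names(free)

    def pack(self, blocks: dict[str, np.ndarray], R: np.ndarray) -> np.ndarray:
        v = [blocks["a"][0, 0], blocks["a"][0, 1], blocks["a"][1, 1],
             blocks["HY"][0, 0], blocks["HY"][0, 1], blocks["HY"][1, 1]]
        if self.has_ss:
            v += [blocks["SS"][0, 0], blocks["SS"][0, 1], blocks["SS"][1, 1]]
        v += [R[0, 0], R[0, 1], R[1, 1]] if self.free_r12 else [R[0, 0], R[1, 1]]
        return np.array(v, dtype=float)

    def unpack(self, theta: np.ndarray):
        def m22(a, b, c):
            return np.array([[a, b], [b, c]])

        blocks = {"a": m22(*theta[0:3]), "HY": m22(*theta[3:6])}
        i = 6
        if self.has_ss:
            blocks["SS"] = m22(*theta[6:9])
            i = 9
        if self.free_r12:
            R = m22(*theta[i:i + 3])
        else:
            R = m22(theta[i], 0.0, theta[i + 1])
        return blocks, R

    def project(self, theta: np.ndarray, floor_frac: float) -> np.ndarray:
        blocks, R = self.unpack(theta)
        blocks = {k: _psd_clip(v, floor_frac) for k, v in blocks.items()}
        R = _psd_clip(R, floor_frac)
        if not self.free_r12:
            R[0, 1] = R[1, 0] = 0.0
        return self.pack(blocks, R)

    # -- AI matrix ---------------------------------------------------------

    def ai_matrix(self, theta: np.ndarray) -> np.ndarray:
        blocks, R = self.unpack(theta)
        sol, _, _, _, _, _ = self._factorize(blocks, R)
        resid = self.y - np.asarray(self.Omega @ sol).ravel()
        Py = self._rinv_apply(resid, R)

        fs: list[np.ndarray] = []
        pair_elems = [(0, 0), (0, 1), (1, 1)]
        for name in ["a", "HY"] + (["SS"] if self.has_ss else []):
            Mb = blocks[name]
            Minv = np.linalg.inv(Mb)
            sl = self.slices[name]
            q = (sl.stop - sl.start) // 2
            U = sol[sl].reshape(2, q)
            V = Minv @ U
            Z = next(t[1] for t in self.terms if t[0] == name)
            for (i, j) in pair_elems:
                E = np.zeros((2, 2))
                E[i, j] = E[j, i] = 1.0
                fs.append(np.asarray(Z @ (E @ V).ravel()).ravel())
        # residual parameters
        f = np.zeros(self.n); f[self.tvec == 0] = Py[self.tvec == 0]
        fs.append(f)
        if self.free_r12:
            f = np.zeros(self.n)
            f[self.pair1] = Py[self.pair2]
            f[self.pair2] = Py[self.pair1]
            fs.append(f)
        f = np.zeros(self.n); f[self.tvec == 1] = Py[self.tvec == 1]
        fs.append(f)

        Pf = []
        for f in fs:
            rf = self._rinv_apply(f, R)
            sol_f = self._ldl.solve(np.asarray(self.Omega.T @ rf).ravel())
            Pf.append(
                self._rinv_apply(f - np.asarray(self.Omega @ sol_f).ravel(), R)
            )
        m = len(fs)
        AI = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])
        return AI

    def fd_grad(self, theta: np.ndarray, f0: float, scales: np.ndarray) -> np.ndarray:
        g = np.empty(len(theta))
        for j in range(len(theta)):
            h = 1e-4 * scales[j]
            up = theta.copy(); up[j] += h
            dn = theta.copy(); dn[j] -= h
            fu, fd = self.neg2ll(up), self.neg2ll(dn)
            if np.isfinite(fu) and np.isfinite(fd):
                g[j] = (fu - fd) / (2 * h)
            elif np.isfinite(fu):
                g[j] = (fu - f0) / h
            elif np.isfinite(fd):
                g[j] = (f0 - fd) / h
            else:
                g[j] = 0.0
        return g


# ---------------------------------------------------------------------------


def _start_theta(
    eng: _BivariateEngine,
    vc1: VarianceComponents,
    vc2: VarianceComponents,
    opts: BivariateOptions,
) -> np.ndarray:
    # floored-out single-trait components make degenerate 2x2 starts;
    # keep every starting diagonal at >= 0.1% of the stage phenotypic variance
    p1, p2 = vc1.total, vc2.total
    lo1, lo2 = 1e-3 * p1, 1e-3 * p2

    def m22(d1, d2, rho):
        d1, d2 = max(d1, lo1), max(d2, lo2)
        c = rho * np.sqrt(d1 * d2)
        return np.array([[d1, c], [c, d2]])

    G = m22(vc1.sigma2_a, vc2.sigma2_a, opts.start_rg)
    if opts.start_g12 is not None:
        G[0, 1] = G[1, 0] = opts.start_g12
    blocks = {"a": G, "HY": m22(vc1.sigma2_hy or 0.0, vc2.sigma2_hy or 0.0, 0.0)}
    if eng.has_ss:
        blocks["SS"] = m22(vc1.sigma2_ss or 0.0, vc2.sigma2_ss or 0.0, opts.start_rg)
    R = m22(vc1.sigma2_e, vc2.sigma2_e, 0.0)
    return eng.project(eng.pack(blocks, R), opts.eig_floor)


def estimate_bivariate_reml(
    joint: BivariateData,
    spec1: ModelSpec,
    spec2: ModelSpec,
    ainv: AInverse,
    ass_inv: AInverse | None = None,
    opts: BivariateOptions | None = None,
    starts: tuple[VarianceComponents, VarianceComponents] | None = None,
    engine: "_BivariateEngine | None" = None,
) -> CovarianceSet:
    """AI-REML for the 2x2 covariance blocks and the genetic correlation.

    Single-trait fits provide the starting diagonals (run internally when
    ``starts`` is not given).  Non-convergence and near-boundary solutions
    are flagged, not raised — mirroring how two-trait fertility models
    frequently fail to converge in practice.
    """
    opts = opts or BivariateOptions()
    if engine is None:
        eng = _BivariateEngine(joint, spec1, spec2, ainv, ass_inv)
    else:
        eng = engine
        eng.set_response(np.concatenate([joint.ds1.y, joint.ds2.y]))
    eng.set_free_r12(eng.n_pairs >= opts.min_pairs)
    if starts is None:
        uni_opts = REMLOptions()
        starts = (
            estimate_reml(joint.ds1, spec1, ainv, ass_inv, uni_opts),
            estimate_reml(joint.ds2, spec2, ainv, ass_inv, uni_opts),
        )
    theta = _start_theta(eng, starts[0], starts[1], opts)
    names = eng.names

    def scales(th):
        blocks, R = eng.unpack(th)
        P = blocks["a"] + blocks["HY"] + R + blocks.get("SS", np.zeros((2, 2)))
        s = []
        for nm in names:
            i, j = int(nm[-2]) - 1, int(nm[-1]) - 1
            s.append(np.sqrt(P[i, i] * P[j, j]))
        return np.array(s)

    f_cur = eng.neg2ll(theta)
    converged = False
    projected_last = False
    n_proj = 0
    n_iter = 0
    for it in range(opts.max_iter):
        n_iter += 1
        sc = scales(theta)
        g = eng.fd_grad(theta, f_cur, sc)
        AI = eng.ai_matrix(theta)
        # Marquardt ladder: raw AI step first, then increasingly damped
        improved = False
        mu0 = 1e-3 * float(np.mean(np.diag(AI)))
        for damp in [0.0, 1.0, 1e2, 1e4]:
            H = AI + damp * mu0 * np.eye(len(g))
            try:
                step = -0.5 * np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = -0.5 * np.linalg.lstsq(H, g, rcond=None)[0]
            for _half in range(8):
                cand = eng.project(theta + step, opts.eig_floor)
                f_new = eng.neg2ll(cand)
                if np.isfinite(f_new) and f_new < f_cur - 1e-12 * (1.0 + abs(f_cur)):
                    improved = True
                    break
                step *= 0.5
            if improved:
                break
        if not improved:
            converged = True  # no descent direction left at FD resolution
            break
        rel = float(np.max(np.abs(cand - theta) / np.maximum(sc, 1e-300)))
        projected_last = bool(np.max(np.abs(cand - (theta + step))) > 1e-12 * sc.max())
        n_proj = n_proj + 1 if projected_last else 0
        df = f_cur - f_new
        theta, f_cur = cand, f_new
        if opts.verbose:
            G_ = theta[0:3]
            log.info("iter %d  -2ll=%.5f  df=%.2e  rg=%.4f", it, f_cur, df,
                     G_[1] / max(np.sqrt(G_[0] * G_[2]), 1e-300))
        if rel < opts.tol or (it >= 4 and df < opts.f_tol):
            converged = True
            break
        if n_proj >= 3 and df < opts.boundary_f_tol:
            # solution pinned to the PSD boundary; only creep remains
            converged = True
            break
    else:
        log.warning("bivariate REML hit max_iter without converging")

    AI = eng.ai_matrix(theta)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    blocks, R = eng.unpack(theta)
    G, HY = blocks["a"], blocks["HY"]
    SS = blocks.get("SS")

    rg = float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
    iG = [names.index(k) for k in ("G11", "G12", "G22")]
    grad = np.zeros(len(names))
    grad[iG[0]] = -0.5 * rg / G[0, 0]
    grad[iG[1]] = 1.0 / np.sqrt(G[0, 0] * G[1, 1])
    grad[iG[2]] = -0.5 * rg / G[1, 1]
    rg_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    P = G + HY + R + (SS if SS is not None else 0.0)
    rp = float(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    h2 = tuple(float(G[t, t] / P[t, t]) for t in (0, 1))
    h2_se = []
    for t in (0, 1):
        gr = np.zeros(len(names))
        for i, nm in enumerate(names):
            if not nm.endswith(f"{t + 1}{t + 1}"):
                continue
            gr[i] = ((P[t, t] - G[t, t]) if nm.startswith("G") else -G[t, t]) / P[t, t] ** 2
        h2_se.append(float(np.sqrt(max(gr @ cov @ gr, 0.0))))

    near = (
        abs(rg) > opts.boundary_rg
        or rg_se > opts.boundary_se
        or projected_last
    )
    return CovarianceSet(
        G=G, HY=HY, R=R, SS=SS, se=se,
        rg=max(-1.0, min(1.0, rg)), rg_se=rg_se, rp=rp,
        h2=h2, h2_se=tuple(h2_se),
        converged=converged, near_boundary=near,
        residual_cov_fixed=not eng.free_r12,
        n_iter=n_iter, neg2ll=f_cur,
    )


def merge_traits(ds1: TraitDataset, ds2: TraitDataset) -> TraitDataset:
    """Concatenate the stages into one trait, with stage as a fixed effect.

    Single-trait REML then applies directly; used when the stage genetic
    correlation is high enough to treat heifer and cow expression as one
    trait.
    """
    merged = ds1.concatenate(ds2, stage="all")
    merged.fixed = dict(merged.fixed)
    merged.fixed["stage"] = np.array(
        [ds1.stage] * ds1.n + [ds2.stage] * ds2.n, dtype=object
    )
    return merged


def write_covariance_csv(cs: CovarianceSet, path,
                         labels: tuple[str, str] = ("heifer", "cow")) -> None:
    """Two-trait summary: h2 on the diagonal, rg in the lower triangle,
    standard errors in parentheses."""
    import pandas as pd

    rows = [
        {labels[0]: f"{cs.h2[0]:.4f} ({cs.h2_se[0]:.4f})", labels[1]: ""},
        {
            labels[0]: f"{cs.rg:.4f} ({cs.rg_se:.4f})",
            labels[1]: f"{cs.h2[1]:.4f} ({cs.h2_se[1]:.4f})",
        },
    ]
    pd.DataFrame(rows, index=labels).to_csv(path)
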