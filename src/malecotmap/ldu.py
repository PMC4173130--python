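"""LD-unit (LDU) genetic maps from pairwise |D'|.

The map is the weighted least-squares fit of the Malecot decline

    |D'|_ij = (1 - L) * M * exp(-sum_{k=i..j-1} eps_k d_k) + L

over all marker pairs (i, j) within a distance cap, with one decay rate
``eps_k >= 0`` per inter-marker interval.  The cumulative map position of
marker ``i`` is ``sum_{k<i} eps_k d_k`` in LD units; plateaus of the
cumulative curve are LD blocks, sharp rises are recombination-driven
steps.  One LDU is one "swept radius": the physical distance over which
association decays by a factor e.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import InvalidConfigurationError, MapFitError, OutOfRangeError

__all__ = ["LDUMap", "LDUMapModel", "fit_ldu_map", "interpolate_ldu", "invert_ldu"]

_SNAP = 1e-9  # LDU tolerance for snapping queries onto plateau values


@dataclass
class LDUMap:
    """A fitted (or true) cumulative LDU map over a marker grid."""

    positions_kb: np.ndarray
    cumulative_ldu: np.ndarray
    epsilon_hat: np.ndarray
    M_hat: float = 1.0
    L_hat: float = 0.0
    fit_rss: float = float("nan")
    converged: bool = True
    snp_ids: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_kb = np.asarray(self.positions_kb, float)
        self.cumulative_ldu = np.asarray(self.cumulative_ldu, float)
        self.epsilon_hat = np.asarray(self.epsilon_hat, float)
        if self.cumulative_ldu[0] != 0.0:
            raise InvalidConfigurationError("cumulative_ldu must start at 0")
        if np.any(np.diff(self.cumulative_ldu) < -1e-12):
            raise InvalidConfigurationError("cumulative_ldu must be non-decreasing")
        if np.any(self.epsilon_hat < 0):
            raise InvalidConfigurationError("epsilon_hat must be >= 0")
        if not self.snp_ids:
            self.snp_ids = [f"snp{k + 1:04d}" for k in range(self.positions_kb.size)]

    @property
    def total_ldu(self) -> float:
        return float(self.cumulative_ldu[-1])

    # -- coordinate transforms -------------------------------------------
    def interpolate(self, query_kb: float | np.ndarray) -> float | np.ndarray:
        """kb -> LDU, piecewise linear with slope eps_k inside interval k."""
        q = np.asarray(query_kb, float)
        if np.any(q < self.positions_kb[0] - 1e-9) or np.any(
            q > self.positions_kb[-1] + 1e-9
        ):
            raise OutOfRangeError("query_kb outside the mapped marker span")
        out = np.interp(q, self.positions_kb, self.cumulative_ldu)
        return float(out) if np.isscalar(query_kb) else out

    def invert(self, query_ldu: float) -> tuple[float, float]:
        """LDU -> kb interval (lower, upper).

        On strictly increasing stretches the interval collapses to a
        point; a query landing on a zero-eps plateau returns the kb span
        of the whole block, since every position in the block shares that
        map coordinate.
        """
        c = self.cumulative_ldu
        pos = self.positions_kb
        q = float(query_ldu)
        if q < -_SNAP or q > c[-1] + _SNAP:
            raise OutOfRangeError("query_ldu outside [0, total_ldu]")
        q = min(max(q, 0.0), c[-1])
        # snap onto a marker value if within tolerance, so plateau queries
        # arriving with float fuzz still widen to the block
        near = np.flatnonzero(np.abs(c - q) <= _SNAP)
        if near.size:
            q = c[near[0]]
        q = min(max(q, 0.0), c[-1])

        i_lo = min(int(np.searchsorted(c, q, side="left")), c.size - 1)
        if i_lo == 0:
            lo = pos[0]
        else:
            dc = c[i_lo] - c[i_lo - 1]
            lo = pos[i_lo - 1] + (q - c[i_lo - 1]) / dc * (pos[i_lo] - pos[i_lo - 1])
        i_hi = int(np.searchsorted(c, q, side="right"))
        if i_hi == c.size:
            hi = pos[-1]
        else:
            dc = c[i_hi] - c[i_hi - 1]
            hi = pos[i_hi - 1] + (q - c[i_hi - 1]) / dc * (pos[i_hi] - pos[i_hi - 1])
        return float(lo), float(hi)

    # -- serialisation ----------------------------------------------------
    def to_tsv(self, path) -> None:
        eps = np.concatenate([self.epsilon_hat, [np.nan]])
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "position_kb": self.positions_kb,
                "cumulative_ldu": self.cumulative_ldu,
                "epsilon_to_next": eps,
            }
        )
        header = (
            f"# M_hat={self.M_hat!r}\tL_hat={self.L_hat!r}\t"
            f"rss={self.fit_rss!r}\tconverged={self.converged}\n"
            f"# settings={self.settings!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LDUMap":
        meta: dict = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# settings="):
                    continue
                if line.startswith("#"):
                    for part in line[1:].strip().split("\t"):
                        k, v = part.split("=", 1)
                        meta[k] = v
                    continue
                lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
        return cls(
            positions_kb=df["position_kb"].to_numpy(),
            cumulative_ldu=df["cumulative_ldu"].to_numpy(),
            epsilon_hat=df["epsilon_to_next"].to_numpy()[:-1],
            M_hat=float(meta.get("M_hat", "nan")),
            L_hat=float(meta.get("L_hat", "nan")),
            fit_rss=float(meta.get("rss", "nan")),
            converged=meta.get("converged", "True") == "True",
            snp_ids=list(df["snp_id"].astype(str)),
        )


class LDUMapModel:
    """Weighted nonlinear least-squares fit of the Malecot decline.

    Parameters
    ----------
    pairs
        Pair table from :func:`malecotmap.pairwise.pairwise_ld_table`
        (columns ``i, j, d_kb, D_prime, K_weight``).
    positions_kb
        Marker positions for the full grid the ``i, j`` indices refer to.
    L_mode
        ``"fitted"`` estimates the large-distance residual association L
        freely; ``"predicted"`` fixes it at the Monte-Carlo expectation
        of |D'| between independent loci at the table's median sample
        size (the small-sample |D'| bias).
    max_pair_kb
        Distance cap; pairs beyond it are dropped before fitting.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        positions_kb: np.ndarray,
        snp_ids: list[str] | None = None,
        L_mode: str = "fitted",
        max_pair_kb: float = 500.0,
        depth_penalty: float = 1e-4,
    ) -> None:
        self.depth_penalty = float(depth_penalty)
        if L_mode not in ("fitted", "predicted"):
            raise InvalidConfigurationError("L_mode must be 'fitted' or 'predicted'")
        self.positions_kb = np.asarray(positions_kb, float)
        if self.positions_kb.size < 3:
            raise InvalidConfigurationError("need at least 3 markers")
        keep = pairs["d_kb"].to_numpy() <= max_pair_kb
        pairs = pairs.loc[keep]
        if len(pairs) == 0:
            raise InvalidConfigurationError("no pairs within max_pair_kb")
        self.snp_ids = snp_ids
        self.L_mode = L_mode
        self.max_pair_kb = max_pair_kb
        self._i = pairs["i"].to_numpy(int)
        self._j = pairs["j"].to_numpy(int)
        self._y = np.abs(pairs["D_prime"].to_numpy(float))
        self._K = pairs["K_weight"].to_numpy(float)
        self._n_med = (
            float(np.median(pairs["n_used"])) if "n_used" in pairs else float("nan")
        )
        self._d = np.diff(self.positions_kb)
        # minimal-map ridge: a step deeper than the data can resolve leaves
        # the weighted RSS flat, so the fit keeps the *shallowest* depth
        # consistent with the data - deepening stops once it improves the
        # fit by less than depth_penalty of the null variation per LDU
        ybar = float(self._K @ self._y / self._K.sum())
        self._base_variation = float(self._K @ (self._y - ybar) ** 2)

    # objective pieces ----------------------------------------------------
    def _x(self, eps: np.ndarray) -> np.ndarray:
        u = np.concatenate(([0.0], np.cumsum(eps * self._d)))
        return np.exp(-(u[self._j] - u[self._i]))

    def _rss(self, eps: np.ndarray, a: float, L: float) -> float:
        r = self._y - a * self._x(eps) - L
        return float(np.sum(self._K * r * r))

    def _objective(self, eps: np.ndarray, a: float, L: float) -> float:
        """Penalised objective the alternation monotonically decreases."""
        lam = self.depth_penalty * self._base_variation
        return self._rss(eps, a, L) + lam * float(np.sum(eps * self._d))

    def _update_amplitude(self, x: np.ndarray, L_fixed: float | None):
        """Closed-form weighted LS for (a, L) given the decay covariate."""
        K, y = self._K, self._y
        if L_fixed is None:
            sw = K.sum()
            sx = float(K @ x)
            sxx = float(K @ (x * x))
            sy = float(K @ y)
            sxy = float(K @ (x * y))
            det = sw * sxx - sx * sx
            if det <= 1e-12:
                a, L = 1.0, 0.0
            else:
                a = (sw * sxy - sx * sy) / det
                L = (sy - a * sx) / sw
            L = float(np.clip(L, 0.0, 0.95))
            a = float(np.clip(a, 1e-6, 1.0 - L))
            return a, L
        L = L_fixed
        sxx = float(K @ (x * x))
        a = float(K @ (x * (y - L))) / max(sxx, 1e-12)
        return float(np.clip(a, 1e-6, 1.0 - L)), L

    def _fit_eps(self, eps0: np.ndarray, a: float, L: float, maxiter: int):
        i, j, d, K, y = self._i, self._j, self._d, self._K, self._y
        m1 = d.size
        lam = self.depth_penalty * self._base_variation

        def fun(eps):
            u = np.concatenate(([0.0], np.cumsum(eps * d)))
            x = np.exp(-(u[j] - u[i]))
            r = y - a * x - L
            F = float(np.sum(K * r * r)) + lam * float(np.sum(eps * d))
            t = 2.0 * K * r * a * x
            diff = np.zeros(m1 + 1)
            np.add.at(diff, i, t)
            np.add.at(diff, j, -t)
            grad = d * np.cumsum(diff)[:-1] + lam * d
            return F, grad

        res = minimize(
            fun,
            eps0,
            jac=True,
            method="L-BFGS-B",
            # |D'| across a step deeper than ~8 swept radii is below any
            # realistic noise floor, so deeper rates are unidentifiable
            bounds=[(0.0, 8.0 / dk) for dk in d],
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        return np.asarray(res.x), bool(res.success)

    def _initial_eps(self) -> np.ndarray:
        """Adjacent-pair moment start: eps_k d_k ~ -log|D'| of pair (k, k+1)."""
        eps = np.zeros(self._d.size)
        adj = self._j == self._i + 1
        y_adj = np.clip(self._y[adj], 0.05, 1.0)
        eps[self._i[adj]] = -np.log(y_adj) / self._d[self._i[adj]]
        return eps

    def predicted_L(self, seed: int = 0, n_sim: int = 200) -> float:
        """Monte-Carlo expected |D'| between independent loci.

        Uses the table's median pairwise-complete sample size and MAF 0.25
        as a representative spectrum; this is the |D'| noise floor the
        ``predicted`` mode plugs in for L.
        """
        from .pairwise import _d_prime_vec, _em_tables

        rng = np.random.default_rng(seed)
        n = int(self._n_med) if np.isfinite(self._n_med) else 500
        g1 = rng.binomial(2, 0.25, size=(n_sim, n))
        g2 = rng.binomial(2, 0.25, size=(n_sim, n))
        counts = np.zeros((n_sim, 3, 3))
        for s in range(n_sim):
            np.add.at(counts[s], (g1[s], g2[s]), 1)
        f, _, _, _ = _em_tables(counts)
        _, dp = _d_prime_vec(f)
        return float(np.mean(np.abs(dp)))

    def fit(
        self,
        n_restarts: int = 3,
        max_outer: int = 30,
        inner_maxiter: int = 25,
        rtol: float = 1e-8,
        seed: int = 0,
    ) -> "LDUMapResults":
        """Alternate closed-form (M, L) updates with bounded quasi-Newton
        steps on the decay rates; keep the best of ``n_restarts`` starts."""
        rng = np.random.default_rng(seed)
        L_fixed = self.predicted_L(seed=seed) if self.L_mode == "predicted" else None
        base = self._initial_eps()
        starts = [base]
        for _ in range(n_restarts - 1):
            starts.append(base * rng.lognormal(0.0, 0.5, base.size) + 1e-4)

        best = None
        for eps0 in starts:
            eps = eps0.copy()
            a, L = self._update_amplitude(self._x(eps), L_fixed)
            obj = self._objective(eps, a, L)
            converged = False
            for _ in range(max_outer):
                eps, _ok = self._fit_eps(eps, a, L, inner_maxiter)
                x = self._x(eps)
                a_new, L_new = self._update_amplitude(x, L_fixed)
                # the closed form is unconstrained; after clipping to the
                # parameter box keep whichever (a, L) scores better
                if self._rss(eps, a_new, L_new) <= self._rss(eps, a, L):
                    a, L = a_new, L_new
                obj_new = self._objective(eps, a, L)
                if obj_new > obj + 1e-9:  # alternation must not increase it
                    raise MapFitError("objective increased during alternation")
                if obj - obj_new < rtol * max(obj, 1e-12):
                    converged = True
                    obj = obj_new
                    break
                obj = obj_new
            cand = (obj, eps, a, L, converged)
            if best is None or obj < best[0]:
                best = cand
        if best is None or not np.all(np.isfinite(best[1])):
            raise MapFitError("LDU map optimisation failed for every restart")
        _obj, eps, a, L, converged = best
        rss = self._rss(eps, a, L)  # report the unpenalised weighted RSS
        M = a / (1.0 - L)
        cum = np.concatenate(([0.0], np.cumsum(eps * self._d)))
        ldu_map = LDUMap(
            positions_kb=self.positions_kb.copy(),
            cumulative_ldu=cum,
            epsilon_hat=eps,
            M_hat=float(M),
            L_hat=float(L),
            fit_rss=float(rss),
            converged=converged,
            snp_ids=list(self.snp_ids) if self.snp_ids else [],
            settings={
                "L_mode": self.L_mode,
                "max_pair_kb": self.max_pair_kb,
                "n_restarts": n_restarts,
            },
        )
        return LDUMapResults(model=self, map=ldu_map)


@dataclass
class LDUMapResults:
    """Results wrapper around a fitted :class:`LDUMap`."""

    model: LDUMapModel
    map: LDUMap

    @property
    def total_ldu(self) -> float:
        return self.map.total_ldu

    @property
    def M_hat(self) -> float:
        return self.map.M_hat

    @property
    def L_hat(self) -> float:
        return self.map.L_hat

    @property
    def fit_rss(self) -> float:
        return self.map.fit_rss

    def summary(self) -> str:
        m = self.map
        lines = [
            "LDU map fit (Malecot decline, weighted least squares)",
            "=" * 56,
            f"markers:          {m.positions_kb.size}",
            f"pairs used:       {self.model._y.size}",
            f"span (kb):        {m.positions_kb[0]:.3f} - {m.positions_kb[-1]:.3f}",
            f"total map (LDU):  {m.total_ldu:.4f}",
            f"M_hat:            {m.M_hat:.4f}",
            f"L_hat:            {m.L_hat:.4f}  (mode: {self.model.L_mode})",
            f"weighted RSS:     {m.fit_rss:.6g}",
            f"converged:        {m.converged}",
        ]
        return "\n".join(lines)


def fit_ldu_map(
    pairs: pd.DataFrame,
    positions_kb: np.ndarray,
    L_mode: str = "fitted",
    max_pair_kb: float = 500.0,
    snp_ids: list[str] | None = None,
    **fit_kwargs,
) -> LDUMap:
    """Functional wrapper: fit and return the :class:`LDUMap` directly."""
    model = LDUMapModel(
        pairs, positions_kb, snp_ids=snp_ids, L_mode=L_mode, max_pair_kb=max_pair_kb
    )
    return model.fit(**fit_kwargs).map


def interpolate_ldu(ldu_map: LDUMap, query_kb: float) -> float:
    """kb -> LDU on a fitted map (marker positions map exactly)."""
    return float(ldu_map.interpolate(query_kb))


def invert_ldu(ldu_map: LDUMap, query_ldu: float) -> tuple[float, float]:
    """LDU -> kb; returns an interval that collapses to a point off-plateau."""
    return ldu_map.invert(query_ldu)
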