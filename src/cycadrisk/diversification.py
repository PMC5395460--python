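"""Diversification model fitting on branching times and clade rate comparison.

Six models are fitted to the descending node ages of an ultrametric tree:
two rate-constant models (pure birth; birth-death with net rate r and
extinction fraction a = d/b) and four rate-variable models (density-dependent
linear DDL, density-dependent exponential DDX, and two- and three-era
piecewise pure-birth "yule2rate"/"yule3rate").  The likelihood conditions on
two lineages at the root age: with k lineages and per-lineage speciation
rate lambda, each inter-event interval contributes -k*lambda*dt and each
lineage addition ln(k*lambda).  The ln k event constants (summing to
ln (N-1)!) are kept in every model, including the Nee et al. birth-death
form, so AIC values are directly comparable across models.

Model choice follows the rate-constant vs rate-variable AIC contrast
delta_AIC_rc = AIC(best rate-constant) - AIC(best rate-variable): positive
values favor rate variability, ties favor the simpler family.

The clade rate comparison contrasts the branch-length distribution inside a
focal clade against the rest of the tree with an exponential likelihood
ratio test (ML rate = 1/mean branch length), flagging "hot" clades whose
branches are significantly shorter (faster diversification).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .tree import Phylogeny, TreeError

__all__ = [
    "DiversificationError",
    "DiversificationFit",
    "ModelSelection",
    "CladeRateResult",
    "piecewise_yule_loglik",
    "fit_rate_constant",
    "fit_rate_variable",
    "fit_all_models",
    "select_model",
    "clade_rate_comparison",
]

#: free-parameter counts entering AIC = 2k - 2 lnL
N_PARAMS = {"pureBirth": 1, "bd": 2, "DDL": 2, "DDX": 2, "yule2rate": 3, "yule3rate": 5}


class DiversificationError(ValueError):
    """Invalid branching times or failed model fit."""


@dataclass
class DiversificationFit:
    model: str
    params: dict
    lnl: float
    aic: float

    @classmethod
    def make(cls, model: str, params: dict, lnl: float) -> "DiversificationFit":
        return cls(model, params, float(lnl), 2.0 * N_PARAMS[model] - 2.0 * float(lnl))

    def to_dict(self) -> dict:
        return {"model": self.model, "params": self.params, "lnL": self.lnl, "AIC": self.aic}


@dataclass
class ModelSelection:
    best_rate_constant: DiversificationFit
    best_rate_variable: DiversificationFit
    delta_aic_rc: float
    verdict: str  # "rate_variable" iff delta_aic_rc > 0, else "rate_constant"

    def to_dict(self) -> dict:
        return {
            "best_rate_constant": self.best_rate_constant.to_dict(),
            "best_rate_variable": self.best_rate_variable.to_dict(),
            "delta_aic_rc": self.delta_aic_rc,
            "verdict": self.verdict,
        }


# ---------------------------------------------------------------------- #
# sufficient statistics of the branching times


class _BTStats:
    """Cached lineage-count integrals over descending node ages."""

    def __init__(self, btimes: Sequence[float]):
        bt = np.asarray(btimes, dtype=float)
        if bt.ndim != 1 or bt.size < 2:
            raise DiversificationError("need at least 2 branching times (>= 3 tips)")
        if np.any(~np.isfinite(bt)) or np.any(bt <= 0):
            raise DiversificationError("branching times must be positive and finite")
        if np.any(np.diff(bt) > 0):
            raise DiversificationError("branching times must be in descending order")
        self.bt = bt
        self.m = bt.size              # number of internal nodes
        self.n_tips = self.m + 1
        self.root_age = float(bt[0])
        self.events = bt[1:]          # ages of the N-2 non-root branchings
        self.n_events = self.events.size
        bounds = np.concatenate([bt, [0.0]])
        self._bounds = bounds
        self._widths = bounds[:-1] - bounds[1:]
        self._counts = np.arange(2, self.m + 2, dtype=float)  # lineages per segment
        self._cumG = np.concatenate([[0.0], np.cumsum(self._widths * self._counts)])
        self.G_total = float(self._cumG[-1])
        # sum of ln k over lineage-addition events = ln (N-1)!
        self.ln_k_events = lgamma(self.n_tips)

    def G_above(self, age) -> np.ndarray:
        """Lineage-time integral from ``age`` back to the root age."""
        age = np.asarray(age, dtype=float)
        i = np.searchsorted(-self._bounds, -age, side="right") - 1
        i = np.clip(i, 0, self.m - 1)
        return self._cumG[i] + self._counts[i] * (self._bounds[i] - age)

    def n_above(self, age) -> np.ndarray:
        """Number of events strictly older than ``age``."""
        age = np.asarray(age, dtype=float)
        return np.searchsorted(-self.events, -age, side="left")

    def shift_candidates(self, n_cands: int = 10) -> np.ndarray:
        """Candidate shift ages: a coarse time grid plus event-age deciles.

        The equally spaced grid gives uniform temporal resolution; the
        deciles of the observed event ages adapt to trees whose branchings
        concentrate near the present (coalescent-like topologies).  Keeping
        the candidate set coarse bounds the era widths, which keeps the
        era-rate likelihood away from its boundary degeneracy (sliver eras
        bracketing a few near-simultaneous branchings yield arbitrarily
        large per-era rates and would make the rate-variable family win on
        constant-rate trees almost surely).
        """
        grid = np.linspace(0.0, self.root_age, n_cands + 2)[1:-1]
        ev = np.sort(self.events)
        dec_idx = np.unique((np.arange(1, 10) * ev.size) // 10)
        deciles = ev[dec_idx] if ev.size else np.empty(0)
        cands = np.unique(np.concatenate([grid, deciles]))[::-1]
        return cands[(cands > 0.0) & (cands < self.root_age)]

    def min_era_events(self) -> int:
        """Minimum events per era: 2 on small trees, up to 5 on large ones."""
        return int(max(2, min(5, self.n_events // 10)))

    def min_era_width(self) -> float:
        """Minimum era duration (2% of the root age), the other degeneracy guard."""
        return 0.02 * self.root_age


# ---------------------------------------------------------------------- #
# likelihoods


def piecewise_yule_loglik(
    btimes: Sequence[float], rates: Sequence[float], shifts: Sequence[float]
) -> float:
    """Log-likelihood of a piecewise-constant pure-birth process.

    ``rates`` are the per-lineage speciation rates of the eras from the root
    toward the present; ``shifts`` are the era boundaries as ages strictly
    inside (0, root age), in descending order.  An event falling exactly on
    a boundary belongs to the younger era.
    """
    st = _BTStats(btimes)
    rates = np.asarray(rates, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if rates.size != shifts.size + 1:
        raise DiversificationError("need exactly one more rate than shifts")
    if np.any(rates <= 0):
        raise DiversificationError("rates must be positive")
    if shifts.size:
        if np.any(np.diff(shifts) >= 0):
            raise DiversificationError("shifts must be strictly descending")
        if shifts[0] >= st.root_age or shifts[-1] <= 0:
            raise DiversificationError(
                f"shifts must lie strictly inside (0, {st.root_age})"
            )
    lowers = np.concatenate([shifts, [0.0]])
    uppers = np.concatenate([[st.root_age], shifts])
    G_up = st.G_above(uppers)
    G_lo = st.G_above(lowers)
    G_lo[-1] = st.G_total
    G_era = G_lo - G_up
    n_up = np.asarray(st.n_above(uppers), dtype=int)
    n_lo = np.asarray(st.n_above(lowers), dtype=int)
    n_lo[-1] = st.n_events
    n_era = n_lo - n_up
    return float(st.ln_k_events + np.sum(n_era * np.log(rates) - rates * G_era))


def _pure_birth_loglik(st: _BTStats, r: float) -> float:
    return st.ln_k_events + st.n_events * math.log(r) - r * st.G_total


def _bd_loglik(st: _BTStats, r: float, a: float) -> float:
    """Nee et al. birth-death likelihood of node ages (net rate r, a = d/b)."""
    x = st.bt
    # log(exp(r x) - a) computed stably as r x + log(1 - a exp(-r x))
    inner = 1.0 - a * np.exp(-r * x)
    if np.any(inner <= 0):
        return -np.inf
    term = r * x + np.log(inner)
    return (
        st.ln_k_events
        + st.n_events * math.log(r)
        + r * float(st.events.sum())
        + st.n_tips * math.log1p(-a)
        - 2.0 * float(term.sum())
    )


def fit_rate_constant(btimes: Sequence[float], seed: int = 0) -> dict:
    """ML fits of the two rate-constant models (pureBirth, bd).

    The pure-birth rate has the closed form (number of events) / (lineage-
    time integral); the birth-death fit maximizes the Nee likelihood over
    net rate r > 0 and extinction fraction 0 <= a < 1 with seeded random
    restarts.
    """
    st = _BTStats(btimes)
    if st.m < 2:
        raise DiversificationError("rate-constant fits need >= 3 branching times")
    r_hat = st.n_events / st.G_total
    pb = DiversificationFit.make(
        "pureBirth", {"r": float(r_hat)}, _pure_birth_loglik(st, r_hat)
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43]))

    def nll(theta):
        r, a = math.exp(theta[0]), theta[1]
        val = _bd_loglik(st, r, a)
        return -val if np.isfinite(val) else 1e12

    starts = [(math.log(r_hat), 0.0), (math.log(r_hat), 0.5)]
    for _ in range(10):
        starts.append(
            (math.log(r_hat) + rng.normal(0, 1.0), float(rng.uniform(0.0, 0.95)))
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0=np.asarray(x0), method="L-BFGS-B",
            bounds=[(math.log(r_hat) - 12, math.log(r_hat) + 12), (0.0, 1.0 - 1e-9)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise DiversificationError(f"birth-death optimizer failed: {best}")
    r_bd, a_bd = math.exp(best.x[0]), float(best.x[1])
    bd = DiversificationFit.make("bd", {"r": r_bd, "a": a_bd}, -best.fun)
    return {"pureBirth": pb, "bd": bd}


def _rate_by_k_profile(st: _BTStats, f_of_k) -> tuple[float, float]:
    """Profile lnL of a pure-birth model whose per-lineage rate is r0*f(k).

    Returns (r0_hat, lnL at the profile optimum); f(k) must be positive for
    every lineage count k the tree visits (2..N).
    """
    k_seg = st._counts                      # lineage counts per inter-event segment
    f_seg = f_of_k(k_seg)
    if np.any(f_seg <= 0):
        return math.nan, -np.inf
    W = float(np.sum(k_seg * f_seg * st._widths))
    if W <= 0:
        return math.nan, -np.inf
    k_ev = np.arange(2, st.m + 1, dtype=float)  # event lineage counts 2..N-1
    E = float(np.sum(np.log(f_of_k(k_ev))))
    M = st.n_events
    r0 = M / W
    lnl = st.ln_k_events + M * math.log(r0) + E - M
    return r0, lnl


def _fit_1d(st: _BTStats, f_factory, lo: float, hi: float, n_grid: int = 60):
    """Grid scan + bounded refinement of a one-hyperparameter rate family."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_rate_by_k_profile(st, f_factory(u))[1] for u in grid])
    if not np.any(np.isfinite(vals)):
        raise DiversificationError("no valid candidate in rate-by-diversity fit")
    j = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
    a = grid[max(0, j - 1)]
    b = grid[min(n_grid - 1, j + 1)]
    res = optimize.minimize_scalar(
        lambda u: -_rate_by_k_profile(st, f_factory(u))[1],
        bounds=(a, b), method="bounded",
    )
    u_best = float(res.x) if -res.fun >= vals[j] else float(grid[j])
    r0, lnl = _rate_by_k_profile(st, f_factory(u_best))
    return u_best, r0, lnl


def _fit_ddl(st: _BTStats) -> DiversificationFit:
    n = st.n_tips

    def factory(u):
        K = n + math.exp(u)
        return lambda k: 1.0 - k / K

    u, r0, lnl = _fit_1d(st, factory, math.log(1e-3), math.log(1e12))
    return DiversificationFit.make("DDL", {"r0": r0, "K": n + math.exp(u)}, lnl)


def _fit_ddx(st: _BTStats) -> DiversificationFit:
    def factory(x):
        return lambda k: k ** (-x)

    x, r0, lnl = _fit_1d(st, factory, -3.0, 10.0)
    return DiversificationFit.make("DDX", {"r0": r0, "x": x}, lnl)


def _fit_yule2(st: _BTStats) -> DiversificationFit:
    M = st.n_events
    occ = st.min_era_events()
    cands = st.shift_candidates()
    n1 = st.n_above(cands).astype(float)
    g1 = st.G_above(cands)
    n2 = M - n1
    g2 = st.G_total - g1
    w = st.min_era_width()
    valid = (
        (n1 >= occ) & (n2 >= occ) & (g1 > 0) & (g2 > 0)
        & (st.root_age - cands >= w) & (cands >= w)
    )
    if not valid.any():
        raise DiversificationError("yule2rate needs >= 2 events on each side of a shift")
    with np.errstate(divide="ignore", invalid="ignore"):
        lnl = n1 * np.log(n1 / g1) + n2 * np.log(n2 / g2)
    lnl = np.where(valid, lnl, -np.inf)
    j = int(np.argmax(lnl))
    total = st.ln_k_events + lnl[j] - M
    return DiversificationFit.make(
        "yule2rate",
        {"r1": n1[j] / g1[j], "r2": n2[j] / g2[j], "st": float(cands[j])},
        total,
    )


def _fit_yule3(st: _BTStats) -> DiversificationFit:
    M = st.n_events
    occ = st.min_era_events()
    cands = st.shift_candidates()
    if cands.size < 2:
        raise DiversificationError("yule3rate needs at least two candidate shifts")
    nab = st.n_above(cands).astype(float)
    gab = st.G_above(cands)
    # eras split by (s1, s2) with s1 = cands[i] > s2 = cands[j]
    n_a = nab[:, None]
    n_b = nab[None, :] - nab[:, None]
    n_c = M - nab[None, :]
    g_a = gab[:, None]
    g_b = gab[None, :] - gab[:, None]
    g_c = st.G_total - gab[None, :]
    w = st.min_era_width()
    ordered = cands[:, None] - cands[None, :] >= w
    valid = (
        ordered
        & (n_a >= occ) & (n_b >= occ) & (n_c >= occ)
        & (g_a > 0) & (g_b > 0) & (g_c > 0)
        & (st.root_age - cands[:, None] >= w) & (cands[None, :] >= w)
    )
    if not valid.any():
        raise DiversificationError("yule3rate needs >= 2 events in each of three eras")
    with np.errstate(divide="ignore", invalid="ignore"):
        lnl = (
            n_a * np.log(np.where(valid, n_a / np.where(g_a > 0, g_a, 1), 1))
            + n_b * np.log(np.where(valid, n_b / np.where(g_b > 0, g_b, 1), 1))
            + n_c * np.log(np.where(valid, n_c / np.where(g_c > 0, g_c, 1), 1))
        )
    lnl = np.where(valid, lnl, -np.inf)
    i, j = np.unravel_index(int(np.argmax(lnl)), lnl.shape)
    total = st.ln_k_events + lnl[i, j] - M
    return DiversificationFit.make(
        "yule3rate",
        {
            "r1": float(nab[i] / gab[i]),
            "r2": float((nab[j] - nab[i]) / (gab[j] - gab[i])),
            "r3": float((M - nab[j]) / (st.G_total - gab[j])),
            "st1": float(cands[i]),
            "st2": float(cands[j]),
        },
        total,
    )


def fit_rate_variable(btimes: Sequence[float]) -> dict:
    """ML fits of DDL, DDX, yule2rate and (when feasible) yule3rate.

    yule3rate requires at least two events in each of its three eras; on
    trees too small for that it is omitted with a warning.
    """
    st = _BTStats(btimes)
    if st.m < 5:
        raise DiversificationError("rate-variable fits need >= 5 branching times")
    fits = {"DDL": _fit_ddl(st), "DDX": _fit_ddx(st), "yule2rate": _fit_yule2(st)}
    try:
        fits["yule3rate"] = _fit_yule3(st)
    except DiversificationError as exc:
        warnings.warn(f"yule3rate skipped: {exc}")
    return fits


def fit_all_models(btimes: Sequence[float], seed: int = 0) -> dict:
    fits = fit_rate_constant(btimes, seed=seed)
    fits.update(fit_rate_variable(btimes))
    return fits


_RC_MODELS = frozenset({"pureBirth", "bd"})
_RV_MODELS = frozenset({"DDL", "DDX", "yule2rate", "yule3rate"})


def select_model(fits: Iterable[DiversificationFit] | dict) -> ModelSelection:
    """AIC contrast between the model families; ties favor rate constancy."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    rc = [f for f in fits if f.model in _RC_MODELS]
    rv = [f for f in fits if f.model in _RV_MODELS]
    if not rc or not rv:
        raise DiversificationError("need at least one fit per model family")
    best_rc = min(rc, key=lambda f: (f.aic, f.model))
    best_rv = min(rv, key=lambda f: (f.aic, f.model))
    delta = best_rc.aic - best_rv.aic
    verdict = "rate_variable" if delta > 0 else "rate_constant"
    return ModelSelection(best_rc, best_rv, float(delta), verdict)


# ---------------------------------------------------------------------- #
# clade rate comparison (branch-length distributions)


@dataclass
class CladeRateResult:
    clade_rate: float      # 1 / mean branch length inside the clade
    outside_rate: float
    rate_ratio: float      # clade_rate / outside_rate (> 1: faster clade)
    lrt: float
    p_value: float
    hot: bool              # faster than the rest of the tree at level alpha
    n_clade: int
    n_outside: int

    def to_dict(self) -> dict:
        return {
            "clade_rate": self.clade_rate,
            "outside_rate": self.outside_rate,
            "rate_ratio": self.rate_ratio,
            "LRT": self.lrt,
            "p_value": self.p_value,
            "hot": self.hot,
            "n_clade": self.n_clade,
            "n_outside": self.n_outside,
        }


def clade_rate_comparison(
    tree: Phylogeny, clade_node: int, alpha: float = 0.05
) -> CladeRateResult:
    """Exponential likelihood-ratio comparison of branch lengths.

    Branch lengths inside the focal clade (all edges below ``clade_node``)
    and outside it (every other non-root edge, including the clade stem) are
    modeled as exponential with ML rate 1/mean; the one-degree-of-freedom
    LRT against a pooled rate flags clades with significantly shorter
    branches as "hot" (faster diversification).
    """
    if not (0 <= clade_node < tree.n_nodes):
        raise TreeError(f"unknown node id {clade_node}")
    inside = np.zeros(tree.n_nodes, dtype=bool)
    stack = list(tree._children[clade_node])
    while stack:
        i = stack.pop()
        inside[i] = True
        stack.extend(tree._children[i])
    keep = np.ones(tree.n_nodes, dtype=bool)
    keep[tree.root] = False
    x_in = tree._lengths[inside & keep]
    x_out = tree._lengths[~inside & keep]
    if x_in.size < 3 or x_out.size < 3:
        raise DiversificationError(
            f"need >= 3 branches inside and outside (got {x_in.size}, {x_out.size})"
        )
    s_in, s_out = float(x_in.sum()), float(x_out.sum())
    if s_in <= 0 or s_out <= 0:
        raise DiversificationError("a branch set has zero total length")

    def lnl_exp(n, s):
        lam = n / s
        return n * math.log(lam) - n

    lnl_sep = lnl_exp(x_in.size, s_in) + lnl_exp(x_out.size, s_out)
    lnl_pool = lnl_exp(x_in.size + x_out.size, s_in + s_out)
    lrt = max(0.0, 2.0 * (lnl_sep - lnl_pool))
    p = float(stats.chi2.sf(lrt, df=1))
    lam_in, lam_out = x_in.size / s_in, x_out.size / s_out
    return CladeRateResult(
        clade_rate=lam_in,
        outside_rate=lam_out,
        rate_ratio=lam_in / lam_out,
        lrt=lrt,
        p_value=p,
        hot=bool(lam_in > lam_out and p < alpha),
        n_clade=int(x_in.size),
        n_outside=int(x_out.size),
    )
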