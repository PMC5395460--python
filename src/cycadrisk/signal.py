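"""Phylogenetic signal of a binary trait (Fritz-Purvis D) and ED group tests.

The D statistic rescales the observed sum of sister-clade differences in a
binary trait between two reference points obtained by simulation on the same
tree: the mean under random tip shuffles (D = 1) and the mean under a
thresholded Brownian liability (D = 0).  D < 0 indicates strong clumping,
D > 1 overdispersion.  Both nulls and the observed value use the same
node-value estimator (unweighted child means), which makes the construction
self-normalizing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .tree import Phylogeny, TreeError, resolve_to_binary

__all__ = [
    "SignalError",
    "DStatResult",
    "GroupTestResult",
    "trait_change_sum",
    "d_statistic",
    "ed_group_test",
]


class SignalError(ValueError):
    """Invalid input to a signal test."""


@dataclass
class DStatResult:
    """D statistic with its permutation and Brownian reference distributions."""

    D: float
    d_obs: float
    mean_d_rand: float
    mean_d_bm: float
    p_rand: float      # fraction of permutation d-values <= d_obs (tests D != 1)
    p_bm: float        # fraction of Brownian d-values >= d_obs (tests D != 0)
    p_rand_smoothed: float
    p_bm_smoothed: float
    n_perm: int
    n_sim: int

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "d_obs": self.d_obs,
            "mean_d_rand": self.mean_d_rand,
            "mean_d_bm": self.mean_d_bm,
            "P_rand": self.p_rand,
            "P_BM": self.p_bm,
            "P_rand_smoothed": self.p_rand_smoothed,
            "P_BM_smoothed": self.p_bm_smoothed,
            "n_perm": self.n_perm,
            "n_sim": self.n_sim,
        }


def _trait_vector(tree: Phylogeny, trait: Mapping[str, int]) -> np.ndarray:
    missing = [lab for lab in tree.tip_labels if lab not in trait]
    if missing:
        raise SignalError("trait missing for tips: " + ", ".join(sorted(missing)))
    vec = np.array([trait[lab] for lab in tree.tip_labels], dtype=float)
    states = set(np.unique(vec))
    if not states.issubset({0.0, 1.0}):
        raise SignalError("trait must be binary (0/1)")
    if len(states) < 2:
        raise SignalError("no variation: trait is monomorphic")
    return vec


def _d_values(tree: Phylogeny, trait_matrix: np.ndarray) -> np.ndarray:
    """Sum of absolute sister differences per column of tip values.

    Node values are estimated tips-to-root as unweighted child means;
    every internal node contributes |v_i - v_j| over its unordered child
    pairs (for a binary tree, the single sister contrast).
    """
    n = tree.n_nodes
    vals = np.zeros((n, trait_matrix.shape[1]))
    vals[tree._tip_indices] = trait_matrix
    d = np.zeros(trait_matrix.shape[1])
    for i in tree._postorder:
        kids = tree._children[i]
        if not kids:
            continue
        child_vals = vals[kids]
        vals[i] = child_vals.mean(axis=0)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                d += np.abs(child_vals[a] - child_vals[b])
    return d


def trait_change_sum(tree: Phylogeny, trait: Mapping[str, int]) -> float:
    """Observed d: total sister-clade difference of the binary trait."""
    vec = _trait_vector(tree, trait)
    return float(_d_values(tree, vec[:, None])[0])


def _brownian_tips(tree: Phylogeny, rng, size: int) -> np.ndarray:
    sd = np.sqrt(tree._lengths)
    eps = rng.standard_normal((tree.n_nodes, size)) * sd[:, None]
    vals = np.zeros((tree.n_nodes, size))
    for i in tree._preorder:
        p = tree._parents[i]
        if p >= 0:
            vals[i] = vals[p] + eps[i]
    return vals[tree._tip_indices]


def d_statistic(
    tree: Phylogeny,
    trait: Mapping[str, int],
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> DStatResult:
    """Fritz-Purvis D for a binary trait on an (optionally polytomous) tree.

    Polytomies are resolved to binary (zero-length, label order) before the
    contrasts.  The permutation null shuffles tip labels preserving
    prevalence; the Brownian null simulates a liability (sigma = 1) on the
    tree and thresholds it so the number of 1s matches the observed count.

    D = (d_obs - mean d_BM) / (mean d_rand - mean d_BM).
    """
    if n_perm < 1 or n_sim < 1:
        raise SignalError("n_perm and n_sim must be >= 1")
    if tree.n_tips < 10:
        warnings.warn("D statistic on fewer than 10 tips is unreliable")
    btree = resolve_to_binary(tree)
    vec = _trait_vector(btree, trait)
    k1 = int(vec.sum())
    n = btree.n_tips
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))

    d_obs = float(_d_values(btree, vec[:, None])[0])

    perm = np.empty((n, n_perm))
    for j in range(n_perm):
        perm[:, j] = rng.permutation(vec)
    d_rand = _d_values(btree, perm)

    liab = _brownian_tips(btree, rng, n_sim)
    thresh_idx = np.argpartition(liab, n - k1, axis=0)[n - k1:, :]
    bm = np.zeros((n, n_sim))
    np.put_along_axis(bm, thresh_idx, 1.0, axis=0)
    d_bm = _d_values(btree, bm)

    mean_rand, mean_bm = float(d_rand.mean()), float(d_bm.mean())
    denom = mean_rand - mean_bm
    if abs(denom) < 1e-12:
        raise SignalError(
            f"degenerate nulls: mean d_rand ({mean_rand}) equals mean d_BM ({mean_bm})"
        )
    D = (d_obs - mean_bm) / denom
    c_rand = int(np.sum(d_rand <= d_obs))
    c_bm = int(np.sum(d_bm >= d_obs))
    return DStatResult(
        D=D,
        d_obs=d_obs,
        mean_d_rand=mean_rand,
        mean_d_bm=mean_bm,
        p_rand=c_rand / n_perm,
        p_bm=c_bm / n_sim,
        p_rand_smoothed=(1 + c_rand) / (n_perm + 1),
        p_bm_smoothed=(1 + c_bm) / (n_sim + 1),
        n_perm=n_perm,
        n_sim=n_sim,
    )


@dataclass
class GroupTestResult:
    F: float
    p_value: float
    group_means: dict

    def to_dict(self) -> dict:
        return {"F": self.F, "p_value": self.p_value, "group_means": self.group_means}


def ed_group_test(ed: Mapping[str, float], groups: Mapping[str, str]) -> GroupTestResult:
    """One-way ANOVA of ED (or any score) across groups.

    Used to compare the evolutionary distinctiveness of threatened vs.
    nonthreatened species, or across IUCN categories.  Every group needs at
    least two members.
    """
    by_group: dict[str, list[float]] = {}
    for sp, g in groups.items():
        if sp not in ed:
            raise SignalError(f"no ED value for species {sp!r}")
        by_group.setdefault(str(g), []).append(float(ed[sp]))
    if len(by_group) < 2:
        raise SignalError("need at least two groups")
    small = sorted(g for g, v in by_group.items() if len(v) < 2)
    if small:
        raise SignalError("groups with fewer than 2 members: " + ", ".join(small))
    names = sorted(by_group)
    samples = [np.asarray(by_group[g]) for g in names]
    F, p = stats.f_oneway(*samples)
    if math.isnan(F):  # zero variance everywhere: no effect
        F, p = 0.0, 1.0
    return GroupTestResult(
        F=float(F), p_value=float(p),
        group_means={g: float(np.mean(by_group[g])) for g in names},
    )
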