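"""Remaining-PD loss scenarios against random-pruning nulls.

Each scenario deletes a named set of species from the tree and asks whether
the phylogenetic diversity that remains is smaller than expected when the
same number of species is pruned uniformly at random.  The test is
one-tailed in the "more loss than random" direction and uses the add-one
Monte-Carlo estimator p = (1 + #{null <= observed}) / (reps + 1), which
cannot return an exact zero at finite replication.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    MetricsError,
    fair_proportion_ed,
    is_threatened,
    pd_of_tip_masks,
    percent_pd_lost,
    validate_threat_table,
)
from .tree import Phylogeny, TreeError

__all__ = [
    "ScenarioResult",
    "remaining_pd",
    "random_prune_null",
    "scenario_test",
    "run_standard_scenarios",
]


@dataclass
class ScenarioResult:
    """Observed remaining PD for one loss scenario vs. its random null."""

    name: str
    lost_count: int
    observed_remaining_pd: float
    null_remaining_pd: np.ndarray = field(repr=False)
    null_mean: float = 0.0
    null_sd: float = 0.0
    p_value: float = 1.0
    z_score: float = math.nan
    total_pd: float = 0.0
    percent_pd_lost: float = 0.0

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "lost_count": self.lost_count,
            "total_pd": self.total_pd,
            "observed_remaining_pd": self.observed_remaining_pd,
            "percent_pd_lost": self.percent_pd_lost,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "reps": int(len(self.null_remaining_pd)),
            "p_value": self.p_value,
            "z_score": None if math.isnan(self.z_score) else self.z_score,
        }


def _tip_mask(tree: Phylogeny, labels) -> np.ndarray:
    labset = set(labels)
    unknown = labset.difference(tree.tip_labels)
    if unknown:
        raise TreeError("unknown tip label(s): " + ", ".join(sorted(unknown)))
    return np.array([lab in labset for lab in tree.tip_labels])


def remaining_pd(tree: Phylogeny, lost) -> float:
    """PD of the surviving tips after the ``lost`` set goes extinct.

    Returns the total PD when nothing is lost and 0 when every tip is lost.
    """
    lost_mask = _tip_mask(tree, lost)
    survivors = ~lost_mask
    if not survivors.any():
        return 0.0
    return float(pd_of_tip_masks(tree, survivors)[0])


def random_prune_null(
    tree: Phylogeny,
    k: int,
    reps: int,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Remaining PD after deleting k uniform tips, ``reps`` times.

    With ``exhaustive=True`` every one of the C(n, k) loss sets is evaluated
    exactly once (small trees only) and ``reps`` is ignored.
    """
    n = tree.n_tips
    if not (0 < k < n):
        raise MetricsError(f"k must satisfy 0 < k < n_tips (got k={k}, n={n})")
    if exhaustive:
        combos = list(itertools.combinations(range(n), k))
        mask = np.ones((n, len(combos)), dtype=bool)
        for j, combo in enumerate(combos):
            mask[list(combo), j] = False
        return pd_of_tip_masks(tree, mask)
    if reps < 1:
        raise MetricsError("reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    )
    survivors = np.ones((n, reps), dtype=bool)
    noise = rng.random((reps, n))
    lost_idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
    for j in range(reps):
        survivors[lost_idx[j], j] = False
    return pd_of_tip_masks(tree, survivors)


def scenario_test(
    tree: Phylogeny,
    lost,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    name: str = "scenario",
    exhaustive: bool = False,
) -> ScenarioResult:
    """One-tailed random-pruning test for a named loss set.

    p is the add-one fraction of null prunings whose remaining PD is at most
    the observed remaining PD (i.e. the probability that random loss is at
    least as severe).  z = (observed - null mean) / null sd; when the null
    is degenerate (sd = 0) z is reported as NaN and p stays valid.
    """
    lost = set(lost)
    if not lost:
        raise MetricsError("loss set must be nonempty")
    if len(lost) >= tree.n_tips:
        raise MetricsError("loss set must be a proper subset of the tips")
    observed = remaining_pd(tree, lost)
    null = random_prune_null(tree, len(lost), reps, seed, exhaustive=exhaustive)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    p = (1.0 + int(np.sum(null <= observed))) / (len(null) + 1.0)
    z = (observed - null_mean) / null_sd if null_sd > 0 else math.nan
    total = tree.total_length
    return ScenarioResult(
        name=name,
        lost_count=len(lost),
        observed_remaining_pd=observed,
        null_remaining_pd=null,
        null_mean=null_mean,
        null_sd=null_sd,
        p_value=p,
        z_score=z,
        total_pd=total,
        percent_pd_lost=percent_pd_lost(observed, total),
    )


def run_standard_scenarios(
    tree: Phylogeny,
    threats: pd.DataFrame,
    top_ed_count: int | None = None,
    reps: int = 100,
    seed: int = 0,
) -> list[ScenarioResult]:
    """The five standard loss scenarios.

    (1) the ``top_ed_count`` most evolutionarily distinct species (default:
    half the tips), (2) all threatened species (VU, EN or CR; DD counts as
    nonthreatened), and (3-5) each threatened category alone.  Scenarios
    with an empty loss set are skipped with a warning.
    """
    tab = validate_threat_table(threats)
    missing = sorted(set(tree.tip_labels) - set(tab["species"]))
    if missing:
        raise MetricsError("threat table does not cover tips: " + ", ".join(missing))
    cat = tab.set_index("species")["category"]
    if top_ed_count is None:
        top_ed_count = tree.n_tips // 2
    if not (0 < top_ed_count < tree.n_tips):
        raise MetricsError("top_ed_count must be a proper fraction of the tips")
    ed = fair_proportion_ed(tree)
    ranked = ed.reset_index().sort_values(
        ["ED", "species"], ascending=[False, True], kind="mergesort"
    )
    top_ed = list(ranked["species"].iloc[:top_ed_count])

    tips = tree.tip_labels
    loss_sets = {
        "topED": top_ed,
        "threatened": [s for s in tips if is_threatened(cat[s])],
        "VU": [s for s in tips if cat[s] == "VU"],
        "EN": [s for s in tips if cat[s] == "EN"],
        "CR": [s for s in tips if cat[s] == "CR"],
    }
    results = []
    ss = np.random.SeedSequence([int(seed), 37])
    children = ss.spawn(len(loss_sets))
    for child, (nm, lost) in zip(children, loss_sets.items()):
        if not lost:
            warnings.warn(f"scenario {nm!r} has an empty loss set; skipped")
            continue
        rng = np.random.default_rng(child)
        results.append(scenario_test(tree, lost, reps=reps, seed=rng, name=nm))
    return results
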