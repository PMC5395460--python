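"""Synthetic cycad-like datasets: trees, threat tables, occurrences, protection masks.

This module generates data with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline is testable without
external downloads:

* ultrametric birth-death trees (forward Gillespie simulation, extinct
  lineages pruned), optionally with piecewise-constant speciation rates for
  rate-shift recovery experiments;
* "cycad-like" trees: monophyletic genera with long stem branches (40-300
  Myr) subtending recent crown radiations (2-13 Myr), with a right-skewed
  distribution of genus sizes;
* threat tables matching the observed cycad marginals (215 threatened of
  339: VU 78, EN 70, CR 67), drawn either i.i.d. per tip or by thresholding
  a Brownian liability simulated on the tree (which induces phylogenetic
  signal and is exactly the Brownian null of the D statistic);
* species occurrences on a rectangular lattice: contiguous ranges grown by
  random walk around a niche center, lognormal range sizes, and optional
  Brownian evolution of niche centers so close relatives co-occur;
* a patchy protected-area fraction field with a chosen overall mean;
* a genus-constrained grafting step that attaches species without DNA data
  uniformly at random inside their genus crown, as a single-draw stand-in
  for taxonomic imputation of missing taxa.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import CATEGORIES, OccurrenceMatrix
from .tree import Phylogeny, _freeze, _MutableNode, _thaw

__all__ = [
    "SimulationError",
    "SimConfig",
    "DEFAULT_CATEGORY_PROBS",
    "CYCAD_GENERA",
    "simulate_tree",
    "simulate_cycad_like_tree",
    "simulate_threats",
    "simulate_occurrences",
    "simulate_protected_mask",
    "simulate_dataset",
    "graft_missing_taxa",
]


class SimulationError(ValueError):
    """Invalid simulation configuration or failed simulation."""


#: Default IUCN category frequencies, matching the cycad marginals
#: (VU 78, EN 70, CR 67 of 339 taxa; the 124 nonthreatened split LC 94 / NT 30).
DEFAULT_CATEGORY_PROBS: dict[str, float] = {
    "LC": 94 / 339,
    "NT": 30 / 339,
    "VU": 78 / 339,
    "EN": 70 / 339,
    "CR": 67 / 339,
    "DD": 0.0,
}

#: The 11 cycad genera with approximate extant species counts, used as the
#: default right-skewed genus-size profile of the synthetic tree.
CYCAD_GENERA: tuple[tuple[str, int], ...] = (
    ("Cycas", 113),
    ("Zamia", 79),
    ("Encephalartos", 65),
    ("Macrozamia", 41),
    ("Ceratozamia", 27),
    ("Dioon", 13),
    ("Bowenia", 2),
    ("Lepidozamia", 2),
    ("Chigua", 2),
    ("Stangeria", 1),
    ("Microcycas", 1),
)

# liability ordering of categories, least to most threatened; the threatened
# block {VU, EN, CR} is contiguous at the top so the binary threatened trait
# is a single threshold of the Brownian liability.
_LIABILITY_ORDER = ("LC", "NT", "DD", "CD", "VU", "EN", "CR")

# fixed sub-stream tags so each generator is independent of the others
_TAG_TREE, _TAG_CYCAD, _TAG_THREAT, _TAG_OCC, _TAG_MASK = 11, 13, 17, 19, 23


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generators.

    Defaults emulate the cycad dataset: 339 species in 11 monophyletic
    genera, the observed IUCN marginals, and a patchy protection mask on an
    abstract 40 x 20 lattice of nominal 100 x 100 km cells.
    """

    seed: int = 0
    n_species: int = 339
    n_genera: int = 11
    birth: float = 0.1            # speciation events / lineage / Myr
    death: float = 0.0            # extinction events / lineage / Myr
    shift_times: tuple[float, ...] = ()   # forward times (Myr from the root) of rate shifts
    shift_rates: tuple[float, ...] = ()   # speciation rate after each shift
    threat_mode: str = "clustered"        # "iid" or "clustered" (Brownian liability)
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    grid_width: int = 40
    grid_height: int = 20
    range_size_log_mean: float = 1.8      # lognormal median ~6 cells
    range_size_log_sd: float = 1.0
    niche_brownian: bool = True           # niche centers evolve on the tree
    niche_sigma: float = 1.0              # cells per sqrt(Myr)
    protected_fraction: float = 0.3

    def validate(self) -> None:
        probs = dict(self.category_probs)
        bad = sorted(set(probs) - set(CATEGORIES))
        if bad:
            raise SimulationError("unknown categories in category_probs: " + ", ".join(bad))
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"category_probs must sum to 1 (got {total!r})")
        if any(p < 0 for p in probs.values()):
            raise SimulationError("category probabilities must be nonnegative")
        if self.birth < 0 or self.death < 0 or any(r < 0 for r in self.shift_rates):
            raise SimulationError("rates must be nonnegative")
        if len(self.shift_times) != len(self.shift_rates):
            raise SimulationError("shift_times and shift_rates must have equal length")
        if list(self.shift_times) != sorted(self.shift_times) or any(
            t <= 0 for t in self.shift_times
        ):
            raise SimulationError("shift_times must be positive and increasing")
        if self.grid_width < 1 or self.grid_height < 1:
            raise SimulationError("grid dimensions must be >= 1")
        if not (0.0 <= self.protected_fraction <= 1.0):
            raise SimulationError("protected_fraction must be in [0, 1]")
        if self.threat_mode not in ("iid", "clustered"):
            raise SimulationError("threat_mode must be 'iid' or 'clustered'")
        if self.n_species < 2:
            raise SimulationError("n_species must be >= 2")
        if self.range_size_log_sd < 0:
            raise SimulationError("range_size_log_sd must be >= 0")


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), tag]))


# ---------------------------------------------------------------------- #
# birth-death tree simulation


def _birth_rate_schedule(config: SimConfig):
    times = (0.0,) + tuple(config.shift_times)
    rates = (config.birth,) + tuple(config.shift_rates)
    return times, rates


def _era_index(times, t):
    k = 0
    while k + 1 < len(times) and t >= times[k + 1]:
        k += 1
    return k


def _gillespie(config: SimConfig, rng, n_target=None, duration=None):
    """Forward birth-death simulation from 2 lineages.

    Returns (root _MutableNode, present time) or None on total extinction.
    With ``n_target`` the simulation stops when the extant count first
    reaches the target and the present is placed at the time the next event
    would have occurred; with ``duration`` it runs for a fixed span.
    """
    times, rates = _birth_rate_schedule(config)
    death = config.death
    root = _MutableNode(None, 0.0)
    starts: dict[int, float] = {}
    extant: list[_MutableNode] = []
    for _ in range(2):
        c = root.add(_MutableNode())
        starts[id(c)] = 0.0
        extant.append(c)
    t = 0.0
    while True:
        k = len(extant)
        if k == 0:
            return None
        if n_target is not None and k >= n_target:
            era = _era_index(times, t)
            total = k * (rates[era] + death)
            dt = rng.exponential(1.0 / total) if total > 0 else np.inf
            # advance era by era so a rate shift inside the wait is honored
            while era + 1 < len(times) and t + dt > times[era + 1]:
                t = times[era + 1]
                era += 1
                total = k * (rates[era] + death)
                dt = rng.exponential(1.0 / total) if total > 0 else np.inf
            present = t + dt
            if not np.isfinite(present):
                present = t + 1.0  # all rates zero: close the tree arbitrarily
            break
        era = _era_index(times, t)
        birth = rates[era]
        total = k * (birth + death)
        if total <= 0:
            if duration is not None:
                present = duration
                break
            return None
        dt = rng.exponential(1.0 / total)
        if era + 1 < len(times) and t + dt > times[era + 1]:
            t = times[era + 1]  # cross into the next era and redraw
            continue
        t += dt
        if duration is not None and t >= duration:
            present = duration
            break
        idx = int(rng.integers(k))
        if rng.random() < birth / (birth + death):
            node = extant.pop(idx)
            node.length = t - starts.pop(id(node))
            for _ in range(2):
                c = node.add(_MutableNode())
                starts[id(c)] = t
            extant.extend(node.children[-2:])
        else:
            node = extant.pop(idx)
            node.length = t - starts.pop(id(node))
            node.label = "__extinct__"
    for node in extant:
        node.length = present - starts.pop(id(node))
    return root, present


def _prune_extinct(root: _MutableNode) -> _MutableNode | None:
    """Drop extinct subtrees and suppress unbranched internals.

    Returns the reconstructed tree of survivors, rooted at their MRCA with a
    zero-length root edge, or None if nothing survived.
    """

    def rec(node: _MutableNode) -> _MutableNode | None:
        if not node.children:
            return None if node.label == "__extinct__" else node
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        node.children = []
        for c in kept:
            node.add(c)
        return node

    out = rec(root)
    if out is not None:
        out.length = 0.0
        out.parent = None
    return out


def _label_tips(root: _MutableNode, prefix: str = "sp") -> None:
    i = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            i += 1
            node.label = f"{prefix}{i:04d}"
        else:
            stack.extend(reversed(node.children))


_MAX_RETRIES = 1000


def simulate_tree(config: SimConfig, duration: float | None = None) -> Phylogeny:
    """Simulate an ultrametric (piecewise) birth-death tree.

    By default the simulation is conditioned on ``config.n_species`` extant
    tips; with ``duration`` it instead runs for a fixed time span (used for
    checking the lineage-growth law E[N(T)] = 2 exp(rT) of the pure-birth
    process).  Extinct lineages are pruned; total extinction is retried up
    to 1000 times before raising.
    """
    config.validate()
    if config.birth <= 0:
        raise SimulationError("birth rate must be positive")
    rng = _rng(config, _TAG_TREE)
    n_target = None if duration is not None else config.n_species
    for _ in range(_MAX_RETRIES):
        sim = _gillespie(config, rng, n_target=n_target, duration=duration)
        if sim is None:
            continue
        root, _present = sim
        root = _prune_extinct(root)
        if root is None or not root.children:
            continue
        if n_target is not None:
            n_extant = sum(1 for _ in _iter_tips(root))
            if n_extant != n_target:
                continue
        _label_tips(root)
        return _freeze(root)
    raise SimulationError(
        f"no surviving tree in {_MAX_RETRIES} attempts (birth={config.birth}, "
        f"death={config.death})"
    )


def _iter_tips(root: _MutableNode):
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            yield node
        else:
            stack.extend(reversed(node.children))


# ---------------------------------------------------------------------- #
# cycad-like tree


def _genus_weights(n_genera: int) -> np.ndarray:
    if n_genera <= len(CYCAD_GENERA):
        w = np.array([c for _, c in CYCAD_GENERA[:n_genera]], dtype=float)
    else:
        w = np.exp(-0.45 * np.arange(n_genera))
    return w / w.sum()


def _genus_names(n_genera: int) -> list[str]:
    if n_genera <= len(CYCAD_GENERA):
        return [g for g, _ in CYCAD_GENERA[:n_genera]]
    return [f"Genus{i + 1:02d}" for i in range(n_genera)]


def simulate_cycad_like_tree(config: SimConfig) -> Phylogeny:
    """Ultrametric tree of monophyletic genera on long stems.

    Genus stems attach to a ladder backbone at ages drawn uniformly in
    40-300 Myr; each genus crown radiates at an age drawn uniformly in
    2-13 Myr as a rescaled Yule tree, echoing the decoupling of old genus
    origins from recent radiations that makes the cycad tree coalescent-like.
    Genus sizes follow a right-skewed multinomial (the observed genus-size
    profile for 11 genera), with at least one species per genus.
    """
    config.validate()
    if config.n_genera < 2:
        raise SimulationError("n_genera must be >= 2")
    if config.n_species < config.n_genera:
        raise SimulationError("n_species must be >= n_genera")
    rng = _rng(config, _TAG_CYCAD)
    g = config.n_genera
    weights = _genus_weights(g)
    counts = np.ones(g, dtype=int)
    counts += rng.multinomial(config.n_species - g, weights)

    backbone_ages = np.sort(rng.uniform(40.0, 300.0, size=g - 1))[::-1]
    crown_ages = rng.uniform(2.0, 13.0, size=g)
    names = _genus_names(g)

    def genus_subtree(gi: int) -> _MutableNode:
        k = int(counts[gi])
        if k == 1:
            node = _MutableNode()
            node.age = 0.0
            return node
        sub_seed = int(rng.integers(2**31 - 1))
        sub_cfg = replace(config, seed=sub_seed, n_species=k, birth=1.0,
                          death=0.0, shift_times=(), shift_rates=())
        crown_tree = simulate_tree(sub_cfg)
        scale = crown_ages[gi] / crown_tree.height
        node = _thaw(crown_tree)

        def rescale(m: _MutableNode):
            m.length *= scale
            m.age = (m.age or 0.0) * scale
            for c in m.children:
                rescale(c)

        rescale(node)
        node.age = crown_ages[gi]
        return node

    # ladder backbone: the node at backbone_ages[i] splits genus i off the spine
    spine = _MutableNode(None, 0.0)
    spine.age = backbone_ages[0]
    current = spine
    crown_nodes: list[_MutableNode] = []
    for gi in range(g):
        crown = genus_subtree(gi)
        current.add(crown)
        crown.length = current.age - crown.age
        crown_nodes.append(crown)
        if gi < g - 2:
            nxt = current.add(_MutableNode(None, current.age - backbone_ages[gi + 1]))
            nxt.age = backbone_ages[gi + 1]
            current = nxt
        # the last genus (gi == g - 1) attaches to the same node as genus g - 2
    for gi, crown in enumerate(crown_nodes):
        j = 0
        for tip in _iter_tips(crown):
            j += 1
            tip.label = f"{names[gi]}_sp{j:03d}"
    return _freeze(spine)


def genus_of(label: str) -> str:
    """Genus of a species label (the prefix before the first underscore)."""
    return label.split("_", 1)[0]


# ---------------------------------------------------------------------- #
# threat status


def _category_counts(probs: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n species to categories."""
    cats = [c for c in _LIABILITY_ORDER if probs.get(c, 0.0) > 0]
    raw = np.array([probs[c] * n for c in cats])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(cats, base))


def _brownian_tip_values(tree: Phylogeny, rng, size: int = 1) -> np.ndarray:
    """Brownian motion (sigma=1 per sqrt(Myr)) simulated down the tree."""
    n = tree.n_nodes
    vals = np.zeros((n, size))
    sd = np.sqrt(tree._lengths)
    eps = rng.standard_normal((n, size)) * sd[:, None]
    for i in tree._preorder:
        p = tree._parents[i]
        if p >= 0:
            vals[i] = vals[p] + eps[i]
    return vals[tree._tip_indices]


def simulate_threats(tree: Phylogeny, config: SimConfig) -> pd.DataFrame:
    """Assign IUCN categories to the tips of ``tree``.

    ``iid`` mode draws categories independently per tip; ``clustered`` mode
    simulates a Brownian liability on the tree and cuts it at the category
    quantiles, which yields exact marginal counts and phylogenetic signal
    (the Brownian-threshold null of the D statistic, so D is centered on 0).
    """
    config.validate()
    rng = _rng(config, _TAG_THREAT)
    labels = tree.tip_labels
    probs = dict(config.category_probs)
    if config.threat_mode == "iid":
        cats = [c for c in _LIABILITY_ORDER if probs.get(c, 0.0) > 0]
        p = np.array([probs[c] for c in cats])
        draw = rng.choice(len(cats), size=len(labels), p=p / p.sum())
        assigned = [cats[i] for i in draw]
    else:
        counts = _category_counts(probs, len(labels))
        liab = _brownian_tip_values(tree, rng)[:, 0]
        order = np.argsort(liab, kind="stable")
        assigned = [None] * len(labels)
        pos = 0
        for cat in _LIABILITY_ORDER:
            for _ in range(counts.get(cat, 0)):
                assigned[order[pos]] = cat
                pos += 1
    return pd.DataFrame({"species": labels, "category": assigned})


# ---------------------------------------------------------------------- #
# occurrences and protection


def _fold(x: np.ndarray, span: float) -> np.ndarray:
    """Reflect coordinates into [0, span) (triangle-wave folding)."""
    period = 2.0 * span
    x = np.mod(x, period)
    return np.where(x < span, x, period - x - 1e-9)


def _grow_patch(rng, start: tuple[int, int], size: int, w: int, h: int) -> set[int]:
    cells = {start}
    order = [start]
    tries = 0
    while len(cells) < size and tries < 50 * size + 100:
        tries += 1
        x, y = order[int(rng.integers(len(order)))]
        dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[int(rng.integers(4))]
        nx, ny = x + dx, y + dy
        if 0 <= nx < w and 0 <= ny < h and (nx, ny) not in cells:
            cells.add((nx, ny))
            order.append((nx, ny))
    return {y * w + x for x, y in cells}


def simulate_occurrences(tree: Phylogeny, config: SimConfig) -> OccurrenceMatrix:
    """Contiguous species ranges on the lattice.

    Range sizes are lognormal (right-skewed); each range is a random-walk
    patch grown from a niche center.  With ``niche_brownian`` the centers
    evolve by 2-D Brownian motion on the tree (reflected into the grid), so
    close relatives co-occur more than random pairs.
    """
    config.validate()
    rng = _rng(config, _TAG_OCC)
    w, h = config.grid_width, config.grid_height
    labels = tree.tip_labels
    n = len(labels)
    sizes = np.clip(
        np.rint(rng.lognormal(config.range_size_log_mean, config.range_size_log_sd, n)),
        1, w * h,
    ).astype(int)
    if config.niche_brownian:
        bm = _brownian_tip_values(tree, rng, size=2) * config.niche_sigma
        cx = _fold(bm[:, 0] + w / 2.0, w)
        cy = _fold(bm[:, 1] + h / 2.0, h)
    else:
        cx = rng.uniform(0, w, n)
        cy = rng.uniform(0, h, n)
    records = []
    for i, lab in enumerate(labels):
        start = (min(int(cx[i]), w - 1), min(int(cy[i]), h - 1))
        for cell in sorted(_grow_patch(rng, start, int(sizes[i]), w, h)):
            records.append((lab, cell))
    return OccurrenceMatrix.from_records(records, grid_width=w, grid_height=h)


def simulate_protected_mask(config: SimConfig) -> pd.Series:
    """Patchy per-cell protected fraction with overall mean ~ protected_fraction.

    A smoothed Gaussian random field is rank-uniformized and raised to the
    power (1 - f)/f, which has mean f for u ~ Uniform(0, 1) while keeping
    spatial patchiness from the smoothing.
    """
    config.validate()
    rng = _rng(config, _TAG_MASK)
    w, h = config.grid_width, config.grid_height
    n = w * h
    idx = pd.Index(range(n), name="cell_id")
    f = config.protected_fraction
    if f == 0.0:
        return pd.Series(np.zeros(n), index=idx, name="protected_fraction")
    if f == 1.0:
        return pd.Series(np.ones(n), index=idx, name="protected_fraction")
    field_ = rng.standard_normal((h, w))
    sigma = max(1.0, min(w, h) / 8.0)
    smooth = ndimage.gaussian_filter(field_, sigma=sigma, mode="wrap").ravel()
    ranks = np.empty(n)
    ranks[np.argsort(smooth, kind="stable")] = (np.arange(n) + 0.5) / n
    frac = ranks ** ((1.0 - f) / f)
    return pd.Series(frac, index=idx, name="protected_fraction")


def simulate_dataset(config: SimConfig) -> dict:
    """One coherent synthetic study: tree, threats, occurrences, mask."""
    tree = simulate_cycad_like_tree(config)
    return {
        "tree": tree,
        "threats": simulate_threats(tree, config),
        "occurrences": simulate_occurrences(tree, config),
        "mask": simulate_protected_mask(config),
    }


# ---------------------------------------------------------------------- #
# genus-constrained grafting of species without DNA data


def graft_missing_taxa(
    constraint_tree: Phylogeny, taxon_list: Mapping[str, str], seed: int
) -> Phylogeny:
    """Attach each missing species inside its genus on the constraint tree.

    ``taxon_list`` maps new species labels to genus names; genera of existing
    tips are read from the label prefix before the first underscore.  Each
    species is attached uniformly at random to a branch within its genus
    crown (the genus tip's own branch for a monotypic genus), at an age
    uniform on that branch, so the output stays ultrametric and genus
    monophyly and the relationships among original tips are preserved.

    A genus with no representative on the constraint tree is an error (no
    taxonomic anchor to attach to).
    """
    if not taxon_list:
        return constraint_tree
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    present_genera: dict[str, list[str]] = {}
    for lab in constraint_tree.tip_labels:
        present_genera.setdefault(genus_of(lab), []).append(lab)
    missing = sorted(set(taxon_list.values()) - set(present_genera))
    if missing:
        raise SimulationError(
            "genera absent from the constraint tree (no anchor): " + ", ".join(missing)
        )
    dup = sorted(set(taxon_list) & set(constraint_tree.tip_labels))
    if dup:
        raise SimulationError("species already on the tree: " + ", ".join(dup))

    root = _thaw(constraint_tree)
    tips_by_genus: dict[str, list[_MutableNode]] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            tips_by_genus.setdefault(genus_of(node.label), []).append(node)
        else:
            stack.extend(reversed(node.children))

    def crown_node(genus: str) -> _MutableNode:
        tips = tips_by_genus[genus]
        if len(tips) == 1:
            return tips[0]
        # MRCA in the mutable tree
        paths = []
        for t in tips:
            path, cur = [], t
            while cur is not None:
                path.append(cur)
                cur = cur.parent
            paths.append(path[::-1])
        k, limit = 0, min(len(p) for p in paths)
        while k < limit and all(p[k] is paths[0][k] for p in paths):
            k += 1
        return paths[0][k - 1]

    for species in sorted(taxon_list):
        genus = taxon_list[species]
        tips = tips_by_genus[genus]
        if len(tips) == 1:
            candidates = [tips[0]]
        else:
            crown = crown_node(genus)
            candidates = []
            st = list(crown.children)
            while st:
                nd = st.pop()
                candidates.append(nd)
                st.extend(nd.children)
        edge = candidates[int(rng.integers(len(candidates)))]
        parent = edge.parent
        attach_age = rng.uniform(edge.age, parent.age)
        joint = _MutableNode(None, parent.age - attach_age)
        joint.age = attach_age
        parent.children[parent.children.index(edge)] = joint
        joint.parent = parent
        joint.add(edge)
        edge.length = attach_age - edge.age
        tip = joint.add(_MutableNode(species, attach_age))
        tip.age = 0.0
        tips_by_genus[genus].append(tip)
    return _freeze(root)
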