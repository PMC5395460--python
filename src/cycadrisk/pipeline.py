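"""End-to-end orchestration: load or simulate data, score, test, map, report.

The pipeline composes the package's stages in the order of the underlying
analysis: EDGE scoring of every assessed species, loss scenarios against
random-pruning nulls, phylogenetic signal of threat, diversification model
selection with per-genus rate comparisons, and gridded diversity metrics
with hotspot extraction and a protected-area gap report.  Every stochastic
stage draws from a stream derived from the single pipeline seed, so a given
configuration always produces a byte-identical output bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversification import (
    DiversificationError,
    clade_rate_comparison,
    fit_all_models,
    select_model,
)
from .hotspots import (
    cumulative_hotspots,
    hotspot_overlap,
    protection_coverage,
    select_hotspots,
)
from .metrics import (
    CATEGORIES,
    MetricsError,
    OccurrenceMatrix,
    edge_scores,
    fair_proportion_ed,
    grid_mean_edge,
    grid_pd,
    grid_sr,
    is_threatened,
    phylogenetic_endemism,
    validate_threat_table,
    weighted_endemism,
)
from .scenarios import run_standard_scenarios
from .signal import SignalError, d_statistic, ed_group_test
from .simulate import SimConfig, genus_of, simulate_dataset
from .tree import Phylogeny, branching_times, drop_tips, mrca, parse_newick

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "read_tree",
    "write_tree",
    "read_threats",
    "write_threats",
    "read_occurrences",
    "write_occurrences",
    "read_mask",
    "write_mask",
    "validate_inputs",
    "run_pipeline",
]

HOTSPOT_METRICS = ("SR", "PD", "CWE", "PE", "meanEDGE")


class PipelineError(ValueError):
    """Invalid pipeline configuration or inconsistent inputs."""


# ---------------------------------------------------------------------- #
# file I/O (Newick + flat TSV/CSV tables)


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_tree(path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_threats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    return validate_threat_table(df)


def write_threats(threats: pd.DataFrame, path) -> None:
    threats.sort_values("species").to_csv(path, sep=_sep(path), index=False)


def read_occurrences(path) -> OccurrenceMatrix:
    df = pd.read_csv(path, sep=_sep(path))
    return OccurrenceMatrix.from_long(df)


def write_occurrences(occ: OccurrenceMatrix, path) -> None:
    occ.to_long().sort_values(["species", "cell_id"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_mask(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep(path))
    if not {"cell_id", "protected_fraction"}.issubset(df.columns):
        raise PipelineError("mask needs 'cell_id' and 'protected_fraction' columns")
    mask = df.set_index(df["cell_id"].astype(int))["protected_fraction"].astype(float)
    mask.index.name = "cell_id"
    return mask.sort_index()


def write_mask(mask: pd.Series, path) -> None:
    mask.rename("protected_fraction").rename_axis("cell_id").to_csv(
        path, sep=_sep(path)
    )


# ---------------------------------------------------------------------- #
# validation


def validate_inputs(
    tree: Phylogeny | None = None,
    threats: pd.DataFrame | None = None,
    occ: OccurrenceMatrix | None = None,
    mask: pd.Series | None = None,
) -> list[str]:
    """Cross-check the inputs; returns a list of human-readable findings."""
    findings: list[str] = []
    tips = set(tree.tip_labels) if tree is not None else None
    if threats is not None:
        dup = threats["species"][threats["species"].duplicated()]
        if len(dup):
            findings.append(
                "duplicate threat rows: " + ", ".join(sorted(set(dup)))
            )
        bad = sorted(set(threats["category"]) - set(CATEGORIES))
        if bad:
            findings.append("unknown categories: " + ", ".join(bad))
        if tips is not None:
            missing = sorted(tips - set(threats["species"]))
            if missing:
                findings.append("tips without threat status: " + ", ".join(missing))
            extra = sorted(set(threats["species"]) - tips)
            if extra:
                findings.append("threat species not on tree: " + ", ".join(extra))
    if occ is not None and tips is not None:
        extra = sorted(set(occ.species) - tips)
        if extra:
            findings.append("occurrence species not on tree: " + ", ".join(extra))
    if mask is not None and occ is not None:
        missing = sorted(int(c) for c in occ.cells if c not in mask.index)
        if missing:
            findings.append(
                "occupied cells without protection value: "
                + ", ".join(map(str, missing))
            )
    if tree is not None and not tree.is_ultrametric():
        findings.append(
            f"tree not ultrametric (max deviation {tree.ultrametric_deviation():.6g} Myr)"
        )
    return findings


# ---------------------------------------------------------------------- #
# configuration


@dataclass
class PipelineConfig:
    """Inputs are either four file paths or one synthetic-data configuration."""

    tree_path: str | None = None
    threats_path: str | None = None
    occ_path: str | None = None
    mask_path: str | None = None
    sim: SimConfig | None = None
    seed: int = 0
    reps: int = 100
    hotspot_thresholds: tuple[float, ...] = (2.5, 5.0)
    top_ed_count: int | None = None      # default: half of the tips
    outgroups: tuple[str, ...] = ()      # dropped before diversification fits
    d_n_perm: int = 1000
    d_n_sim: int = 1000
    out_dir: str | None = None

    def validate(self) -> None:
        has_paths = self.tree_path is not None
        if has_paths == (self.sim is not None):
            raise PipelineError(
                "exactly one of input paths or a simulation config must be given"
            )
        if has_paths and self.threats_path is None:
            raise PipelineError("a threat table path is required with a tree path")
        if self.reps < 1:
            raise PipelineError("reps must be >= 1")


# ---------------------------------------------------------------------- #
# pipeline


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _genus_clade_rates(tree: Phylogeny) -> pd.DataFrame:
    """Per-genus hot/cold clade table from branch-length rate comparisons."""
    genera: dict[str, list[str]] = {}
    for lab in tree.tip_labels:
        genera.setdefault(genus_of(lab), []).append(lab)
    rows = []
    for genus in sorted(genera):
        labs = genera[genus]
        if len(labs) < 2 or len(labs) >= tree.n_tips - 1:
            continue
        node = mrca(tree, labs)
        try:
            res = clade_rate_comparison(tree, node)
        except DiversificationError:
            continue
        rows.append({"genus": genus, "n_tips": len(labs), **res.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and (optionally) write the report bundle.

    Returns a dict of in-memory results; when ``config.out_dir`` is set the
    same results are written as a deterministic TSV/JSON bundle.
    """
    config.validate()
    report: dict = {}

    if config.sim is not None:
        data = simulate_dataset(config.sim)
        tree, threats = data["tree"], data["threats"]
        occ, mask = data["occurrences"], data["mask"]
    else:
        tree = read_tree(config.tree_path)
        threats = read_threats(config.threats_path)
        occ = read_occurrences(config.occ_path) if config.occ_path else None
        mask = read_mask(config.mask_path) if config.mask_path else None

    findings = validate_inputs(tree, threats, occ, mask)
    report["validation"] = findings
    if occ is not None:
        extra = sorted(set(occ.species) - set(tree.tip_labels))
        if extra:
            raise PipelineError(
                "occurrence species absent from tree: " + ", ".join(extra)
            )
    missing_status = sorted(set(tree.tip_labels) - set(threats["species"]))
    if missing_status:
        raise PipelineError(
            "tips without threat status: " + ", ".join(missing_status)
        )

    cat = threats.set_index("species")["category"]

    # --- species scores -------------------------------------------------
    ed = fair_proportion_ed(tree)
    report["total_pd"] = tree.total_length
    scored = threats[threats["category"] != "DD"]
    if scored.empty:
        warnings.warn("all species are data deficient; EDGE stage skipped")
        edge_table = None
    else:
        edge_table = edge_scores(ed, threats)
    report["ed"] = ed
    report["edge_table"] = edge_table

    # --- loss scenarios --------------------------------------------------
    scen = run_standard_scenarios(
        tree, threats, top_ed_count=config.top_ed_count,
        reps=config.reps, seed=config.seed,
    )
    report["scenarios"] = scen

    # --- phylogenetic signal ---------------------------------------------
    trait = {s: int(is_threatened(c)) for s, c in cat.items() if s in set(tree.tip_labels)}
    try:
        report["d_statistic"] = d_statistic(
            tree, trait, n_perm=config.d_n_perm, n_sim=config.d_n_sim,
            seed=config.seed,
        )
    except SignalError as exc:
        warnings.warn(f"D statistic skipped: {exc}")
        report["d_statistic"] = None
    groups = {
        s: ("threatened" if is_threatened(c) else "nonthreatened")
        for s, c in cat.items()
        if s in ed.index and c != "DD"
    }
    try:
        report["ed_threat_anova"] = ed_group_test(ed, groups)
    except SignalError as exc:
        warnings.warn(f"ED-vs-threat ANOVA skipped: {exc}")
        report["ed_threat_anova"] = None
    counts = cat[cat != "DD"].value_counts()
    cat_groups = {
        s: c for s, c in cat.items()
        if c != "DD" and counts.get(c, 0) >= 2 and s in ed.index
    }
    try:
        report["ed_category_anova"] = ed_group_test(ed, cat_groups)
    except SignalError as exc:
        warnings.warn(f"ED-vs-category ANOVA skipped: {exc}")
        report["ed_category_anova"] = None

    # --- diversification --------------------------------------------------
    div_tree = drop_tips(tree, config.outgroups) if config.outgroups else tree
    try:
        bt = branching_times(div_tree)
        fits = fit_all_models(bt, seed=config.seed)
        report["diversification_fits"] = fits
        report["model_selection"] = select_model(fits)
        report["branching_times"] = bt
    except (DiversificationError, ValueError) as exc:
        warnings.warn(f"diversification stage skipped: {exc}")
        report["diversification_fits"] = None
        report["model_selection"] = None
        report["branching_times"] = None
    report["clade_rates"] = _genus_clade_rates(div_tree)

    # --- grid metrics, hotspots, protection --------------------------------
    if occ is not None:
        maps = {"SR": grid_sr(occ).astype(float), "PD": grid_pd(tree, occ)}
        we, cwe = weighted_endemism(occ)
        maps["WE"], maps["CWE"] = we, cwe
        maps["PE"] = phylogenetic_endemism(tree, occ)
        if edge_table is not None:
            try:
                maps["meanEDGE"] = grid_mean_edge(edge_table, occ)
            except MetricsError as exc:
                warnings.warn(f"meanEDGE map skipped: {exc}")
        report["grid_metrics"] = maps
        hotspot_sets: dict[float, list] = {}
        for tier in config.hotspot_thresholds:
            hotspot_sets[tier] = [
                select_hotspots(maps[m], tier) for m in HOTSPOT_METRICS if m in maps
            ]
        report["hotspots"] = hotspot_sets
        primary = hotspot_sets[min(config.hotspot_thresholds)]
        report["venn"] = hotspot_overlap(primary) if len(primary) >= 2 else None
        report["cumulative"] = cumulative_hotspots(primary, n_occupied=occ.n_cells)
        if mask is not None:
            report["protection"] = protection_coverage(primary, mask)
        else:
            report["protection"] = None
    else:
        report["grid_metrics"] = None

    if config.out_dir is not None:
        _write_bundle(config, report, tree, threats, occ, mask)
    return report


# ---------------------------------------------------------------------- #
# report bundle


def _write_bundle(config, report, tree, threats, occ, mask) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = asdict(config.sim) if config.sim is not None else None
    if sim_cfg is not None:
        sim_cfg["category_probs"] = dict(sim_cfg["category_probs"])
    manifest = {
        "package": "cycadrisk",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("sim",)
            },
            "sim": sim_cfg,
        },
        "validation_findings": report["validation"],
    }
    _json_dump(manifest, out / "manifest.json")

    if config.sim is not None:
        write_tree(tree, out / "tree.nwk")
        write_threats(threats, out / "threats.tsv")
        if occ is not None:
            write_occurrences(occ, out / "occurrences.tsv")
        if mask is not None:
            write_mask(mask, out / "mask.tsv")

    if report["edge_table"] is not None:
        report["edge_table"].to_csv(out / "edge_table.tsv", sep="\t", index=False)

    _json_dump([s.to_dict() for s in report["scenarios"]], out / "scenarios.json")
    nulls = pd.concat(
        [
            pd.DataFrame(
                {
                    "scenario": s.name,
                    "draw": np.arange(1, len(s.null_remaining_pd) + 1),
                    "remaining_pd": s.null_remaining_pd,
                }
            )
            for s in report["scenarios"]
        ],
        ignore_index=True,
    )
    nulls.to_csv(out / "scenario_nulls.tsv", sep="\t", index=False)

    if report["d_statistic"] is not None:
        _json_dump(report["d_statistic"].to_dict(), out / "d_statistic.json")
    anova = {}
    for key in ("ed_threat_anova", "ed_category_anova"):
        if report[key] is not None:
            anova[key] = report[key].to_dict()
    _json_dump(anova, out / "ed_anova.json")

    if report["model_selection"] is not None:
        _json_dump(
            {
                "fits": {m: f.to_dict() for m, f in report["diversification_fits"].items()},
                "selection": report["model_selection"].to_dict(),
            },
            out / "diversification.json",
        )
        pd.DataFrame({"age": report["branching_times"]}).to_csv(
            out / "branching_times.tsv", sep="\t", index=False
        )
    if len(report["clade_rates"]):
        report["clade_rates"].to_csv(out / "clade_rates.tsv", sep="\t", index=False)

    if report["grid_metrics"] is not None:
        long = pd.concat(
            [
                pd.DataFrame(
                    {"cell_id": m.index.astype(int), "metric": name, "value": m.to_numpy()}
                )
                for name, m in report["grid_metrics"].items()
            ],
            ignore_index=True,
        )
        long.to_csv(out / "grid_metrics.tsv", sep="\t", index=False)
        rows = []
        for tier, sets in report["hotspots"].items():
            for s in sets:
                values = report["grid_metrics"][s.metric]
                for cell in s.ranked_cells:
                    rows.append(
                        {
                            "metric": s.metric,
                            "tier_percent": tier,
                            "cell_id": cell,
                            "value": float(values.loc[cell]),
                            "protected": bool(mask is not None and mask.loc[cell] >= 0.5),
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        if report["venn"] is not None:
            venn_rows = [
                {"region": "+".join(names), "n_sets": len(names), "count": count}
                for names, count in report["venn"].items()
            ]
            pd.DataFrame(venn_rows).to_csv(out / "venn.tsv", sep="\t", index=False)
        _json_dump(report["cumulative"].to_dict(), out / "cumulative_hotspots.json")
        if report["protection"] is not None:
            _json_dump(report["protection"].to_dict(), out / "protection.json")
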