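# cycadrisk

Phylogeny-aware extinction-risk and diversity-hotspot analysis for cycads —
the plant lineage with the highest proportion of threatened species — and for
any group with a comparable data shape: a dated phylogeny, IUCN threat
statuses, gridded occurrences, and a protected-area layer.

Cycad trees are unusual: each genus sits on a long stem (its origin is tens
to hundreds of Myr old) but radiated only in the last few Myr, so most
branch length is concentrated in a handful of deep branches.  Whether
extinction would erase a disproportionate share of that accumulated
evolutionary history, and whether conservation hotspots capture it, are
quantitative questions this package answers end to end.

## What it computes

**Species scores.**  Fair-proportion evolutionary distinctiveness (ED):
every branch length is split equally among its descendant tips, so
Σ ED = PD, Faith's phylogenetic diversity of the whole tree.  Global
endangerment GE codes the IUCN category (LC=0, NT/CD=1, VU=2, EN=3, CR=4),
and species are ranked by

    EDGE = ln(1 + ED) + GE · ln 2.

**Loss scenarios.**  For a named loss set S (the top-k ED species, all
threatened species, or one IUCN category), the observed remaining
PD(tips ∖ S) is compared with the remaining PD after pruning |S| random
tips, over 100 randomizations by default:

    p = (1 + #{null ≤ observed}) / (reps + 1)

(one-tailed: does the scenario destroy *more* PD than chance?).

**Phylogenetic signal.**  The Fritz–Purvis D statistic of the binary
threatened/nonthreatened trait, rescaled between its permutation null
(D = 1, random) and Brownian-threshold null (D = 0, clumped as under
Brownian motion), plus one-way ANOVA of ED across threat groups.

**Diversification.**  Six likelihood models on the branching times — pure
birth, birth–death, density-dependent (DDL, DDX), and two- and three-era
piecewise Yule — compared by ΔAIC_rc = AIC(best rate-constant) − AIC(best
rate-variable), with a per-clade exponential likelihood-ratio test that
flags "hot" (fast-diversifying) genera from their branch-length
distribution.

**Hotspots.**  Per grid cell: species richness, PD, (corrected) weighted
endemism, phylogenetic endemism, and mean EDGE; hotspot sets are the richest
2.5% (and 5%) of occupied cells per metric, with Venn overlaps, cumulative
extent, and a protected-area gap report (a cell counts as protected when at
least 50% of it is covered).

A synthetic-data module generates cycad-like trees (monophyletic genera,
stems 40–300 Myr, crowns 2–13 Myr), threat tables matching the observed
marginals (215 threatened of 339: VU 78, EN 70, CR 67), contiguous gridded
ranges with phylogenetically conserved niche centers, patchy protection
masks, and a genus-constrained grafting step for species without DNA data —
so the full pipeline runs and is tested without any downloads.

## Worked example

```python
import warnings
warnings.filterwarnings("ignore")

from cycadrisk import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(seed=42), seed=42, reps=100,
                        top_ed_count=165)
report = run_pipeline(config)

print(f"total PD: {report['total_pd']:.1f} Myr")
print(report["edge_table"].head(3)[["species", "category", "ED", "EDGE"]]
      .to_string(index=False))
for s in report["scenarios"]:
    print(f"{s.name:>10}: lose {s.lost_count:3d} species -> "
          f"{s.percent_pd_lost:4.1f}% of PD lost, p = {s.p_value:.3f}")
d = report["d_statistic"]
print(f"D = {d.D:.3f} (P_rand = {d.p_rand:.3f}, P_BM = {d.p_bm:.3f})")
sel = report["model_selection"]
print(f"delta_AIC_rc = {sel.delta_aic_rc:.2f} -> {sel.verdict}")
cum = report["cumulative"]
print(f"hotspot union: {len(cum.union_cells)} cells = {cum.area_km2:,.0f} km^2 "
      f"({cum.percent_of_occupied:.1f}% of occupied cells)")
```

prints

```
total PD: 2463.6 Myr
    species category       ED     EDGE
Zamia_sp014       CR 8.806561 5.055640
Zamia_sp015       CR 8.806561 5.055640
Zamia_sp016       CR 7.966120 4.966042
     topED: lose 165 species -> 60.6% of PD lost, p = 0.010
threatened: lose 215 species -> 30.0% of PD lost, p = 0.010
        VU: lose  78 species ->  2.3% of PD lost, p = 0.990
        EN: lose  70 species ->  2.3% of PD lost, p = 0.832
        CR: lose  67 species ->  6.3% of PD lost, p = 0.238
D = -0.079 (P_rand = 0.000, P_BM = 0.831)
delta_AIC_rc = -60.91 -> rate_constant
hotspot union: 44 cells = 440,000 km^2 (11.4% of occupied cells)
```

Reading this: on this synthetic tree, losing the 165 most evolutionarily
distinct species would erase 60.6% of all accumulated branch length —
far more than random loss of 165 species ever does in 100 randomizations
(p = 0.010, the add-one floor).  Losing all 215 threatened species is also
significantly worse than random, while losing any single category is not.
D = −0.079 says threat status is clumped on the tree about as strongly as a
thresholded Brownian trait (the generator's default mode, so this is the
expected calibration), and the AIC contrast prefers a constant
diversification rate for this particular realization.  The same run writes a
full TSV/JSON bundle when `out_dir` is set, and `seed` makes it
byte-reproducible.

The same stages are available from the shell:

```sh
cycadrisk simulate --seed 42 --out data/
cycadrisk pipeline --tree data/tree.nwk --threats data/threats.tsv \
    --occ data/occurrences.tsv --mask data/mask.tsv \
    --reps 100 --seed 42 --top-ed 50% --out results/
cycadrisk validate --tree data/tree.nwk --threats data/threats.tsv
```

Input formats: Newick (branch lengths in Myr); TSV/CSV tables
`species,category`, `species,cell_id`, and `cell_id,protected_fraction`.

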