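# gutlapse

Stem-cell lineage dynamics from long-term midgut explant time-lapse
imaging.

Adult *Drosophila* midgut explants can now be live-imaged for 2–3 days —
long enough to watch intestinal stem cells (ISCs) divide repeatedly,
their daughters divide again or differentiate, and whole lineages unfold.
`gutlapse` is a Python library (plus a thin CLI) for the analysis such
movies need:

* **registration** — tile the field into overlapping ROIs and stabilize
  local tissue drift by normalized cross-correlation, so per-cell
  positions are comparable across hourly frames;
* **quantification** — Otsu dual-channel (GFP ∩ nuclear) masks with
  per-cell and per-organ mean fluorescence, local-median background
  adjustment in a 50 µm window, sub-pixel nuclear areas, and the
  median-normalized cell-death (NucGreen) time-series;
* **lineage** — reconstruct lineage trees from track tables (annotated
  parents, or positional linking of mothers to daughter pairs), and
  measure cell-cycle durations between consecutive divisions;
* **siblings** — classify each division's daughter pair as *co-dividing*
  (both daughters divide again; the proxy for a symmetric ISC division)
  or *non-co-dividing* (one divides, the other stays quiescent ≥ 6 h; the
  asymmetric proxy), and compute internuclear-distance series, motility
  with IQR outlier flagging, sister-relative movement, and out-of-plane
  sister angles in flat epithelium;
* **stats / report** — exact Fisher 2×2 test (hypergeometric enumeration
  of all margin-fixed tables), Mann-Whitney U, and deterministic report
  tables comparing genotypes or groups;
* **synthetic** — an agent-based lineage simulator and movie renderer
  with recoverable ground truth (cycle times ~ N(8, 2.76²) h,
  symmetric-like daughters actively separating, differentiating
  quiescent daughters, asynchronous GFP onset, photobleaching, tissue
  drift, nuclear volume exclusion), used to verify every stage.

## Worked example

Simulate two genetic stimulation regimes that differ only in their
symmetric-division probability, run the lineage/classification chain on
each, and compare them:

```python
import gutlapse as gl

groups = {}
for name, p_sym, seed in (("ras", 0.1, 31), ("stgcyce", 0.5, 32)):
    params = gl.SimulationParams(n_founders=15, t_max=48.0,
                                 p_symmetric=p_sym, seed=seed,
                                 field_size_um=(300.0, 300.0))
    scene = gl.simulate_lineages(params)
    trees = gl.build_lineage_trees(scene.truth_tracks)
    pairs = gl.find_sibling_pairs(trees)
    end = int(scene.truth_tracks["frame"].max())
    for p in pairs:
        gl.classify_pair(p, end)
    from gutlapse.siblings import pair_table
    groups[name] = {
        "pairs": pair_table(pairs),
        "cycles": [d for t in trees for d in gl.cell_cycle_durations(t)],
    }

from gutlapse import AnalysisConfig, build_report
bundle = build_report({g: v["pairs"] for g, v in groups.items()},
                      {g: v["cycles"] for g, v in groups.items()},
                      AnalysisConfig())
print(bundle.codividing_frequency.to_string(index=False))
print(f"fisher p = {bundle.fisher_p:.4g}")
print(bundle.cycle_summary.to_string(index=False))
```

Output:

```
  group  lineages_with_codividing  lineages_without
    ras                         8                 7
stgcyce                        15                 0
fisher p = 0.006322
  group  n_cycles   mean_h     sd_h
    ras        88 7.568182 2.819454
stgcyce       199 7.688442 2.852151
```

The frequency table counts, per group, lineages containing at least one
co-dividing sibling pair; the Fisher p-value tests whether that frequency
differs between the groups (here it does — the high-`p_symmetric` group
produces co-dividing lineages far more often), while the cycle-duration
summary shows both groups cycling at the configured ~8 h mean, compared
by Mann-Whitney in the full report bundle.

The same chain is available from a shell:

```bash
gutlapse simulate --out run/ras --seed 31 --p-symmetric 0.1
gutlapse lineage  --tracks run/ras/tracks.csv --out run/ras/lineage
gutlapse classify --tracks run/ras/tracks.csv --out run/ras/pairs.csv
gutlapse report   --pairs ras=run/ras/pairs.csv \
                  --cycles ras=run/ras/lineage/cycle_durations.csv \
                  --out run/report
```

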