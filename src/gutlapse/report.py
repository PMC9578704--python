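"""Report tables summarizing lineage behavior across genotypes/groups.

Produces, as plain CSV plus a JSON manifest:

* a per-group proliferating-cell fraction table (when per-cell counts are
  supplied);
* the co-dividing-lineage frequency table with Fisher's exact p when
  exactly two groups are compared;
* a cell-cycle duration summary (mean ± SD, n) with a Mann-Whitney
  comparison for two groups;
* the internuclear-distance-vs-time ensemble table (mean ± SD at t0..t5
  per pair label).

Output is deterministic: groups and rows are sorted and floats are
written at fixed precision, so regenerating a report from the same inputs
is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .siblings import LABEL_CODIVIDING, LABEL_NONCODIVIDING
from .stats import fisher_exact_2x2, mann_whitney

FLOAT_FORMAT = "%.6g"


class MissingStageError(FileNotFoundError):
    pass


@dataclasses.dataclass
class ReportBundle:
    codividing_frequency: pd.DataFrame
    cycle_summary: pd.DataFrame
    distance_vs_time: pd.DataFrame
    proliferation: pd.DataFrame | None
    fisher_p: float | None
    mannwhitney_p: float | None
    manifest: dict


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format=FLOAT_FORMAT).encode()
    ).hexdigest()[:16]


def build_report(
    pair_tables: Mapping[str, pd.DataFrame],
    cycle_durations: Mapping[str, Sequence[float]],
    config: AnalysisConfig,
    outdir: str | Path | None = None,
    cell_counts: Mapping[str, tuple[int, int]] | None = None,
) -> ReportBundle:
    """Assemble the cross-group report from per-group pair tables.

    ``pair_tables`` maps group name to a sibling-pair table (schema of
    :func:`gutlapse.siblings.pair_table`, including ``lineage_id`` and
    ``label``); ``cycle_durations`` maps group name to completed cycle
    durations in hours; ``cell_counts`` optionally maps group name to
    ``(n_proliferating, n_total)`` progenitor counts. With exactly two
    groups the co-dividing frequencies are compared by Fisher's exact test
    and the cycle durations by Mann-Whitney; with fewer or more groups the
    tables are written without a test.
    """
    groups = sorted(pair_tables)
    if sorted(cycle_durations) != groups:
        raise MissingStageError(
            "cycle_durations groups do not match pair_tables groups"
        )

    freq_rows = []
    for g in groups:
        tbl = pair_tables[g]
        if len(tbl) == 0:
            with_codiv, without = 0, 0
        else:
            per_lineage = tbl.groupby("lineage_id")["label"].apply(
                lambda s: (s == LABEL_CODIVIDING).any()
            )
            with_codiv = int(per_lineage.sum())
            without = int((~per_lineage).sum())
        freq_rows.append({"group": g, "lineages_with_codividing": with_codiv,
                          "lineages_without": without})
    freq = pd.DataFrame(freq_rows)

    fisher_p = None
    total_pairs = sum(len(t) for t in pair_tables.values())
    if len(groups) == 2 and total_pairs > 0 and freq[
            ["lineages_with_codividing", "lineages_without"]].to_numpy().sum() > 0:
        fisher_p = fisher_exact_2x2(
            freq[["lineages_with_codividing", "lineages_without"]].to_numpy()
        )

    cyc_rows = []
    for g in groups:
        vals = np.asarray(list(cycle_durations[g]), dtype=float)
        cyc_rows.append({
            "group": g,
            "n_cycles": len(vals),
            "mean_h": float(vals.mean()) if len(vals) else np.nan,
            "sd_h": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    cycles = pd.DataFrame(cyc_rows)
    mw_p = None
    if len(groups) == 2 and all(len(cycle_durations[g]) > 0 for g in groups):
        mw_p = mann_whitney(cycle_durations[groups[0]],
                            cycle_durations[groups[1]]).pvalue

    dist_cols = [c for c in next(iter(pair_tables.values()), pd.DataFrame()).columns
                 if str(c).startswith("dist_t")]
    dist_rows = []
    for g in groups:
        tbl = pair_tables[g]
        for label in (LABEL_CODIVIDING, LABEL_NONCODIVIDING):
            sub = tbl[tbl["label"] == label] if len(tbl) else tbl
            for col in dist_cols:
                vals = sub[col].dropna().to_numpy() if len(sub) else np.array([])
                dist_rows.append({
                    "group": g, "label": label, "timepoint_h": int(col[6:]),
                    "n": len(vals),
                    "mean_um": float(vals.mean()) if len(vals) else np.nan,
                    "sd_um": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                })
    dist = pd.DataFrame(dist_rows)

    prolif = None
    if cell_counts is not None:
        prolif = pd.DataFrame([
            {"group": g, "n_proliferating": cell_counts[g][0],
             "n_total": cell_counts[g][1],
             "fraction": cell_counts[g][0] / cell_counts[g][1]
             if cell_counts[g][1] else np.nan}
            for g in sorted(cell_counts)
        ])

    manifest = {
        "config": dataclasses.asdict(config),
        "groups": groups,
        "n_pairs": {g: int(len(pair_tables[g])) for g in groups},
        "input_hashes": {g: _hash_frame(pair_tables[g]) for g in groups},
        "fisher_p": fisher_p,
        "mannwhitney_p": mw_p,
    }

    bundle = ReportBundle(
        codividing_frequency=freq, cycle_summary=cycles,
        distance_vs_time=dist, proliferation=prolif,
        fisher_p=fisher_p, mannwhitney_p=mw_p, manifest=manifest,
    )
    if outdir is not None:
        write_report(bundle, outdir)
    return bundle


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.codividing_frequency.to_csv(
        out / "codividing_frequency.csv", index=False, float_format=FLOAT_FORMAT)
    bundle.cycle_summary.to_csv(
        out / "cycle_summary.csv", index=False, float_format=FLOAT_FORMAT)
    bundle.distance_vs_time.to_csv(
        out / "distance_vs_time.csv", index=False, float_format=FLOAT_FORMAT)
    if bundle.proliferation is not None:
        bundle.proliferation.to_csv(
            out / "proliferation.csv", index=False, float_format=FLOAT_FORMAT)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
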