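"""Study-style reporting: group tables, longitudinal deltas, correlations.

Works on a tidy cohort table (one row per animal; a ``group`` column such as
``wt_M3`` / ``mdx_M6`` plus numeric readout columns) and produces the
summaries a preclinical readout paper tabulates: per-group mean ± SEM, the
M6-vs-M3 percent change per genotype, the ANOVA + Bonferroni battery per
readout, and pairwise readout correlations with R².
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from diaus.config import RunConfig, write_csv_with_provenance
from diaus.physiology import percent_change, percent_change_per_animal
from diaus.stats import bonferroni_pairwise, pearson_fit

log = logging.getLogger(__name__)


def group_summary(cohort: pd.DataFrame, readouts: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean, SD, SEM and n for each readout column."""
    readouts = readouts or [
        c for c in cohort.columns
        if c not in ("animal_id", "group") and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    rows = []
    for label, sub in cohort.groupby("group", sort=False):
        for r in readouts:
            v = sub[r].to_numpy(dtype=float)
            rows.append({
                "group": label,
                "readout": r,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def longitudinal_deltas(
    cohort: pd.DataFrame,
    pairs: list[tuple[str, str]],
    readouts: list[str],
    mode: str = "means",
) -> pd.DataFrame:
    """Percent change between paired groups (e.g. M6 vs M3 per genotype).

    ``mode='means'`` compares group means; ``'per_animal'`` averages the
    per-animal percent changes (requires equal group sizes with animals in
    matching order).
    """
    rows = []
    for ref_label, new_label in pairs:
        ref = cohort[cohort["group"] == ref_label]
        new = cohort[cohort["group"] == new_label]
        if ref.empty or new.empty:
            raise ValueError(f"group pair ({ref_label}, {new_label}) not found")
        for r in readouts:
            if mode == "means":
                delta = percent_change(ref[r].mean(), new[r].mean())
            elif mode == "per_animal":
                delta = percent_change_per_animal(
                    ref[r].to_numpy(), new[r].to_numpy()
                )
            else:
                raise ValueError(f"unknown delta mode {mode!r}")
            rows.append({
                "reference": ref_label, "comparison": new_label,
                "readout": r, "delta_percent": delta,
            })
    return pd.DataFrame(rows)


def readout_statistics(
    cohort: pd.DataFrame, readouts: list[str], alpha: float = 0.05
) -> dict:
    """ANOVA + Bonferroni pairwise comparisons for each readout."""
    out = {}
    labels = list(cohort["group"].unique())
    for r in readouts:
        groups = [cohort.loc[cohort["group"] == g, r].to_numpy() for g in labels]
        comp = bonferroni_pairwise(groups, labels=labels, alpha=alpha)
        out[r] = {
            "F": comp.F,
            "df": [comp.df_between, comp.df_within],
            "p_anova": comp.p_anova,
            "pairwise": [
                {
                    "pair": list(c.pair),
                    "t": c.t,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in comp.pairwise
            ],
        }
    return out


def readout_correlations(
    cohort: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson fit for each requested (x, y) readout pair, pooled animals."""
    rows = []
    for x, y in pairs:
        fit = pearson_fit(cohort[x].to_numpy(), cohort[y].to_numpy())
        rows.append({
            "x": x, "y": y, "n": fit.n, "r": fit.r,
            "r_squared": fit.r_squared, "slope": fit.slope,
            "intercept": fit.intercept,
        })
    return pd.DataFrame(rows)


def correlation_plot(cohort: pd.DataFrame, x: str, y: str, path: Path) -> None:
    """Scatter of two readouts with the fitted line and R² annotation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = pearson_fit(cohort[x].to_numpy(), cohort[y].to_numpy())
    fig, ax = plt.subplots()
    for label, sub in cohort.groupby("group", sort=False):
        ax.scatter(sub[x], sub[y], label=label, alpha=0.8)
    xs = np.linspace(cohort[x].min(), cohort[x].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-",
            label=f"R² = {fit.r_squared:.2f}")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(
    cohort: pd.DataFrame,
    config: RunConfig,
    delta_pairs: list[tuple[str, str]] | None = None,
    correlation_pairs: list[tuple[str, str]] | None = None,
    make_plots: bool = True,
) -> dict:
    """End-to-end cohort report: tables, statistics, correlations, plots.

    Writes ``group_summary.csv``, ``deltas.csv``, ``correlations.csv`` and
    ``statistics.json`` (all stamped with the config hash and seed) into
    ``config.out_dir`` and returns the bundle as a dict.  Identical
    config + seed + input reproduce byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    readouts = [
        c for c in cohort.columns
        if c not in ("animal_id", "group") and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    summary = group_summary(cohort, readouts)
    write_csv_with_provenance(summary, out / "group_summary.csv", config)

    bundle: dict = {"group_summary": summary}
    if delta_pairs:
        deltas = longitudinal_deltas(cohort, delta_pairs, readouts,
                                     mode=config.delta_mode)
        write_csv_with_provenance(deltas, out / "deltas.csv", config)
        bundle["deltas"] = deltas

    stats_block = readout_statistics(cohort, readouts, alpha=config.alpha)
    (out / "statistics.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed,
             "readouts": stats_block},
            indent=2,
        ) + "\n"
    )
    bundle["statistics"] = stats_block

    if correlation_pairs:
        corr = readout_correlations(cohort, correlation_pairs)
        write_csv_with_provenance(corr, out / "correlations.csv", config)
        bundle["correlations"] = corr
        if make_plots:
            for x, y in correlation_pairs:
                correlation_plot(cohort, x, y, out / f"corr_{x}_vs_{y}.png")
    log.info("report written to %s", out)
    return bundle
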