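"""Ensemble summaries: mean pattern weights, evidence ratios, OFD histograms.

Per-SRS pattern probabilities are reduced per (extent, dispersal group) cell
to mean Akaike weights with percentile confidence intervals, evidence ratios
between pattern pairs, and the mean taxa number. OFD histograms bin each
taxon's relative occupancy into equal-width classes over (0, 1] and average
the per-class counts over the SRS ensemble.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .resampling import SRS

logger = logging.getLogger("streamofd")

PATTERNS = ("bimodal", "unimodal", "random")

#: Evidence-ratio pairs reported (numerator, denominator).
ER_PAIRS = (("bimodal", "unimodal"), ("unimodal", "bimodal"),
            ("random", "bimodal"), ("random", "unimodal"))


def records_frame(records: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Normalize an iterable of per-SRS record dicts into a DataFrame."""
    df = pd.DataFrame(list(records))
    required = {"srs_index", "extent", "group", "S",
                "w_bimodal", "w_unimodal", "w_random"}
    missing = required - set(df.columns)
    if len(df) and missing:
        raise ValueError(f"per-SRS records missing columns {sorted(missing)}")
    return df


def _evidence_ratio(num: float, den: float) -> float:
    if num == 0:
        return 0.0
    if den == 0:
        return float("inf")
    return num / den


def summarize(
    per_srs: pd.DataFrame,
    ci: float = 0.95,
    ci_method: str = "percentile",
) -> pd.DataFrame:
    """Mean weights, CIs, evidence ratios and mean taxa number per cell.

    The CI is the (2.5, 97.5) percentile interval across SRSs by default;
    ``ci_method='normal'`` uses mean +/- z * sd instead. Evidence ratios are
    computed from the unrounded mean weights.
    """
    if per_srs.empty:
        logger.warning("summarize: no per-SRS records")
        return pd.DataFrame()
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for (extent, group), cell in per_srs.groupby(["extent", "group"], sort=True):
        row: dict[str, object] = {"extent": extent, "group": group,
                                  "n_srs_used": len(cell)}
        means = {}
        for pat in PATTERNS:
            w = cell[f"w_{pat}"].to_numpy(dtype=float)
            means[pat] = w.mean()
            row[f"mean_w_{pat}"] = w.mean()
            if ci_method == "percentile":
                row[f"ci_low_{pat}"] = np.quantile(w, lo_q)
                row[f"ci_high_{pat}"] = np.quantile(w, hi_q)
            elif ci_method == "normal":
                from scipy.stats import norm

                z = norm.ppf(hi_q)
                half = z * w.std(ddof=1) / np.sqrt(len(w)) if len(w) > 1 else 0.0
                row[f"ci_low_{pat}"] = w.mean() - half
                row[f"ci_high_{pat}"] = w.mean() + half
            else:
                raise ValueError(f"unknown ci_method {ci_method!r}")
        for num, den in ER_PAIRS:
            row[f"er_{num[:2]}_{den[:2]}"] = _evidence_ratio(means[num], means[den])
        row["mean_taxa_number"] = cell["S"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def ofd_histogram(
    srss: Iterable[SRS],
    groups: Mapping[str, str] | None = None,
    n_classes: int = 5,
) -> pd.DataFrame:
    """Mean number of taxa per occupancy class across SRSs, per group.

    Classes are left-open right-closed equal-width intervals over (0, 1]:
    (0, .2], (.2, .4], ... with the default 5 classes, so a taxon occupying
    every ARS falls in the top class and per-SRS class counts sum to S.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 occupancy classes")
    from .rsoc import occupancies

    edges = np.linspace(0, 1, n_classes + 1)
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    extent = None
    for srs in srss:
        extent = srs.extent
        cells: dict[str, set[str] | None]
        if groups:
            cells = {g: {t for t, lab in groups.items() if lab == g}
                     for g in sorted(set(groups.values()))}
        else:
            cells = {"all": None}
        for gname, subset in cells.items():
            rsoc = occupancies(srs, subset, group=gname)
            if rsoc is None:
                continue
            # right-closed bins over (0, 1]; O > 0 by construction
            idx = np.digitize(rsoc.occupancy, edges[1:-1], right=True)
            binned = np.bincount(idx, minlength=n_classes).astype(float)
            sums[gname] = sums.get(gname, np.zeros(n_classes)) + binned
            counts[gname] = counts.get(gname, 0) + 1
    rows = []
    for gname in sorted(sums):
        mean_counts = sums[gname] / counts[gname]
        for c in range(n_classes):
            rows.append({
                "extent": extent, "group": gname,
                "class_low": edges[c], "class_high": edges[c + 1],
                "mean_taxa": mean_counts[c],
            })
    return pd.DataFrame(rows)


def plot_weights_by_extent(summary: pd.DataFrame, path: str) -> None:
    """Mean pattern weights against extent, one panel per group, CI bars.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    extents = [e for e in ("reach", "subbasin", "basin", "region")
               if e in set(summary["extent"])]
    groups = sorted(set(summary["group"]))
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                             sharey=True, squeeze=False)
    x = np.arange(len(extents))
    for ax, g in zip(axes[0], groups):
        cell = summary[summary["group"] == g].set_index("extent").loc[extents]
        for pat, marker in zip(PATTERNS, "osd"):
            y = cell[f"mean_w_{pat}"].to_numpy()
            lo = y - cell[f"ci_low_{pat}"].to_numpy()
            hi = cell[f"ci_high_{pat}"].to_numpy() - y
            ax.errorbar(x, y, yerr=[lo, hi], marker=marker, capsize=3,
                        label=pat)
        ax.set_xticks(x, extents, rotation=30)
        ax.set_title(g)
        ax.set_ylim(-0.05, 1.05)
    axes[0][0].set_ylabel("mean Akaike weight")
    axes[0][-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
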