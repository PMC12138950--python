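"""RT-qPCR fold changes (2^-ddCt) and ChIP-qPCR percent-input quantification.

RT-qPCR: per cell line, dCt = Ct_target - mean(Ct_references); relative to a
calibrator line, ddCt = dCt_line - dCt_calibrator and fold = 2^-ddCt, so the
calibrator's fold is exactly 1.

ChIP-qPCR: with an input fraction f (default 4%) set aside before
immunoprecipitation, enrichment at a site is

    % input = 100 * 2^((Ct_input - log2(1/f)) - Ct_IP),

the IgG control's % input is subtracted per cell line and site (negative
nets are kept but flagged), and cell lines are compared per site with a
Kruskal-Wallis test followed, when significant, by exact pairwise
Mann-Whitney U tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from metaregnet.enrich import bh_adjust


class QpcrError(ValueError):
    pass


@dataclass
class CtTable:
    """Long-format Ct measurements.

    RT rows: columns (cell_line, gene, replicate, ct).
    ChIP rows: columns (cell_line, site, antibody, replicate, ct) plus input
    rows flagged by antibody == "input"; ``input_fraction`` is f.
    """

    data: pd.DataFrame
    assay: str  # "RT" or "ChIP"
    input_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.assay not in ("RT", "ChIP"):
            raise QpcrError("assay must be 'RT' or 'ChIP'")
        if (self.data["ct"] <= 0).any():
            raise QpcrError("Ct values must be positive")
        if not (0 < self.input_fraction < 1):
            raise QpcrError("input fraction must lie in (0, 1)")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def ddct_fold_change(ct: CtTable, target: str, references: list[str],
                     calibrator: str) -> pd.Series:
    """2^-ddCt fold change of the target per cell line relative to the calibrator.

    Reference Cts are aggregated by their arithmetic mean (equivalently the
    geometric mean of the linear quantities).  Replicate Cts are averaged
    per gene before the delta.
    """
    if ct.assay != "RT":
        raise QpcrError("ddct_fold_change requires an RT table")
    mean_ct = ct.data.groupby(["cell_line", "gene"])["ct"].mean()
    lines = sorted(ct.data["cell_line"].unique())
    if calibrator not in lines:
        raise QpcrError(f"calibrator {calibrator!r} not measured")
    dct = {}
    for line in lines:
        try:
            t = mean_ct.loc[(line, target)]
            refs = [mean_ct.loc[(line, g)] for g in references]
        except KeyError as exc:
            raise QpcrError(f"missing measurement for line {line!r}: {exc}") from exc
        dct[line] = t - float(np.mean(refs))
    folds = {line: 2.0 ** (-(d - dct[calibrator])) for line, d in dct.items()}
    return pd.Series(folds, name="fold").sort_index()


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.04) -> float:
    """ChIP enrichment as % of dilution-adjusted input chromatin."""
    if not (0 < input_fraction < 1):
        raise QpcrError("input fraction must lie in (0, 1)")
    adjusted_input = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted_input - ct_ip))


def chip_percent_input(ct: CtTable) -> pd.DataFrame:
    """Replicate-level % input per (cell line, site, antibody).

    Input Cts (antibody == 'input') are averaged per line and site; each IP
    replicate is normalized against that mean input Ct.
    """
    if ct.assay != "ChIP":
        raise QpcrError("chip_percent_input requires a ChIP table")
    d = ct.data
    inputs = (
        d[d["antibody"] == "input"].groupby(["cell_line", "site"])["ct"].mean()
    )
    rows = []
    for r in d[d["antibody"] != "input"].itertuples():
        key = (r.cell_line, r.site)
        if key not in inputs.index:
            raise QpcrError(f"no input measurement for {key}")
        rows.append(
            {
                "cell_line": r.cell_line,
                "site": r.site,
                "antibody": r.antibody,
                "replicate": r.replicate,
                "percent_input": percent_input(r.ct, inputs.loc[key], ct.input_fraction),
            }
        )
    return pd.DataFrame(rows)


def subtract_igg(percent_table: pd.DataFrame, igg_antibody: str = "IgG") -> pd.DataFrame:
    """Subtract the matched IgG % input per cell line and site.

    The IgG mean over replicates is the baseline; negative net values are
    retained with ``negative=True`` so downstream rank tests stay unbiased.
    """
    igg = (
        percent_table[percent_table["antibody"] == igg_antibody]
        .groupby(["cell_line", "site"])["percent_input"]
        .mean()
    )
    spec = percent_table[percent_table["antibody"] != igg_antibody].copy()
    nets, flags = [], []
    for r in spec.itertuples():
        key = (r.cell_line, r.site)
        if key not in igg.index:
            raise QpcrError(f"missing IgG control for {key}")
        net = r.percent_input - igg.loc[key]
        nets.append(net)
        flags.append(net < 0)
    spec["net_percent"] = nets
    spec["negative"] = flags
    return spec.reset_index(drop=True)


@dataclass
class ChipComparison:
    site: str
    kruskal_H: float
    kruskal_p: float
    pairwise: pd.DataFrame | None  # columns: line_a, line_b, U, p, adj_p


def compare_cell_lines(net_table: pd.DataFrame, site: str,
                       alpha: float = 0.05) -> ChipComparison:
    """Kruskal-Wallis across cell lines at one site; exact pairwise MWU if significant.

    The Mann-Whitney test is exact for group sizes <= 8 and uses the
    normal approximation with tie correction above.  Three identical groups
    yield H = 0 and p = 1 (every rank assignment is equivalent).
    """
    sub = net_table[net_table["site"] == site]
    groups = {line: g["net_percent"].to_numpy() for line, g in sub.groupby("cell_line")}
    if len(groups) < 2:
        raise QpcrError("need at least two cell lines to compare")
    if any(len(v) < 2 for v in groups.values()):
        raise QpcrError("need at least two replicates per cell line")
    arrays = [groups[k] for k in sorted(groups)]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = stats.kruskal(*arrays)
    pairwise = None
    if p_kw <= alpha:
        rows = []
        for a, b in combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            method = "exact" if max(len(xa), len(xb)) <= 8 else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            rows.append({"line_a": a, "line_b": b, "U": float(res.statistic), "p": float(res.pvalue)})
        pairwise = pd.DataFrame(rows)
        pairwise["adj_p"] = bh_adjust(pairwise["p"].to_numpy())
    return ChipComparison(site, float(H), float(p_kw), pairwise)


def site_fold_ratio(percent_a: float, percent_b: float) -> float:
    """Enrichment ratio between two % input values, rounded to one decimal."""
    if percent_b <= 0:
        raise QpcrError("denominator % input must be positive")
    return round(percent_a / percent_b, 1)


def chip_summary(net_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of net % input per cell line and site."""
    g = net_table.groupby(["site", "cell_line"])["net_percent"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "net_mean", "std": "net_sd", "count": "n"})
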