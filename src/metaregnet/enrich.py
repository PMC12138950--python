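"""Over-representation analysis of regulons against gene-set collections.

A regulon (the inferred target set of one TF) is tested against each curated
gene set with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the gene-set size inside the universe, n the
regulon size and k the overlap.  p-values are Benjamini-Hochberg adjusted
across the collection.  The universe defaults to the harmonized cross-cohort
gene space, not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise EnrichError(f"empty gene set {name!r}")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then genes, tab-separated.

    Duplicate genes within a set are counted once; a line with fewer than
    three fields is rejected with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichError(f"line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


@dataclass
class OraResult:
    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p: float
    adj_p: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise EnrichError("overlap exceeds set or query size")
        if not (0 <= self.p <= 1):
            raise EnrichError("p outside [0, 1]")


def ora_test(query, gene_set, universe, set_name: str = "") -> OraResult:
    """Hypergeometric upper-tail enrichment of a query list in one gene set.

    The gene set is intersected with the universe before testing; the query
    must be a subset of the universe.
    """
    universe_s = set(universe)
    query_s = set(query)
    stray = sorted(query_s - universe_s)
    if stray:
        raise EnrichError(f"query genes outside the universe: {stray[:10]}")
    set_s = set(gene_set) & universe_s
    N, K, n = len(universe_s), len(set_s), len(query_s)
    k = len(query_s & set_s)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    return OraResult(set_name, N, K, n, k, min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise EnrichError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_collection(query, collection: GeneSetCollection, universe,
                   adj_p_cutoff: float | None = None) -> pd.DataFrame:
    """Test a query against every set in a collection; BH-adjust; sort by adj_p."""
    results = [
        ora_test(query, genes, universe, set_name=name)
        for name, genes in collection.sets.items()
    ]
    adj = bh_adjust([r.p for r in results])
    rows = []
    for r, a in zip(results, adj):
        r.adj_p = float(a)
        rows.append(
            {
                "set": r.set_name,
                "N": r.universe_size,
                "K": r.set_size,
                "n": r.query_size,
                "k": r.overlap,
                "p": r.p,
                "adj_p": r.adj_p,
            }
        )
    df = pd.DataFrame(rows).sort_values(["adj_p", "p", "set"]).reset_index(drop=True)
    if adj_p_cutoff is not None:
        df = df[df["adj_p"] <= adj_p_cutoff].reset_index(drop=True)
    return df


def enrichment_summary(per_regulon: dict[str, pd.DataFrame],
                       adj_p_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-pathway count of regulons enriched (adj p <= cutoff), best p first."""
    rows: dict[str, dict] = {}
    for tf, table in per_regulon.items():
        hit = table[table["adj_p"] <= adj_p_cutoff]
        for r in hit.itertuples():
            entry = rows.setdefault(r.set, {"set": r.set, "n_regulons": 0,
                                            "best_adj_p": 1.0, "regulons": []})
            entry["n_regulons"] += 1
            entry["regulons"].append(tf)
            entry["best_adj_p"] = min(entry["best_adj_p"], float(r.adj_p))
    out = pd.DataFrame(rows.values(),
                       columns=["set", "n_regulons", "best_adj_p", "regulons"])
    return out.sort_values(["best_adj_p", "set"]).reset_index(drop=True)
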