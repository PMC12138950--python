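"""ARACne-style signed regulatory-network inference.

Edges between transcription factors (TFs) and candidate targets are weighted
by plug-in mutual information (MI, in bits) on rank-based equal-frequency
binnings of the two expression profiles.  Significance is assessed against
an empirical permutation null pooled across targets (and, by default,
across TFs too — see :func:`permutation_adjusted_p`), with
Benjamini-Hochberg adjustment over all TF-target pairs.  Retained candidate
edges must then
survive a bootstrap robustness screen (the edge's MI must exceed the
resample's own significance floor in a consensus fraction of resamples), DPI
pruning of indirect triangles, and finally receive a sign from the Pearson
correlation of the two profiles.

The MI estimator is deliberately parameter-light: B = floor(sqrt(n))
equal-frequency bins, plug-in entropies.  Rank binning makes the estimator
invariant to strictly monotone transforms of either profile and exactly
symmetric in its arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class TrnError(ValueError):
    pass


@dataclass
class TrnParams:
    """Inference thresholds.

    ``n_perm`` permutations feed the pooled null; pairs with BH-adjusted
    empirical p below ``adj_p_cutoff`` become candidates; candidates need
    bootstrap support >= ``boot_consensus`` over ``n_boot`` resamples;
    ``dpi_tolerance`` softens the DPI triangle rule; ``mi_bins`` is an
    integer or ``"auto"`` (= floor(sqrt(n))).
    """

    n_perm: int = 1000
    adj_p_cutoff: float = 3.28e-7
    n_boot: int = 1000
    boot_consensus: float = 0.95
    dpi_tolerance: float = 0.0
    mi_bins: int | str = "auto"
    n_perm_boot: int = 30
    boot_floor_alpha: float = 1e-3
    pool_across_tfs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.boot_consensus <= 1):
            raise TrnError("boot_consensus must lie in (0, 1]")
        if self.dpi_tolerance < 0:
            raise TrnError("dpi_tolerance must be >= 0")
        if self.mi_bins != "auto" and int(self.mi_bins) < 2:
            raise TrnError("mi_bins must be >= 2")

    def bins_for(self, n: int) -> int:
        return int(np.sqrt(n)) if self.mi_bins == "auto" else int(self.mi_bins)


@dataclass
class Network:
    """Edge list plus the gene space and provenance it was inferred on."""

    edges: pd.DataFrame  # columns: tf, target, mi, sign, adj_p, support
    tf_list: tuple[str, ...]
    gene_space: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.tf_list) - set(self.gene_space)
        if missing:
            raise TrnError(f"TFs outside the gene space: {sorted(missing)}")
        if self.edges.duplicated(subset=["tf", "target"]).any():
            raise TrnError("duplicate (tf, target) pairs")

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)
        Path(str(path) + ".json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str)
        )

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for row in self.edges.itertuples():
            attrs = {
                k: getattr(row, k)
                for k in self.edges.columns
                if k not in ("tf", "target")
            }
            g.add_edge(row.tf, row.target, **{k: float(v) if v is not None else 0.0
                                              for k, v in attrs.items()})
        nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# binning and MI internals

def _as_frame(matrix) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a bare genes x samples DataFrame."""
    if isinstance(matrix, pd.DataFrame):
        return matrix
    v = getattr(matrix, "values", None)
    if isinstance(v, pd.DataFrame):
        return v
    raise TrnError("matrix must be an ExpressionMatrix or DataFrame")



def rank_bins(x: np.ndarray, B: int) -> np.ndarray:
    """Equal-frequency bin labels 0..B-1 by rank (stable tie-break by index)."""
    n = x.shape[-1]
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    idx = np.arange(n)
    if x.ndim == 1:
        ranks[order] = idx
    else:
        np.put_along_axis(ranks, order, np.broadcast_to(idx, ranks.shape), axis=-1)
    return (ranks * B) // n


def _plogp_table(n: int) -> np.ndarray:
    """c * log2(c) for c = 0..n (0 log 0 := 0)."""
    c = np.arange(n + 1, dtype=float)
    t = np.zeros(n + 1)
    t[1:] = c[1:] * np.log2(c[1:])
    return t


def _mi_vector(tbin: np.ndarray, dbin: np.ndarray, B: int, plogp: np.ndarray,
               ls: np.ndarray | None = None) -> np.ndarray:
    """MI in bits between one binned profile and each row of a binned matrix.

    ``ls`` optionally caches sum_b s_b log2 s_b of the rows' bin marginals.
    """
    n = tbin.shape[0]
    G = dbin.shape[0]
    joint = dbin + (B * B) * np.arange(G)[:, None] + B * tbin[None, :]
    counts = np.bincount(joint.ravel(), minlength=G * B * B).reshape(G, B * B)
    lc = plogp[counts].sum(axis=1)
    rt = np.bincount(tbin, minlength=B)
    lr = plogp[rt].sum()
    if ls is None:
        ls = _marginal_plogp(dbin, B, plogp)
    return (lc + n * np.log2(n) - lr - ls) / n


def _marginal_plogp(dbin: np.ndarray, B: int, plogp: np.ndarray) -> np.ndarray:
    G = dbin.shape[0]
    m = np.bincount((dbin + B * np.arange(G)[:, None]).ravel(), minlength=G * B).reshape(G, B)
    return plogp[m].sum(axis=1)


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in MI in bits on equal-frequency binnings of ``x`` and ``y``.

    Symmetric, invariant to strictly monotone transforms, and exactly
    log2(B) for identical rank vectors of length divisible by B.  A constant
    input yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TrnError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise TrnError("need at least 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = bins if bins is not None else int(np.sqrt(n))
    if B < 2:
        raise TrnError("need at least 2 bins")
    plogp = _plogp_table(n)
    return float(_mi_vector(rank_bins(x, B), rank_bins(y, B)[None, :], B, plogp)[0])


# ---------------------------------------------------------------------------
# inference stages

def permutation_adjusted_p(matrix, tf_list, params: TrnParams, targets=None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Observed MI and pooled-null BH-adjusted p for every TF-target pair.

    For each TF the null is built from ``n_perm`` permutations of the TF
    profile, each scored against *all* targets, and the empirical p for a
    pair is (1 + #null >= observed) / (1 + pool size).  Because every
    rank-binned profile carries the identical marginal bin multiset, the
    permutation null is exactly exchangeable across TFs; by default
    (``pool_across_tfs``) the nulls of all TFs are therefore pooled into one
    reference distribution of size n_perm * n_targets * n_tfs, which buys
    the empirical resolution that sub-1e-3 adjusted cutoffs need at desk
    scale.  Set ``pool_across_tfs=False`` for strictly per-TF pools of size
    n_perm * n_targets.  BH adjustment runs across the full TF x target
    family.  Returns a DataFrame (tf, target, mi, p, adj_p).
    """
    if params.n_perm < 10:
        raise TrnError("n_perm must be >= 10")
    values = _as_frame(matrix)
    genes = list(values.index)
    arr = values.to_numpy(dtype=float)
    if not tf_list:
        raise TrnError("empty TF list")
    missing = set(tf_list) - set(genes)
    if missing:
        raise TrnError(f"TFs absent from matrix: {sorted(missing)}")
    rng = rng or np.random.default_rng(params.seed)
    n = arr.shape[1]
    B = params.bins_for(n)
    plogp = _plogp_table(n)
    gene_idx = {g: i for i, g in enumerate(genes)}
    binned = rank_bins(arr, B)

    rows = []
    nulls = []
    for tf in tf_list:
        tgt = [g for g in (targets if targets is not None else genes) if g != tf]
        tbin = binned[gene_idx[tf]]
        dbin = binned[[gene_idx[g] for g in tgt]]
        ls = _marginal_plogp(dbin, B, plogp)
        obs = _mi_vector(tbin, dbin, B, plogp, ls)
        null = np.empty(params.n_perm * len(tgt))
        for p in range(params.n_perm):
            perm = rng.permutation(tbin)
            null[p * len(tgt):(p + 1) * len(tgt)] = _mi_vector(perm, dbin, B, plogp, ls)
        if params.pool_across_tfs:
            nulls.append(null)
            rows.append(pd.DataFrame({"tf": tf, "target": tgt, "mi": obs}))
        else:
            null.sort()
            n_ge = len(null) - np.searchsorted(null, obs, side="left")
            pvals = (1.0 + n_ge) / (1.0 + len(null))
            rows.append(pd.DataFrame({"tf": tf, "target": tgt, "mi": obs, "p": pvals}))
    out = pd.concat(rows, ignore_index=True)
    if params.pool_across_tfs:
        pooled = np.concatenate(nulls)
        pooled.sort()
        n_ge = len(pooled) - np.searchsorted(pooled, out["mi"].to_numpy(), side="left")
        out["p"] = (1.0 + n_ge) / (1.0 + len(pooled))
    out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def bootstrap_support(matrix, candidates: pd.DataFrame, params: TrnParams,
                      rng: np.random.Generator | None = None) -> pd.Series:
    """Fraction of bootstrap resamples in which each candidate edge stays significant.

    In each resample (samples drawn with replacement) all involved profiles
    are re-binned, each TF's candidate MIs are recomputed, and the resample's
    significance floor is the (1 - boot_floor_alpha) quantile of a pooled
    permutation null recomputed on that resample (``n_perm_boot`` permutations
    of the TF profile against its candidate targets).  Support is the fraction
    of resamples where the edge's MI strictly exceeds the floor.

    The null permutes the *original* TF profile and then applies the same
    bootstrap column indices: duplicated samples inflate plug-in MI even
    between independent profiles, so a valid null must preserve the
    resample's duplication structure.
    """
    values = _as_frame(matrix)
    arr = values.to_numpy(dtype=float)
    genes = list(values.index)
    n = arr.shape[1]
    if n < 10:
        raise TrnError("bootstrap requires at least 10 samples")
    rng = rng or np.random.default_rng(params.seed + 1)
    B = params.bins_for(n)
    plogp = _plogp_table(n)
    gene_idx = {g: i for i, g in enumerate(genes)}

    by_tf = {
        tf: sub["target"].tolist() for tf, sub in candidates.groupby("tf", sort=True)
    }
    involved = sorted({g for tf, ts in by_tf.items() for g in [tf, *ts]})
    inv_idx = {g: i for i, g in enumerate(involved)}
    sub_arr = arr[[gene_idx[g] for g in involved]]

    hits = {(r.tf, r.target): 0 for r in candidates.itertuples()}
    q = 1.0 - params.boot_floor_alpha
    for _ in range(params.n_boot):
        cols = rng.integers(0, n, size=n)
        binned = rank_bins(sub_arr[:, cols], B)
        for tf, tgt in by_tf.items():
            tbin = binned[inv_idx[tf]]
            dbin = binned[[inv_idx[g] for g in tgt]]
            ls = _marginal_plogp(dbin, B, plogp)
            mi = _mi_vector(tbin, dbin, B, plogp, ls)
            orig = sub_arr[inv_idx[tf]]
            perms = np.stack([
                rng.permutation(orig)[cols] for _ in range(params.n_perm_boot)
            ])
            pbins = rank_bins(perms, B)
            null = np.concatenate([
                _mi_vector(pbins[i], dbin, B, plogp, ls)
                for i in range(params.n_perm_boot)
            ])
            floor = np.quantile(null, q)
            for g, m in zip(tgt, mi):
                if m > floor:
                    hits[(tf, g)] += 1
    return pd.Series(
        {k: v / params.n_boot for k, v in hits.items()}, name="support"
    ).rename_axis(["tf", "target"])


def apply_dpi(edges: pd.DataFrame, tolerance: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality pruning of indirect triangles.

    For every connected triplet in the undirected MI graph, the strictly
    weakest edge is marked for removal when its MI < min(other two) -
    tolerance; all removals are decided on the input graph and applied
    simultaneously.  Exactly tied minima are kept (strict inequality), and a
    second application removes nothing (idempotent).
    """
    w: dict[frozenset, float] = {}
    adj: dict[str, set[str]] = {}
    for r in edges.itertuples():
        key = frozenset((r.tf, r.target))
        w[key] = max(w.get(key, -np.inf), float(r.mi))
        adj.setdefault(r.tf, set()).add(r.target)
        adj.setdefault(r.target, set()).add(r.tf)
    doomed: set[frozenset] = set()
    for a in sorted(adj):
        for b in sorted(adj[a]):
            if b <= a:
                continue
            for c in sorted(adj[a] & adj[b]):
                if c <= b:
                    continue
                trio = [
                    (w[frozenset((a, b))], frozenset((a, b))),
                    (w[frozenset((a, c))], frozenset((a, c))),
                    (w[frozenset((b, c))], frozenset((b, c))),
                ]
                trio.sort(key=lambda t: t[0])
                if trio[0][0] < trio[1][0] - tolerance:
                    doomed.add(trio[0][1])
    keep = [
        frozenset((r.tf, r.target)) not in doomed for r in edges.itertuples()
    ]
    return edges.loc[keep].reset_index(drop=True)


def assign_edge_sign(matrix, tf: str, target: str) -> int:
    """Sign of the Pearson correlation between the two profiles (0 = unsigned)."""
    values = _as_frame(matrix)
    x = values.loc[tf].to_numpy(dtype=float)
    y = values.loc[target].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0
    r = stats.pearsonr(x, y).statistic
    return int(np.sign(r))


def infer_network(matrix, tf_list, params: TrnParams | None = None,
                  provenance: dict | None = None) -> Network:
    """Full inference: MI -> pooled permutation filter -> bootstrap -> DPI -> sign."""
    params = params or TrnParams()
    values = _as_frame(matrix)
    genes = tuple(values.index)
    if not tf_list:
        raise TrnError("empty TF list")
    rng = np.random.default_rng(params.seed)

    pairs = permutation_adjusted_p(matrix, tf_list, params, rng=rng)
    cand = pairs[pairs["adj_p"] < params.adj_p_cutoff].reset_index(drop=True)
    if len(cand):
        support = bootstrap_support(matrix, cand, params, rng=rng)
        cand = cand.assign(
            support=support.loc[list(zip(cand["tf"], cand["target"]))].to_numpy()
        )
        cand = cand[cand["support"] >= params.boot_consensus].reset_index(drop=True)
    else:
        cand = cand.assign(support=pd.Series(dtype=float))
    cand = apply_dpi(cand, params.dpi_tolerance)
    signs = [assign_edge_sign(matrix, r.tf, r.target) for r in cand.itertuples()]
    edges = cand.assign(sign=signs)[["tf", "target", "mi", "sign", "adj_p", "support"]]
    prov = dict(provenance or {})
    prov["params"] = asdict(params)
    return Network(edges, tuple(tf_list), genes, prov)
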