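"""Consensus network construction and topology summaries.

Subtype x cohort networks are intersected into a consensus that keeps only
edges present in every input network (by default with the same sign
everywhere); the consensus edge weight is the arithmetic mean of the source
MI values.  Per-TF regulons are classified by target counts (reliable: more
than 15 targets; balanced: at least 15 positive and 15 negative targets), and
degree distributions are checked for power-law adequacy with a Clauset-style
discrete maximum-likelihood fit and a semiparametric bootstrap KS test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from metaregnet.trn import Network


class ConsensusError(ValueError):
    pass


def intersect_networks(networks: list[Network], require_sign_agreement: bool = True) -> Network:
    """Edges present in every network (and sign-consistent), MI averaged.

    Commutative, associative and idempotent in edge sets; intersecting k
    copies of one network returns it with the same MI values.
    """
    if len(networks) < 2:
        raise ConsensusError("need at least two networks")
    space = set(networks[0].gene_space)
    for net in networks[1:]:
        if set(net.gene_space) != space:
            raise ConsensusError("networks were inferred on different gene spaces")
    keyed = []
    for net in networks:
        e = net.edges.set_index(["tf", "target"])
        if e.index.duplicated().any():
            raise ConsensusError("duplicate edges within a source network")
        keyed.append(e)
    common = keyed[0].index
    for e in keyed[1:]:
        common = common.intersection(e.index)
    rows = []
    for tf, target in common:
        mis = [e.loc[(tf, target), "mi"] for e in keyed]
        signs = {int(e.loc[(tf, target), "sign"]) for e in keyed}
        if require_sign_agreement and (len(signs) > 1 or signs == {0}):
            continue
        rows.append(
            {
                "tf": tf,
                "target": target,
                "mean_mi": float(np.mean(mis)),
                "sign": signs.pop() if len(signs) == 1 else 0,
                "n_sources": len(networks),
            }
        )
    edges = pd.DataFrame(rows, columns=["tf", "target", "mean_mi", "sign", "n_sources"])
    edges = edges.sort_values(["tf", "target"]).reset_index(drop=True)
    tf_list = tuple(sorted(set(networks[0].tf_list)))
    prov = {"n_sources": len(networks), "sources": [n.provenance for n in networks]}
    out_edges = edges.rename(columns={"mean_mi": "mi"})
    net = Network(out_edges, tf_list, networks[0].gene_space, prov)
    net.edges = edges  # keep the consensus column name mean_mi
    return net


@dataclass
class RegulonSummary:
    tf: str
    n_targets: int
    n_positive: int
    n_negative: int
    reliable: bool  # more than 15 targets
    balanced: bool  # at least 15 positive AND at least 15 negative


def regulon_summary(consensus: Network) -> pd.DataFrame:
    """Per-TF target counts and the reliable / balanced class flags."""
    rows = []
    for tf, sub in consensus.edges.groupby("tf", sort=True):
        pos = int((sub["sign"] > 0).sum())
        neg = int((sub["sign"] < 0).sum())
        n = len(sub)
        rows.append(
            {
                "tf": tf,
                "n_targets": n,
                "n_positive": pos,
                "n_negative": neg,
                "reliable": n > 15,
                "balanced": pos >= 15 and neg >= 15,
            }
        )
    return pd.DataFrame(rows, columns=["tf", "n_targets", "n_positive", "n_negative", "reliable", "balanced"])


def degree_profile(consensus: Network) -> dict:
    """Out-degree (per TF with >= 1 target) and in-degree (per regulated target) summaries."""
    if not len(consensus.edges):
        raise ConsensusError("empty network")
    out_deg = consensus.edges.groupby("tf").size().to_numpy()
    in_deg = consensus.edges.groupby("target").size().to_numpy()

    def _summ(deg):
        hist = np.bincount(deg)
        return {
            "median": float(np.median(deg)),
            "max": int(deg.max()),
            "histogram": {int(k): int(v) for k, v in enumerate(hist) if v},
        }

    return {"out_degree": _summ(out_deg), "in_degree": _summ(in_deg)}


@dataclass
class PowerLawFit:
    alpha: float
    x_min: int
    ks_D: float
    p: float | None

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ConsensusError("power-law exponent must exceed 1")


def _zeta_loglik(alpha: float, x: np.ndarray, x_min: int) -> float:
    return -alpha * np.log(x).sum() - len(x) * np.log(
        special.zeta(alpha, x_min)
    )


def _fit_alpha(x: np.ndarray, x_min: int) -> float:
    res = optimize.minimize_scalar(
        lambda a: -_zeta_loglik(a, x, x_min), bounds=(1.01, 8.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ks_discrete(x: np.ndarray, alpha: float, x_min: int) -> float:
    """KS distance between the empirical tail CDF and the zeta model CDF.

    Evaluated at the observed support points only, with the model CDF in
    closed form, CDF(v) = 1 - zeta(alpha, v+1)/zeta(alpha, x_min), so heavy
    bootstrap tails stay cheap.
    """
    xs, counts = np.unique(x, return_counts=True)
    ecdf = np.cumsum(counts) / len(x)
    z0 = special.zeta(alpha, x_min)
    cdf = 1.0 - special.zeta(alpha, xs + 1.0) / z0
    return float(np.abs(ecdf - cdf).max())


def _sample_zeta(rng: np.random.Generator, alpha: float, x_min: int, size: int) -> np.ndarray:
    """Approximate discrete power-law sampler (continuous inversion, rounded)."""
    u = rng.random(size)
    vals = np.floor((x_min - 0.5) * (1 - u) ** (-1.0 / (alpha - 1.0)) + 0.5)
    return np.minimum(vals, 2**31).astype(np.int64)


def powerlaw_fit_ks(degrees, n_boot: int = 500, x_min: int | None = None,
                    seed: int = 0) -> PowerLawFit:
    """Discrete power-law fit with KS x_min selection and bootstrap adequacy p.

    The exponent is fitted by maximizing the zeta likelihood on the tail
    x >= x_min; x_min (unless fixed) is chosen to minimize the KS distance.
    The adequacy p-value is a semiparametric bootstrap: replicates draw the
    tail from the fitted model and the body from the observed sub-x_min
    values, refit x_min and alpha, and p is the fraction of replicate KS
    distances at least as large as the observed one.  Set ``n_boot=0`` to
    skip the bootstrap (p is then None).
    """
    x = np.asarray(degrees, dtype=int)
    if len(x) < 50:
        raise ConsensusError("need at least 50 degree values")
    if np.ptp(x) == 0:
        raise ConsensusError("all degree values are equal")
    if (x < 1).any():
        raise ConsensusError("degrees must be >= 1")

    def _fit(xv, fixed_xmin):
        if fixed_xmin is not None:
            candidates = [int(fixed_xmin)]
        else:
            uniq = np.unique(xv)
            cand = uniq[:-1] if len(uniq) > 1 else uniq
            if len(cand) > 20:  # cap the x_min scan for tractable bootstraps
                cand = cand[np.linspace(0, len(cand) - 1, 20).astype(int)]
            candidates = [int(u) for u in cand]
        best = None
        for xm in candidates:
            tail = xv[xv >= xm]
            if len(tail) < 10 or np.ptp(tail) == 0:
                continue
            a = _fit_alpha(tail, xm)
            d = _ks_discrete(tail, a, xm)
            if best is None or d < best[2]:
                best = (a, xm, d)
        if best is None:  # degenerate tails everywhere: fit the full sample
            a = _fit_alpha(xv, int(xv.min()))
            best = (a, int(xv.min()), _ks_discrete(xv, a, int(xv.min())))
        return best

    alpha, xm, d_obs = _fit(x, x_min)
    p = None
    if n_boot:
        rng = np.random.default_rng(seed)
        body = x[x < xm]
        n_tail = int((x >= xm).sum())
        exceed = 0
        for _ in range(n_boot):
            take_tail = rng.binomial(len(x), n_tail / len(x))
            rep = np.concatenate(
                [
                    _sample_zeta(rng, alpha, xm, take_tail),
                    rng.choice(body, size=len(x) - take_tail, replace=True)
                    if len(body)
                    else _sample_zeta(rng, alpha, xm, len(x) - take_tail),
                ]
            )
            _, _, d_rep = _fit(rep, x_min)
            if d_rep >= d_obs:
                exceed += 1
        p = exceed / n_boot
    return PowerLawFit(alpha, xm, d_obs, p)
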