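"""PWM scanning of promoter / first-intron regions with canonical-site filtering.

JASPAR-format position frequency matrices are parsed (via Biopython),
converted to log-odds with a pseudocount distributed by the background
composition, and slid over both strands of a region.  A window's score S is
rescaled to a relative score

    rel = (S - S_min) / (S_max - S_min)  in [0, 1],

where S_min/S_max are the per-column worst/best attainable scores; hits are
windows with rel >= threshold (default 0.85).  Hits can then be filtered to
canonical sites: the forward-strand matched string must equal the motif's
literature consensus (forward or reverse-complement form); motifs without an
established consensus pass through on score alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MotifError(ValueError):
    pass


@dataclass
class Pwm:
    """Position weight matrix with counts, probabilities and log-odds scores."""

    name: str
    counts: np.ndarray  # shape (4, L), rows ordered A, C, G, T
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    probs: np.ndarray = field(init=False)
    log_odds: np.ndarray = field(init=False)
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 2:
            raise MotifError(f"{self.name}: need a 4 x L matrix with L >= 2")
        if (self.counts < 0).any():
            raise MotifError(f"{self.name}: negative counts")
        bg = np.asarray(self.background, dtype=float)[:, None]
        pseudo = self.pseudocount * bg  # pseudocount split by background
        col_tot = self.counts.sum(axis=0, keepdims=True) + self.pseudocount
        self.probs = (self.counts + pseudo) / col_tot
        self.log_odds = np.log2(self.probs / bg)
        self.s_min = float(self.log_odds.min(axis=0).sum())
        self.s_max = float(self.log_odds.max(axis=0).sum())
        if not self.s_min < self.s_max:
            raise MotifError(f"{self.name}: degenerate matrix (S_min == S_max)")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.counts[::-1, ::-1], self.pseudocount, self.background)


@dataclass
class RegionSpec:
    """A scanned regulatory region: the promoter (TSS-relative) or first intron."""

    gene: str
    region: str  # "promoter" or "intron1"
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MotifError(f"illegal characters in sequence: {sorted(bad)}")
        if self.region not in ("promoter", "intron1"):
            raise MotifError(f"unknown region kind {self.region!r}")

    def tss_relative(self, start: int) -> int | None:
        """Promoter coordinates reported as -len..-1 relative to the TSS (+1)."""
        if self.region != "promoter":
            return None
        return start - len(self.sequence) - 1


@dataclass
class MotifHit:
    pwm: str
    gene: str
    region: str
    start: int  # 1-based within the region, forward strand
    strand: str
    matched_forward: str
    rel_score: float
    canonical: bool | None = None


def read_jaspar_pfm(path, pseudocount: float = 0.8,
                    background=(0.25, 0.25, 0.25, 0.25)) -> list[Pwm]:
    """Parse a JASPAR PFM file (">ID name" headers + four base rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        name = m.matrix_id or m.name
        if m.matrix_id and m.name:
            name = f"{m.matrix_id}"
        out.append(Pwm(name, counts, pseudocount, background))
    if not out:
        raise MotifError(f"no matrices parsed from {path}")
    return out


def write_jaspar_pfm(pwms: list[Pwm], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{int(c) if float(c).is_integer() else c}" for c in p.counts[i])
                fh.write(f"{b} [ {row} ]\n")


def reverse_complement(seq: str) -> str:
    """Standard DNA reverse complement over the A/C/G/T/N alphabet."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise MotifError(f"illegal characters: {sorted(bad)}")
    return str(Seq(seq.upper()).reverse_complement())


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def relative_score(pwm: Pwm, window: str) -> float:
    """(S - S_min)/(S_max - S_min) for one window; any N forces 0."""
    if len(window) != pwm.length:
        raise MotifError(f"window length {len(window)} != motif length {pwm.length}")
    enc = _encode(window.upper())
    if (enc == 4).any():
        return 0.0
    s = float(pwm.log_odds[enc, np.arange(pwm.length)].sum())
    return (s - pwm.s_min) / (pwm.s_max - pwm.s_min)


def _scores_all_windows(pwm: Pwm, enc: np.ndarray) -> np.ndarray:
    L = pwm.length
    n_win = len(enc) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    padded = np.vstack([pwm.log_odds, np.full((1, L), -np.inf)])
    raw = padded[windows, np.arange(L)].sum(axis=1)
    rel = (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)
    rel[~np.isfinite(rel)] = 0.0  # windows containing N
    return rel[:n_win]


def scan_region(pwm: Pwm, region: RegionSpec, threshold: float = 0.85) -> list[MotifHit]:
    """Slide the PWM over both strands; emit hits with rel_score >= threshold.

    Starts are 1-based forward-strand coordinates; ``matched_forward`` is
    always the forward-strand substring, so a minus-strand hit matched the
    reverse complement of that substring.
    """
    import warnings

    if len(region.sequence) < pwm.length:
        warnings.warn(
            f"region shorter than motif {pwm.name}; no scan performed"
        )
        return []
    enc = _encode(region.sequence)
    fwd = _scores_all_windows(pwm, enc)
    rev = _scores_all_windows(pwm.reverse_complement(), enc)
    hits = []
    for start0 in range(len(fwd)):
        for strand, rel in (("+", fwd[start0]), ("-", rev[start0])):
            if rel >= threshold:
                hits.append(
                    MotifHit(
                        pwm=pwm.name,
                        gene=region.gene,
                        region=region.region,
                        start=start0 + 1,
                        strand=strand,
                        matched_forward=region.sequence[start0:start0 + pwm.length],
                        rel_score=float(rel),
                    )
                )
    return hits


def filter_canonical_hits(hits: list[MotifHit],
                          consensus_map: dict[str, tuple[str, str] | None]) -> list[MotifHit]:
    """Keep hits whose forward-strand match equals the canonical consensus.

    ``consensus_map`` maps a PWM name to its (forward, reverse) consensus
    strings, or to None for motifs without an established consensus, which
    pass through unfiltered (score-only).
    """
    out = []
    for h in hits:
        entry = consensus_map.get(h.pwm, None) if h.pwm in consensus_map else None
        if h.pwm in consensus_map and entry is not None:
            fwd, rev = entry
            if len(fwd) != len(h.matched_forward):
                raise MotifError(
                    f"consensus length {len(fwd)} != motif length for {h.pwm}"
                )
            keep = h.matched_forward in (fwd.upper(), rev.upper())
        else:
            keep = True  # no consensus entry: the VENTX-style exception
        if keep:
            h.canonical = h.pwm in consensus_map and entry is not None
            out.append(h)
    return out


def hits_table(hits: list[MotifHit]) -> pd.DataFrame:
    """BED-like table of hits (end inclusive)."""
    return pd.DataFrame(
        [
            {
                "gene": h.gene,
                "region": h.region,
                "start": h.start,
                "end": h.start + len(h.matched_forward) - 1,
                "pwm": h.pwm,
                "rel_score": h.rel_score,
                "strand": h.strand,
                "matched_forward": h.matched_forward,
                "canonical": h.canonical,
            }
            for h in hits
        ],
        columns=[
            "gene", "region", "start", "end", "pwm",
            "rel_score", "strand", "matched_forward", "canonical",
        ],
    )
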