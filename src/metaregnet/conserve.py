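"""Cross-species conservation of binding sites inside a multiple alignment.

An :class:`AlignedBlock` holds one gapped row per species with the human
(reference) row first.  Binding sites found on the ungapped human sequence
are projected into alignment columns, and each site receives a per-species,
per-position boolean conservation grid: a cell is true iff the species base
is identical to the human base (case-insensitive) and neither row has a gap
at that column.  A site is fully conserved when every cell is true.

A small Needleman-Wunsch global aligner (linear gap penalty, deterministic
tie-breaking) is included for pairwise desk-scale alignments; real multiple
alignments are ingested pre-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = "-"


class ConserveError(ValueError):
    pass


@dataclass
class AlignedBlock:
    """Equal-length gapped rows, reference (human) row first."""

    species: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ConserveError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ConserveError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if len(self.species) != len(self.rows):
            raise ConserveError("species/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def human_row(self) -> str:
        return self.rows[0]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.species, self.rows):
                fh.write(f">{name}\n{row}\n")


def read_aligned_fasta(path, reference: str | None = None) -> AlignedBlock:
    """Read an aligned FASTA; the reference row is moved first if named."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ConserveError(f"no sequences in {path}")
    names = [r.id for r in records]
    if reference is not None:
        if reference not in names:
            raise ConserveError(f"reference row {reference!r} missing from {path}")
        order = [names.index(reference)] + [
            i for i in range(len(names)) if names[i] != reference
        ]
        records = [records[i] for i in order]
    return AlignedBlock([r.id for r in records], [str(r.seq) for r in records])


def project_site_coordinates(block: AlignedBlock, human_start: int, length: int) -> tuple[int, int]:
    """Alignment column span (1-based, inclusive) covering an ungapped human site.

    ``human_start`` is the 1-based position on the ungapped human sequence.
    Gaps in the human row widen the span; the function is strictly increasing
    in ``human_start`` for a fixed block.
    """
    if human_start < 1 or length < 1:
        raise ConserveError("human_start and length must be >= 1")
    human = block.human_row
    cols = [i + 1 for i, b in enumerate(human) if b != GAP]
    if human_start + length - 1 > len(cols):
        raise ConserveError("site extends past the end of the human sequence")
    return cols[human_start - 1], cols[human_start + length - 2]


@dataclass
class SiteConservation:
    """Conservation grid of one site: (n_species - 1) x site-length booleans."""

    name: str
    human_start: int
    length: int
    species: list[str]  # non-human species, alignment order
    match: np.ndarray  # bool grid, rows = species, cols = human-base positions

    @property
    def fully_conserved(self) -> bool:
        return bool(self.match.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.match,
            index=self.species,
            columns=[f"pos{i + 1}" for i in range(self.match.shape[1])],
        )

    def render(self) -> str:
        """Text rendering: '*' conserved, '.' divergent, per species x position."""
        lines = [f"site {self.name} (human {self.human_start}, len {self.length})"]
        for sp, row in zip(self.species, self.match):
            lines.append(f"{sp:>24} " + "".join("*" if m else "." for m in row))
        return "\n".join(lines)


def site_conservation_matrix(block: AlignedBlock, span: tuple[int, int],
                             name: str = "", human_start: int = 0) -> SiteConservation:
    """Per-species, per-position identity with the human row over a column span.

    Columns where the human row carries a gap are skipped, so grid columns
    correspond to human bases.  A species gap counts as non-conserved.
    """
    lo, hi = span
    if not (1 <= lo <= hi <= block.length):
        raise ConserveError(f"invalid span {span} for alignment of length {block.length}")
    human = block.human_row
    cols = [c for c in range(lo - 1, hi) if human[c] != GAP]
    grid = np.zeros((len(block.rows) - 1, len(cols)), dtype=bool)
    for i, row in enumerate(block.rows[1:]):
        for j, c in enumerate(cols):
            grid[i, j] = row[c] == human[c] and row[c] != GAP
    return SiteConservation(
        name=name,
        human_start=human_start,
        length=len(cols),
        species=block.species[1:],
        match=grid,
    )


def pairwise_align_nw(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                      gap: float = -2.0) -> tuple[str, str, float]:
    """Global Needleman-Wunsch alignment with a linear gap penalty.

    Tie-breaking is deterministic: diagonal > up (gap in b) > left (gap in a).
    Empty inputs align against all gaps.  Returns (aligned_a, aligned_b, score).
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(b.encode(), np.uint8) == ord(a[i - 1]), match, mismatch)
        for j in range(1, m + 1):
            options = (
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )
            k = int(np.argmax(options))  # first max wins: diag > up > left
            score[i, j] = options[k]
            move[i, j] = k
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        k = move[i, j]
        if k == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif k == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])
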