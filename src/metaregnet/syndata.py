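"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline is built for: three
cohorts of tumor expression profiles on two platform models (negative-
binomial RNA-seq counts; batch-shifted microarray-like intensities), each
stratified into two histological subtypes, all driven by one planted signed
TF -> target network containing a hub focal target regulated by a small,
tightly co-activated regulator module (an EMT-program analog).  It also
plants consensus binding sites into a promoter + first-intron sequence,
simulates primate-like ortholog alignments with controlled per-site
divergence, and produces RT-qPCR / ChIP-qPCR Ct plates by inverting the
2^-ddCt and percent-input formulas.

Latent model.  Non-focal TF activities are i.i.d. standard normal per
sample.  The activities of the focal regulators share a common program
factor f with equicorrelation rho, sign-aligned with each planted edge:

    a_i = sigma_i * (sqrt(rho) f + sqrt(1 - rho) e_i),

so each regulator's marginal correlation with the focal target carries its
planted sign and is large enough to clear downstream effect-size filters
(with i.i.d. activities the marginal correlation of six additive regulators
is bounded by 1/sqrt(6) ~ 0.41 even at zero noise).  Every target's latent
value is sum(sign * strength * activity) + Gaussian noise.

All outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metaregnet.conserve import AlignedBlock
from metaregnet.dataio import ExpressionMatrix
from metaregnet.motif import Pwm, reverse_complement
from metaregnet.qpcr import CtTable

BASES = np.array(list("ACGT"))


class SynDataError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study conditions for the synthetic multi-cohort experiment.

    Defaults mirror the desk-scale design: 300 genes of which 30 are TFs,
    three cohorts (one counts platform, two intensity platforms) with 100
    samples per subtype, a power-law TF out-degree with exponent 2.5, and a
    six-member co-activated regulator module on the focal target.
    """

    n_genes: int = 300
    n_tfs: int = 30
    cohorts: tuple = (
        ("cohortA", "counts", (("diffuse", 100), ("intestinal", 100))),
        ("cohortB", "intensity", (("diffuse", 100), ("intestinal", 100))),
        ("cohortC", "intensity", (("diffuse", 100), ("intestinal", 100))),
    )
    out_degree_exponent: float = 2.5
    noise_sd: float = 0.3
    batch_shift_sd: float = 0.2
    seed: int = 0
    # focal regulator module
    n_focal_regulators: int = 6
    focal_strength: tuple[float, float] = (0.85, 0.95)
    focal_activity_corr: float = 0.8
    background_strength: tuple[float, float] = (0.4, 0.9)
    # platform models
    nb_dispersion: tuple[float, float] = (3.0, 0.05)  # alpha(mu) = a/mu + b
    base_log_mean: float = 5.5
    count_link_scale: float = 0.7
    intensity_scale: float = 0.6
    intensity_noise_sd: float = 0.12
    size_factor_sd: float = 0.2
    n_batches: int = 2

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise SynDataError("n_tfs must be < n_genes")
        for _, platform, sizes in self.cohorts:
            if platform not in ("counts", "intensity"):
                raise SynDataError(f"unknown platform {platform!r}")
            for _, n in sizes:
                if n < 8:
                    raise SynDataError("all per-subtype sample sizes must be >= 8")
        if not (0 <= self.focal_activity_corr < 1):
            raise SynDataError("focal_activity_corr must lie in [0, 1)")
        if self.n_focal_regulators > self.n_tfs:
            raise SynDataError("n_focal_regulators cannot exceed n_tfs")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def target_names(self) -> list[str]:
        n_targets = self.n_genes - self.n_tfs
        return ["FOCAL"] + [f"G{i + 1:04d}" for i in range(n_targets - 1)]

    @property
    def gene_names(self) -> list[str]:
        return self.tf_names + self.target_names


@dataclass
class GroundTruthNetwork:
    """The planted signed regulatory network."""

    tfs: list[str]
    edges: list[tuple[str, str, int, float]]  # (tf, target, sign, strength)
    focal_target: str
    focal_regulators: list[str]

    def __post_init__(self) -> None:
        pairs = [(t, g) for t, g, _, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            raise SynDataError("duplicate (tf, target) pairs in the truth network")
        if any(s <= 0 for _, _, _, s in self.edges):
            raise SynDataError("strengths must be positive")
        focal_edges = {t for t, g, _, _ in self.edges if g == self.focal_target}
        missing = set(self.focal_regulators) - focal_edges
        if missing:
            raise SynDataError(f"focal regulators without focal edge: {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "target", "sign", "strength"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_truth_network(config: SynthConfig) -> GroundTruthNetwork:
    """Plant a signed TF -> target network with power-law out-degrees.

    TF out-degrees follow a discrete power law with the configured exponent;
    ``n_focal_regulators`` TFs additionally form the regulator module of the
    focal target.  Deterministic under the config seed.
    """
    if config.out_degree_exponent <= 1:
        raise SynDataError("out_degree_exponent must exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    tfs = config.tf_names
    targets = config.target_names
    background_targets = [t for t in targets if t != "FOCAL"]
    max_deg = len(background_targets)

    degrees = rng.zipf(config.out_degree_exponent, size=config.n_tfs)
    degrees = np.minimum(degrees, max_deg)

    lo, hi = config.background_strength
    edges: list[tuple[str, str, int, float]] = []
    for tf, d in zip(tfs, degrees):
        chosen = rng.choice(background_targets, size=int(d), replace=False)
        for g in sorted(chosen):
            sign = int(rng.choice([-1, 1]))
            strength = float(rng.uniform(lo, hi))
            edges.append((tf, g, sign, strength))

    focal_regulators = sorted(
        rng.choice(tfs, size=config.n_focal_regulators, replace=False)
    )
    n_pos = int(np.ceil(config.n_focal_regulators * 2 / 3))
    focal_signs = np.array([1] * n_pos + [-1] * (config.n_focal_regulators - n_pos))
    rng.shuffle(focal_signs)
    flo, fhi = config.focal_strength
    for tf, sign in zip(focal_regulators, focal_signs):
        edges.append((tf, "FOCAL", int(sign), float(rng.uniform(flo, fhi))))

    return GroundTruthNetwork(list(tfs), edges, "FOCAL", list(focal_regulators))


def simulate_latents(truth: GroundTruthNetwork, config: SynthConfig, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Latent gene values (genes x samples) under the planted network."""
    genes = config.gene_names
    rho = config.focal_activity_corr
    focal_sign = {
        t: s for t, g, s, _ in truth.edges if g == truth.focal_target
    }

    program = rng.standard_normal(n)
    activities = {}
    for tf in truth.tfs:
        e = rng.standard_normal(n)
        if tf in focal_sign:
            activities[tf] = focal_sign[tf] * (
                np.sqrt(rho) * program + np.sqrt(1 - rho) * e
            )
        else:
            activities[tf] = e

    values = {tf: activities[tf] for tf in truth.tfs}
    by_target: dict[str, list] = {}
    for tf, g, s, w in truth.edges:
        by_target.setdefault(g, []).append((tf, s, w))
    for g in genes:
        if g in values:
            continue
        regs = by_target.get(g, [])
        base = sum(s * w * activities[tf] for tf, s, w in regs)
        noise = rng.standard_normal(n)
        if regs:
            values[g] = base + config.noise_sd * noise
        else:
            values[g] = noise
    return pd.DataFrame(
        np.vstack([values[g] for g in genes]), index=genes,
        columns=[f"s{i}" for i in range(n)],
    )


def simulate_cohorts(truth: GroundTruthNetwork, config: SynthConfig) -> list[ExpressionMatrix]:
    """Expression matrices for every configured cohort, with annotations.

    Counts platform: mu = s_j * exp(m_g + c * latent) with lognormal sample
    size factors s_j, then negative-binomial sampling with dispersion
    alpha(mu) = a/mu + b.  Intensity platform: log-scale intensities
    b_g + c_I * latent + per-(batch, gene) offsets + Gaussian measurement
    noise, with samples alternating over ``n_batches`` batches.
    """
    out = []
    for ci, (name, platform, sizes) in enumerate(config.cohorts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, ci]))
        frames, ann_rows = [], []
        gene_log_mean = config.base_log_mean + 0.5 * rng.standard_normal(config.n_genes)
        gene_base_intensity = 8.0 + rng.standard_normal(config.n_genes)
        batch_offsets = config.batch_shift_sd * rng.standard_normal(
            (config.n_batches, config.n_genes)
        )
        for subtype, n in sizes:
            lat = simulate_latents(truth, config, n, rng).to_numpy()
            sample_ids = [f"{name}_{subtype}_{i}" for i in range(n)]
            batches = [f"{name}_b{i % config.n_batches}" for i in range(n)]
            if platform == "counts":
                sf = np.exp(config.size_factor_sd * rng.standard_normal(n))
                mu = sf[None, :] * np.exp(
                    gene_log_mean[:, None] + config.count_link_scale * lat
                )
                a, b = config.nb_dispersion
                alpha = a / mu + b
                r = 1.0 / alpha
                p = r / (r + mu)
                vals = rng.negative_binomial(r, p)
            elif platform == "intensity":
                batch_idx = np.arange(n) % config.n_batches
                vals = (
                    gene_base_intensity[:, None]
                    + config.intensity_scale * lat
                    + batch_offsets[batch_idx].T
                    + config.intensity_noise_sd * rng.standard_normal(lat.shape)
                )
            else:  # pragma: no cover - validated in SynthConfig
                raise SynDataError(f"unknown platform {platform!r}")
            frames.append(pd.DataFrame(vals, index=config.gene_names, columns=sample_ids))
            for s, bt in zip(sample_ids, batches):
                ann_rows.append({"sample": s, "cohort": name, "subtype": subtype, "batch": bt})
        values = pd.concat(frames, axis=1)
        ann = pd.DataFrame(ann_rows).set_index("sample")
        out.append(ExpressionMatrix(values, platform, ann))
    return out


# ---------------------------------------------------------------------------
# promoter / alignment planting

@dataclass
class PlantedPromoter:
    """Promoter + first-intron sequence with recorded planted binding sites."""

    gene: str
    sequence: str
    planted_sites: list[tuple[str, int, str, str]]  # (motif, start, strand, consensus)
    region_labels: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for motif, start, strand, consensus in self.planted_sites:
            end = start + len(consensus) - 1
            if start < 1 or end > len(self.sequence):
                raise SynDataError(f"site {motif} at {start} outside the sequence")
            written = consensus if strand == "+" else reverse_complement(consensus)
            if self.sequence[start - 1:end] != written:
                raise SynDataError(f"planted site {motif} does not match its consensus")
        for name, (lo, hi) in self.region_labels.items():
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise SynDataError(f"region {name} outside sequence bounds")

    def region_sequence(self, region: str) -> str:
        lo, hi = self.region_labels[region]
        return self.sequence[lo - 1:hi]

    def sites_in_region(self, region: str) -> list[tuple[str, int, str, str]]:
        """Planted sites whose start falls in the region, start made region-relative."""
        lo, hi = self.region_labels[region]
        return [
            (m, s - lo + 1, st, c)
            for m, s, st, c in self.planted_sites
            if lo <= s <= hi
        ]


def plant_promoters(motifs, sites, seed: int = 0, promoter_len: int = 3000,
                    intron_len: int = 2186, gene: str = "FOCAL") -> PlantedPromoter:
    """Write consensus sites into a uniform-background promoter + intron.

    ``motifs`` is a list of (name, forward_consensus) pairs (the reverse form
    is derived); ``sites`` is a list of (motif_name, start, strand) with
    1-based starts on the concatenated sequence.  A minus-strand site writes
    the reverse complement of the consensus on the forward strand.
    Overlapping site requests raise an error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    total = promoter_len + intron_len
    by_name = {}
    for name, fwd in motifs:
        if set(fwd.upper()) - set("ACGT"):
            raise SynDataError(f"consensus for {name} must be over ACGT")
        by_name[name] = fwd.upper()
    seq = rng.choice(BASES, size=total)

    occupied: list[tuple[int, int]] = []
    planted = []
    for motif_name, start, strand in sites:
        consensus = by_name[motif_name]
        end = start + len(consensus) - 1
        if start < 1 or end > total:
            raise SynDataError(f"site {motif_name} at {start} outside the sequence")
        for lo, hi in occupied:
            if start <= hi and end >= lo:
                raise SynDataError(
                    f"site {motif_name} at {start} overlaps a previous site"
                )
        occupied.append((start, end))
        written = consensus if strand == "+" else reverse_complement(consensus)
        seq[start - 1:end] = list(written)
        planted.append((motif_name, start, strand, consensus))

    return PlantedPromoter(
        gene=gene,
        sequence="".join(seq),
        planted_sites=planted,
        region_labels={
            "promoter": (1, promoter_len),
            "intron1": (promoter_len + 1, total),
        },
    )


def simulate_ortholog_alignment(promoter: PlantedPromoter, n_species: int,
                                rate_outside: float, rate_inside: float,
                                seed: int = 0) -> AlignedBlock:
    """Gap-free primate-like ortholog panel with controlled divergence.

    ``n_species`` non-human rows are derived from the (unchanged) human row
    by i.i.d. per-site substitutions: probability ``rate_inside`` within
    planted binding sites and ``rate_outside`` elsewhere.  A substitution
    always changes the base, so the rates are mismatch probabilities.
    """
    if n_species < 1:
        raise SynDataError("need at least one non-human species")
    for r in (rate_outside, rate_inside):
        if not (0 <= r <= 1):
            raise SynDataError("substitution rates must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    human = np.array(list(promoter.sequence))
    L = len(human)
    inside = np.zeros(L, dtype=bool)
    for _, start, _, consensus in promoter.planted_sites:
        inside[start - 1:start - 1 + len(consensus)] = True
    rates = np.where(inside, rate_inside, rate_outside)

    base_idx = {b: i for i, b in enumerate("ACGT")}
    human_idx = np.array([base_idx[b] for b in human])
    species, rows = ["human"], [promoter.sequence]
    for s in range(n_species):
        mutate = rng.random(L) < rates
        shift = rng.integers(1, 4, size=L)  # always lands on a different base
        new_idx = np.where(mutate, (human_idx + shift) % 4, human_idx)
        rows.append("".join(BASES[new_idx]))
        species.append(f"species{s + 1:02d}")
    return AlignedBlock(species, rows)


# ---------------------------------------------------------------------------
# qPCR plate simulation

@dataclass
class PlateDesign:
    """Layout of the RT and ChIP plates."""

    cell_lines: tuple[str, ...] = ("HIGH1", "LOW1", "LOW2")
    calibrator: str = "LOW2"
    target_gene: str = "FOCAL"
    reference_genes: tuple[str, ...] = ("REF1", "REF2")
    reference_ct: tuple[float, ...] = (18.0, 20.0)
    calibrator_dct: float = 5.0
    sites: tuple[tuple[str, str], ...] = (("P3", "AB1"),)  # (site, antibody)
    igg_antibody: str = "IgG"
    igg_percent: float = 0.05
    input_ct: float = 24.0
    input_fraction: float = 0.04
    replicates: int = 3


def simulate_qpcr_plates(design: PlateDesign, true_folds: dict[str, float],
                         true_percent_inputs: dict[tuple[str, str], float],
                         ct_noise_sd: float = 0.0, seed: int = 0) -> tuple[CtTable, CtTable]:
    """Invert the 2^-ddCt and percent-input formulas into Ct plates.

    ``true_folds`` maps cell line -> expression fold relative to the
    calibrator; ``true_percent_inputs`` maps (cell line, site) -> the net
    (IgG-subtracted) % input of the specific antibody.  Gaussian Ct noise of
    sd ``ct_noise_sd`` is added per replicate; at zero noise the analysis
    recovers the planted values exactly.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise SynDataError("true fold values must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    ref_ct = dict(zip(design.reference_genes, design.reference_ct))

    rt_rows = []
    for line in design.cell_lines:
        fold = true_folds[line]
        for gene, ct0 in ref_ct.items():
            for rep in range(design.replicates):
                rt_rows.append(
                    {"cell_line": line, "gene": gene, "replicate": rep,
                     "ct": ct0 + ct_noise_sd * rng.standard_normal()}
                )
        target_ct = (
            float(np.mean(list(ref_ct.values())))
            + design.calibrator_dct
            - np.log2(fold)
        )
        for rep in range(design.replicates):
            rt_rows.append(
                {"cell_line": line, "gene": design.target_gene, "replicate": rep,
                 "ct": target_ct + ct_noise_sd * rng.standard_normal()}
            )
    rt = CtTable(pd.DataFrame(rt_rows), assay="RT")

    dilution = np.log2(1.0 / design.input_fraction)
    chip_rows = []
    for line in design.cell_lines:
        for site, antibody in design.sites:
            net = true_percent_inputs[(line, site)]
            for ab, pct in ((antibody, net + design.igg_percent),
                            (design.igg_antibody, design.igg_percent)):
                if pct <= 0:
                    raise SynDataError("planted % input must be positive")
                ct_ip = design.input_ct - dilution - np.log2(pct / 100.0)
                for rep in range(design.replicates):
                    chip_rows.append(
                        {"cell_line": line, "site": site, "antibody": ab,
                         "replicate": rep,
                         "ct": ct_ip + ct_noise_sd * rng.standard_normal()}
                    )
            for rep in range(design.replicates):
                chip_rows.append(
                    {"cell_line": line, "site": site, "antibody": "input",
                     "replicate": rep,
                     "ct": design.input_ct + ct_noise_sd * rng.standard_normal()}
                )
    chip = CtTable(pd.DataFrame(chip_rows), assay="ChIP",
                   input_fraction=design.input_fraction)
    return rt, chip


# ---------------------------------------------------------------------------
# synthetic motif matrices and gene sets for the end-to-end pipeline

def make_tf_motifs(tfs, seed: int = 0, length: int = 8,
                   dominant: int = 85, minor: int = 5) -> tuple[list[Pwm], dict]:
    """One concentrated synthetic PWM + consensus pair per TF.

    Each column gives ``dominant`` counts to the consensus base and ``minor``
    to the rest, so the consensus scores a relative score of exactly 1.
    Returns (pwms, consensus_map) with the map in the forward/reverse form
    the canonical-site filter expects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    pwms, consensus_map = [], {}
    for tf in tfs:
        cons = "".join(rng.choice(BASES, size=length))
        counts = np.full((4, length), float(minor))
        for j, b in enumerate(cons):
            counts["ACGT".index(b), j] = float(dominant)
        pwms.append(Pwm(tf, counts))
        consensus_map[tf] = (cons, reverse_complement(cons))
    return pwms, consensus_map


def make_gene_sets(truth: GroundTruthNetwork, universe, seed: int = 0,
                   n_random_sets: int = 20, random_set_size: int = 40):
    """A planted program gene set (the focal regulators' targets) + random sets."""
    from metaregnet.enrich import GeneSetCollection

    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    universe = list(universe)
    program = sorted(
        {g for tf, g, _, _ in truth.edges if tf in truth.focal_regulators}
        | {truth.focal_target}
    )
    sets = {"PLANTED_PROGRAM": program}
    for i in range(n_random_sets):
        sets[f"RANDOM_{i + 1:02d}"] = sorted(
            rng.choice(universe, size=min(random_set_size, len(universe)), replace=False)
        )
    return GeneSetCollection(sets, source="synthetic")
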