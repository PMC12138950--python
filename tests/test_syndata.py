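import numpy as np
import pandas as pd
import pytest

from metaregnet import syndata
from metaregnet.consensus import powerlaw_fit_ks
from metaregnet.conserve import site_conservation_matrix
from metaregnet.motif import RegionSpec, filter_canonical_hits, scan_region
from metaregnet.syndata import (
    PlantedPromoter,
    SynDataError,
    SynthConfig,
    generate_truth_network,
    make_tf_motifs,
    plant_promoters,
    simulate_cohorts,
    simulate_latents,
    simulate_ortholog_alignment,
)
from metaregnet.trn import mutual_information


def small_config(**kw):
    defaults = dict(
        n_genes=40, n_tfs=8, n_focal_regulators=3, seed=5,
        cohorts=(("c1", "counts", (("diffuse", 30),)),),
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestTruthNetwork:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        t1 = generate_truth_network(cfg)
        t2 = generate_truth_network(cfg)
        assert t1.edges == t2.edges and t1.focal_regulators == t2.focal_regulators

    def test_single_tf_owns_every_edge(self):
        cfg = small_config(n_tfs=1, n_focal_regulators=1)
        truth = generate_truth_network(cfg)
        assert {e[0] for e in truth.edges} == {"TF001"}

    def test_invalid_exponent_rejected(self):
        with pytest.raises(SynDataError, match="exponent"):
            generate_truth_network(small_config(out_degree_exponent=1.0))

    def test_out_degree_exponent_refit_by_mle(self):
        cfg = SynthConfig(n_genes=2000, n_tfs=200, out_degree_exponent=2.5, seed=2)
        truth = generate_truth_network(cfg)
        degrees = pd.DataFrame(truth.edges, columns=list("abcd")).groupby("a").size()
        fit = powerlaw_fit_ks(degrees.to_numpy(), n_boot=0, x_min=1)
        assert abs(fit.alpha - 2.5) <= 0.3

    def test_focal_regulators_have_focal_edges(self):
        truth = generate_truth_network(small_config())
        focal_tfs = {t for t, g, _, _ in truth.edges if g == truth.focal_target}
        assert set(truth.focal_regulators) <= focal_tfs


class TestLatents:
    def test_zero_noise_single_edge_correlation_is_plus_one(self):
        cfg = small_config(noise_sd=0.0, n_focal_regulators=1,
                           focal_activity_corr=0.0)
        truth = syndata.GroundTruthNetwork(
            cfg.tf_names, [("TF001", "FOCAL", 1, 0.8)], "FOCAL", ["TF001"]
        )
        lat = simulate_latents(truth, cfg, 50, np.random.default_rng(0))
        r = np.corrcoef(lat.loc["TF001"], lat.loc["FOCAL"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_noise_negative_edge_correlation_is_minus_one(self):
        cfg = small_config(noise_sd=0.0, n_focal_regulators=1,
                           focal_activity_corr=0.0)
        truth = syndata.GroundTruthNetwork(
            cfg.tf_names, [("TF001", "FOCAL", -1, 0.8)], "FOCAL", ["TF001"]
        )
        lat = simulate_latents(truth, cfg, 50, np.random.default_rng(0))
        r = np.corrcoef(lat.loc["TF001"], lat.loc["FOCAL"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_focal_regulators_rank_in_top_mi_decile(self):
        cfg = SynthConfig(seed=4)
        truth = generate_truth_network(cfg)
        m = simulate_cohorts(truth, cfg)[0]
        sub = m.values.iloc[:, :100]  # one subtype block
        mis = {
            tf: mutual_information(sub.loc[tf].to_numpy(float),
                                   sub.loc["FOCAL"].to_numpy(float))
            for tf in cfg.tf_names
        }
        ranked = sorted(mis, key=mis.get, reverse=True)
        top = set(ranked[:max(len(ranked) // 10, len(truth.focal_regulators))])
        assert set(truth.focal_regulators) <= top


class TestCohorts:
    def test_byte_identical_under_seed(self):
        cfg = small_config()
        truth = generate_truth_network(cfg)
        a = simulate_cohorts(truth, cfg)[0]
        b = simulate_cohorts(truth, cfg)[0]
        assert a.values.to_csv() == b.values.to_csv()
        assert a.annotations.to_csv() == b.annotations.to_csv()

    def test_unknown_platform_rejected(self):
        with pytest.raises(SynDataError, match="platform"):
            small_config(cohorts=(("c", "banana", (("diffuse", 10),)),))

    def test_annotations_cover_all_samples(self):
        cfg = small_config(cohorts=(
            ("c", "intensity", (("diffuse", 12), ("intestinal", 9))),
        ))
        truth = generate_truth_network(cfg)
        m = simulate_cohorts(truth, cfg)[0]
        assert m.annotations["subtype"].value_counts().to_dict() == {
            "diffuse": 12, "intestinal": 9,
        }


class TestPlantedPromoters:
    MOTIFS = [("TWIST1", "CATCTG"), ("SNAI2", "CACCTG")]

    def test_forward_site_written_verbatim(self):
        p = plant_promoters(self.MOTIFS, [("SNAI2", 100, "+")], seed=1)
        assert p.sequence[99:105] == "CACCTG"

    def test_minus_strand_site_is_reverse_complement(self):
        p = plant_promoters(self.MOTIFS, [("TWIST1", 50, "-")], seed=1)
        assert p.sequence[49:55] == "CAGATG"

    def test_overlapping_sites_rejected(self):
        with pytest.raises(SynDataError, match="overlap"):
            plant_promoters(self.MOTIFS, [("SNAI2", 100, "+"), ("TWIST1", 103, "+")])

    def test_region_labels_partition_sequence(self):
        p = plant_promoters(self.MOTIFS, [], promoter_len=3000, intron_len=2186)
        assert p.region_labels["promoter"] == (1, 3000)
        assert p.region_labels["intron1"] == (3001, 5186)
        assert len(p.sequence) == 5186

    def test_background_false_positive_rate_matches_enumeration(self):
        # scan of a site-free background: canonical hits == exact substring count
        pwms, cmap = make_tf_motifs(["TF001"], seed=9, length=6)
        p = plant_promoters([("TF001", cmap["TF001"][0])], [], seed=9)
        region = RegionSpec("FOCAL", "promoter", p.region_sequence("promoter"))
        hits = filter_canonical_hits(scan_region(pwms[0], region, 0.85), cmap)
        fwd, rev = cmap["TF001"]
        seq = region.sequence
        expected = sum(
            seq[i:i + 6] in {fwd, rev} for i in range(len(seq) - 5)
        ) * (2 if fwd != rev else 1)
        # each matching substring is reported once per matching strand
        observed = len(hits)
        assert observed == expected


class TestOrthologAlignment:
    def _promoter(self):
        return plant_promoters(
            [("SNAI2", "CACCTG")], [("SNAI2", 100, "+")], seed=3,
            promoter_len=400, intron_len=100,
        )

    def test_human_row_unchanged_and_zero_rate_identical(self):
        p = self._promoter()
        block = simulate_ortholog_alignment(p, 4, 0.0, 0.0, seed=1)
        assert block.rows[0] == p.sequence
        assert all(r == p.sequence for r in block.rows[1:])

    def test_zero_inside_rate_keeps_sites_fully_conserved(self):
        p = self._promoter()
        block = simulate_ortholog_alignment(p, 6, 0.3, 0.0, seed=1)
        sc = site_conservation_matrix(block, (100, 105))
        assert sc.fully_conserved

    def test_unit_outside_rate_mutates_every_background_base(self):
        p = self._promoter()
        block = simulate_ortholog_alignment(p, 2, 1.0, 0.0, seed=1)
        human = np.array(list(block.rows[0]))
        other = np.array(list(block.rows[1]))
        outside = np.ones(len(human), dtype=bool)
        outside[99:105] = False
        assert (human[outside] != other[outside]).all()
        assert (human[~outside] == other[~outside]).all()

    def test_match_fraction_tracks_binomial_expectation(self):
        p = self._promoter()
        rate = 0.3
        matches, total = 0, 0
        for seed in range(30):
            block = simulate_ortholog_alignment(p, 11, rate, rate, seed=seed)
            sc = site_conservation_matrix(block, (100, 105))
            matches += sc.match.sum()
            total += sc.match.size
        frac = matches / total
        sd = np.sqrt((1 - rate) * rate / total)
        assert abs(frac - (1 - rate)) < 4 * sd

    def test_fully_conserved_site_count_matches_closed_form(self):
        # per-site full conservation probability is (1-rate)^(L * n_species)
        p = self._promoter()
        rate, n_species, L = 0.02, 11, 6
        expected = (1 - rate) ** (L * n_species)
        hits = 0
        reps = 1000
        for seed in range(reps):
            block = simulate_ortholog_alignment(p, n_species, 0.5, rate, seed=seed)
            hits += site_conservation_matrix(block, (100, 105)).fully_conserved
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 4 * se

    def test_no_species_rejected(self):
        with pytest.raises(SynDataError):
            simulate_ortholog_alignment(self._promoter(), 0, 0.1, 0.1)


class TestTfMotifs:
    def test_consensus_scores_one_and_map_is_reverse_complement(self):
        pwms, cmap = make_tf_motifs(["TF001", "TF002"], seed=1)
        from metaregnet.motif import relative_score, reverse_complement

        for pwm in pwms:
            fwd, rev = cmap[pwm.name]
            assert relative_score(pwm, fwd) == pytest.approx(1.0)
            assert rev == reverse_complement(fwd)
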