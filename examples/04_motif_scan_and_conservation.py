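"""Scan a promoter for canonical binding sites and check their conservation.

Plants two consensus sites (one on each strand) into a 3-kb promoter +
first intron, scans both strands at the 85% relative-score threshold,
filters to canonical matches, and classifies per-species conservation in a
simulated 11-species primate-like alignment.
"""

import numpy as np

from metaregnet import conserve, syndata
from metaregnet.motif import (
    Pwm,
    RegionSpec,
    filter_canonical_hits,
    reverse_complement,
    scan_region,
)

motifs = [("TWIST1_like", "CATCTG"), ("SNAI2_like", "CACCTG")]
consensus_map = {name: (fwd, reverse_complement(fwd)) for name, fwd in motifs}

promoter = syndata.plant_promoters(
    motifs, [("TWIST1_like", 420, "+"), ("SNAI2_like", 3150, "-")], seed=5
)

pwm_by = {}
for name, cons in motifs:
    counts = np.full((4, len(cons)), 2.0)
    for j, b in enumerate(cons):
        counts["ACGT".index(b), j] = 90.0
    pwm_by[name] = Pwm(name, counts)

block = syndata.simulate_ortholog_alignment(promoter, n_species=11,
                                            rate_outside=0.12, rate_inside=0.0,
                                            seed=5)
offsets = {r: lo for r, (lo, hi) in promoter.region_labels.items()}
for region_name in ("promoter", "intron1"):
    region = RegionSpec("FOCAL", region_name, promoter.region_sequence(region_name))
    for name, pwm in pwm_by.items():
        hits = filter_canonical_hits(scan_region(pwm, region, 0.85), consensus_map)
        for h in hits:
            abs_start = offsets[region_name] + h.start - 1
            span = conserve.project_site_coordinates(block, abs_start, pwm.length)
            sc = conserve.site_conservation_matrix(block, span)
            print(f"{name} hit in {region_name} at {h.start} ({h.strand}): "
                  f"{h.matched_forward}, rel score {h.rel_score:.2f}, "
                  f"fully conserved across 11 species: {sc.fully_conserved}")
# The two planted sites (promoter 420 "+", intron 150 "-") come back fully
# conserved because planted positions mutate at rate 0; the remaining hits are
# chance 6-mer matches in the background, which diverges at 12% per species --
# exactly the contrast the conservation filter exploits.
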