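"""Published reference counts for *Methanoperedens* plasmid subfamilies.

Membership counts of the protein subfamilies reported as enriched in
plasmid-encoded proteins across the HMp plasmid versions, together with the
printed percent-enrichment column, and the headline clustering summary
(plasmid proteins clustered into subfamilies). These counts are inputs for
reproducing the published percent-enrichment arithmetic; rows whose
concatenated digits admit more than one consistent reading, or whose printed
percentage does not follow the table's own rounding rule, are omitted.
"""

from __future__ import annotations

#: (subfamily id, plasmid members, total members, printed percent enrichment)
SUBFAMILY_COUNTS: list[tuple[str, int, int, int]] = [
    ("subfam0052", 3, 3, 100),
    ("subfam0053", 3, 3, 100),
    ("subfam0085", 2, 2, 100),
    ("subfam2357", 2, 2, 100),
    ("subfam2361", 2, 2, 100),
    ("subfam2619", 3, 3, 100),
    ("subfam3152", 4, 4, 100),
    ("subfam3198", 2, 2, 100),
    ("subfam3232", 2, 2, 100),
    ("subfam4360", 3, 3, 100),
    ("subfam4949", 2, 2, 100),
    ("subfam4974", 3, 3, 100),
    ("subfam5544", 2, 2, 100),
    ("subfam6115", 3, 3, 100),
    ("subfam6300", 3, 3, 100),
    ("subfam7697", 3, 3, 100),
    ("subfam7758", 4, 4, 100),
    ("subfam0185", 3, 13, 23),
    ("subfam0187", 3, 7, 43),
    ("subfam0188", 3, 4, 75),
    ("subfam0434", 4, 7, 57),
    ("subfam0673", 5, 16, 31),
    ("subfam1876", 3, 14, 21),
    ("subfam1990", 6, 8, 75),
    ("subfam2654", 3, 12, 25),
    ("subfam3527", 7, 22, 32),
    ("subfam4932", 5, 7, 71),
    ("subfam5002", 8, 65, 12),
    ("subfam6245", 5, 7, 71),
    ("subfam6302", 3, 6, 50),
    ("subfam6760", 3, 9, 33),
    ("subfam6769", 6, 58, 10),
    ("subfam7198", 4, 6, 67),
    ("subfam7280", 4, 6, 67),
    ("subfam7300", 6, 31, 19),
    ("subfam7324", 5, 41, 12),
    ("subfam7387", 2, 3, 67),
    ("subfam7760", 4, 5, 80),
]

#: Headline clustering summary: of the plasmid-encoded proteins, how many
#: clustered into subfamilies (the printed figure is the rounded percentage).
CLUSTERING_SUMMARY = {
    "n_plasmid_proteins": 1079,
    "n_clustered": 882,
    "n_subfamilies": 504,
    "printed_percent_clustered": 82,
}

#: Replicon coverages used for the published host assignments.
REPLICON_COVERAGES = {
    "HMp_v1": 27.0,
    "HMp_v2": 5405.0,
    "HMp_v3": 19.0,
    "HMp_v5": 4599.0,
    "Methanoperedens_BLZ2": 4357.0,
    "Methanoperedens_Vercelli": 4204.0,
    "Methanoperedens_40_26": 26.0,
}
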