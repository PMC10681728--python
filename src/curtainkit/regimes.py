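"""Wild-type reference regimes emulated by the synthetic-data generator.

These are the published single-molecule and genetic operating points for the
untagged/wild-type Rdh54 system; the generator uses them as ground-truth
inputs so that parameter-recovery suites exercise the estimators under
realistic conditions.
"""

#: Net translocation kinematics of wild-type Rdh54-mCherry on dsDNA
#: (mean +/- SD over N observed tracks).
WT_TRANSLOCATION = {
    "mean_velocity_bp_s": 81.7,
    "sd_velocity_bp_s": 51.0,
    "mean_track_length_kb": 12.1,
    "sd_track_length_kb": 7.1,
    "n_tracks": 110,
}

#: Photobleaching step-count mixture of directly countable Rdh54 foci:
#: dimers dominate (59%), tetramers second (26%), monomers and trimers rare.
STEP_COUNT_MIXTURE = {1: 0.07, 2: 0.59, 3: 0.07, 4: 0.26}

#: Median copies per cluster for intensity-sized wild-type foci, and the
#: cohort size over which that median was taken.
CLUSTER_SIZE_MEDIAN = 7.06
CLUSTER_FIELD_N = 201

#: Two-color self-mixing: fraction of mCherry-tagged foci colocalized with
#: GFP-tagged foci, over N scored foci.
COLOC_FRACTION_WT = 0.93
COLOC_N = 142

#: Pearson correlation between the two channels' focus intensities, for
#: active kinase and for the kinase-dead (D339A) partner.
INTENSITY_CORR_WT = 0.7
INTENSITY_CORR_KINASE_DEAD = 0.2

#: Percent survival of wild-type cells after MMS treatment.
SURVIVAL_WT_PCT = 41.6

#: Wild-type interhomolog gene-conversion frequency (Leu+ per cell).
CONVERSION_FREQ_WT = 1.03e-5

#: Wild-type crossover / non-crossover shares among sectored colonies (%).
OUTCOME_PCT_WT = {"CO": 53.0, "NCO": 41.0}
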