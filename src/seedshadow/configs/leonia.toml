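# Dense understory tree scenario ("leonia-like"):
# 5-11 adults/ha, 11 loci, slow gut passage (120-240 min), tiny crops
# visited in trap-lining sequences, background fruit sources for energy.

[scenario]
base = "leonia"
home_range_area_ha = 38.1
adult_density_per_ha = 8.0
n_loci = 11
alleles_per_locus = 8
gut_window_min = [120.0, 240.0]
n_days = 31

[scenario.true_kernel]
family = "exponential"
mean_m = 200.0

[ibm]
n_days = 200
gut_window_min = [120.0, 240.0]
revisit_cap = 1
crop_bouts_per_day = 2

[parentage]
n_candidates = 194
proportion_sampled = 0.15
genotyping_error = 0.01
min_typed_loci = 6
n_confidence_sims = 10000

[run]
n_offspring = 150
n_seed_coats = 120
osd_events_per_day = 3
n_gut_sample = 6
n_boot_mean = 10000
n_boot_kernel = 100
n_other_trees = 40
candidate_fraction = 0.15
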