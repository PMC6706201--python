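# Sparse canopy tree scenario ("parkia-like"):
# ~1 adult/ha in a ~39 ha home range, 9 microsatellite loci, fast gut
# passage (30-240 min), large fruit crops revisited up to 4x/day.

[scenario]
base = "parkia"
home_range_area_ha = 38.9
adult_density_per_ha = 1.0
n_loci = 9
alleles_per_locus = 8
gut_window_min = [30.0, 240.0]
n_days = 31

[scenario.true_kernel]
family = "exponential"
mean_m = 200.0

[ibm]
n_days = 200
gut_window_min = [30.0, 240.0]
revisit_cap = 4
crop_bouts_per_day = 8

[parentage]
n_candidates = 33
proportion_sampled = 0.99
genotyping_error = 0.01
min_typed_loci = 5
n_confidence_sims = 10000

[run]
n_offspring = 150
n_seed_coats = 120
osd_events_per_day = 3
n_gut_sample = 60
n_boot_mean = 10000
n_boot_kernel = 100
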