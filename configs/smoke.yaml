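# Desk-test cohort: 5 samples (10 haplotypes) on a 6 Mb two-chromosome
# layout; the full pipeline completes in a few seconds.
n_afr_samples: 2
n_nonafr_samples: 3
chrom_lengths:
  chr1: 3000000
  chr2: 3000000
n_sd_pairs: 50
n_afr_regions: 6
afr_region_length: 8000
n_families: 12
n_shifted_families: 3
n_depth_samples: 4
max_length: 30000
n_planted_families: 2
n_background_reads: 15
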