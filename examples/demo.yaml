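# Desk-scale synthetic study: 20 hairpin loci, 18 libraries
# (8 annual-diapause, 7 non-annual, 3 diapause-skipped)
out_dir: scratch/demo_run
seed: 11
n_loci: 20
planted_dem_fraction: 0.15
planted_lfc: 2.0
planted_switch_loci: 2
genome_length: 60000
coverage: 2.0
copies_annual: 6
copies_nonannual: 18
n_species_per_group: 3
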