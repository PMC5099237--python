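# Every threshold used by the pipeline, in one place.
min_contig_len: 1000          # contigs shorter than this are discarded (inclusive keep)
min_spacers: 2                # validated arrays need at least this many spacers
rms_min_coverage: 0.70        # REBASE hit query coverage (inclusive)
rms_max_gene_distance: 4      # REase-MTase pairing window, gene ordinals
rms_cluster_window: 4         # same-type system merge window, gene ordinals
cas_max_gene_gap: 5           # array-to-cas-locus adjacency window, gene ordinals
enrichment_factor: 1.5        # fold-change for sponge/seawater enrichment
target_evalue_max: 0.1        # spacer target search E-value cutoff
target_word_size: 7           # exact seed word size for the target search
repeat_reference_evalue_max: 0.01  # repeat-vs-reference match cutoff
lca_top_score_fraction: 0.1   # retain hits within 10% of the best bit score
cas_mapping_path: null        # null -> packaged cas_mapping.tsv
cas_subtypes_path: null       # null -> packaged cas_subtypes.tsv
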