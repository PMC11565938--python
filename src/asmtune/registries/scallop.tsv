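# Scallop v0.10.2 tunable parameters: name, default, kind
# warmup_step left blank -> derived by the package's step convention
name	default	kind	warmup_step
uniquely_mapped_only	0	binary
use_second_alignment	0	binary
max_dp_table_size	10000	integer
max_edit_distance	10	integer
max_num_exons	1000	integer
min_bundle_gap	50	integer
min_exon_length	20	integer
min_flank_length	3	integer
min_mapping_quality	1	integer
min_num_hits_in_bundle	20	integer
min_router_count	1	integer
min_splice_boundary_hits	1	integer
min_subregion_gap	3	integer
min_subregion_length	15	integer
min_transcript_length_base	150	integer
min_transcript_length_increase	50	integer
max_intron_contamination_coverage	2	float
min_subregion_overlap	1.5	float
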