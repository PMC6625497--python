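# Small EDAM-style subset (format/data axes, is-a links only) bundled for
# offline tests and demos. Columns: term_id<TAB>label<TAB>parent,parent
data_0006	Data
data_2044	Sequence	data_0006
data_2977	Nucleic acid sequence	data_2044
data_2976	Protein sequence	data_2044
data_0850	Sequence set	data_0006
data_1234	Sequence set (nucleic acid)	data_0850
data_0863	Sequence alignment	data_0006
data_1383	Nucleic acid sequence alignment	data_0863
data_3498	Sequence variations	data_0006
data_0582	Annotation	data_0006
data_1255	Sequence feature	data_0582
data_2012	Sequence coordinates	data_0006
data_1016	Sequence position	data_2012
data_1017	Sequence range	data_2012
format_1915	Format
format_2330	Textual format	format_1915
format_2333	Binary format	format_1915
format_2332	XML	format_2330
format_2006	Sequence record format	format_1915
format_2551	Sequence record format (text)	format_2006,format_2330
format_2552	Sequence record format (XML)	format_2006,format_2332
format_1929	FASTA	format_2551
format_2200	FASTA-like (text)	format_2551
format_2536	FASTQ-like format	format_2006
format_2182	FASTQ-like format (text)	format_2536,format_2330
format_1930	FASTQ	format_2182
format_1931	FASTQ-illumina	format_1930
format_1932	FASTQ-sanger	format_1930
format_1933	FASTQ-solexa	format_1930
format_2055	Sequence assembly format	format_1915
format_2561	Sequence assembly format (text)	format_2055,format_2330
format_2920	Alignment format (pair only)	format_1915
format_2077	Alignment format	format_1915
format_2554	Alignment format (text)	format_2077,format_2330
format_2555	Alignment format (XML)	format_2077,format_2332
format_2573	SAM	format_2554
format_2572	BAM	format_2077,format_2333
format_3462	CRAM	format_2077,format_2333
format_2919	Sequence annotation track format	format_1915
format_3003	BED	format_2919,format_2330
format_3004	bigBed	format_2919,format_2333
format_2305	GFF	format_2919,format_2330
format_1975	GFF3	format_2305
format_2306	GTF	format_2305
format_3016	VCF	format_2330
format_3020	BCF	format_2333
format_3475	TSV	format_2330
format_3752	CSV	format_2330
format_3464	JSON	format_2330
format_3750	YAML	format_2330
format_1964	plain text format (unformatted)	format_2330
format_2549	OBO	format_2330
format_3876	HDF5	format_2333
format_3590	HDF	format_2333
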