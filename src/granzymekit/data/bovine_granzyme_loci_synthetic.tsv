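# Cattle (UMD3.1) granzyme locus table. Locus intervals (interval_start,
# interval_end) and the gene complement, order and biotypes are those of the
# published cattle assembly annotation; the per-gene coordinates within each
# interval are SYNTHETIC (schematic, evenly spaced placeholders) because the
# individual gene coordinates are not distributed with this package. Spans
# and gene counts derived from this table are exact; intergenic distances
# within a locus are schematic. trypsin-like locus: GZMA and GZMK anchor the
# interval boundaries so the printed A--K separation equals the interval span.
species	chromosome	locus	interval_start	interval_end	gene_id	gene_start	gene_end	strand	biotype
cattle	20	trypsin_like	24033747	24107687	GZMA	24033747	24038747	+	functional
cattle	20	trypsin_like	24033747	24107687	GZMO	24068000	24072500	-	functional
cattle	20	trypsin_like	24033747	24107687	GZMK	24102000	24107687	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	CMA1A	35113000	35116000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	CMA1B	35128000	35131000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	DDN2	35143000	35146000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	DDN3	35158000	35161000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	CTSG1	35173000	35176000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	CTSG2	35188000	35191000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	GZMH	35203000	35206000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	DDN4	35218000	35221000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	DDN1	35233000	35236000	+	functional
cattle	21	chymotrypsin_like	35112322	35267979	GZMB	35248000	35251000	+	functional
cattle	7	metase_like	44797942	45032845	GZMM	44797942	44803000	+	functional
cattle	7	metase_like	44797942	45032845	ZAU1	44968000	44972000	+	functional
cattle	7	metase_like	44797942	45032845	PRTN3	44980000	44984000	+	functional
cattle	7	metase_like	44797942	45032845	ELANE	44992000	44996000	+	functional
cattle	7	metase_like	44797942	45032845	CFD	45028000	45032845	+	functional
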